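"""Synthetic cohort generator: determinism, truth bookkeeping, and the
statistical structure downstream stages rely on."""

from __future__ import annotations

import numpy as np
import pytest

from mutscape.consensus import intersect_callers
from mutscape.simulate import (
    SimulationConfig, default_design, simulate_cohort, simulate_genome,
    simulate_rna, simulate_truth,
)
from mutscape.spectrum import collapse_class


class TestGenome:
    def test_deterministic_given_seed(self):
        a, _ = simulate_genome(SimulationConfig(genome_length=50_000, rng_seed=7))
        b, _ = simulate_genome(SimulationConfig(genome_length=50_000, rng_seed=7))
        assert a.sequences == b.sequences

    def test_gene_fraction_near_target(self):
        _, ann = simulate_genome(SimulationConfig(genome_length=2_000_000,
                                                  rng_seed=2))
        frac = ann.genome_fraction("genic")
        assert 0.25 <= frac <= 0.35

    def test_zero_gene_fraction_all_intergenic(self):
        _, ann = simulate_genome(SimulationConfig(genome_length=20_000,
                                                  gene_fraction=0.0, rng_seed=1))
        assert ann.genes == []
        assert ann.genome_fraction("intergenic") == 1.0

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(genome_length=5000)


class TestTruth:
    def test_background_shared_by_all_plants(self, default_cohort):
        co = default_cohort
        plants = list(co.truth.entries)
        ref = co.truth.keys_for(plants[0], origins=["background"])
        assert len(ref) > 0
        for p in plants[1:]:
            assert co.truth.keys_for(p, origins=["background"]) == ref

    def test_control_plants_carry_no_induced_mutations(self, default_cohort):
        co = default_cohort
        for group in ("kitaake", "tissue_culture", "agro_infection", "cas_only"):
            for p in co.design.plants(group=group):
                if p not in co.truth.entries:
                    continue
                origins = {tv.origin for tv in co.truth.entries[p]}
                assert origins <= {"background", "tissue_culture"}

    def test_induced_ag_fraction_matches_config(self, default_cohort):
        co = default_cohort
        f = co.config.induced_ag_fraction
        n_ag = n_tot = 0
        for _, row in co.design.table.iterrows():
            if row["group"] != "abe" or row["callus_id"] != "." or not int(row["dna"]):
                continue
            for tv in co.truth.entries[row["plant_id"]]:
                if tv.origin in ("induced_AG", "induced_other"):
                    n_tot += 1
                    n_ag += tv.origin == "induced_AG"
        sd = np.sqrt(f * (1 - f) / n_tot)
        assert abs(n_ag / n_tot - f) <= 3 * sd

    def test_ag_fraction_boundary_one(self):
        cfg = SimulationConfig(genome_length=200_000, induced_ag_fraction=1.0,
                               common_stage_ag_fraction=1.0,
                               unique_stage_ag_fraction=1.0, rng_seed=4)
        genome, ann = simulate_genome(cfg)
        design = default_design(cfg)
        truth = simulate_truth(cfg, genome, ann, design)
        for pid, entries in truth.entries.items():
            for tv in entries:
                if tv.origin.startswith("induced"):
                    assert collapse_class(tv.key.ref, tv.key.alt) == "A>G"

    def test_sibling_common_sets_identical(self, default_cohort):
        co = default_cohort
        for callus in sorted(set(co.design.table["callus_id"]) - {"."}):
            a, b = co.design.plants(callus_id=callus)
            ca = co.truth.keys_for(a, origins=["induced_AG", "induced_other"])
            cb = co.truth.keys_for(b, origins=["induced_AG", "induced_other"])
            shared = ca & cb
            assert len(shared) > 0
            stages_a = {tv.stage for tv in co.truth.entries[a]
                        if tv.key in shared}
            assert stages_a == {"pre_integration"}

    def test_partial_plants_have_fewer_induced(self, default_cohort):
        co = default_cohort
        n_partial, n_complete = [], []
        for _, row in co.design.table.iterrows():
            if row["group"] != "abe" or not int(row["dna"]) or row["callus_id"] != ".":
                continue
            n = len(co.truth.keys_for(row["plant_id"],
                                      origins=["induced_AG", "induced_other"]))
            (n_complete if int(row["tdna_complete"]) else n_partial).append(n)
        assert max(n_partial) < min(n_complete)

    def test_cluster_members_within_span_and_het(self, default_cohort):
        co = default_cohort
        span = co.config.dna_cluster_span
        for pid in co.design.plants(dna_clusters=1):
            keys = sorted(co.truth.keys_for(pid, origins=["cluster"]))
            assert keys
            runs, cur = [], [keys[0]]
            for k in keys[1:]:
                if k.chrom == cur[-1].chrom and k.pos - cur[-1].pos <= 30:
                    cur.append(k)
                else:
                    runs.append(cur)
                    cur = [k]
            runs.append(cur)
            for run in runs:
                assert 2 <= len(run) <= 10
                assert run[-1].pos - run[0].pos <= span
                for k in run:
                    assert collapse_class(k.ref, k.alt) == "A>G"


class TestCallers:
    def test_noise_free_intersection_equals_truth(self, noise_free_cohort):
        co = noise_free_cohort
        pid = "TC_s1"
        cons = intersect_callers(co.dna_calls[pid], genome=co.genome)
        assert cons.keys() == co.truth.keys_for(pid)

    def test_three_way_intersection_recovery_rate(self, default_cohort):
        co = default_cohort
        s = co.config.caller_sensitivity
        expected = s ** 3
        hits = total = 0
        for pid in list(co.truth.entries)[:10]:
            cons_keys = intersect_callers(co.dna_calls[pid],
                                          genome=co.genome).keys()
            truth_snvs = {k for k in co.truth.keys_for(pid)
                          if len(k.ref) == 1 and len(k.alt) == 1}
            total += len(truth_snvs)
            hits += len(truth_snvs & cons_keys)
        sd = np.sqrt(expected * (1 - expected) / total)
        assert abs(hits / total - expected) <= 3 * sd

    def test_false_positives_rarely_survive_intersection(self, default_cohort):
        co = default_cohort
        extra = 0
        for pid in list(co.truth.entries)[:10]:
            cons_keys = intersect_callers(co.dna_calls[pid],
                                          genome=co.genome).keys()
            extra += len(cons_keys - co.truth.keys_for(pid))
        assert extra == 0  # collision probability ~ (fp/L)^2 * L ~ 1e-4


class TestRnaSim:
    def test_yan_bias_boundary(self):
        cfg = SimulationConfig(genome_length=500_000, yan_bias=1.0, rng_seed=6)
        genome, ann = simulate_genome(cfg)
        design = default_design(cfg)
        rna = simulate_rna(cfg, genome, ann, design)
        for l in rna.loci:
            chrom, pos = l.locus.chrom, l.locus.pos
            if l.locus.ref_base == "A":
                assert genome.base(chrom, pos - 1) in "CT"
            else:
                assert genome.base(chrom, pos + 1) in "AG"

    def test_observed_ratio_tracks_planted_mean(self, default_cohort):
        co = default_cohort
        active = co.design.plants(rna_active=1)
        pile = co.rna.pileups
        ratios, planted = [], []
        for l in co.rna.loci:
            planted.append(l.base_ratio)
            for pid in active:
                sub = pile[(pile.plant_id == pid) & (pile.chrom == l.locus.chrom)
                           & (pile.pos == l.locus.pos)]
                if sub.empty:
                    continue
                r = sub.iloc[0]
                num, den = ((r.nG, r.nA + r.nG) if l.locus.ref_base == "A"
                            else (r.nC, r.nC + r.nT))
                if den:
                    ratios.append(num / den)
        assert abs(np.mean(ratios) - np.mean(planted)) < 0.02

    def test_cas_only_pileups_consistent_with_reference(self, default_cohort):
        co = default_cohort
        pid = co.design.plants(group="cas_only")[0]
        sub = co.rna.pileups[co.rna.pileups.plant_id == pid]
        bg_pos = {(k.chrom, k.pos) for k in co.rna.background_keys}
        mism = 0
        total = 0
        for _, r in sub.iterrows():
            if (r.chrom, r.pos) in bg_pos:
                continue
            counts = np.array([r.nA, r.nC, r.nG, r.nT])
            total += counts.sum()
            mism += counts.sum() - counts.max()
        assert mism / total < 0.01  # sequencing-noise floor only

    def test_determinism_and_per_plant_stream_isolation(self):
        cfg = SimulationConfig(genome_length=200_000, rng_seed=9)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a.truth.to_frame().equals(b.truth.to_frame())
        assert a.rna.pileups.equals(b.rna.pileups)
        pid = "TC_s1"
        for caller in cfg.caller_ids:
            ka = [(c.pos, c.alt, c.allele_depths) for c in a.dna_calls[pid][caller]]
            kb = [(c.pos, c.alt, c.allele_depths) for c in b.dna_calls[pid][caller]]
            assert ka == kb


class TestTdnaSim:
    def test_complete_plants_uniform_partial_plants_gapped(self, default_cohort):
        co = default_cohort
        fm = co.config.tdna_features
        for pid, track in co.tdna_tracks.items():
            row = co.design.row(pid)
            copies = int(row["tdna_copies"])
            expected = copies * co.genome_mean_cov / 2
            if int(row["tdna_complete"]):
                assert abs(track.mean() - expected) < 0.1 * expected + 1
            else:
                s, e = fm.interval(row["missing_feature"])
                flank_mean = np.concatenate([track[:s - 1], track[e:]]).mean()
                assert track[s - 1:e].mean() < 0.1 * flank_mean
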