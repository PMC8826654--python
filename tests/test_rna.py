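"""RNA editing ratios, per-plant tests, RPM, motif matrices, and the
RNA-minus-DNA subtraction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mutscape.consensus import ConsensusSet
from mutscape.core_io import GenomeSequence, VariantCall, VariantKey
from mutscape.rna import (
    RnaEditLocus, abe_rpm, editing_ratio, expression_grouping, motif_matrix,
    per_plant_test, rna_minus_dna,
)


class TestEditingRatio:
    def test_reference_a_formula(self):
        # counts are (nA, nC, nG, nT)
        assert editing_ratio((30, 0, 10, 0), "A") == pytest.approx(0.25)

    def test_reference_t_uses_complement_counts(self):
        assert editing_ratio((0, 2, 0, 18), "T") == pytest.approx(0.10)

    def test_coverage_threshold_is_strict(self):
        assert editing_ratio((5, 0, 5, 0), "A") is None        # exactly 10
        assert editing_ratio((5, 0, 6, 0), "A") is not None    # 11

    def test_non_at_reference_rejected(self):
        with pytest.raises(ValueError):
            editing_ratio((10, 10, 10, 10), "C")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 60)] * 4))
    def test_bounded_and_strand_symmetric(self, counts):
        r = editing_ratio(counts, "A")
        if r is not None:
            assert 0.0 <= r <= 1.0
        nA, nC, nG, nT = counts
        flipped = (nT, nG, nC, nA)  # complement every base
        assert editing_ratio(counts, "A") == editing_ratio(flipped, "T")


class TestRnaMinusDna:
    def _cons(self, plant, *positions):
        calls = [VariantCall(plant, None, "c1", p, "A", "G", "het", (5, 5))
                 for p in positions]
        return ConsensusSet(plant, calls, {})

    def test_subtracts_dna_and_background(self):
        rna = self._cons("p", 1, 2, 3, 4)
        dna = self._cons("p", 2)
        bg = [self._cons("bg1", 3)]
        out = rna_minus_dna(rna, dna, bg)
        assert {k.pos for k in out} == {1, 4}

    def test_missing_dna_partner_rejected(self):
        with pytest.raises(ValueError, match="DNA"):
            rna_minus_dna(self._cons("p", 1), None, [])

    def test_noise_free_recovery_of_planted_loci(self, noise_free_cohort,
                                                 noise_free_result):
        co = noise_free_cohort
        for pid, keys in noise_free_result.rna_only.items():
            if not int(co.design.row(pid)["rna_active"]):
                continue
            planted = {(l.locus.chrom, l.locus.pos) for l in co.rna.loci}
            planted |= {(c, p) for l in co.rna.loci for c, p, _ in l.satellites}
            found = {(k.chrom, k.pos) for k in keys}
            # every RNA-only SNV is a planted edit; detection requires the
            # binomial draw to clear the read-support threshold
            assert found <= planted
            assert len(found) > 0.5 * len(planted)


class TestExpressionAndRpm:
    def test_rpm_formula(self):
        assert abe_rpm(1000, 3000, 20_000_000) == pytest.approx(100.0)
        assert abe_rpm(0, 0, 1_000_000) == 0.0

    def test_zero_total_reads_rejected(self):
        with pytest.raises(ValueError):
            abe_rpm(1, 1, 0)

    def test_simulated_rpm_matches_design(self, default_cohort):
        co = default_cohort
        for _, r in co.rna.read_counts.iterrows():
            rpm = abe_rpm(r["cas_reads"], r["tada_reads"], r["total_reads"])
            expected = float(co.design.row(r["plant_id"])["expression_rpm"])
            assert rpm == pytest.approx(expected, abs=0.05)

    def test_grouping_compound_rule(self):
        rpm = {"a": 300.0, "b": 20.0, "c": 250.0}
        n_snvs = {"a": 40, "b": 1, "c": 40}
        pvals = {"a": 1e-9, "b": 0.5, "c": 0.3}  # c: many SNVs but ns test
        groups, _ = expression_grouping(rpm, n_snvs, pvals)
        assert groups["with_RNA_mutations"] == ["a"]
        assert sorted(groups["without_RNA_mutations"]) == ["b", "c"]

    def test_all_cas_only_gives_empty_with_group(self):
        groups, table = expression_grouping({"x": 10.0}, {"x": 0}, {"x": None})
        assert groups["with_RNA_mutations"] == []
        assert table.empty


class TestPerPlantTest:
    def test_identical_to_pool_not_significant(self):
        rng = np.random.default_rng(0)
        vals = list(rng.random(50))
        p, _ = per_plant_test(vals, vals)
        assert p >= 0.5

    def test_too_few_ratios_reports_missing(self):
        assert per_plant_test([0.1], [0.2, 0.3, 0.4]) is None

    def test_shifted_plant_is_significant(self):
        rng = np.random.default_rng(1)
        cas = list(rng.random(100) * 0.01)
        plant = list(0.2 + rng.random(100) * 0.2)
        p, logp = per_plant_test(plant, cas)
        assert p < 1e-10 and logp > 10


class TestMotif:
    def test_single_locus_context_is_fully_conserved(self):
        genome = GenomeSequence(["c"], {"c": "GGGTAGGGG"})
        pfm, bits = motif_matrix([RnaEditLocus("c", 5, "A")], genome, flank=1)
        assert pfm.loc["T", -1] == 1 and pfm.loc["A", 0] == 1
        assert bits[0] == pytest.approx(2.0)   # -1 column: single T
        assert bits[1] == pytest.approx(2.0)   # center A

    def test_t_reference_window_reverse_complemented(self):
        # edited strand reads revcomp; -1 base of the edited A pairs with +1
        genome = GenomeSequence(["c"], {"c": "GGGGTAGGG"})
        pfm, _ = motif_matrix([RnaEditLocus("c", 5, "T")], genome, flank=1)
        assert pfm.loc["A", 0] == 1
        assert pfm.loc["T", -1] == 1  # revcomp of the A at +1

    def test_uniform_random_contexts_have_low_information(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        genome = GenomeSequence(["c"], {"c": seq})
        loci = [RnaEditLocus("c", int(p) + 1, seq[p])
                for p in np.flatnonzero(np.frombuffer(seq.encode(), np.uint8)
                                        == ord("A"))[:400]]
        pfm, bits = motif_matrix(loci, genome, flank=3)
        assert bits[3] == pytest.approx(2.0)       # center is A by construction
        off = [b for i, b in enumerate(bits) if i != 3]
        assert max(off) < 0.05

    def test_columns_sum_to_locus_count(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        genome = GenomeSequence(["c"], {"c": seq})
        loci = [RnaEditLocus("c", p, seq[p - 1]) for p in range(100, 120)
                if seq[p - 1] in "AT"]
        pfm, _ = motif_matrix(loci, genome, flank=2)
        assert (pfm.sum(axis=0) == len(loci)).all()

    def test_edge_locus_truncates_window(self):
        genome = GenomeSequence(["c"], {"c": "AGGG"})
        pfm, bits = motif_matrix([RnaEditLocus("c", 1, "A")], genome, flank=2)
        assert pfm[-1].sum() == 0 and pfm[-2].sum() == 0
        assert pfm.loc["A", 0] == 1

    def test_no_loci_rejected(self):
        genome = GenomeSequence(["c"], {"c": "ACGT"})
        with pytest.raises(ValueError):
            motif_matrix([], genome)

    def test_yan_bias_recovered_from_planted_contexts(self, default_cohort):
        co = default_cohort
        genome = co.genome
        n_yan = 0
        for l in co.rna.loci:
            if l.locus.ref_base == "A":
                n_yan += genome.base(l.locus.chrom, l.locus.pos - 1) in "CT"
            else:
                n_yan += genome.base(l.locus.chrom, l.locus.pos + 1) in "AG"
        frac = n_yan / len(co.rna.loci)
        bias = co.config.yan_bias
        sd = np.sqrt(bias * (1 - bias) / len(co.rna.loci))
        assert abs(frac - bias) <= 3 * sd
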