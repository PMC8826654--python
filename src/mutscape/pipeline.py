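"""End-to-end orchestration of the analysis stages.

Stage order mirrors the study workflow: caller consensus -> background
subtraction -> homozygosity screen and homozygote removal -> on-target
masking -> spectra / enrichment / group statistics -> sibling and T-DNA
analyses -> RNA editing -> clustered-editing detection.  The pipeline is
a pure function of (inputs, thresholds) and writes one TSV per
stage plus a JSON summary; re-running with identical inputs is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from mutscape import consensus as cns
from mutscape import clusters as clu
from mutscape import core_io
from mutscape import guides as gd
from mutscape import rna as rnamod
from mutscape import spectrum as spc
from mutscape import tdna as tdnamod
from mutscape.core_io import GenomeSequence, GuideSpec
from mutscape.rna import RnaEditLocus
from mutscape.tdna import TdnaFeatureMap

log = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """All analysis thresholds, defaulting to the study's printed values."""

    min_snv_callers: int = 3
    min_indel_callers: int = 2
    alpha_binomial: float = 0.01
    max_mm: int = 6
    seed_len: int = 12
    max_seed_mm: int = 2
    on_target_flank: int = 0
    cov_thr: int = 10
    ratio_thr: float = 0.05
    flank_window: int = 30
    merge_distance: int = 30
    rna_snv_threshold: int = 5
    rna_alpha: float = 0.05
    tdna_min_frac: float = 0.1


@dataclass
class CohortInputs:
    """Everything the pipeline consumes, already parsed."""

    genome: GenomeSequence
    annotation: AnnotationSet
    design: CohortDesign
    guides: list[GuideSpec]
    dna_calls: dict[str, dict[str, list]]          # plant -> caller -> calls
    rna_calls: dict[str, dict[str, list]] = field(default_factory=dict)
    rna_pileups: pd.DataFrame = field(default_factory=pd.DataFrame)
    read_counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    tdna_tracks: dict[str, np.ndarray] = field(default_factory=dict)
    tdna_features: TdnaFeatureMap | None = None
    genome_mean_cov: float = 0.0


def inputs_from_cohort(cohort) -> CohortInputs:
    """Adapt a :class:`mutscape.simulate.SyntheticCohort` (in memory)."""
    return CohortInputs(
        genome=cohort.genome, annotation=cohort.annotation,
        design=cohort.design, guides=cohort.guides,
        dna_calls=cohort.dna_calls, rna_calls=cohort.rna.calls,
        rna_pileups=cohort.rna.pileups, read_counts=cohort.rna.read_counts,
        tdna_tracks=cohort.tdna_tracks,
        tdna_features=cohort.config.tdna_features,
        genome_mean_cov=cohort.genome_mean_cov)


def load_inputs(indir) -> CohortInputs:
    """Read a cohort directory as written by ``mutscape simulate``."""
    indir = Path(indir)
    genome = core_io.read_fasta(indir / "genome.fa")
    annotation = core_io.read_annotation(indir / "annotation.gff3", genome)
    design = core_io.read_design(indir / "design.tsv")
    guide_list = core_io.read_guides(indir / "guides.tsv")

    def read_calls(sub):
        calls: dict[str, dict[str, list]] = {}
        for path in sorted((indir / sub).glob("*.vcf")):
            pid, caller = path.stem.rsplit(".", 1)
            calls.setdefault(pid, {})[caller] = core_io.read_vcf(
                path, plant_id=pid, caller_id=caller)
        return calls

    features = None
    fpath = indir / "tdna_features.bed"
    if fpath.exists():
        feats = core_io.read_bed_features(fpath)
        features = TdnaFeatureMap(features=feats,
                                  length=max(e for _, _, e in feats))
    tracks = {p.stem.replace(".cov", ""): core_io.read_coverage_track(p)
              for p in sorted((indir / "tdna").glob("*.cov.tsv"))} \
        if (indir / "tdna").is_dir() else {}
    gcov = 0.0
    gpath = indir / "genome_coverage.tsv"
    if gpath.exists():
        gcov = float(pd.read_csv(gpath, sep="\t")["genome_mean_coverage"].iloc[0])
    pileups = (core_io.read_pileups(indir / "pileups_rna.tsv")
               if (indir / "pileups_rna.tsv").exists() else pd.DataFrame())
    reads = (pd.read_csv(indir / "read_counts.tsv", sep="\t", dtype={"plant_id": str})
             if (indir / "read_counts.tsv").exists() else pd.DataFrame())
    return CohortInputs(genome=genome, annotation=annotation, design=design,
                        guides=guide_list,
                        dna_calls=read_calls("vcf_dna"),
                        rna_calls=read_calls("vcf_rna") if (indir / "vcf_rna").is_dir() else {},
                        rna_pileups=pileups, read_counts=reads,
                        tdna_tracks=tracks, tdna_features=features,
                        genome_mean_cov=gcov)


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    consensus: dict[str, cns.ConsensusSet]
    filtered: dict[str, cns.ConsensusSet]      # post background/hom/on-target
    summaries: dict[str, spc.SpectrumSummary]
    rna_only: dict[str, set]
    cluster_calls: list
    groups: dict


# ---------------------------------------------------------------------------


def analyze_cohort(inputs: CohortInputs,
                   thresholds: Thresholds | None = None) -> PipelineResult:
    """Run every analysis stage in memory; see module docstring for order."""
    th = thresholds or Thresholds()
    design = inputs.design
    genome = inputs.genome
    annotation = inputs.annotation
    tables: dict[str, pd.DataFrame] = {}

    # -- stage 1: per-plant caller consensus ------------------------------
    consensus: dict[str, cns.ConsensusSet] = {}
    for pid in sorted(inputs.dna_calls):
        consensus[pid] = cns.intersect_callers(
            inputs.dna_calls[pid], min_snv_callers=th.min_snv_callers,
            min_indel_callers=th.min_indel_callers, genome=genome)

    # -- stage 2: background subtraction ----------------------------------
    background_plants = design.plants(group="kitaake")
    background_sets = [consensus[p] for p in background_plants if p in consensus]
    experimental = [p for p in sorted(consensus) if p not in background_plants]
    subtracted = {p: cns.subtract_background(consensus[p], background_sets)
                  for p in experimental}

    # -- stage 3: recurrence + homozygosity screen, then hom removal ------
    if len(subtracted) >= 2:
        recurrence = cns.recurrence_table(subtracted)
        screen = cns.binomial_screen(recurrence, cohort_size=len(subtracted),
                                     alpha=th.alpha_binomial)
        tables["recurrence"] = recurrence
        tables["binomial_screen"] = screen
    het_sets = {p: cns.remove_homozygous(s) for p, s in subtracted.items()}

    # -- stage 4: guide sites and on-target masking -----------------------
    guide_by_name = {g.name: g for g in inputs.guides}
    full_sites = {g.name: gd.find_sites_full(genome, g, max_mm=th.max_mm,
                                             seed_len=th.seed_len)
                  for g in inputs.guides}
    seed_sites = {g.name: gd.find_sites_seed(genome, g, seed_len=th.seed_len,
                                             max_seed_mm=th.max_seed_mm)
                  for g in inputs.guides}
    tables["site_counts"] = pd.DataFrame(
        [{"guide": n, "full_sites": len(full_sites[n]),
          "seed_sites": len(seed_sites[n]),
          "on_target_sites": sum(1 for s in full_sites[n] if s.is_on_target)}
         for n in sorted(guide_by_name)])

    filtered: dict[str, cns.ConsensusSet] = {}
    on_rows = []
    for pid, s in het_sets.items():
        gnames = design.guides_of(pid) if pid in design.table["plant_id"].values else []
        sites = [t for gn in gnames for t in full_sites.get(gn, [])]
        on, off = gd.mask_on_target(s.variants, sites, flank=th.on_target_flank)
        filtered[pid] = cns.ConsensusSet(pid, off, {v.key(): s.provenance.get(v.key(), frozenset()) for v in off})
        on_rows.append({"plant_id": pid, "n_on_target": len(on),
                        "n_off_target": len(off)})
    tables["on_target"] = pd.DataFrame(on_rows)

    # variants at guide-dependent off-target sites, per mismatch stratum
    strata_rows = []
    for mode, sites_by_guide in (("full", full_sites), ("seed", seed_sites)):
        for gn in sorted(sites_by_guide):
            offsites = [s for s in sites_by_guide[gn] if not s.is_on_target]
            plants_with = [p for p in filtered if gn in design.guides_of(p)]
            variants = [v for p in plants_with for v in filtered[p].variants]
            counts = gd.count_variants_at_sites(variants, offsites)
            strata_rows.append({"mode": mode, "guide": gn,
                                "n_off_sites": len(offsites),
                                "n_variants_at_sites": sum(counts.values())})
    tables["guide_dependent_offtargets"] = pd.DataFrame(strata_rows)

    # -- stage 5: spectra, enrichment, chromosome distribution, groups ----
    summaries = {p: spc.spectrum_summary(filtered[p].variants, plant_id=p)
                 for p in sorted(filtered)}
    spectab = spc.spectrum_table([summaries[p] for p in sorted(summaries)])
    meta = design.table.set_index("plant_id")
    spectab["group"] = [meta.loc[p, "group"] for p in spectab["plant_id"]]
    spectab["editor"] = [meta.loc[p, "editor"] for p in spectab["plant_id"]]
    tables["spectrum"] = spectab

    metrics = ("n_snvs", "n_indels", "n_ag", "pct_ag")

    def metric_values(plants):
        vals = {m: [] for m in metrics}
        for p in plants:
            s = summaries[p]
            vals["n_snvs"].append(s.n_snvs)
            vals["n_indels"].append(s.n_indels)
            vals["n_ag"].append(s.n_ag)
            vals["pct_ag"].append(np.nan if s.pct_ag is None else s.pct_ag)
        return vals

    groups_def = {
        "C1": design.plants(group="tissue_culture"),
        "C2": design.plants(group="agro_infection"),
        "ABE": [p for p in design.plants(group="abe") if p in summaries],
    }
    for editor in sorted(set(meta["editor"]) - {"none"}):
        groups_def[editor] = [p for p in design.plants(group="abe", editor=editor)
                              if p in summaries]
    gvals = {k: metric_values(v) for k, v in groups_def.items() if v}
    comparisons = []
    for m in metrics:
        if "C1" in gvals and "C2" in gvals:
            comparisons.append(("C1", "C2", m, "greater"))
        if "ABE" in gvals and "C2" in gvals:
            comparisons.append(("ABE", "C2", m, "greater"))
        for ed in sorted(set(meta["editor"]) - {"none"}):
            if ed in gvals and "C2" in gvals:
                comparisons.append((ed, "C2", m, "greater"))
        for a, b in (("rBE49b", "rBE46b"), ("rBE53", "rBE50"),
                     ("rBE50", "rBE46b"), ("rBE53", "rBE49b")):
            if a in gvals and b in gvals:
                comparisons.append((a, b, m, "greater"))
    tables["group_comparisons"] = spc.compare_groups_table(gvals, comparisons)

    abe_keys = [k for p in groups_def["ABE"] for k in filtered[p].keys(snvs_only=True)]
    control_keys = [k for p in groups_def.get("C2", []) + groups_def.get("C1", [])
                    for k in filtered[p].keys(snvs_only=True)]
    ag_keys = [k for k in abe_keys
               if spc.collapse_class(k.ref, k.alt) == "A>G"]
    tables["region_enrichment_abe"] = spc.region_enrichment(abe_keys, annotation)
    tables["region_enrichment_abe_ag"] = spc.region_enrichment(ag_keys, annotation)
    if control_keys:
        tables["region_enrichment_control"] = spc.region_enrichment(control_keys, annotation)
    tables["chromosome_distribution"] = spc.chromosome_distribution(abe_keys, genome)

    # -- stage 6: pairwise overlap + sibling partitions -------------------
    if len(filtered) >= 2:
        overlap, n_cmp = cns.pairwise_overlap(filtered)
        tables["overlap_matrix"] = overlap.reset_index(names="plant_id")
        tables["overlap_info"] = pd.DataFrame(
            [{"n_plants": len(filtered), "n_comparisons": n_cmp}])
    partitions = []
    for callus in sorted(set(design.table["callus_id"]) - {"."}):
        sibs = design.plants(callus_id=callus)
        sibs = [p for p in sibs if p in filtered]
        if len(sibs) != 2:
            continue
        a, b = sibs
        partitions.append(tdnamod.partition_siblings(
            filtered[a].keys(snvs_only=True), filtered[b].keys(snvs_only=True),
            a, b, callus, callus))
    if partitions:
        stage_tab, stage_cmp = tdnamod.stage_attribution(partitions)
        tables["sibling_sets"] = stage_tab
        if not stage_cmp.empty:
            tables["sibling_stage_test"] = stage_cmp

    # -- stage 7: T-DNA integrity and copy number -------------------------
    if inputs.tdna_tracks and inputs.tdna_features is not None:
        rows = []
        est_complete: dict[str, bool] = {}
        for pid in sorted(inputs.tdna_tracks):
            track = inputs.tdna_tracks[pid]
            res = tdnamod.tdna_integrity(track, inputs.tdna_features,
                                         min_frac=th.tdna_min_frac)
            present_iv = [inputs.tdna_features.interval(n)
                          for n, call in res["features"].items()
                          if call == "present"]
            if present_iv and inputs.genome_mean_cov > 0:
                mean_cov = float(np.mean(np.concatenate(
                    [track[s - 1:e] for s, e in present_iv])))
                copies, rounded = tdnamod.tdna_copy_number(
                    mean_cov, inputs.genome_mean_cov)
            else:
                copies, rounded = 0.0, 0
            est_complete[pid] = res["status"] == "complete"
            rows.append({"plant_id": pid, "status": res["status"],
                         "missing": ",".join(n for n, c in res["features"].items()
                                             if c == "missing") or ".",
                         "copies_real": copies, "copies": rounded})
        tables["tdna"] = pd.DataFrame(rows)
        abe_sum = {p: summaries[p] for p in groups_def["ABE"] if p in est_complete}
        if abe_sum and len(set(est_complete[p] for p in abe_sum)) == 2:
            tables["tdna_completeness_effect"] = tdnamod.completeness_effect(
                abe_sum, {p: est_complete[p] for p in abe_sum})
        copy_flags = {p: tables["tdna"].set_index("plant_id").loc[p, "copies"] > 1
                      for p in abe_sum}
        if abe_sum and len(set(copy_flags.values())) == 2:
            tables["tdna_copy_effect"] = tdnamod.completeness_effect(
                abe_sum, copy_flags)

    # -- stage 8: RNA editing ---------------------------------------------
    rna_only: dict[str, set] = {}
    rna_tables_done = False
    if inputs.rna_calls:
        rna_cons = {p: cns.intersect_callers(inputs.rna_calls[p],
                                             min_snv_callers=th.min_snv_callers,
                                             min_indel_callers=th.min_indel_callers,
                                             genome=genome)
                    for p in sorted(inputs.rna_calls)}
        rna_bg = [rna_cons[p] for p in design.plants(group="agro_infection")
                  if p in rna_cons]
        t0_rna = [p for p in rna_cons
                  if meta.loc[p, "generation"] == "T0"
                  and meta.loc[p, "group"] not in ("agro_infection",)]
        for pid in t0_rna:
            dna_partner = consensus.get(pid)
            if dna_partner is None and int(meta.loc[pid, "dna"]) == 0:
                dna_partner = cns.ConsensusSet(pid, [], {})
            rna_only[pid] = rnamod.rna_minus_dna(rna_cons[pid], dna_partner, rna_bg)
        ag_only = {p: {k for k in ks
                       if spc.collapse_class(k.ref, k.alt) == "A>G"}
                   for p, ks in rna_only.items()}
        combined = sorted({k for ks in ag_only.values() for k in ks})
        loci = [RnaEditLocus(k.chrom, k.pos, k.ref) for k in combined
                if k.ref in ("A", "T")]
        tables["rna_snv_counts"] = pd.DataFrame(
            [{"plant_id": p, "n_rna_snvs": len(rna_only[p]),
              "n_rna_ag": len(ag_only[p])} for p in sorted(rna_only)])
        if loci and not inputs.rna_pileups.empty:
            ratios, covs = rnamod.ratio_matrix(loci, inputs.rna_pileups,
                                               cov_thr=th.cov_thr)
            tables["rna_ratio_matrix"] = ratios.reset_index(names="locus")
            cas_plants = [p for p in design.plants(group="cas_only")
                          if p in ratios.columns]
            cas_pool = [v for p in cas_plants for v in ratios[p] if not pd.isna(v)]
            test_rows = []
            pvals: dict[str, float | None] = {}
            for pid in sorted(rna_only):
                if pid not in ratios.columns:
                    continue
                res = rnamod.per_plant_test(list(ratios[pid]), cas_pool)
                pvals[pid] = None if res is None else res[0]
                test_rows.append({"plant_id": pid,
                                  "n_ratios": int(ratios[pid].notna().sum()),
                                  "pvalue": np.nan if res is None else res[0],
                                  "minus_log10_p": np.nan if res is None else res[1]})
            tables["rna_per_plant_test"] = pd.DataFrame(test_rows)

            rpm_map: dict[str, float] = {}
            for _, r in inputs.read_counts.iterrows():
                rpm_map[r["plant_id"]] = rnamod.abe_rpm(
                    float(r["cas_reads"]), float(r["tada_reads"]),
                    float(r["total_reads"]))
            abe_rna = [p for p in sorted(rna_only)
                       if meta.loc[p, "group"] == "abe" and p in rpm_map]
            grouping, rpm_cmp = rnamod.expression_grouping(
                {p: rpm_map[p] for p in abe_rna},
                {p: len(ag_only[p]) for p in abe_rna},
                {p: pvals.get(p) for p in abe_rna},
                snv_threshold=th.rna_snv_threshold, alpha=th.rna_alpha)
            tables["rna_expression_groups"] = pd.DataFrame(
                [{"plant_id": p, "group": g}
                 for g, ps in grouping.items() for p in ps])
            if not rpm_cmp.empty:
                tables["rna_rpm_comparison"] = rpm_cmp
            tables["rna_rpm"] = pd.DataFrame(
                [{"plant_id": p, "rpm": rpm_map[p]} for p in sorted(rpm_map)])

            pfm, bits = rnamod.motif_matrix(loci, genome, flank=3)
            pfm_out = pfm.copy()
            pfm_out.insert(0, "base", pfm_out.index)
            tables["rna_motif_pfm"] = pfm_out.reset_index(drop=True)
            tables["rna_motif_bits"] = pd.DataFrame(
                {"offset": list(pfm.columns), "bits": bits})

            t1 = design.table[design.table["generation"] == "T1"]
            if not t1.empty:
                tables["rna_segregation"] = rnamod.segregation_check(
                    t1, ratios, cas_pool)

            # -- stage 9a: RNA flanking profiles --------------------------
            focal = [(k.chrom, k.pos) for k in combined]
            prof_rows = []
            for pid in sorted(set(inputs.rna_pileups["plant_id"])):
                sub = inputs.rna_pileups[inputs.rna_pileups["plant_id"] == pid]
                prof = clu.flank_profile(focal, sub, genome,
                                         window=th.flank_window,
                                         ratio_thr=th.ratio_thr,
                                         cov_thr=th.cov_thr)
                prof.insert(0, "plant_id", pid)
                prof_rows.append(prof)
            if prof_rows:
                tables["rna_flank_profiles"] = pd.concat(prof_rows,
                                                         ignore_index=True)
            rna_tables_done = True
    if not rna_tables_done:
        log.info("RNA inputs absent or empty: RNA stages skipped")

    # -- stage 9b: DNA clusters and group classification ------------------
    abe_plants = [p for p in groups_def["ABE"]]
    keys_by_plant = {p: sorted(filtered[p].keys(snvs_only=True))
                     for p in abe_plants}
    calls = clu.detect_dna_clusters(keys_by_plant,
                                    merge_distance=th.merge_distance,
                                    annotation=annotation)
    tables["dna_clusters"] = pd.DataFrame(
        [{"chrom": c.chrom, "start": c.start, "end": c.end,
          "n_members": c.n_members, "plants": ",".join(sorted(c.plants)),
          "region": c.region} for c in calls])
    grp, grp_cmp, genic_tab = clu.classify_cluster_groups(
        {p: summaries[p] for p in abe_plants}, calls,
        all_ag_keys_by_plant=keys_by_plant, annotation=annotation)
    tables["cluster_groups"] = pd.DataFrame(
        [{"plant_id": p, "group": g} for g, ps in grp.items() for p in ps])
    if not grp_cmp.empty:
        tables["cluster_group_comparisons"] = grp_cmp
    if not genic_tab.empty:
        tables["cluster_genic_fraction"] = genic_tab

    return PipelineResult(tables=tables, consensus=consensus,
                          filtered=filtered, summaries=summaries,
                          rna_only=rna_only, cluster_calls=calls, groups=grp)


def run_all(indir, outdir, thresholds: Thresholds | None = None) -> PipelineResult:
    """File-level entry point: load inputs, analyze, write the report bundle."""
    th = thresholds or Thresholds()
    inputs = load_inputs(indir)
    result = analyze_cohort(inputs, th)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "consensus_vcf").mkdir(exist_ok=True)
    contigs = inputs.genome.lengths
    for pid in sorted(result.filtered):
        chrom_order = {c: i for i, c in enumerate(inputs.genome.chrom_names)}
        calls = sorted(result.filtered[pid].variants,
                       key=lambda v: (chrom_order[v.chrom], v.pos, v.alt))
        core_io.write_vcf(calls, out / "consensus_vcf" / f"{pid}.vcf",
                          contigs=contigs, sample=pid)
    for name in sorted(result.tables):
        result.tables[name].to_csv(out / f"{name}.tsv", sep="\t", index=False,
                                   float_format="%.6g")
    summary = {
        "n_plants": len(result.consensus),
        "n_experimental": len(result.filtered),
        "thresholds": asdict(th),
        "tables": sorted(result.tables),
        "n_dna_clusters": len(result.cluster_calls),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return result
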