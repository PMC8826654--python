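"""Synthetic study generator.

Builds a complete desk-scale cohort with the statistical structure the
analysis assumes: a random genome with gene models, a cohort design
mirroring the study arms (wild-type background plants, tissue-culture and
infection controls, Cas-only plants, and ABE plants for four editors with
and without guides), a per-plant truth table of planted mutations,
emulated three-caller variant calls, RNA pileups with expression-dependent
A>G editing in a pyrimidine-A-N context, T-DNA coverage tracks, and
editor read counts.  Everything is a pure function of the configuration
and the seed: per-plant RNG streams are derived from (seed, plant_id) so
adding a plant never perturbs any other plant's data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from mutscape import core_io
from mutscape.core_io import (
    AnnotationSet, CohortDesign, DESIGN_COLUMNS, GeneModel, GenomeSequence,
    GuideSpec, IUPAC, VariantCall, VariantKey,
)
from mutscape.rna import RnaEditLocus
from mutscape.tdna import TdnaFeatureMap

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: PAM pattern of the Cas module carried by each editor construct.
EDITOR_PAM = {"rBE46b": "NGG", "rBE49b": "NGG", "rBE50": "NG", "rBE53": "NG"}

#: Default T-DNA functional map (bp over the 9-kb T-DNA sequence).
DEFAULT_TDNA_FEATURES = TdnaFeatureMap(
    features=[("LB", 1, 25), ("promoter", 101, 2000), ("Cas", 2101, 6100),
              ("TadA", 6201, 6700), ("NLS", 6721, 6780),
              ("terminator", 6801, 7050), ("RB", 8976, 9000)],
    length=9000)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Counts are per-plant means of Poisson distributions unless stated
    otherwise; rates and fractions are probabilities in [0, 1].
    """

    # genome
    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    gene_fraction: float = 0.3
    mean_gene_length: int = 3000
    # cohort
    n_background_plants: int = 10
    n_tissue_culture: int = 3
    n_agro_infection: int = 3
    n_cas_only: int = 3
    n_plants_per_abe_arm: int = 3
    editors: tuple = ("rBE46b", "rBE49b", "rBE50", "rBE53")
    # DNA mutations
    background_hom_snvs: int = 300
    background_indels: int = 100
    tissue_culture_het_snvs: float = 300.0
    tissue_culture_indels: float = 150.0
    induced_snvs_mean: float = 300.0
    induced_ag_fraction: float = 0.6
    genic_enrichment: float = 1.5
    sibling_common_snvs: float = 120.0
    common_stage_ag_fraction: float = 0.4
    unique_stage_ag_fraction: float = 0.8
    partial_tdna_scale: float = 0.3
    # clustered DNA editing
    dna_cluster_loci: int = 3
    dna_cluster_span: int = 60
    cluster_genic_fraction: float = 0.45
    # RNA editing
    rna_edit_loci: int = 300
    rna_cluster_fraction: float = 0.2
    rna_ratio_mean: float = 0.3
    yan_bias: float = 0.9
    rna_background_snvs: int = 30
    high_expression_rpm: float = 300.0
    low_expression_rpm: float = 20.0
    total_rna_reads: int = 20_000_000
    # sequencing / callers
    caller_ids: tuple = ("gatk", "lofreq", "strelka2")
    caller_sensitivity: float = 0.95
    caller_fp_per_mb: float = 2.0
    coverage_mean: float = 40.0
    base_error: float = 0.002
    # T-DNA
    tdna_features: TdnaFeatureMap = field(default_factory=lambda: DEFAULT_TDNA_FEATURES)
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("gene_fraction", "induced_ag_fraction", "yan_bias",
                     "rna_cluster_fraction", "rna_ratio_mean",
                     "caller_sensitivity", "base_error",
                     "common_stage_ag_fraction", "unique_stage_ag_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.gene_fraction >= 1.0 and self.gene_fraction != 0:
            raise ValueError("gene_fraction must be < 1")
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10 kb")

    def noise_free(self) -> "SimulationConfig":
        """Variant of the config with perfect callers and no read errors."""
        return replace(self, caller_sensitivity=1.0, caller_fp_per_mb=0.0,
                       base_error=0.0)


class TruthVariant(NamedTuple):
    key: VariantKey
    zygosity: str   # het | hom
    origin: str     # background | tissue_culture | induced_AG | induced_other
                    # | cluster | on_target
    stage: str      # pre_integration | post_integration | NA


@dataclass
class TruthTable:
    """Per-plant planted variants with origin and temporal-stage labels."""

    entries: dict[str, list[TruthVariant]] = field(default_factory=dict)

    def keys_for(self, plant_id: str, origins: Sequence[str] | None = None,
                 zygosity: str | None = None) -> set[VariantKey]:
        out = set()
        for tv in self.entries.get(plant_id, []):
            if origins is not None and tv.origin not in origins:
                continue
            if zygosity is not None and tv.zygosity != zygosity:
                continue
            out.add(tv.key)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [{"plant_id": pid, "chrom": tv.key.chrom, "pos": tv.key.pos,
                 "ref": tv.key.ref, "alt": tv.key.alt, "zygosity": tv.zygosity,
                 "origin": tv.origin, "stage": tv.stage}
                for pid in sorted(self.entries) for tv in self.entries[pid]]
        return pd.DataFrame(rows, columns=["plant_id", "chrom", "pos", "ref",
                                           "alt", "zygosity", "origin", "stage"])


@dataclass
class SimEditLocus:
    """An RNA edit site in the truth: focal position plus satellites."""

    locus: RnaEditLocus
    base_ratio: float
    clustered: bool
    yan: bool
    satellites: list[tuple[str, int, str]] = field(default_factory=list)


@dataclass
class RnaSimulation:
    loci: list[SimEditLocus]
    background_keys: list[VariantKey]
    pileups: pd.DataFrame
    calls: dict[str, dict[str, list[VariantCall]]]
    read_counts: pd.DataFrame


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    genome: GenomeSequence
    annotation: AnnotationSet
    design: CohortDesign
    guides: list[GuideSpec]
    on_target_edits: dict[str, VariantKey]
    truth: TruthTable
    dna_calls: dict[str, dict[str, list[VariantCall]]]
    rna: RnaSimulation
    tdna_tracks: dict[str, np.ndarray]
    genome_mean_cov: float


def _stream(seed: int, *tokens) -> np.random.Generator:
    """Deterministic per-entity RNG stream from (seed, labels...)."""
    parts = [int(seed) & 0x7FFFFFFF]
    for t in tokens:
        parts.append(zlib.crc32(str(t).encode()) & 0xFFFFFFFF)
    return np.random.default_rng(parts)


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> tuple[GenomeSequence, AnnotationSet]:
    """I.i.d. uniform ACGT genome plus non-overlapping gene models.

    Genes cover about ``gene_fraction`` of the genome (exponential gaps
    calibrated so span/(span+gap) equals the target); each gene carries
    one to three exons.  Deterministic given ``rng_seed``.
    """
    rng = _stream(config.rng_seed, "genome")
    n_chrom = config.n_chromosomes
    chrom_len = config.genome_length // n_chrom
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs = {}
    genes: list[GeneModel] = []
    gid = 0
    for name in names:
        codes = rng.integers(0, 4, size=chrom_len, dtype=np.uint8)
        seqs[name] = _BASE_BYTES[codes].tobytes().decode()
        if config.gene_fraction <= 0:
            continue
        f = config.gene_fraction
        gap_mean = config.mean_gene_length * (1 - f) / f
        pos = int(rng.exponential(gap_mean))
        while True:
            length = int(rng.integers(config.mean_gene_length // 3,
                                      config.mean_gene_length * 5 // 3))
            if pos + length >= chrom_len:
                break
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _split_exons(rng, pos, pos + length)
            genes.append(GeneModel(f"gene{gid:04d}", name, pos, pos + length,
                                   strand, exons))
            pos += length + max(1, int(rng.exponential(gap_mean)))
    genome = GenomeSequence(chrom_names=names, sequences=seqs)
    annotation = AnnotationSet(chrom_lengths=genome.lengths, genes=genes)
    return genome, annotation


def _split_exons(rng, start0: int, end0: int) -> list[tuple[int, int]]:
    n_ex = int(rng.integers(1, 4))
    if n_ex == 1:
        return [(start0, end0)]
    n_seg = 2 * n_ex - 1
    w = rng.random(n_seg) + 0.2
    bounds = np.concatenate([[0.0], np.cumsum(w) / w.sum()])
    length = end0 - start0
    cuts = start0 + np.round(bounds * length).astype(int)
    exons = [(int(cuts[i]), int(cuts[i + 1])) for i in range(0, n_seg, 2)
             if cuts[i + 1] > cuts[i]]
    return exons or [(start0, end0)]


# ---------------------------------------------------------------------------
# Guides and design
# ---------------------------------------------------------------------------

def _pick_guides(config: SimulationConfig, genome: GenomeSequence,
                 annotation: AnnotationSet) -> tuple[list[GuideSpec], dict[str, VariantKey]]:
    """One guide per editor, placed on a real genic protospacer with a
    matching PAM and an editable A inside the editing window (spacer
    positions 4-10)."""
    rng = _stream(config.rng_seed, "guides")
    guides, edits = [], {}
    genic_genes = annotation.genes
    for editor in config.editors:
        pam = EDITOR_PAM[editor]
        placed = False
        for _ in range(2000):
            if genic_genes:
                g = genic_genes[int(rng.integers(0, len(genic_genes)))]
                chrom, lo, hi = g.chrom, g.start0, g.end0
            else:
                chrom = genome.chrom_names[0]
                lo, hi = 0, genome.lengths[chrom]
            if hi - lo < 30:
                continue
            s = int(rng.integers(lo, hi - 23))
            spacer = genome.fetch(chrom, s, s + 20)
            pam_seq = genome.fetch(chrom, s + 20, s + 20 + len(pam))
            if len(pam_seq) < len(pam) or set(spacer) - set("ACGT"):
                continue
            if not all(b in IUPAC[c] for b, c in zip(pam_seq, pam)):
                continue
            window = [i for i in range(3, 10) if spacer[i] == "A"]
            if not window:
                continue
            off = window[int(rng.integers(0, len(window)))]
            guides.append(GuideSpec(name=f"g_{editor}", spacer=spacer,
                                    pam_pattern=pam, editor_id=editor))
            edits[f"g_{editor}"] = VariantKey(chrom, s + off + 1, "A", "G")
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place a guide for {editor}")
    return guides, edits


def default_design(config: SimulationConfig) -> CohortDesign:
    """The study layout at desk scale (see module docstring)."""
    rng = _stream(config.rng_seed, "design")
    rows = []

    def add(pid, group, editor="none", guides=".", callus=".", complete=1,
            copies=0, rpm=0.0, dna=1, rna=0, gen="T0", transgene=".",
            active=0, clusters=0, missing="."):
        rows.append(dict(zip(DESIGN_COLUMNS,
                             [pid, group, editor, guides, callus, complete,
                              copies, rpm, dna, rna, gen, transgene, active,
                              clusters, missing])))

    for i in range(config.n_background_plants):
        add(f"WT{i + 1:02d}", "kitaake")
    for i in range(config.n_tissue_culture):
        add(f"TC_s{i + 1}", "tissue_culture")
    for i in range(config.n_agro_infection):
        add(f"AG_s{i + 1}", "agro_infection", rna=1)
    for i in range(config.n_cas_only):
        add(f"Cas_s{i + 1}", "cas_only", copies=1, rna=1)

    partial = {("rBE50", "M", 3), ("rBE50", "G", 3),
               ("rBE53", "M", 3), ("rBE53", "G", 3)}
    for editor in config.editors:
        has_rna = editor in ("rBE46b", "rBE49b")
        for arm in ("M", "G"):  # M = no guides, G = with guide(s)
            for i in range(1, config.n_plants_per_abe_arm + 1):
                pid = f"{editor}{arm}_s{i}"
                guides = f"g_{editor}" if arm == "G" else "."
                callus = f"callus_{editor}M" if (arm == "M" and i in (2, 3)
                                                 and has_rna) else "."
                is_partial = (editor, arm, i) in partial
                copies = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
                rpm = 0.0
                active = 0
                if has_rna:
                    if i == 1:
                        rpm, active = config.high_expression_rpm, 1
                    else:
                        rpm = config.low_expression_rpm
                add(pid, "abe", editor=editor, guides=guides, callus=callus,
                    complete=0 if is_partial else 1, copies=copies, rpm=rpm,
                    rna=1 if has_rna else 0, active=active,
                    clusters=1 if i == 1 else 0,
                    missing=str(rng.choice(["Cas", "TadA"])) if is_partial else ".")
    # segregation generation of a high-expression line: two carriers, two nulls
    for i, tg in enumerate((1, 1, 0, 0), start=1):
        add(f"rBE49bG_T1_N{i}", "abe", editor="rBE49b", guides="g_rBE49b",
            dna=0, rna=1, gen="T1", transgene=tg, copies=1 if tg else 0,
            rpm=config.high_expression_rpm if tg else 0.0, active=tg)
    return CohortDesign(pd.DataFrame(rows, columns=DESIGN_COLUMNS))


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------

class _PositionPools:
    """Pre-indexed sampling pools over the genome (0-based global coords)."""

    def __init__(self, genome: GenomeSequence, annotation: AnnotationSet):
        from mutscape import intervals as iv

        self.names = genome.chrom_names
        self.offsets = np.cumsum([0] + [genome.lengths[c] for c in self.names])
        self.genome = genome
        at_genic, at_inter = [], []
        genic_iv = annotation.region_intervals("genic")
        for ci, c in enumerate(self.names):
            codes = np.frombuffer(genome.sequences[c].encode(), dtype=np.uint8)
            is_at = (codes == ord("A")) | (codes == ord("T"))
            pos = np.flatnonzero(is_at)
            in_genic = iv.contains_points(genic_iv[c], pos)
            at_genic.append(pos[in_genic] + self.offsets[ci])
            at_inter.append(pos[~in_genic] + self.offsets[ci])
        self.at_genic = np.concatenate(at_genic) if at_genic else np.empty(0, int)
        self.at_inter = np.concatenate(at_inter) if at_inter else np.empty(0, int)
        self.at_by_chrom = {c: np.flatnonzero(
            (np.frombuffer(genome.sequences[c].encode(), dtype=np.uint8) == ord("A")) |
            (np.frombuffer(genome.sequences[c].encode(), dtype=np.uint8) == ord("T")))
            for c in self.names}
        self.total = int(self.offsets[-1])

    def decode(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.offsets, gpos, side="right") - 1)
        return self.names[ci], int(gpos - self.offsets[ci])

    def base(self, gpos: int) -> str:
        c, p = self.decode(gpos)
        return self.genome.sequences[c][p]


def _draw_distinct(rng, n: int, pool_size: int, taken: set[int],
                   pool: np.ndarray | None = None) -> list[int]:
    """Sample n distinct (and not-yet-taken) values, with-replacement + reject."""
    out: list[int] = []
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 1000:
            raise RuntimeError("position pool exhausted")
        size = max(8, 2 * (n - len(out)))
        draw = (rng.choice(pool, size=size) if pool is not None
                else rng.integers(0, pool_size, size=size))
        for v in map(int, draw):
            if v not in taken:
                taken.add(v)
                out.append(v)
                if len(out) == n:
                    break
    return out


_NON_AG_ALTS = {"A": "CT", "T": "AG", "C": "AGT", "G": "ACT"}


def _snv_at(pools: _PositionPools, gpos: int, rng, force_ag: bool) -> VariantKey:
    chrom, p0 = pools.decode(gpos)
    ref = pools.genome.sequences[chrom][p0]
    if force_ag:
        alt = "G" if ref == "A" else "C"
    else:
        choices = _NON_AG_ALTS[ref]
        alt = choices[int(rng.integers(0, len(choices)))]
    return VariantKey(chrom, p0 + 1, ref, alt)


def _induced_set(rng, pools: _PositionPools, n: int, f_ag: float,
                 genic_enrichment: float, genic_fraction: float,
                 taken: set[int], origin_stage: str) -> list[TruthVariant]:
    """Induced het SNVs: fraction f_ag are A>G-class placed on A/T bases
    with genic enrichment; the rest are uniform non-A>G substitutions."""
    p_genic = min(1.0, genic_enrichment * genic_fraction)
    out = []
    for _ in range(n):
        if rng.random() < f_ag:
            pool = pools.at_genic if (rng.random() < p_genic and
                                      len(pools.at_genic)) else pools.at_inter
            if not len(pool):
                pool = pools.at_genic
            gpos = _draw_distinct(rng, 1, pools.total, taken, pool)[0]
            key = _snv_at(pools, gpos, rng, force_ag=True)
            out.append(TruthVariant(key, "het", "induced_AG", origin_stage))
        else:
            gpos = _draw_distinct(rng, 1, pools.total, taken)[0]
            key = _snv_at(pools, gpos, rng, force_ag=False)
            out.append(TruthVariant(key, "het", "induced_other", origin_stage))
    return out


def _indel_at(pools: _PositionPools, gpos: int, rng) -> VariantKey | None:
    from mutscape.core_io import normalize_key

    chrom, p0 = pools.decode(gpos)
    seq = pools.genome.sequences[chrom]
    if p0 + 1 >= len(seq):
        return None
    if rng.random() < 0.5:  # insertion
        ref = seq[p0]
        ins = "ACGT"[int(rng.integers(0, 4))]
        key = VariantKey(chrom, p0 + 1, ref, ref + ins)
    else:
        ref = seq[p0:p0 + 2]
        key = VariantKey(chrom, p0 + 1, ref, ref[0])
    # emit the left-aligned canonical spelling so truth bookkeeping matches
    # what any normalizing caller-consensus will report
    return normalize_key(key.chrom, key.pos, key.ref, key.alt, pools.genome)


def simulate_truth(config: SimulationConfig, genome: GenomeSequence,
                   annotation: AnnotationSet, design: CohortDesign,
                   on_target_edits: Mapping[str, VariantKey] | None = None
                   ) -> TruthTable:
    """Plant the cohort's true mutations.

    Shared homozygous background in every plant; per-plant Poisson het
    tissue-culture SNVs/indels of uniform spectrum in every regenerated
    plant; ABE plants additionally receive induced het SNVs (A>G fraction
    f, genic enrichment), sibling-callus common subsets with a lower A>G
    fraction, clustered A>G runs in flagged plants, and guide-directed
    on-target edits.  Partial-T-DNA plants get induced counts scaled down.
    """
    pools = _PositionPools(genome, annotation)
    genic_fraction = annotation.genome_fraction("genic")
    taken_shared: set[int] = set()

    bg_rng = _stream(config.rng_seed, "background")
    background: list[TruthVariant] = []
    for gpos in _draw_distinct(bg_rng, config.background_hom_snvs, pools.total,
                               taken_shared):
        chrom, p0 = pools.decode(gpos)
        ref = genome.sequences[chrom][p0]
        alt = "ACGT".replace(ref, "")[int(bg_rng.integers(0, 3))]
        background.append(TruthVariant(VariantKey(chrom, p0 + 1, ref, alt),
                                       "hom", "background", "NA"))
    for gpos in _draw_distinct(bg_rng, config.background_indels, pools.total,
                               taken_shared):
        key = _indel_at(pools, gpos, bg_rng)
        if key is not None:
            background.append(TruthVariant(key, "hom", "background", "NA"))

    # common-stage subsets shared within each callus
    common_by_callus: dict[str, list[TruthVariant]] = {}
    for callus in sorted(set(design.table["callus_id"]) - {"."}):
        crng = _stream(config.rng_seed, "callus", callus)
        n = int(crng.poisson(config.sibling_common_snvs))
        common_by_callus[callus] = _induced_set(
            crng, pools, n, config.common_stage_ag_fraction,
            config.genic_enrichment, genic_fraction, taken_shared,
            "pre_integration")

    truth = TruthTable()
    for _, row in design.table.iterrows():
        pid = row["plant_id"]
        if not int(row["dna"]):
            continue
        rng = _stream(config.rng_seed, "truth", pid)
        taken = set(taken_shared)
        entries: list[TruthVariant] = list(background)

        # clustered runs are planted first and reserve a +/-31 bp margin in
        # ``taken`` so later singleton draws cannot bleed into a cluster's
        # merge window
        cluster_entries: list[TruthVariant] = []
        if row["group"] == "abe" and int(row["dna_clusters"]):
            cluster_entries = _cluster_runs(rng, pools, config, taken)

        if row["group"] != "kitaake":
            n_tc = int(rng.poisson(config.tissue_culture_het_snvs))
            for gpos in _draw_distinct(rng, n_tc, pools.total, taken):
                chrom, p0 = pools.decode(gpos)
                ref = genome.sequences[chrom][p0]
                alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
                entries.append(TruthVariant(VariantKey(chrom, p0 + 1, ref, alt),
                                            "het", "tissue_culture", "NA"))
            n_ind = int(rng.poisson(config.tissue_culture_indels))
            for gpos in _draw_distinct(rng, n_ind, pools.total, taken):
                key = _indel_at(pools, gpos, rng)
                if key is not None:
                    entries.append(TruthVariant(key, "het", "tissue_culture", "NA"))

        if row["group"] == "abe":
            scale = 1.0 if int(row["tdna_complete"]) else config.partial_tdna_scale
            callus = row["callus_id"]
            if callus != ".":
                for tv in common_by_callus[callus]:
                    entries.append(tv)
                    taken.add(_gpos_of(pools, tv.key))
                f_unique = config.unique_stage_ag_fraction
            else:
                f_unique = config.induced_ag_fraction
            n_unique = int(rng.poisson(config.induced_snvs_mean * scale))
            entries.extend(_induced_set(rng, pools, n_unique, f_unique,
                                        config.genic_enrichment, genic_fraction,
                                        taken, "post_integration"))
            entries.extend(cluster_entries)
            for gname in (row["guides"].split(",") if row["guides"] != "." else []):
                if on_target_edits and gname in on_target_edits:
                    key = on_target_edits[gname]
                    gp = _gpos_of(pools, key)
                    if gp not in taken:
                        taken.add(gp)
                        entries.append(TruthVariant(key, "het", "on_target",
                                                    "pre_integration"))
        entries.sort(key=lambda tv: (tv.key.chrom, tv.key.pos, tv.key.alt))
        truth.entries[pid] = entries
    return truth


def _gpos_of(pools: _PositionPools, key: VariantKey) -> int:
    ci = pools.names.index(key.chrom)
    return int(pools.offsets[ci] + key.pos - 1)


def _cluster_runs(rng, pools: _PositionPools, config: SimulationConfig,
                  taken: set[int]) -> list[TruthVariant]:
    """Plant runs of 2-10 A>G SNVs on nearby A/T sites within the span."""
    out = []
    for _ in range(config.dna_cluster_loci):
        for _attempt in range(200):
            genic = rng.random() < config.cluster_genic_fraction
            pool = pools.at_genic if genic and len(pools.at_genic) else pools.at_inter
            anchor = int(pool[int(rng.integers(0, len(pool)))])
            chrom, p0 = pools.decode(anchor)
            at = pools.at_by_chrom[chrom]
            off = pools.offsets[pools.names.index(chrom)]
            i0 = int(np.searchsorted(at, p0))
            k = int(rng.integers(2, 11))
            members = [p0]
            j = i0
            while len(members) < k:
                j += int(rng.integers(1, 4))
                if j >= len(at) or at[j] - p0 > config.dna_cluster_span or \
                        at[j] - members[-1] > 30:
                    break
                members.append(int(at[j]))
            if len(members) < 2:
                continue
            gmembers = [int(off + m) for m in members]
            if any(g in taken for g in gmembers):
                continue
            # reserve a margin so nothing else lands in the merge window
            for g in range(gmembers[0] - 31, gmembers[-1] + 32):
                taken.add(g)
            for m in members:
                ref = pools.genome.sequences[chrom][m]
                alt = "G" if ref == "A" else "C"
                out.append(TruthVariant(VariantKey(chrom, m + 1, ref, alt),
                                        "het", "cluster", "post_integration"))
            break
    return out


# ---------------------------------------------------------------------------
# Caller emulation
# ---------------------------------------------------------------------------

def _depths(rng, zygosity: str, coverage_mean: float) -> tuple[int, int]:
    cov = max(2, int(rng.poisson(coverage_mean)))
    p = 0.98 if zygosity == "hom" else 0.5
    hi = cov if zygosity == "hom" else cov - 1
    alt = min(max(int(rng.binomial(cov, p)), 1), hi)
    return cov - alt, alt


def emulate_callers(truth: TruthTable, genome: GenomeSequence,
                    config: SimulationConfig
                    ) -> dict[str, dict[str, list[VariantCall]]]:
    """Per-plant per-caller variant calls.

    Each true variant is detected by each caller independently with
    probability ``caller_sensitivity``; caller-specific false positives
    are added at ``caller_fp_per_mb`` (het, uniform positions and
    alleles).  The third caller calls no indels, so the two-caller indel
    consensus rule is meaningful.
    """
    chrom_order = {c: i for i, c in enumerate(genome.chrom_names)}
    lengths = genome.lengths
    total_mb = genome.total_length / 1e6
    out: dict[str, dict[str, list[VariantCall]]] = {}
    for pid in sorted(truth.entries):
        out[pid] = {}
        for caller in config.caller_ids:
            rng = _stream(config.rng_seed, "caller", pid, caller)
            calls: list[VariantCall] = []
            for tv in truth.entries[pid]:
                is_indel = len(tv.key.ref) != 1 or len(tv.key.alt) != 1
                if is_indel and caller == "lofreq":
                    continue
                if rng.random() > config.caller_sensitivity:
                    continue
                ad = _depths(rng, tv.zygosity, config.coverage_mean)
                calls.append(VariantCall(pid, caller, tv.key.chrom, tv.key.pos,
                                         tv.key.ref, tv.key.alt, tv.zygosity, ad))
            n_fp = int(rng.poisson(total_mb * config.caller_fp_per_mb))
            for _ in range(n_fp):
                chrom = genome.chrom_names[int(rng.integers(0, len(genome.chrom_names)))]
                pos = int(rng.integers(1, lengths[chrom] + 1))
                ref = genome.base(chrom, pos)
                if ref == "N":
                    continue
                alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
                ad = _depths(rng, "het", config.coverage_mean)
                calls.append(VariantCall(pid, caller, chrom, pos, ref, alt,
                                         "het", ad))
            calls.sort(key=lambda c: (chrom_order[c.chrom], c.pos, c.alt))
            out[pid][caller] = calls
    return out


# ---------------------------------------------------------------------------
# RNA simulation
# ---------------------------------------------------------------------------

def _exonic_a_pools(genome: GenomeSequence, annotation: AnnotationSet):
    """Exonic A/T positions split by whether the -1 context on the edited
    strand is a pyrimidine (the YAN-favoured context)."""
    from mutscape import intervals as iv

    pools = {("A", True): [], ("A", False): [], ("T", True): [], ("T", False): []}
    exonic = annotation.region_intervals("exonic")
    for c in genome.chrom_names:
        seq = genome.sequences[c]
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        ex_mask = iv.contains_points(exonic[c], np.arange(len(seq)))
        for p0 in np.flatnonzero(ex_mask):
            b = seq[p0]
            if b == "A" and p0 >= 1:
                pools[("A", seq[p0 - 1] in "CT")].append((c, int(p0 + 1)))
            elif b == "T" and p0 + 1 < len(seq):
                # edited strand is the complement; its -1 base pairs with p0+1
                pools[("T", seq[p0 + 1] in "AG")].append((c, int(p0 + 1)))
    return pools


def simulate_rna(config: SimulationConfig, genome: GenomeSequence,
                 annotation: AnnotationSet, design: CohortDesign) -> RnaSimulation:
    """Expression-dependent RNA A>G editing with YAN context bias.

    Edited loci sit on exonic adenines (or thymines for minus-strand
    transcripts); a fraction carry 2-6 satellite edits within 30 bp.  The
    per-locus base editing ratio is shared across plants (driving the
    cross-plant concordance of real ABE targets); plants with low editor
    expression, Cas-only plants, infection controls and transgene-free
    offspring stay at the sequencing noise floor.
    """
    rng = _stream(config.rng_seed, "rna")
    pools = _exonic_a_pools(genome, annotation)
    for key in pools:
        pools[key] = sorted(pools[key])
    used: set[tuple[str, int]] = set()

    def pick(ref: str, yan: bool) -> tuple[str, int] | None:
        pool = pools[(ref, yan)]
        for _ in range(200):
            if not pool:
                return None
            cand = pool[int(rng.integers(0, len(pool)))]
            if cand not in used:
                used.add(cand)
                return cand
        return None

    m = config.rna_ratio_mean
    conc = 10.0
    loci: list[SimEditLocus] = []
    for _ in range(config.rna_edit_loci):
        ref = "A" if rng.random() < 0.5 else "T"
        yan = rng.random() < config.yan_bias
        hit = pick(ref, yan) or pick(ref, not yan)
        if hit is None:
            raise RuntimeError("not enough exonic A/T positions for RNA loci")
        chrom, pos = hit
        ratio = float(rng.beta(conc * m, conc * (1 - m))) if m > 0 else 0.0
        clustered = rng.random() < config.rna_cluster_fraction
        sat: list[tuple[str, int, str]] = []
        if clustered:
            seq = genome.sequences[chrom]
            cand = [(chrom, pos + d, seq[pos - 1 + d])
                    for d in range(-30, 31) if d != 0
                    and 1 <= pos + d <= len(seq)
                    and seq[pos - 1 + d] in "AT"
                    and (chrom, pos + d) not in used]
            def _is_yan(c):
                _, p, ref = c
                if ref == "A":
                    return p >= 2 and seq[p - 2] in "CT"
                return p < len(seq) and seq[p] in "AG"
            yan_cand = [c for c in cand if _is_yan(c)]
            other_cand = [c for c in cand if not _is_yan(c)]
            n_sat = min(int(rng.integers(2, 7)), len(cand))
            for _ in range(n_sat):
                pool_c = yan_cand if (rng.random() < config.yan_bias and
                                      yan_cand) else (other_cand or yan_cand)
                c = pool_c.pop(int(rng.integers(0, len(pool_c))))
                used.add((c[0], c[1]))
                sat.append(c)
        loci.append(SimEditLocus(RnaEditLocus(chrom, pos, ref), ratio,
                                 clustered, yan, sat))

    # germline-like RNA background shared by every transcriptome; kept out
    # of the +/-35 bp flanking windows so control flank profiles measure
    # editing noise only
    near_focal: set[tuple[str, int]] = set()
    for l in loci:
        for d in range(-35, 36):
            near_focal.add((l.locus.chrom, l.locus.pos + d))
    background_keys: list[VariantKey] = []
    exonic_any = sorted(set().union(*[set(p) for p in pools.values()]))
    for _ in range(config.rna_background_snvs):
        for _try in range(200):
            chrom, pos = exonic_any[int(rng.integers(0, len(exonic_any)))]
            if (chrom, pos) in used or (chrom, pos) in near_focal:
                continue
            used.add((chrom, pos))
            ref = genome.base(chrom, pos)
            alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
            background_keys.append(VariantKey(chrom, pos, ref, alt))
            break

    # pileup positions: +/- (window+1) around each focal locus + backgrounds
    positions: set[tuple[str, int]] = set()
    for l in loci:
        L = len(genome.sequences[l.locus.chrom])
        for p in range(max(1, l.locus.pos - 31), min(L, l.locus.pos + 31) + 1):
            positions.add((l.locus.chrom, p))
    for k in background_keys:
        positions.add((k.chrom, k.pos))
    pos_list = sorted(positions)

    edit_p: dict[tuple[str, int], tuple[str, float]] = {}
    for l in loci:
        edit_p[(l.locus.chrom, l.locus.pos)] = (l.locus.ref_base, l.base_ratio)
        for chrom, pos, ref in l.satellites:
            edit_p[(chrom, pos)] = (ref, l.base_ratio * 0.7)
    bg_map = {(k.chrom, k.pos): (k.ref, k.alt) for k in background_keys}

    refs = np.array([genome.base(c, p) for c, p in pos_list])
    base_idx = {b: i for i, b in enumerate("ACGT")}
    ref_idx = np.array([base_idx[b] for b in refs])
    n_pos = len(pos_list)

    frames = []
    calls: dict[str, dict[str, list[VariantCall]]] = {}
    rna_plants = design.plants(rna=1)
    for pid in sorted(rna_plants):
        prow = design.row(pid)
        active = bool(int(prow["rna_active"]))
        prng = _stream(config.rng_seed, "rna_plant", pid)
        pvals = np.full((n_pos, 4), config.base_error / 3.0)
        target = np.full(n_pos, -1)
        p_t = np.zeros(n_pos)
        for i, cp in enumerate(pos_list):
            if cp in edit_p and active:
                ref, pr = edit_p[cp]
                target[i] = base_idx["G"] if ref == "A" else base_idx["C"]
                p_t[i] = pr
            elif cp in bg_map:
                ref, alt = bg_map[cp]
                target[i] = base_idx[alt]
                p_t[i] = 0.5
        rows_idx = np.arange(n_pos)
        pvals[rows_idx, ref_idx] = 0.0
        has_t = target >= 0
        pvals[rows_idx[has_t], target[has_t]] += p_t[has_t]
        pvals[rows_idx, ref_idx] = 1.0 - pvals.sum(axis=1)
        cov = prng.poisson(config.coverage_mean, size=n_pos)
        counts = prng.multinomial(cov, pvals)
        frames.append(pd.DataFrame({
            "plant_id": pid, "source": "RNA",
            "chrom": [c for c, _ in pos_list], "pos": [p for _, p in pos_list],
            "nA": counts[:, 0], "nC": counts[:, 1],
            "nG": counts[:, 2], "nT": counts[:, 3]}))

        # variants detectable from this plant's transcriptome
        detected: list[VariantCall] = []
        for i, cp in enumerate(pos_list):
            if target[i] < 0:
                continue
            n_alt = int(counts[i, target[i]])
            ctot = int(counts[i].sum())
            if ctot == 0 or n_alt < 3 or n_alt / ctot < 0.1:
                continue
            ref = refs[i]
            alt = "ACGT"[int(target[i])]
            detected.append(VariantCall(pid, None, cp[0], cp[1], ref, alt,
                                        "het", (ctot - n_alt, n_alt)))
        calls[pid] = {}
        for caller in config.caller_ids:
            crng = _stream(config.rng_seed, "rna_caller", pid, caller)
            kept = [VariantCall(v.plant_id, caller, v.chrom, v.pos, v.ref,
                                v.alt, v.zygosity, v.allele_depths)
                    for v in detected
                    if crng.random() <= config.caller_sensitivity]
            calls[pid][caller] = kept

    read_rows = []
    for pid in sorted(rna_plants):
        rpm = float(design.row(pid)["expression_rpm"])
        n = int(round(rpm * config.total_rna_reads / 1e6))
        read_rows.append({"plant_id": pid, "cas_reads": n, "tada_reads": n,
                          "total_reads": config.total_rna_reads})
    pileups = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=["plant_id", "source", "chrom", "pos",
                                          "nA", "nC", "nG", "nT"]))
    return RnaSimulation(loci=loci, background_keys=background_keys,
                         pileups=pileups, calls=calls,
                         read_counts=pd.DataFrame(read_rows))


# ---------------------------------------------------------------------------
# T-DNA coverage
# ---------------------------------------------------------------------------

def simulate_tdna_coverage(design: CohortDesign, config: SimulationConfig
                           ) -> tuple[dict[str, np.ndarray], float]:
    """Per-plant T-DNA coverage tracks plus the genome mean coverage.

    Complete insertions give uniform Poisson coverage at
    copies x (genome coverage / 2) across LB..RB; a partial insertion
    zeroes out its missing feature's interval (residual mapping noise
    lambda = 0.2).
    """
    fm = config.tdna_features
    tracks: dict[str, np.ndarray] = {}
    for _, row in design.table.iterrows():
        if row["editor"] == "none" or not int(row["dna"]):
            continue
        pid = row["plant_id"]
        rng = _stream(config.rng_seed, "tdna", pid)
        copies = int(row["tdna_copies"])
        lam = np.full(fm.length, copies * config.coverage_mean / 2.0)
        if not int(row["tdna_complete"]):
            name = row["missing_feature"]
            if name not in fm.names():
                raise ValueError(f"unknown T-DNA feature {name!r}")
            s, e = fm.interval(name)
            lam[s - 1:e] = 0.2
        tracks[pid] = rng.poisson(lam).astype(float)
    return tracks, config.coverage_mean


# ---------------------------------------------------------------------------
# Orchestration and output
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full synthetic study for one configuration."""
    genome, annotation = simulate_genome(config)
    guides, edits = _pick_guides(config, genome, annotation)
    design = default_design(config)
    truth = simulate_truth(config, genome, annotation, design, edits)
    dna_calls = emulate_callers(truth, genome, config)
    rna = simulate_rna(config, genome, annotation, design)
    tdna_tracks, genome_mean = simulate_tdna_coverage(design, config)
    return SyntheticCohort(config=config, genome=genome, annotation=annotation,
                           design=design, guides=guides, on_target_edits=edits,
                           truth=truth, dna_calls=dna_calls, rna=rna,
                           tdna_tracks=tdna_tracks, genome_mean_cov=genome_mean)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Emit the cohort as plain-text files (FASTA, GFF3, VCFs, TSVs)."""
    out = Path(outdir)
    (out / "vcf_dna").mkdir(parents=True, exist_ok=True)
    (out / "vcf_rna").mkdir(exist_ok=True)
    (out / "tdna").mkdir(exist_ok=True)
    core_io.write_fasta(cohort.genome, out / "genome.fa")
    core_io.write_gff3(cohort.annotation, out / "annotation.gff3")
    core_io.write_design(cohort.design, out / "design.tsv")
    core_io.write_guides(cohort.guides, out / "guides.tsv")
    cohort.truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    contigs = cohort.genome.lengths
    for pid in sorted(cohort.dna_calls):
        for caller, calls in sorted(cohort.dna_calls[pid].items()):
            core_io.write_vcf(calls, out / "vcf_dna" / f"{pid}.{caller}.vcf",
                              contigs=contigs, sample=pid)
    for pid in sorted(cohort.rna.calls):
        for caller, calls in sorted(cohort.rna.calls[pid].items()):
            core_io.write_vcf(calls, out / "vcf_rna" / f"{pid}.{caller}.vcf",
                              contigs=contigs, sample=pid)
    core_io.write_pileups(cohort.rna.pileups, out / "pileups_rna.tsv")
    cohort.rna.read_counts.to_csv(out / "read_counts.tsv", sep="\t", index=False)
    with open(out / "tdna_features.bed", "w") as fh:
        for name, s, e in cohort.config.tdna_features.features:
            fh.write(f"tdna\t{s - 1}\t{e}\t{name}\t0\t+\n")
    for pid in sorted(cohort.tdna_tracks):
        core_io.write_coverage_track(cohort.tdna_tracks[pid],
                                     out / "tdna" / f"{pid}.cov.tsv")
    pd.DataFrame([{"genome_mean_coverage": cohort.genome_mean_cov}]).to_csv(
        out / "genome_coverage.tsv", sep="\t", index=False)
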