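"""RNA off-target editing analysis.

Deaminase domains of ABEs act on transcripts independently of the guide,
producing transcriptome-wide A-to-G changes (read as T-to-C on the
opposite strand).  This module detects RNA-only SNVs (called in the
transcriptome but absent from the same plant's genome and from pooled
infection-control transcriptomes), quantifies per-locus editing ratios,
tests each ABE plant against the Cas-only pool, quantifies editor
expression (RPM), and summarises the sequence context of edited sites as
a position frequency matrix with per-column information content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mutscape.consensus import ConsensusSet
from mutscape.core_io import GenomeSequence, VariantKey, revcomp
from mutscape.spectrum import group_compare

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class RnaEditLocus:
    """A candidate edited position; ref_base is A or T on the genome strand."""

    chrom: str
    pos: int
    ref_base: str

    def __post_init__(self):
        if self.ref_base not in ("A", "T"):
            raise ValueError(f"edit locus ref must be A or T, got {self.ref_base!r}")


def rna_minus_dna(rna_consensus: ConsensusSet, dna_consensus: ConsensusSet | None,
                  background_rna: Sequence[ConsensusSet]) -> set[VariantKey]:
    """RNA-only SNVs: RNA consensus minus DNA consensus minus RNA background.

    The DNA partner is mandatory (pass an explicit empty set only for
    plants that genuinely have no genome data, e.g. segregation-test
    offspring handled elsewhere).
    """
    if dna_consensus is None:
        raise ValueError(f"plant {rna_consensus.plant_id}: missing DNA consensus")
    bg: set[VariantKey] = set()
    for b in background_rna:
        bg |= b.keys(snvs_only=True)
    return rna_consensus.keys(snvs_only=True) - dna_consensus.keys() - bg


def editing_ratio(counts: tuple[int, int, int, int], ref_base: str,
                  cov_thr: int = 10) -> float | None:
    """A>G editing ratio at one pileup position.

    Reference A: nG / (nA + nG); reference T (edited strand is the
    complement): nC / (nC + nT).  Returns None (missing) when the total
    read coverage is not strictly above ``cov_thr``.
    """
    nA, nC, nG, nT = counts
    if ref_base == "A":
        denom = nA + nG
        num = nG
    elif ref_base == "T":
        denom = nC + nT
        num = nC
    else:
        raise ValueError(f"reference base must be A or T, got {ref_base!r}")
    if nA + nC + nG + nT <= cov_thr:
        return None
    return num / denom if denom else 0.0


def ratio_matrix(loci: Sequence[RnaEditLocus], pileups: pd.DataFrame,
                 cov_thr: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Editing-ratio and coverage matrices (loci x plants) from pileup counts.

    ``pileups`` holds one row per (plant_id, chrom, pos) with nA/nC/nG/nT.
    Cells with coverage <= cov_thr are missing (NaN).
    """
    plants = sorted(pileups["plant_id"].unique())
    index = [f"{l.chrom}:{l.pos}" for l in loci]
    ratios = pd.DataFrame(np.nan, index=index, columns=plants)
    covs = pd.DataFrame(0, index=index, columns=plants, dtype=int)
    for p, sub in pileups.groupby("plant_id", sort=True):
        lookup = {(c, pos): (a, cc, g, t) for c, pos, a, cc, g, t in
                  zip(sub["chrom"], sub["pos"], sub["nA"], sub["nC"],
                      sub["nG"], sub["nT"])}
        rvec = np.full(len(loci), np.nan)
        cvec = np.zeros(len(loci), dtype=int)
        for i, l in enumerate(loci):
            counts = lookup.get((l.chrom, l.pos))
            if counts is None:
                continue
            counts = tuple(int(x) for x in counts)
            cvec[i] = sum(counts)
            r = editing_ratio(counts, l.ref_base, cov_thr=cov_thr)
            if r is not None:
                rvec[i] = r
        ratios[p] = rvec
        covs[p] = cvec
    return ratios, covs


def per_plant_test(ratios_plant: Sequence[float],
                   ratios_cas_pool: Sequence[float],
                   min_n: int = 3) -> tuple[float, float] | None:
    """One-tailed (greater) rank-sum test of a plant's editing ratios
    against the pooled Cas-only ratios; returns (p, -log10 p) or None when
    either side has fewer than ``min_n`` non-missing ratios."""
    a = [v for v in ratios_plant if not pd.isna(v)]
    b = [v for v in ratios_cas_pool if not pd.isna(v)]
    if len(a) < min_n or len(b) < min_n:
        return None
    cmp = group_compare(a, b, alternative="greater")
    p = max(cmp.pvalue, 1e-300)
    return cmp.pvalue, -math.log10(p)


def abe_rpm(cas_reads: float, tada_reads: float, total_reads: float) -> float:
    """Editor expression: mean of Cas and TadA read counts per million reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return ((cas_reads + tada_reads) / 2.0) / (total_reads / 1e6)


def expression_grouping(rpm: Mapping[str, float], n_rna_snvs: Mapping[str, int],
                        pvalues: Mapping[str, float | None],
                        snv_threshold: int = 5, alpha: float = 0.05
                        ) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Split ABE plants into with/without RNA mutations and compare RPM.

    A plant "has RNA mutations" when it carries more than ``snv_threshold``
    detected RNA-only A>G SNVs *and* its editing-ratio test against the
    Cas pool is significant (compound rule).  Returns the grouping and a
    one-tailed RPM comparison (with > without).
    """
    with_mut, without = [], []
    for pid in sorted(rpm):
        p = pvalues.get(pid)
        hit = n_rna_snvs.get(pid, 0) >= snv_threshold and p is not None and p < alpha
        (with_mut if hit else without).append(pid)
    groups = {"with_RNA_mutations": with_mut, "without_RNA_mutations": without}
    if with_mut and without:
        cmp = group_compare([rpm[p] for p in with_mut],
                            [rpm[p] for p in without], alternative="greater")
        table = pd.DataFrame([{
            "metric": "abe_rpm", "group_a": "with_RNA_mutations",
            "group_b": "without_RNA_mutations", "n_a": len(with_mut),
            "n_b": len(without), "statistic": cmp.statistic,
            "pvalue": cmp.pvalue, "stars": cmp.stars}])
    else:
        table = pd.DataFrame()
    return groups, table


# ---------------------------------------------------------------------------
# Motif matrix
# ---------------------------------------------------------------------------

def motif_matrix(loci: Sequence[RnaEditLocus], genome: GenomeSequence,
                 flank: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Position frequency matrix around edited sites, center fixed to A.

    Windows around reference-T loci are reverse-complemented so the edited
    strand always reads 5'->3' with the edited A in the center column.
    Returns (counts DataFrame, bits per column) where
    bits = 2 - Shannon entropy (log2) of the column frequencies.
    Chromosome-edge windows contribute only their covered columns.
    """
    if not loci:
        raise ValueError("motif matrix needs at least one locus")
    width = 2 * flank + 1
    counts = np.zeros((4, width), dtype=float)
    for l in loci:
        L = len(genome.sequences[l.chrom])
        lo, hi = l.pos - 1 - flank, l.pos + flank  # 0-based half-open window
        seq = genome.fetch(l.chrom, max(lo, 0), min(hi, L))
        pad_left = max(0, -lo)
        pad_right = max(0, hi - L)
        seq = "." * pad_left + seq + "." * pad_right
        if l.ref_base == "T":
            seq = revcomp(seq.replace(".", "N")).replace("N", ".")
        for j, b in enumerate(seq):
            if b in _IDX:
                counts[_IDX[b], j] += 1
    offsets = list(range(-flank, flank + 1))
    df = pd.DataFrame(counts, index=list(BASES), columns=offsets)
    col_tot = counts.sum(axis=0)
    bits = np.zeros(width)
    for j in range(width):
        if col_tot[j] == 0:
            bits[j] = 0.0
            continue
        freqs = counts[:, j] / col_tot[j]
        ent = -sum(f * math.log2(f) for f in freqs if f > 0)
        bits[j] = 2.0 - ent
    return df, bits


def segregation_check(design_t1: pd.DataFrame, ratios: pd.DataFrame,
                      cas_pool: Sequence[float]) -> pd.DataFrame:
    """Editing-ratio tests for segregation-generation (T1) plants.

    Transgene-free offspring are expected to lose RNA editing entirely
    (non-significant test); transgene carriers should remain active.
    """
    rows = []
    for _, r in design_t1.iterrows():
        pid = r["plant_id"]
        vec = ratios[pid] if pid in ratios.columns else pd.Series(dtype=float)
        res = per_plant_test(list(vec), list(cas_pool))
        rows.append({"plant_id": pid, "transgene": int(r["transgene"]),
                     "n_ratios": int(vec.notna().sum()),
                     "pvalue": np.nan if res is None else res[0],
                     "minus_log10_p": np.nan if res is None else res[1]})
    return pd.DataFrame(rows, columns=["plant_id", "transgene", "n_ratios",
                                       "pvalue", "minus_log10_p"])
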