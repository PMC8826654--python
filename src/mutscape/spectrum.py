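"""Mutation spectrum statistics: six strand-collapsed SNV classes, A>G
percentages, genomic-region enrichment, chromosome distribution, and
one-tailed Wilcoxon group comparisons.

The six classes collapse each substitution with its reverse complement
(e.g. T>C is counted as A>G), so the "A>G count" of a plant is the total
number of A>G plus T>C SNVs and the "A>G percentage" is that count over
all six classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mutscape.core_io import AnnotationSet, GenomeSequence, VariantKey

SNV_CLASSES = ("A>G", "C>T", "A>T", "A>C", "C>A", "C>G")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def collapse_class(ref: str, alt: str) -> str:
    """Strand-collapsed class of a single-base substitution.

    Substitutions from G or T are complemented so every class is anchored
    on A or C: T>C -> A>G, G>A -> C>T, G>T -> C>A, and so on.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt or \
            ref not in _COMP or alt not in _COMP:
        raise ValueError(f"not a SNV: {ref}>{alt}")
    if ref in ("G", "T"):
        ref, alt = _COMP[ref], _COMP[alt]
    return f"{ref}>{alt}"


@dataclass
class SpectrumSummary:
    """Per-plant six-class spectrum with indel count and percentages."""

    plant_id: str
    counts: dict[str, int] = field(default_factory=dict)
    n_indels: int = 0

    def __post_init__(self):
        self.counts = {c: int(self.counts.get(c, 0)) for c in SNV_CLASSES}

    @property
    def n_snvs(self) -> int:
        return sum(self.counts.values())

    @property
    def n_ag(self) -> int:
        return self.counts["A>G"]

    def pct(self, cls: str) -> float | None:
        """Class percentage of all SNVs; missing (None) when n_snvs == 0."""
        if self.n_snvs == 0:
            return None
        return 100.0 * self.counts[cls] / self.n_snvs

    @property
    def pct_ag(self) -> float | None:
        return self.pct("A>G")


def spectrum_summary(variants: Iterable, plant_id: str = "") -> SpectrumSummary:
    """Summarise a plant's (already filtered) variant set.

    Accepts VariantCall or VariantKey objects; non-SNVs count as indels.
    """
    counts = {c: 0 for c in SNV_CLASSES}
    n_indels = 0
    for v in variants:
        ref, alt = v.ref, v.alt
        if len(ref) == 1 and len(alt) == 1:
            counts[collapse_class(ref, alt)] += 1
        else:
            n_indels += 1
    return SpectrumSummary(plant_id=plant_id, counts=counts, n_indels=n_indels)


def spectrum_table(summaries: Sequence[SpectrumSummary]) -> pd.DataFrame:
    """One row per plant: counts, indels and percentages (NaN when empty)."""
    rows = []
    for s in summaries:
        row = {"plant_id": s.plant_id, "n_snvs": s.n_snvs, "n_indels": s.n_indels,
               "n_ag": s.n_ag}
        for c in SNV_CLASSES:
            row[f"n[{c}]"] = s.counts[c]
        for c in SNV_CLASSES:
            p = s.pct(c)
            row[f"pct[{c}]"] = np.nan if p is None else p
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Region enrichment
# ---------------------------------------------------------------------------

def region_enrichment(keys: Sequence[VariantKey], annotation: AnnotationSet) -> pd.DataFrame:
    """SNV enrichment per region class.

    For each of genic/exonic/intronic/intergenic: the SNV count, the
    fraction of SNVs, the genome length fraction, the length-normalised
    ratio (snv_fraction / genome_fraction), and the per-region A>G
    percentage.  Each SNV belongs to exactly one of exonic / intronic /
    intergenic; genic = exonic + intronic.
    """
    snvs = [k for k in keys if len(k.ref) == 1 and len(k.alt) == 1]
    assignment = [annotation.classify(k.chrom, k.pos) for k in snvs]
    total = len(snvs)
    rows = []
    for region in ("genic", "exonic", "intronic", "intergenic"):
        if region == "genic":
            members = [k for k, a in zip(snvs, assignment) if a in ("exonic", "intronic")]
        else:
            members = [k for k, a in zip(snvs, assignment) if a == region]
        n = len(members)
        gfrac = annotation.genome_fraction(region)
        sfrac = n / total if total else np.nan
        n_ag = sum(1 for k in members if collapse_class(k.ref, k.alt) == "A>G")
        rows.append({
            "region": region,
            "n_snvs": n,
            "genome_fraction": gfrac,
            "snv_fraction": sfrac,
            "ratio": sfrac / gfrac if total and gfrac > 0 else np.nan,
            "pct_ag": 100.0 * n_ag / n if n else np.nan,
        })
    return pd.DataFrame(rows)


def chromosome_distribution(keys: Sequence[VariantKey],
                            genome: GenomeSequence) -> pd.DataFrame:
    """Per-chromosome variant counts and per-Mb densities."""
    counts = {c: 0 for c in genome.chrom_names}
    for k in keys:
        if k.chrom in counts:
            counts[k.chrom] += 1
    rows = [{"chrom": c, "n": counts[c],
             "length_mb": genome.lengths[c] / 1e6,
             "per_mb": counts[c] / (genome.lengths[c] / 1e6)}
            for c in genome.chrom_names]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group comparison (one-tailed Wilcoxon rank-sum)
# ---------------------------------------------------------------------------

#: Significance stars used throughout the report tables.
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.1, "*"))


def star_category(pvalue: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if pvalue < thr:
            return stars
    return "ns"


@dataclass
class GroupComparison:
    statistic: float
    pvalue: float
    stars: str
    method: str


def group_compare(values_a: Sequence[float], values_b: Sequence[float],
                  alternative: str = "greater") -> GroupComparison:
    """One-tailed Wilcoxon rank-sum (Mann-Whitney) test of a vs b.

    Uses the exact null distribution when both groups have <= 10
    observations and there are no ties, otherwise the normal approximation
    with tie-corrected variance and continuity correction.
    """
    a = np.asarray([v for v in values_a if not (isinstance(v, float) and np.isnan(v))], dtype=float)
    b = np.asarray([v for v in values_b if not (isinstance(v, float) and np.isnan(v))], dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    return GroupComparison(statistic=float(res.statistic), pvalue=float(res.pvalue),
                           stars=star_category(float(res.pvalue)), method=method)


def exact_ranksum_pvalue(a: Sequence[float], b: Sequence[float],
                         alternative: str = "less") -> float:
    """Enumeration oracle: exact one-tailed rank-sum p by listing all
    C(n+m, n) assignments of pooled midranks to group a.  Quadratic-time,
    test use only (n+m <= ~14)."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    ranks = stats.rankdata(pooled)  # midranks handle ties
    n = len(a)
    w_obs = sum(stats.rankdata(a + b)[:n])
    total = hits = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        w = sum(ranks[i] for i in combo)
        total += 1
        if alternative == "less" and w <= w_obs + 1e-9:
            hits += 1
        elif alternative == "greater" and w >= w_obs - 1e-9:
            hits += 1
    return hits / total


def compare_groups_table(groups: Mapping[str, Mapping[str, Sequence[float]]],
                         comparisons: Sequence[tuple[str, str, str, str]]) -> pd.DataFrame:
    """Run a batch of named group comparisons.

    ``groups`` maps group label -> {metric -> values}; ``comparisons`` is a
    list of (group_a, group_b, metric, alternative) tuples.
    """
    rows = []
    for ga, gb, metric, alt in comparisons:
        va = [v for v in groups[ga][metric] if not pd.isna(v)]
        vb = [v for v in groups[gb][metric] if not pd.isna(v)]
        if not va or not vb:
            rows.append({"group_a": ga, "group_b": gb, "metric": metric,
                         "alternative": alt, "statistic": np.nan,
                         "pvalue": np.nan, "stars": "NA", "n_a": len(va),
                         "n_b": len(vb)})
            continue
        cmp = group_compare(va, vb, alternative=alt)
        rows.append({"group_a": ga, "group_b": gb, "metric": metric,
                     "alternative": alt, "statistic": cmp.statistic,
                     "pvalue": cmp.pvalue, "stars": cmp.stars,
                     "n_a": len(va), "n_b": len(vb)})
    return pd.DataFrame(rows)
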