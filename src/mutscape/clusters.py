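"""Clustered-editing detection.

Deaminase off-target events are not always isolated: in transcripts the
editing window can convert several nearby adenines, and in genomes a few
loci accumulate multiple A>G SNVs within tens of base pairs.  Two
statistics capture this:

* the flanking profile — for every focal A>G locus, the fraction of
  eligible A/T positions at each offset in a +/-30 bp window whose
  editing ratio exceeds 0.05 (coverage strictly above 10);
* DNA cluster calls — single-linkage merging of a plant's A>G SNVs
  within a fixed distance, keeping groups of two or more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mutscape.core_io import AnnotationSet, VariantKey
from mutscape.rna import editing_ratio
from mutscape.spectrum import SpectrumSummary, collapse_class, compare_groups_table


def flank_profile(focal_loci: Sequence[tuple[str, int]], pileups: pd.DataFrame,
                  genome, window: int = 30, ratio_thr: float = 0.05,
                  cov_thr: int = 10) -> pd.DataFrame:
    """Aggregate flanking edited-fraction per offset for one plant.

    ``focal_loci`` are (chrom, pos) anchors; ``pileups`` one plant's rows.
    For each offset in -window..window (0 excluded), positions whose
    reference base is A or T and whose coverage is strictly above
    ``cov_thr`` count as eligible; those whose editing ratio is strictly
    above ``ratio_thr`` count as edited.  Fraction is missing when no
    position is eligible at an offset.
    """
    offsets = [o for o in range(-window, window + 1) if o != 0]
    n_edited = {o: 0 for o in offsets}
    n_eligible = {o: 0 for o in offsets}
    lookup = {(c, p): (int(a), int(cc), int(g), int(t))
              for c, p, a, cc, g, t in zip(pileups["chrom"], pileups["pos"],
                                           pileups["nA"], pileups["nC"],
                                           pileups["nG"], pileups["nT"])}
    for chrom, pos in focal_loci:
        L = len(genome.sequences[chrom])
        for o in offsets:
            p = pos + o
            if not 1 <= p <= L:
                continue
            ref = genome.base(chrom, p)
            if ref not in ("A", "T"):
                continue
            counts = lookup.get((chrom, p))
            if counts is None:
                continue
            r = editing_ratio(counts, ref, cov_thr=cov_thr)
            if r is None:
                continue
            n_eligible[o] += 1
            if r > ratio_thr:
                n_edited[o] += 1
    rows = [{"offset": o, "n_edited": n_edited[o], "n_eligible": n_eligible[o],
             "fraction": n_edited[o] / n_eligible[o] if n_eligible[o] else np.nan}
            for o in offsets]
    return pd.DataFrame(rows)


@dataclass
class ClusterCall:
    """A run of nearby A>G SNVs (>= 2 members within the merge distance)."""

    chrom: str
    start: int
    end: int
    members: list[VariantKey] = field(default_factory=list)
    plants: set[str] = field(default_factory=set)
    region: str = ""

    @property
    def n_members(self) -> int:
        return len(self.members)


def _ag_keys(keys: Sequence[VariantKey]) -> list[VariantKey]:
    return [k for k in keys if len(k.ref) == 1 and len(k.alt) == 1
            and collapse_class(k.ref, k.alt) == "A>G"]


def detect_dna_clusters(keys_by_plant: Mapping[str, Sequence[VariantKey]],
                        merge_distance: int = 30,
                        annotation: AnnotationSet | None = None,
                        pooled: bool = False) -> list[ClusterCall]:
    """Single-linkage clusters of A>G SNVs within ``merge_distance``.

    Default mode clusters each plant's SNVs separately; ``pooled=True``
    merges across plants (the cross-plant view of recurrently clustered
    loci).  Only calls with >= 2 members are emitted, sorted by position.
    """
    groups: dict[str, list[tuple[VariantKey, str]]]
    if pooled:
        groups = {"pooled": [(k, p) for p in sorted(keys_by_plant)
                             for k in _ag_keys(keys_by_plant[p])]}
    else:
        groups = {p: [(k, p) for k in _ag_keys(keys_by_plant[p])]
                  for p in sorted(keys_by_plant)}
    calls: list[ClusterCall] = []
    for _, tagged in groups.items():
        by_chrom: dict[str, list[tuple[VariantKey, str]]] = {}
        for k, p in tagged:
            by_chrom.setdefault(k.chrom, []).append((k, p))
        for chrom in sorted(by_chrom):
            items = sorted(set(by_chrom[chrom]), key=lambda t: t[0].pos)
            run: list[tuple[VariantKey, str]] = []
            for item in items:
                if run and item[0].pos - run[-1][0].pos > merge_distance:
                    if len({k for k, _ in run}) >= 2:
                        calls.append(_make_call(chrom, run, annotation))
                    run = []
                run.append(item)
            if len({k for k, _ in run}) >= 2:
                calls.append(_make_call(chrom, run, annotation))
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    return calls


def _make_call(chrom: str, run, annotation) -> ClusterCall:
    members = sorted({k for k, _ in run}, key=lambda k: k.pos)
    plants = {p for _, p in run}
    region = ""
    if annotation is not None:
        mid = members[len(members) // 2]
        cls = annotation.classify(chrom, mid.pos)
        region = "genic" if cls in ("exonic", "intronic") else "intergenic"
    return ClusterCall(chrom=chrom, start=members[0].pos, end=members[-1].pos,
                       members=members, plants=plants, region=region)


def naive_single_linkage(positions: Sequence[int], merge_distance: int) -> list[list[int]]:
    """Quadratic-time single-linkage oracle used in tests.

    Repeatedly unions any two groups containing positions within the merge
    distance of each other until a fixed point; independent of the sorted
    sweep in :func:`detect_dna_clusters`.
    """
    groups = [[p] for p in sorted(set(positions))]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(abs(a - b) <= merge_distance
                       for a in groups[i] for b in groups[j]):
                    groups[i] = sorted(groups[i] + groups[j])
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return [g for g in groups if len(g) >= 2]


def classify_cluster_groups(summaries: Mapping[str, SpectrumSummary],
                            calls: Sequence[ClusterCall],
                            all_ag_keys_by_plant: Mapping[str, Sequence[VariantKey]] | None = None,
                            annotation: AnnotationSet | None = None
                            ) -> tuple[dict[str, list[str]], pd.DataFrame, pd.DataFrame]:
    """Group-1 (>= 1 cluster) vs group-2 classification and comparisons.

    Returns the grouping, three one-tailed Wilcoxon comparisons
    (group1 > group2 on n_snvs, n_ag, pct_ag) and, when the annotation is
    supplied, a two-column genic-fraction table (clustered SNVs vs all A>G
    SNVs).
    """
    clustered_plants = set()
    for c in calls:
        clustered_plants |= c.plants
    group1 = sorted(p for p in summaries if p in clustered_plants)
    group2 = sorted(p for p in summaries if p not in clustered_plants)
    groups = {"group1": group1, "group2": group2}

    metrics = ("n_snvs", "n_ag", "pct_ag")
    if group1 and group2:
        data = {g: {m: [] for m in metrics} for g in ("group1", "group2")}
        for g, plants in (("group1", group1), ("group2", group2)):
            for p in plants:
                s = summaries[p]
                data[g]["n_snvs"].append(s.n_snvs)
                data[g]["n_ag"].append(s.n_ag)
                data[g]["pct_ag"].append(np.nan if s.pct_ag is None else s.pct_ag)
        cmp = compare_groups_table(
            data, [("group1", "group2", m, "greater") for m in metrics])
    else:
        cmp = pd.DataFrame()

    genic = pd.DataFrame()
    if annotation is not None and all_ag_keys_by_plant is not None:
        clustered_keys = sorted({k for c in calls for k in c.members})
        all_keys = sorted({k for ks in all_ag_keys_by_plant.values()
                           for k in _ag_keys(ks)})
        def _genic_frac(keys):
            if not keys:
                return np.nan
            hits = sum(1 for k in keys
                       if annotation.classify(k.chrom, k.pos) != "intergenic")
            return hits / len(keys)
        genic = pd.DataFrame([
            {"set": "clustered_snvs", "n": len(clustered_keys),
             "genic_fraction": _genic_frac(clustered_keys)},
            {"set": "all_ag_snvs", "n": len(all_keys),
             "genic_fraction": _genic_frac(all_keys)},
        ])
    return groups, cmp, genic
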