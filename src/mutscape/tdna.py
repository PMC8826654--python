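"""T-DNA integrity, copy number, and sibling-plant stage attribution.

Transgenic plants carry the editor on a T-DNA segment bounded by the left
and right borders (LB/RB).  Read coverage over the T-DNA sequence reveals
whether every functional fragment (promoter, Cas module, deaminase
module, ...) made it into the genome, and — because T0 plants are
hemizygous at the insertion — the copy number equals the mean T-DNA
coverage divided by half the genome coverage.

Plants regenerated from the same transformed callus share the mutations
that arose before the first cell division (stages 1-2: before/just after
T-DNA integration) while mutations unique to one sibling arose later
(stage 3, with the editor stably expressed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mutscape.core_io import VariantKey
from mutscape.spectrum import SpectrumSummary, compare_groups_table, spectrum_summary


@dataclass
class TdnaFeatureMap:
    """Ordered functional intervals over the T-DNA sequence (1-based closed)."""

    features: list[tuple[str, int, int]]  # (name, start1, end1)
    length: int

    def __post_init__(self):
        spans = sorted((s, e, n) for n, s, e in self.features)
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"features {n1} and {n2} overlap")
        for n, s, e in self.features:
            if s < 1 or e > self.length:
                raise ValueError(f"feature {n} outside T-DNA 1..{self.length}")
        names = [n for n, _, _ in self.features]
        if "LB" in names and "RB" in names:
            lb = next(s for n, s, _ in self.features if n == "LB")
            rb = next(s for n, s, _ in self.features if n == "RB")
            if lb >= rb:
                raise ValueError("LB must precede RB")

    def names(self) -> list[str]:
        return [n for n, _, _ in self.features]

    def interval(self, name: str) -> tuple[int, int]:
        for n, s, e in self.features:
            if n == name:
                return s, e
        raise KeyError(f"unknown T-DNA feature {name!r}")


def tdna_integrity(coverage: np.ndarray, features: TdnaFeatureMap,
                   min_frac: float = 0.1) -> dict:
    """Call each T-DNA feature present or missing from its mean coverage.

    A feature is missing when its mean coverage falls below ``min_frac``
    of the mean coverage of the whole LB..RB span.  A track with zero
    overall coverage yields status 'no_insertion'.
    """
    cov = np.asarray(coverage, dtype=float)
    lb, _ = features.interval("LB") if "LB" in features.names() else (1, 1)
    _, rb = features.interval("RB") if "RB" in features.names() else (1, len(cov))
    span_mean = float(cov[lb - 1:rb].mean()) if rb > lb else 0.0
    if span_mean <= 0:
        return {"status": "no_insertion", "span_mean": 0.0,
                "features": {n: "missing" for n in features.names()}}
    calls = {}
    for name, s, e in features.features:
        fmean = float(cov[s - 1:e].mean())
        calls[name] = "present" if fmean >= min_frac * span_mean else "missing"
    status = "partial" if "missing" in calls.values() else "complete"
    return {"status": status, "span_mean": span_mean, "features": calls}


def tdna_copy_number(tdna_mean_cov: float, genome_mean_cov: float) -> tuple[float, int]:
    """Copy number of the integration in a T0 (hemizygous) plant.

    copies = T-DNA mean coverage / (genome mean coverage / 2).  Returns
    the real-valued estimate and its nearest integer for grouping.
    """
    if genome_mean_cov <= 0:
        raise ValueError("genome mean coverage must be positive")
    copies = tdna_mean_cov / (genome_mean_cov / 2.0)
    return copies, int(round(copies))


@dataclass
class SiblingPartition:
    """Unique/common SNV partition for a callus sibling pair."""

    callus_id: str
    plant_a: str
    plant_b: str
    unique_a: set[VariantKey]
    unique_b: set[VariantKey]
    common: set[VariantKey]
    spectra: dict[str, SpectrumSummary]

    def __post_init__(self):
        assert not (self.unique_a & self.unique_b), "partition sets overlap"
        assert not (self.unique_a & self.common), "partition sets overlap"
        assert not (self.unique_b & self.common), "partition sets overlap"


def partition_siblings(keys_a: set[VariantKey], keys_b: set[VariantKey],
                       plant_a: str, plant_b: str, callus_a: str, callus_b: str,
                       force: bool = False) -> SiblingPartition:
    """Split two sibling plants' SNV keys into unique/unique/common sets."""
    if callus_a != callus_b and not force:
        raise ValueError(f"{plant_a} and {plant_b} come from different calli "
                         f"({callus_a} vs {callus_b}); pass force=True to override")
    common = keys_a & keys_b
    ua, ub = keys_a - common, keys_b - common
    spectra = {"set1": spectrum_summary(sorted(ua), plant_id=plant_a),
               "set2": spectrum_summary(sorted(ub), plant_id=plant_b),
               "overlap": spectrum_summary(sorted(common), plant_id=callus_a)}
    return SiblingPartition(callus_a, plant_a, plant_b, ua, ub, common, spectra)


#: Stage labels: shared mutations predate the first cell division.
STAGE_OF_SET = {"set1": "stage3", "set2": "stage3", "overlap": "stage1/2"}


def stage_attribution(partitions: Sequence[SiblingPartition]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-set stage labels plus the unique-vs-common A>G percentage test.

    Returns (per-set table with set1/set2/overlap rows per pair, the
    one-tailed comparison table unique > common over all pairs).
    """
    rows = []
    uniq_pct, common_pct = [], []
    for p in partitions:
        for label in ("set1", "set2", "overlap"):
            s = p.spectra[label]
            pct = s.pct_ag
            rows.append({"callus_id": p.callus_id, "set": label,
                         "stage": STAGE_OF_SET[label], "n_snvs": s.n_snvs,
                         "n_ag": s.n_ag,
                         "pct_ag": np.nan if pct is None else pct})
            if pct is not None:
                (common_pct if label == "overlap" else uniq_pct).append(pct)
    table = pd.DataFrame(rows, columns=["callus_id", "set", "stage", "n_snvs",
                                        "n_ag", "pct_ag"])
    if uniq_pct and common_pct:
        cmp = compare_groups_table(
            {"unique": {"pct_ag": uniq_pct}, "common": {"pct_ag": common_pct}},
            [("unique", "common", "pct_ag", "greater")])
    else:
        cmp = pd.DataFrame()
    return table, cmp


def completeness_effect(summaries: Mapping[str, SpectrumSummary],
                        complete_flags: Mapping[str, bool]) -> pd.DataFrame:
    """Compare plants with complete vs partial T-DNA insertions.

    Three one-tailed Wilcoxon comparisons (complete > partial) on the SNV
    count, the A>G count, and the A>G percentage.  The same machinery
    serves copy-number groupings (pass any boolean plant grouping).
    """
    metrics = ("n_snvs", "n_ag", "pct_ag")
    groups: dict[str, dict[str, list[float]]] = {
        "complete": {m: [] for m in metrics},
        "partial": {m: [] for m in metrics},
    }
    for pid, s in summaries.items():
        g = "complete" if complete_flags.get(pid, True) else "partial"
        groups[g]["n_snvs"].append(s.n_snvs)
        groups[g]["n_ag"].append(s.n_ag)
        groups[g]["pct_ag"].append(np.nan if s.pct_ag is None else s.pct_ag)
    return compare_groups_table(
        groups, [("complete", "partial", m, "greater") for m in metrics])
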