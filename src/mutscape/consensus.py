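"""Variant-confidence filtering: multi-caller intersection, background
subtraction, the homozygosity binomial test, recurrence, and pairwise
plant overlap.

The confidence rule keeps SNVs supported by all three callers and indels
supported by at least two; variants seen in any designated background
plant are subtracted by key; residual shared homozygous loci are flagged
by an exact binomial test on genotype counts and homozygous calls are
removed before any downstream off-target statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mutscape.core_io import GenomeSequence, VariantCall, VariantKey, normalize_key

log = logging.getLogger(__name__)


@dataclass
class ConsensusSet:
    """A plant's caller-consensus variants with per-variant provenance."""

    plant_id: str
    variants: list[VariantCall] = field(default_factory=list)
    provenance: dict[VariantKey, frozenset] = field(default_factory=dict)

    def keys(self, snvs_only: bool = False) -> set[VariantKey]:
        return {v.key() for v in self.variants if not snvs_only or v.is_snv}

    def het_only(self) -> "ConsensusSet":
        kept = [v for v in self.variants if v.zygosity == "het"]
        return ConsensusSet(self.plant_id, kept,
                            {v.key(): self.provenance.get(v.key(), frozenset())
                             for v in kept})

    def __len__(self) -> int:
        return len(self.variants)


def _dedup(calls: Sequence[VariantCall], caller: str,
           genome: GenomeSequence | None) -> dict[VariantKey, VariantCall]:
    out: dict[VariantKey, VariantCall] = {}
    dups = 0
    for c in calls:
        k = normalize_key(c.chrom, c.pos, c.ref, c.alt, genome)
        if k in out:
            dups += 1
            continue
        out[k] = c
    if dups:
        log.warning("caller %s: %d duplicate keys deduplicated", caller, dups)
    return out


def intersect_callers(callsets: Mapping[str, Sequence[VariantCall]],
                      min_snv_callers: int = 3, min_indel_callers: int = 2,
                      genome: GenomeSequence | None = None) -> ConsensusSet:
    """Keep variants supported by enough callers.

    SNVs require ``min_snv_callers`` supporting callers, indels
    ``min_indel_callers``.  Zygosity is decided by majority vote among the
    supporting callers; a tie is resolved to heterozygous (conservative:
    the variant survives later homozygote removal only when confidently
    homozygous).
    """
    per_caller = {cid: _dedup(calls, cid, genome)
                  for cid, calls in sorted(callsets.items())}
    plant_ids = {c.plant_id for calls in callsets.values() for c in calls}
    if len(plant_ids) > 1:
        raise ValueError(f"mixed plant_ids in one intersection: {sorted(plant_ids)}")
    plant_id = plant_ids.pop() if plant_ids else ""

    support: dict[VariantKey, list[str]] = {}
    for cid, keyed in per_caller.items():
        for k in keyed:
            support.setdefault(k, []).append(cid)

    out = ConsensusSet(plant_id=plant_id)
    for k in sorted(support):
        callers = support[k]
        is_snv = len(k.ref) == 1 and len(k.alt) == 1
        need = min_snv_callers if is_snv else min_indel_callers
        if len(callers) < need:
            continue
        votes = [per_caller[c][k].zygosity for c in callers]
        zyg = "hom" if votes.count("hom") > votes.count("het") else "het"
        rep = per_caller[callers[0]][k]
        out.variants.append(VariantCall(
            plant_id=plant_id, caller_id=None, chrom=k.chrom, pos=k.pos,
            ref=k.ref, alt=k.alt, zygosity=zyg,
            allele_depths=rep.allele_depths))
        out.provenance[k] = frozenset(callers)
    return out


def subtract_background(consensus: ConsensusSet,
                        background_sets: Sequence[ConsensusSet]) -> ConsensusSet:
    """Remove every variant whose key occurs in the union of background sets.

    Removal is by key only, ignoring zygosity (a background variant seen
    het in one background plant removes a hom call at the same key).
    """
    if not background_sets:
        log.warning("empty background list: returning consensus unchanged")
        return ConsensusSet(consensus.plant_id, list(consensus.variants),
                            dict(consensus.provenance))
    bg: set[VariantKey] = set()
    for b in background_sets:
        bg |= b.keys()
    kept = [v for v in consensus.variants if v.key() not in bg]
    return ConsensusSet(consensus.plant_id, kept,
                        {v.key(): consensus.provenance.get(v.key(), frozenset())
                         for v in kept})


def remove_homozygous(consensus: ConsensusSet) -> ConsensusSet:
    """Keep heterozygous variants only."""
    return consensus.het_only()


def recurrence_table(consensus_sets: Mapping[str, ConsensusSet]) -> pd.DataFrame:
    """Per-variant-key plant counts and zygosity breakdown across the cohort."""
    if len(consensus_sets) < 2:
        raise ValueError("recurrence requires at least 2 plants")
    acc: dict[VariantKey, dict[str, int]] = {}
    for pid in sorted(consensus_sets):
        for v in consensus_sets[pid].variants:
            d = acc.setdefault(v.key(), {"n_plants": 0, "n_hom": 0, "n_het": 0})
            d["n_plants"] += 1
            d["n_hom" if v.zygosity == "hom" else "n_het"] += 1
    rows = [{"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt,
             "vtype": "SNV" if len(k.ref) == 1 and len(k.alt) == 1 else "indel",
             **acc[k]} for k in sorted(acc)]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vtype",
                                       "n_plants", "n_hom", "n_het"])


# ---------------------------------------------------------------------------
# Homozygosity binomial test
# ---------------------------------------------------------------------------

@dataclass
class LocusGenotypeCounts:
    """Genotype counts at one locus plus the binomial-test result.

    Under the null model the two alleles of a plant mutate independently
    with per-allele probability p, so P(hom) = p^2, P(het) = 2p(1-p) and
    P(wt) = (1-p)^2.  A locus where homozygotes are over-represented among
    carriers is flagged as residual background.
    """

    key: VariantKey | None
    n_hom: int
    n_het: int
    n_wt: int
    p_hat: float = 0.0
    pvalue: float = 1.0


def homozygosity_binomial_test(n_hom: int, n_het: int, n_wt: int,
                               key: VariantKey | None = None) -> LocusGenotypeCounts:
    """Exact upper-tail binomial test for excess homozygosity at one locus.

    The per-allele mutation probability is estimated as
    p_hat = (2*n_hom + n_het) / (2*(n_hom + n_het + n_wt)); conditional on
    being a carrier, P(hom) = p_hat / (2 - p_hat), and the p-value is the
    exact tail P(X >= n_hom) for X ~ Binomial(n_hom + n_het, p_hat/(2-p_hat)).
    """
    carriers = n_hom + n_het
    if carriers == 0:
        raise ValueError("no carriers: test undefined")
    n = n_hom + n_het + n_wt
    p_hat = (2 * n_hom + n_het) / (2 * n)
    q = p_hat / (2 - p_hat)
    pvalue = float(stats.binom.sf(n_hom - 1, carriers, q))
    return LocusGenotypeCounts(key=key, n_hom=n_hom, n_het=n_het, n_wt=n_wt,
                               p_hat=p_hat, pvalue=pvalue)


def binomial_screen(recurrence: pd.DataFrame, cohort_size: int,
                    alpha: float = 0.01) -> pd.DataFrame:
    """Run the homozygosity test over every locus with >= 1 homozygous plant."""
    rows = []
    for _, r in recurrence.iterrows():
        if r["n_hom"] < 1:
            continue
        n_wt = cohort_size - int(r["n_plants"])
        res = homozygosity_binomial_test(int(r["n_hom"]), int(r["n_het"]), n_wt)
        rows.append({"chrom": r["chrom"], "pos": r["pos"], "ref": r["ref"],
                     "alt": r["alt"], "n_hom": res.n_hom, "n_het": res.n_het,
                     "n_wt": res.n_wt, "p_hat": res.p_hat,
                     "pvalue": res.pvalue, "non_binomial": res.pvalue < alpha})
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "n_hom",
                                       "n_het", "n_wt", "p_hat", "pvalue",
                                       "non_binomial"])


# ---------------------------------------------------------------------------
# Pairwise overlap
# ---------------------------------------------------------------------------

def pairwise_overlap(consensus_sets: Mapping[str, ConsensusSet],
                     snvs_only: bool = True) -> tuple[pd.DataFrame, int]:
    """Symmetric matrix of shared variant counts between every plant pair.

    Returns the matrix and the number of unordered comparisons
    n*(n-1)/2.  By default only SNVs are compared.
    """
    plants = sorted(consensus_sets)
    if len(plants) < 2:
        raise ValueError("overlap requires at least 2 plants")
    keysets = {p: consensus_sets[p].keys(snvs_only=snvs_only) for p in plants}
    n = len(plants)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        mat[i, i] = len(keysets[plants[i]])
        for j in range(i + 1, n):
            shared = len(keysets[plants[i]] & keysets[plants[j]])
            mat[i, j] = mat[j, i] = shared
    df = pd.DataFrame(mat, index=plants, columns=plants)
    return df, n * (n - 1) // 2
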