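"""sgRNA target search: on-target and putative off-target site discovery.

Two search modes mirror how guide-dependent off-target loci are screened:

* full-spacer mode — every PAM-adjacent protospacer within a Hamming
  mismatch budget over the whole 20-nt spacer (default <= 6);
* seed mode — only the PAM-proximal seed (3' 12 nt of the spacer) is
  constrained (default <= 2 mismatches); the PAM is still required, and
  the full-spacer mismatch count is reported for stratification.

The production scanner is vectorised with numpy; ``naive_find_sites`` is a
deliberately simple per-position reimplementation kept in-tree as the
independent oracle for property tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from mutscape.core_io import IUPAC, GenomeSequence, GuideSpec, VariantCall, revcomp

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
# genome code (0..4) -> bitmask (N -> 0, matches nothing)
_CODEBIT = np.array([1, 2, 4, 8, 0], dtype=np.uint8)
_PAT_MASK = {c: sum(1 << "ACGT".index(b) for b in bases) for c, bases in IUPAC.items()}


@dataclass(frozen=True)
class TargetSite:
    """A protospacer match (1-based inclusive span on the forward strand)."""

    chrom: str
    start: int
    end: int
    strand: str
    pam_start: int
    n_mismatches: int
    seed_mismatches: int
    guide_name: str
    pam_len: int = 3

    @property
    def is_on_target(self) -> bool:
        return self.n_mismatches == 0

    def as_tuple(self):
        return (self.chrom, self.start, self.end, self.strand, self.pam_start,
                self.n_mismatches, self.seed_mismatches, self.guide_name,
                self.pam_len)

    @property
    def pam_span(self) -> tuple[int, int]:
        return (self.pam_start, self.pam_start + self.pam_len - 1)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _scan_oriented(codes: np.ndarray, spacer: str, pam: str,
                   seed_len: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scan one orientation; return (start0, n_mm, seed_mm) for PAM-matching windows.

    Layout is protospacer followed immediately by PAM (SpCas9 geometry).
    """
    k, p = len(spacer), len(pam)
    L = len(codes)
    n_win = L - k - p + 1
    if n_win <= 0:
        e = np.empty(0, dtype=np.int64)
        return e, e.copy(), e.copy()
    sp = _encode(spacer)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)[:n_win]
    mm = (win != sp).sum(axis=1).astype(np.int64)  # genome N (code 4) never matches
    seed_mm = (win[:, k - seed_len:] != sp[k - seed_len:]).sum(axis=1).astype(np.int64)
    gbits = _CODEBIT[codes]
    pam_ok = np.ones(n_win, dtype=bool)
    for j, c in enumerate(pam):
        pam_ok &= (gbits[k + j:k + j + n_win] & _PAT_MASK[c]) != 0
    idx = np.flatnonzero(pam_ok)
    return idx, mm[idx], seed_mm[idx]


def _sites_for_chrom(chrom: str, seq: str, guide: GuideSpec, pam: str,
                     seed_len: int, keep) -> list[TargetSite]:
    k, p = len(guide.spacer), len(pam)
    out: list[TargetSite] = []
    codes_f = _encode(seq)
    L = len(seq)
    # forward strand: protospacer at [s, s+k), PAM at [s+k, s+k+p)
    idx, mm, smm = _scan_oriented(codes_f, guide.spacer, pam, seed_len)
    for s, m, sm in zip(idx, mm, smm):
        if keep(m, sm):
            out.append(TargetSite(chrom, int(s) + 1, int(s) + k, "+",
                                  int(s) + k + 1, int(m), int(sm), guide.name, p))
    # reverse strand: scan the reverse complement, map coordinates back
    codes_r = _encode(revcomp(seq))
    idx, mm, smm = _scan_oriented(codes_r, guide.spacer, pam, seed_len)
    for t, m, sm in zip(idx, mm, smm):
        if keep(m, sm):
            s0 = L - int(t) - k  # forward 0-based protospacer start
            out.append(TargetSite(chrom, s0 + 1, s0 + k, "-",
                                  s0 - p + 1, int(m), int(sm), guide.name, p))
    out.sort(key=lambda s: (s.start, s.strand))
    return out


def _check_guide(guide: GuideSpec, pam: str | None) -> str:
    if "N" in guide.spacer:
        raise ValueError(f"guide {guide.name}: spacer contains N")
    return (pam or guide.pam_pattern).upper()


def find_sites_full(genome: GenomeSequence, guide: GuideSpec, max_mm: int = 6,
                    pam: str | None = None, seed_len: int = 12) -> list[TargetSite]:
    """All PAM-adjacent sites within ``max_mm`` mismatches over the full spacer."""
    pam = _check_guide(guide, pam)
    if not 0 <= max_mm <= len(guide.spacer):
        raise ValueError("max_mm outside [0, spacer length]")
    keep = lambda m, sm: m <= max_mm
    return [s for c in genome.chrom_names
            for s in _sites_for_chrom(c, genome.sequences[c], guide, pam, seed_len, keep)]


def find_sites_seed(genome: GenomeSequence, guide: GuideSpec, seed_len: int = 12,
                    max_seed_mm: int = 2, pam: str | None = None) -> list[TargetSite]:
    """Sites whose PAM-proximal seed matches within ``max_seed_mm`` mismatches.

    Non-seed spacer positions are unconstrained; the full-spacer mismatch
    count is still reported on each site.
    """
    pam = _check_guide(guide, pam)
    if seed_len > len(guide.spacer):
        raise ValueError("seed_len exceeds spacer length")
    keep = lambda m, sm: sm <= max_seed_mm
    return [s for c in genome.chrom_names
            for s in _sites_for_chrom(c, genome.sequences[c], guide, pam, seed_len, keep)]


# ---------------------------------------------------------------------------
# Brute-force oracle (independent reimplementation, kept simple on purpose)
# ---------------------------------------------------------------------------

def _naive_match_pam(seq: str, pattern: str) -> bool:
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC[c] for b, c in zip(seq, pattern))


def _naive_mm(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def naive_find_sites(genome: GenomeSequence, guide: GuideSpec, mode: str,
                     max_mm: int = 6, seed_len: int = 12, max_seed_mm: int = 2,
                     pam: str | None = None) -> list[TargetSite]:
    """Per-position brute-force scanner; the test oracle for the fast path."""
    pam = _check_guide(guide, pam)
    k, p = len(guide.spacer), len(pam)
    sites = []
    for chrom in genome.chrom_names:
        seq = genome.sequences[chrom]
        L = len(seq)
        for s in range(L - k + 1):
            # forward orientation
            if s + k + p <= L:
                proto = seq[s:s + k]
                if _naive_match_pam(seq[s + k:s + k + p], pam):
                    mm = _naive_mm(proto, guide.spacer)
                    smm = _naive_mm(proto[k - seed_len:], guide.spacer[k - seed_len:])
                    ok = mm <= max_mm if mode == "full" else smm <= max_seed_mm
                    if ok:
                        sites.append(TargetSite(chrom, s + 1, s + k, "+",
                                                s + k + 1, mm, smm, guide.name, p))
            # reverse orientation: protospacer read on the minus strand
            if s - p >= 0:
                proto = revcomp(seq[s:s + k])
                if _naive_match_pam(revcomp(seq[s - p:s]), pam):
                    mm = _naive_mm(proto, guide.spacer)
                    smm = _naive_mm(proto[k - seed_len:], guide.spacer[k - seed_len:])
                    ok = mm <= max_mm if mode == "full" else smm <= max_seed_mm
                    if ok:
                        sites.append(TargetSite(chrom, s + 1, s + k, "-",
                                                s - p + 1, mm, smm, guide.name, p))
    sites.sort(key=lambda t: (genome.chrom_names.index(t.chrom), t.start, t.strand))
    return sites


# ---------------------------------------------------------------------------
# Variant / site intersection
# ---------------------------------------------------------------------------

def mask_on_target(variants: Sequence[VariantCall], sites: Iterable[TargetSite],
                   flank: int = 0) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition variants into (on_target, off_target).

    A variant is on-target iff it lies within the protospacer+PAM span
    (extended by ``flank``) of any 0-mismatch site.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for s in sites:
        if s.n_mismatches != 0:
            continue
        plo, phi = s.pam_span
        lo, hi = min(s.start, plo), max(s.end, phi)
        spans.setdefault(s.chrom, []).append((lo - flank, hi + flank))
    on, off = [], []
    for v in variants:
        hit = any(lo <= v.pos <= hi for lo, hi in spans.get(v.chrom, ()))
        (on if hit else off).append(v)
    return on, off


def count_variants_at_sites(variants: Sequence[VariantCall],
                            sites: Sequence[TargetSite]) -> dict[int, int]:
    """Per-mismatch-stratum counts of SNVs inside protospacer spans.

    A variant is counted once in every stratum where it falls inside at
    least one site of that mismatch level.
    """
    from mutscape import intervals as iv

    strata = sorted({s.n_mismatches for s in sites})
    counts: dict[int, int] = {m: 0 for m in strata}
    by_stratum: dict[int, dict[str, list[tuple[int, int]]]] = {m: {} for m in strata}
    for s in sites:
        by_stratum[s.n_mismatches].setdefault(s.chrom, []).append((s.start - 1, s.end))
    snvs = [v for v in variants if v.is_snv]
    for m in strata:
        merged = {c: iv.merge(ivs) for c, ivs in by_stratum[m].items()}
        n = 0
        for v in snvs:
            arr = merged.get(v.chrom)
            if arr is not None and bool(iv.contains_points(arr, [v.pos - 1])[0]):
                n += 1
        counts[m] = n
    return counts


def sites_to_bed(sites: Sequence[TargetSite], path) -> None:
    """BED6 export: name=guide:mismatches, score=n_mismatches."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t"
                     f"{s.guide_name}:{s.n_mismatches}\t{s.n_mismatches}\t{s.strand}\n")
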