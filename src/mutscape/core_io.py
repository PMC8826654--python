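"""Domain types and readers/writers for the standard formats used by the pipeline.

Coordinate conventions
----------------------
VCF, GFF/GTF and all user-facing tables are 1-based (GFF intervals are
closed).  Internal interval arithmetic uses 0-based half-open intervals
throughout; conversion happens at the I/O boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from mutscape import intervals as iv

log = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> set of matched bases.  A genomic ``N`` matches
#: nothing; a pattern ``N`` matches the four unambiguous bases only.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class VariantKey(NamedTuple):
    """Normalized matching unit for intersection / subtraction / overlap."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass
class VariantCall:
    """One called variant for one plant from one caller."""

    plant_id: str
    caller_id: str | None
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    zygosity: str  # "het" | "hom"
    allele_depths: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position {self.pos} < 1")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")

    @property
    def vtype(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def is_snv(self) -> bool:
        return self.vtype == "SNV"

    def key(self) -> VariantKey:
        return normalize_key(self.chrom, self.pos, self.ref, self.alt)


def normalize_key(chrom: str, pos: int, ref: str, alt: str,
                  genome: "GenomeSequence | None" = None) -> VariantKey:
    """Normalize a variant representation before key matching.

    Shared suffixes then shared prefixes are trimmed (keeping at least one
    base on each allele); with a reference genome supplied, indels are
    additionally left-aligned.  This reconciles caller dialect differences
    so intersection operates on one canonical spelling per event.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if genome is not None and len(ref) != len(alt):
        # left-align: while alleles end with the same base, prepend the
        # preceding reference base and drop the trailing one
        while ref[-1] == alt[-1] and pos > 1:
            prev = genome.base(chrom, pos - 1)
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
    return VariantKey(chrom, pos, ref, alt)


@dataclass
class GenomeSequence:
    """An in-memory reference genome (uppercase A/C/G/T/N strings)."""

    chrom_names: list[str]
    sequences: dict[str, str]

    def __post_init__(self):
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names are not unique")
        for name in self.chrom_names:
            seq = self.sequences[name].upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"{name}: illegal characters {sorted(bad)}")
            self.sequences[name] = seq

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(self.sequences[c]) for c in self.chrom_names}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """0-based half-open slice, clipped to the chromosome."""
        seq = self.sequences[chrom]
        return seq[max(0, start0):max(0, end0)]

    def base(self, chrom: str, pos1: int) -> str:
        return self.sequences[chrom][pos1 - 1]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start0: int
    end0: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)


REGIONS = ("genic", "exonic", "intronic", "intergenic")


@dataclass
class AnnotationSet:
    """Gene/exon intervals and the derived region classes.

    ``genic`` is the full gene span (introns and UTRs included),
    ``intronic`` = genic minus exonic, ``intergenic`` = genome minus genic.
    """

    chrom_lengths: dict[str, int]
    genes: list[GeneModel]

    def __post_init__(self):
        self._cache: dict[str, dict[str, np.ndarray]] = {}
        unknown = sorted({g.chrom for g in self.genes} - set(self.chrom_lengths))
        if unknown:
            raise ValueError(f"annotation references unknown chromosomes: {unknown}")
        for g in self.genes:
            L = self.chrom_lengths[g.chrom]
            if g.end0 > L or g.start0 < 0:
                raise ValueError(f"gene {g.gene_id} exceeds chromosome {g.chrom} bounds")

    def region_intervals(self, region: str) -> dict[str, np.ndarray]:
        """Merged 0-based half-open intervals for a region class, per chromosome."""
        if region in self._cache:
            return self._cache[region]
        gene_iv = {c: [] for c in self.chrom_lengths}
        exon_iv = {c: [] for c in self.chrom_lengths}
        for g in self.genes:
            gene_iv[g.chrom].append((g.start0, g.end0))
            exon_iv[g.chrom].extend(g.exons)
        out: dict[str, dict[str, np.ndarray]] = {r: {} for r in REGIONS}
        for c, L in self.chrom_lengths.items():
            genic = iv.merge(gene_iv[c])
            exonic = iv.intersect(iv.merge(exon_iv[c]), genic)
            out["genic"][c] = genic
            out["exonic"][c] = exonic
            out["intronic"][c] = iv.subtract(genic, exonic, L)
            out["intergenic"][c] = iv.complement(genic, L)
        self._cache.update(out)
        return self._cache[region]

    def region_length(self, region: str) -> int:
        return sum(iv.total_length(a) for a in self.region_intervals(region).values())

    def genome_fraction(self, region: str) -> float:
        total = sum(self.chrom_lengths.values())
        return self.region_length(region) / total if total else 0.0

    def classify(self, chrom: str, pos1: int) -> str:
        """Region class ('exonic' | 'intronic' | 'intergenic') of a 1-based position."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unannotated chromosome {chrom!r}")
        p = pos1 - 1
        for region in ("exonic", "intronic"):
            if bool(iv.contains_points(self.region_intervals(region).get(chrom, iv.EMPTY), [p])[0]):
                return region
        return "intergenic"

    def classify_many(self, chroms: Sequence[str], pos1: Sequence[int]) -> list[str]:
        return [self.classify(c, p) for c, p in zip(chroms, pos1)]


@dataclass
class GuideSpec:
    """A 20-nt spacer with its degenerate PAM pattern."""

    name: str
    spacer: str
    pam_pattern: str
    editor_id: str = ""

    def __post_init__(self):
        self.spacer = self.spacer.upper()
        self.pam_pattern = self.pam_pattern.upper()
        if set(self.spacer) - set(NUCLEOTIDES):
            raise ValueError(f"guide {self.name}: spacer must be A/C/G/T only")
        if set(self.pam_pattern) - set(IUPAC):
            raise ValueError(f"guide {self.name}: PAM pattern has non-IUPAC codes")


@dataclass
class PileupCounts:
    """Per-position A/C/G/T read counts at a locus of interest."""

    chrom: str
    pos: int  # 1-based
    counts: tuple[int, int, int, int]  # (nA, nC, nG, nT)
    source: str = "DNA"  # "DNA" | "RNA"
    plant_id: str = ""

    @property
    def coverage(self) -> int:
        return int(sum(self.counts))


DESIGN_COLUMNS = [
    "plant_id", "group", "editor", "guides", "callus_id", "tdna_complete",
    "tdna_copies", "expression_rpm", "dna", "rna", "generation", "transgene",
    "rna_active", "dna_clusters", "missing_feature",
]

GROUPS = ("kitaake", "tissue_culture", "agro_infection", "cas_only", "abe")


@dataclass
class CohortDesign:
    """The experiment layout: one row per plant.

    Core columns are ``plant_id, group, editor, guides, callus_id,
    tdna_complete, tdna_copies, expression_rpm``; bookkeeping columns used
    by the synthetic cohort (``dna``, ``rna``, ``generation``, ``transgene``,
    ``rna_active``, ``dna_clusters``, ``missing_feature``) ride along.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if t["plant_id"].duplicated().any():
            raise ValueError("plant_ids are not unique")
        bad = set(t["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")
        abe = t[t["group"] == "abe"]
        if (abe["editor"] == "none").any():
            raise ValueError("abe plants must declare an editor")
        self.table = t.reset_index(drop=True)

    def row(self, plant_id: str) -> pd.Series:
        hits = self.table[self.table["plant_id"] == plant_id]
        if hits.empty:
            raise KeyError(plant_id)
        return hits.iloc[0]

    def plants(self, group: str | None = None, **flags) -> list[str]:
        t = self.table
        if group is not None:
            t = t[t["group"] == group]
        for col, val in flags.items():
            t = t[t[col] == val]
        return list(t["plant_id"])

    def guides_of(self, plant_id: str) -> list[str]:
        raw = self.row(plant_id)["guides"]
        return [] if raw in (".", "", None) or pd.isna(raw) else str(raw).split(",")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _zygosity_from_record(gt, ad_pair, alt_index, warned: list[bool],
                          path) -> str | None:
    """GT when present; else allele-fraction rule (>=0.8 hom, 0.2-0.8 het)."""
    if gt is not None and gt != (None,) and None not in gt:
        n_alt = sum(1 for a in gt if a == alt_index)
        return "hom" if n_alt >= 2 else ("het" if n_alt == 1 else None)
    if not warned[0]:
        warnings.warn(f"{path}: missing GT, falling back to allele-fraction rule")
        warned[0] = True
    ref_n, alt_n = ad_pair
    total = ref_n + alt_n
    if total == 0:
        return None
    frac = alt_n / total
    if frac >= 0.8:
        return "hom"
    if frac >= 0.2:
        return "het"
    log.warning("%s: alt fraction %.2f < 0.2, dropping call", path, frac)
    return None


def read_vcf(path, plant_id: str = "", caller_id: str | None = None) -> list[VariantCall]:
    """Read a VCF 4.x file into VariantCall records.

    Multi-allelic records are split into one call per ALT allele.  Zygosity
    is taken from GT when present; otherwise an allele-fraction rule is
    applied (with a single warning per file).
    """
    path = str(path)
    calls: list[VariantCall] = []
    warned = [False]
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for i, rec in enumerate(vf, start=1):
            try:
                alts = rec.alts or ()
                sample = rec.samples[samples[0]] if samples else None
                gt = sample.get("GT") if sample else None
                ad = sample.get("AD") if sample else None
                for ai, alt in enumerate(alts):
                    if alt is None or alt in ("*", "<NON_REF>"):
                        continue
                    if ad is not None and len(ad) > ai + 1 and ad[0] is not None:
                        depths = (int(ad[0]), int(ad[ai + 1]))
                    else:
                        depths = (0, 0)
                    zyg = _zygosity_from_record(gt, depths, ai + 1, warned, path)
                    if zyg is None:
                        continue
                    calls.append(VariantCall(
                        plant_id=plant_id, caller_id=caller_id,
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        zygosity=zyg, allele_depths=depths))
            except (ValueError, TypeError, KeyError) as exc:
                raise ValueError(f"{path}: malformed record #{i} "
                                 f"({rec.chrom}:{rec.pos}): {exc}") from exc
    return calls


def write_vcf(calls: Sequence[VariantCall], path,
              contigs: Mapping[str, int] | None = None,
              sample: str = "sample") -> None:
    """Write calls as a single-sample VCF with GT and AD.

    Calls must already be sorted by (chrom, pos) with contiguous chromosome
    blocks; round-trips with :func:`read_vcf`.
    """
    seen: list[str] = []
    last_pos = 0
    for c in calls:
        if not seen or c.chrom != seen[-1]:
            if c.chrom in seen:
                raise ValueError("calls are not sorted: chromosome blocks not contiguous")
            seen.append(c.chrom)
            last_pos = 0
        if c.pos < last_pos:
            raise ValueError(f"calls are not sorted at {c.chrom}:{c.pos}")
        last_pos = c.pos

    if contigs is None:
        contigs = {}
        for c in calls:
            contigs[c.chrom] = max(contigs.get(c.chrom, 0), c.pos + len(c.ref))

    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample(sample)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in calls:
            rec = out.new_record(contig=c.chrom, start=c.pos - 1,
                                 alleles=(c.ref, c.alt))
            rec.samples[sample]["GT"] = (1, 1) if c.zygosity == "hom" else (0, 1)
            rec.samples[sample]["AD"] = tuple(int(x) for x in c.allele_depths)
            out.write(rec)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> GenomeSequence:
    fa = Fasta(str(path), sequence_always_upper=True, build_index=True, rebuild=True)
    names = list(fa.keys())
    seqs = {name: str(fa[name][:]) for name in names}
    fa.close()
    return GenomeSequence(chrom_names=names, sequences=seqs)


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 / GTF annotation
# ---------------------------------------------------------------------------

def read_annotation(path, genome: GenomeSequence) -> AnnotationSet:
    """Read a GFF3 or GTF gene annotation (dialect auto-detected).

    GFF/GTF 1-based closed intervals become the internal 0-based half-open
    convention.  Features on unknown chromosomes or beyond chromosome ends
    raise an error listing the offenders.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: list[GeneModel] = []
    offenders: list[str] = []
    lengths = genome.lengths
    for g in db.features_of_type("gene"):
        if g.seqid not in lengths:
            offenders.append(f"{g.id}@{g.seqid}")
            continue
        if g.end > lengths[g.seqid]:
            raise ValueError(f"feature {g.id} ends at {g.end} beyond "
                             f"{g.seqid} length {lengths[g.seqid]}")
        exons = [(e.start - 1, e.end) for e in db.children(g, featuretype="exon")]
        genes.append(GeneModel(gene_id=g.id, chrom=g.seqid,
                               start0=g.start - 1, end0=g.end,
                               strand=g.strand or "+",
                               exons=sorted(set(exons))))
    if offenders:
        raise ValueError(f"annotation references unknown chromosomes: {offenders}")
    return AnnotationSet(chrom_lengths=dict(lengths), genes=genes)


def write_gff3(annotation: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c, L in annotation.chrom_lengths.items():
            fh.write(f"##sequence-region {c} 1 {L}\n")
        for g in sorted(annotation.genes, key=lambda x: (x.chrom, x.start0)):
            fh.write(f"{g.chrom}\tmutscape\tgene\t{g.start0 + 1}\t{g.end0}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tmutscape\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.exon{k};Parent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# TSV formats: guides, pileups, cohort design, coverage tracks
# ---------------------------------------------------------------------------

def read_guides(path) -> list[GuideSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [GuideSpec(r["name"], r["spacer"], r["pam_pattern"], r.get("editor_id", ""))
            for _, r in df.iterrows()]


def write_guides(guides: Iterable[GuideSpec], path) -> None:
    pd.DataFrame([{"name": g.name, "spacer": g.spacer,
                   "pam_pattern": g.pam_pattern, "editor_id": g.editor_id}
                  for g in guides]).to_csv(path, sep="\t", index=False)


def read_pileups(path) -> pd.DataFrame:
    """Pileup TSV -> DataFrame (plant_id, source, chrom, pos, nA, nC, nG, nT)."""
    df = pd.read_csv(path, sep="\t", dtype={"plant_id": str, "chrom": str})
    for col in ("pos", "nA", "nC", "nG", "nT"):
        df[col] = df[col].astype(np.int64)
    return df


def write_pileups(df: pd.DataFrame, path) -> None:
    cols = ["plant_id", "source", "chrom", "pos", "nA", "nC", "nG", "nT"]
    df[cols].to_csv(path, sep="\t", index=False)


def read_design(path) -> CohortDesign:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    for col in ("tdna_complete", "tdna_copies", "dna", "rna", "transgene",
                "rna_active", "dna_clusters"):
        if col in df:
            df[col] = df[col].replace(".", "0").astype(int)
    if "expression_rpm" in df:
        df["expression_rpm"] = df["expression_rpm"].replace(".", "0").astype(float)
    return CohortDesign(df)


def write_design(design: CohortDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_coverage_track(path) -> np.ndarray:
    """Coverage TSV (pos, depth) -> depth array indexed by pos-1."""
    df = pd.read_csv(path, sep="\t")
    depth = np.zeros(int(df["pos"].max()), dtype=float)
    depth[df["pos"].to_numpy() - 1] = df["depth"].to_numpy()
    return depth


def write_coverage_track(depth: np.ndarray, path) -> None:
    pd.DataFrame({"pos": np.arange(1, len(depth) + 1),
                  "depth": np.asarray(depth)}).to_csv(path, sep="\t", index=False)


def read_bed_features(path) -> list[tuple[str, int, int]]:
    """BED (0-based half-open) -> list of (name, start1, end1) 1-based closed."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[3] if len(f) > 3 else f"{f[0]}:{f[1]}",
                        int(f[1]) + 1, int(f[2])))
    return out


def validate_file(path) -> str:
    """Best-effort format sniff + parse used by ``mutscape io validate``."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix in (".vcf",):
        read_vcf(p)
        return "vcf"
    if suffix in (".fa", ".fasta", ".fna"):
        read_fasta(p)
        return "fasta"
    if suffix in (".gff", ".gff3", ".gtf"):
        import gffutils
        gffutils.create_db(str(p), dbfn=":memory:", force=True)
        return "annotation"
    if suffix in (".tsv", ".txt"):
        pd.read_csv(p, sep="\t")
        return "tsv"
    if suffix == ".bed":
        read_bed_features(p)
        return "bed"
    raise ValueError(f"unrecognized file type: {p}")
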