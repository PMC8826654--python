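"""Domain types, VCF/FASTA/GFF round-trips, and region-class arithmetic."""

from __future__ import annotations

import numpy as np
import pytest

from mutscape import core_io
from mutscape.core_io import (
    AnnotationSet, GeneModel, GenomeSequence, VariantCall, normalize_key,
)
from mutscape.simulate import SimulationConfig, simulate_genome


def _call(pos, ref, alt, zyg="het", chrom="chr1", plant="p1", caller="c1",
          ad=(12, 10)):
    return VariantCall(plant, caller, chrom, pos, ref, alt, zyg, ad)


class TestVcf:
    def test_round_trip_identity(self, tmp_path):
        calls = [_call(100, "A", "G"), _call(250, "AT", "A", zyg="hom"),
                 _call(50, "C", "CGG", chrom="chr2")]
        path = tmp_path / "x.vcf"
        core_io.write_vcf(calls, path, contigs={"chr1": 1000, "chr2": 1000})
        back = core_io.read_vcf(path, plant_id="p1", caller_id="c1")
        assert [(c.chrom, c.pos, c.ref, c.alt, c.zygosity, c.allele_depths)
                for c in back] == \
               [(c.chrom, c.pos, c.ref, c.alt, c.zygosity, c.allele_depths)
                for c in calls]

    def test_empty_call_list_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.vcf"
        core_io.write_vcf([], path, contigs={"chr1": 100})
        assert core_io.read_vcf(path) == []
        assert all(line.startswith("#") for line in path.read_text().splitlines())

    def test_genotype_encoding(self, tmp_path):
        path = tmp_path / "gt.vcf"
        core_io.write_vcf([_call(10, "A", "G", "het"),
                           _call(20, "A", "G", "hom")],
                          path, contigs={"chr1": 100})
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert "0/1" in body[0] and "1/1" in body[1]

    def test_unsorted_input_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="sorted"):
            core_io.write_vcf([_call(200, "A", "G"), _call(100, "A", "G")],
                              tmp_path / "bad.vcf", contigs={"chr1": 1000})

    def test_multiallelic_record_split(self, tmp_path):
        text = ("##fileformat=VCFv4.2\n"
                "##contig=<ID=chr1,length=1000>\n"
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
                '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts\n"
                "chr1\t100\t.\tA\tG,T\t.\t.\t.\tGT:AD\t1/2:2,10,9\n")
        path = tmp_path / "ma.vcf"
        path.write_text(text)
        calls = core_io.read_vcf(path)
        assert [(c.pos, c.ref, c.alt, c.zygosity) for c in calls] == \
               [(100, "A", "G", "het"), (100, "A", "T", "het")]

    def test_missing_gt_falls_back_to_allele_fraction(self, tmp_path):
        header = ("##fileformat=VCFv4.2\n"
                  "##contig=<ID=chr1,length=1000>\n"
                  '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
                  "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts\n")
        body = ("chr1\t10\t.\tA\tG\t.\t.\t.\tAD\t2,38\n"    # 0.95 -> hom
                "chr1\t20\t.\tA\tG\t.\t.\t.\tAD\t20,20\n"   # 0.50 -> het
                "chr1\t30\t.\tA\tG\t.\t.\t.\tAD\t38,2\n")   # 0.05 -> dropped
        path = tmp_path / "nogt.vcf"
        path.write_text(header + body)
        with pytest.warns(UserWarning, match="allele-fraction"):
            calls = core_io.read_vcf(path)
        assert [(c.pos, c.zygosity) for c in calls] == [(10, "hom"), (20, "het")]


class TestNormalizeKey:
    @pytest.mark.parametrize("raw, expected", [
        ((100, "AT", "GT"), (100, "A", "G")),      # shared suffix trimmed
        ((100, "CA", "CG"), (101, "A", "G")),      # shared prefix trimmed
        ((100, "A", "G"), (100, "A", "G")),        # SNV unchanged
        ((100, "ATT", "AT"), (100, "AT", "A")),    # deletion trimmed
    ])
    def test_trim(self, raw, expected):
        pos, ref, alt = raw
        key = normalize_key("c", pos, ref, alt)
        assert (key.pos, key.ref, key.alt) == expected

    def test_left_alignment_in_homopolymer(self):
        genome = GenomeSequence(["c"], {"c": "GAAAAT"})
        # deleting one A anywhere in the run left-aligns to position 1
        k1 = normalize_key("c", 3, "AA", "A", genome)
        k2 = normalize_key("c", 4, "AA", "A", genome)
        assert k1 == k2
        assert k1.pos == 1 and k1.ref == "GA" and k1.alt == "G"


class TestFastaAnnotation:
    def test_fasta_uppercased_round_trip(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">c1\nacgt\n")
        genome = core_io.read_fasta(path)
        assert genome.sequences["c1"] == "ACGT"
        assert genome.lengths == {"c1": 4}

    def test_region_arithmetic_on_tiny_annotation(self, tiny_genome):
        _, ann = tiny_genome
        # gene 11-20 (1-based) with exon 11-14 on a 30-bp chromosome
        assert ann.region_length("exonic") == 4
        assert ann.region_length("intronic") == 6
        assert ann.region_length("intergenic") == 20
        assert ann.classify("c1", 12) == "exonic"
        assert ann.classify("c1", 16) == "intronic"
        assert ann.classify("c1", 25) == "intergenic"

    def test_zero_genes_all_intergenic(self):
        ann = AnnotationSet(chrom_lengths={"c1": 50}, genes=[])
        assert ann.region_length("intergenic") == 50
        assert ann.region_length("genic") == 0

    def test_gff3_round_trip_preserves_regions(self, tmp_path):
        genome, ann = simulate_genome(SimulationConfig(
            genome_length=20_000, n_chromosomes=1, rng_seed=5))
        core_io.write_fasta(genome, tmp_path / "g.fa")
        core_io.write_gff3(ann, tmp_path / "a.gff3")
        genome2 = core_io.read_fasta(tmp_path / "g.fa")
        ann2 = core_io.read_annotation(tmp_path / "a.gff3", genome2)
        for region in ("genic", "exonic", "intronic", "intergenic"):
            assert ann2.region_length(region) == ann.region_length(region)

    def test_region_classes_partition_genome(self):
        genome, ann = simulate_genome(SimulationConfig(
            genome_length=50_000, rng_seed=11))
        total = sum(ann.chrom_lengths.values())
        assert ann.region_length("genic") + ann.region_length("intergenic") == total
        assert (ann.region_length("exonic") + ann.region_length("intronic")
                == ann.region_length("genic"))

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            AnnotationSet(chrom_lengths={"c1": 100},
                          genes=[GeneModel("g", "c9", 0, 10, "+", [(0, 10)])])

    def test_feature_beyond_chromosome_end_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            AnnotationSet(chrom_lengths={"c1": 100},
                          genes=[GeneModel("g", "c1", 50, 150, "+", [(50, 150)])])


class TestVariantCall:
    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError):
            _call(10, "A", "A")

    def test_vtype(self):
        assert _call(10, "A", "G").vtype == "SNV"
        assert _call(10, "A", "AG").vtype == "indel"


class TestDesign:
    def test_duplicate_plants_rejected(self):
        import pandas as pd
        from mutscape.core_io import CohortDesign, DESIGN_COLUMNS
        row = dict.fromkeys(DESIGN_COLUMNS, ".")
        row.update(plant_id="p1", group="kitaake", editor="none")
        with pytest.raises(ValueError, match="unique"):
            CohortDesign(pd.DataFrame([row, row]))

    def test_design_round_trip(self, tmp_path, default_cohort):
        core_io.write_design(default_cohort.design, tmp_path / "d.tsv")
        back = core_io.read_design(tmp_path / "d.tsv")
        assert back.plants(group="kitaake") == default_cohort.design.plants(group="kitaake")
        assert back.guides_of("rBE49bG_s1") == ["g_rBE49b"]
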