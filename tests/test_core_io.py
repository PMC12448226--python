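import numpy as np
import pandas as pd
import pytest

from clinekit import core_io
from clinekit import synthetic_data as sd
from conftest import make_gm

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1>\n##contig=<ID=Z_1>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf_text(path, body, samples=("s1", "s2")):
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_HEADER + cols + "\n" + body)


class TestReadVcf:
    def test_keeps_only_biallelic_snps(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\n"
            "chr1\t200\t.\tA\tC,G\t.\tPASS\t.\tGT\t0/1\t1/2\n"  # triallelic
            "chr1\t250\t.\tA\tAT\t.\tPASS\t.\tGT\t0/0\t0/1\n"  # indel
            "chr1\t300\t.\tG\tT\t.\tPASS\t.\tGT\t1/1\t./.\n"
        )
        p = tmp_path / "t.vcf"
        write_vcf_text(p, body)
        gm = core_io.read_vcf_biallelic(p)
        assert list(gm.loci["pos"]) == [100, 300]
        assert gm.counts[0, 1] == 2
        assert gm.counts[1, 1] == core_io.MISSING

    def test_female_z_hemizygosity(self, tmp_path):
        body = (
            "Z_1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/0\n"
            "Z_1\t200\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        )
        p = tmp_path / "t.vcf"
        write_vcf_text(p, body)
        gm = core_io.read_vcf_biallelic(p, sex_map={"s1": "F", "s2": "M"})
        f = gm.samples.index("s1")
        m = gm.samples.index("s2")
        # female homozygote 0/0 -> one ref copy; heterozygote -> missing
        assert gm.counts[f, 0] == 0 and gm.ploidy[f, 0] == 1
        assert gm.counts[f, 1] == core_io.MISSING
        assert gm.counts[m, 1] == 2 and gm.ploidy[m, 1] == 2
        # ploidy rule: a female never carries two Z copies
        z = gm.loci["chrom"] == "Z_1"
        assert (gm.counts[f, z.to_numpy()] <= 1).all()

    def test_unknown_sex_on_z_becomes_missing(self, tmp_path):
        body = "Z_1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\t1/1\n"
        p = tmp_path / "t.vcf"
        write_vcf_text(p, body)
        gm = core_io.read_vcf_biallelic(p, sex_map={"s1": "M"})
        unk = gm.samples.index("s2")
        assert gm.counts[unk, 0] == core_io.MISSING
        assert gm.ploidy[unk, 0] == 0

    def test_unsorted_vcf_names_offending_record(self, tmp_path):
        body = (
            "chr1\t300\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/0\n"
            "chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/0\n"
        )
        p = tmp_path / "t.vcf"
        write_vcf_text(p, body)
        with pytest.raises(ValueError, match="chr1:100"):
            core_io.read_vcf_biallelic(p)

    def test_round_trip_preserves_counts(self, tmp_path):
        cfg = sd.SyntheticConfig(seed=5, n_parental_each=6, n_transect=20,
                                 l_diag=60, l_background=40)
        gm, table = sd.make_dataset(cfg)
        p = tmp_path / "rt.vcf"
        core_io.write_vcf(gm, p)
        back = core_io.read_vcf_biallelic(
            p, sex_map=core_io.sex_map_from_table(table)
        )
        assert back.samples == gm.samples
        np.testing.assert_array_equal(back.counts, gm.counts)
        np.testing.assert_array_equal(back.ploidy, gm.ploidy)


class TestThinByWindow:
    def test_same_window_keeps_lowest_position(self):
        gm = make_gm(np.zeros((1, 2)), spacing=0, start=1_000)
        gm.loci.loc[1, "pos"] = 9_000
        out = core_io.thin_by_window(gm, 10_000)
        assert list(out.loci["pos"]) == [1_000]

    def test_window_boundary_splits(self):
        gm = make_gm(np.zeros((1, 2)))
        gm.loci["pos"] = [9_999, 10_001]
        out = core_io.thin_by_window(gm, 10_000)
        assert out.n_loci == 2

    def test_retained_count_matches_brute_force(self):
        rng = np.random.default_rng(11)
        pos = np.sort(rng.choice(np.arange(1, 10**6 + 1), size=100, replace=False))
        gm = make_gm(np.zeros((1, 100)))
        gm.loci["pos"] = pos
        out = core_io.thin_by_window(gm, 10_000)
        # oracle: direct scan over fixed windows [k*w+1, (k+1)*w]
        nonempty = {(p - 1) // 10_000 for p in pos}
        assert out.n_loci == len(nonempty)

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(np.arange(1, 200_000), size=40, replace=False))
        gm = make_gm(np.zeros((2, 40)))
        gm.loci["pos"] = pos
        once = core_io.thin_by_window(gm, 10_000)
        twice = core_io.thin_by_window(once, 10_000)
        pd.testing.assert_frame_equal(once.loci, twice.loci)


GFF_BODY = (
    "##gff-version 3\n"
    "chr1\tsrc\tgene\t10000\t12000\t.\t+\t.\tID=geneA\n"
    "chr1\tsrc\tmRNA\t10000\t12000\t.\t+\t.\tID=rnaA;Parent=geneA\n"
    "chr1\tsrc\texon\t10000\t11000\t.\t+\t.\tParent=rnaA\n"
    "chr1\tsrc\tCDS\t10000\t11000\t.\t+\t.\tID=cdsA;Parent=rnaA\n"
    "chr2\tsrc\tgene\t2000\t3000\t.\t-\t.\tID=geneB\n"
    "chr2\tsrc\tregion\t1\t500000\t.\t.\t.\tID=chr2region\n"
    "chr2\tsrc\texon\t2000\t2500\t.\t-\t.\tParent=geneB\n"
    "chr2\tsrc\texon\t2600\t3000\t.\t-\t.\tParent=geneB\n"
    "chr3\tsrc\tgene\t50000\t60000\t.\t+\t.\tID=geneC\n"
    "chr3\tsrc\tCDS\t50000\t60000\t.\t+\t.\tID=cdsC;Parent=geneC\n"
)


class TestReadGff:
    def test_flank_extension_and_clamp(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(GFF_BODY)
        genes = core_io.read_gff_genes(p, flank_bp=5_000).set_index("gene_id")
        assert (genes.loc["geneA", ["search_start", "search_end"]] == [5_000, 17_000]).all()
        # clamp at position 1
        assert (genes.loc["geneB", ["search_start", "search_end"]] == [1, 8_000]).all()

    def test_only_gene_features_returned(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(GFF_BODY)
        genes = core_io.read_gff_genes(p, flank_bp=0)
        assert sorted(genes["gene_id"]) == ["geneA", "geneB", "geneC"]

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\nchr1\tsrc\tgene\t100\n")
        with pytest.raises(ValueError, match="line 2"):
            core_io.read_gff_genes(p)


def test_sample_table_rejects_duplicates(tmp_path):
    p = tmp_path / "s.tsv"
    p.write_text("sample_id\tpopulation_label\nx\ta\nx\tb\n")
    with pytest.raises(ValueError, match="duplicate"):
        core_io.read_sample_table(p)
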