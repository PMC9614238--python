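import numpy as np
import pandas as pd
import pytest

from epiblup.genio import (
    GenioError,
    GenotypeData,
    filter_genotypes,
    read_genotypes,
    read_haplotypes,
    read_phenotypes,
    write_genotypes,
)

RAW_HEADER = "FID IID PAT MAT SEX PHENOTYPE"


def _write_raw(tmp_path, rows, snps=("s1_A", "s2_A"), chroms=("1", "2")):
    lines = [RAW_HEADER + " " + " ".join(snps)]
    for j, row in enumerate(rows):
        lines.append(f"f{j} i{j} 0 0 1 -9 " + " ".join(str(x) for x in row))
    gpath = tmp_path / "geno.raw"
    gpath.write_text("\n".join(lines) + "\n")
    mpath = tmp_path / "map.tsv"
    base = [s.rsplit("_", 1)[0] for s in snps]
    pd.DataFrame({"snp": base, "chrom": chroms, "pos": range(100, 100 + len(base))}).to_csv(
        mpath, sep="\t", index=False
    )
    return gpath, mpath


def test_read_raw_counts_and_freqs(tmp_path):
    gpath, mpath = _write_raw(tmp_path, [(2, 0), (1, 1), (0, 2)])
    geno = read_genotypes(gpath, mpath)
    assert geno.n == 3 and geno.m == 2
    assert np.allclose(geno.freqs, [0.5, 0.5])
    assert geno.snp_ids == ["s1", "s2"]
    assert geno.chromosomes.tolist() == ["1", "2"]


@pytest.mark.parametrize(
    "miss_max,expect_m", [(0.10, 1), (0.5, 2)],
    ids=["strict-removes", "loose-retains"],
)
def test_missingness_threshold(tmp_path, miss_max, expect_m):
    # one NA cell out of 3 -> missing rate 1/3
    gpath, mpath = _write_raw(tmp_path, [(2, "NA"), (1, 1), (0, 2)])
    geno = read_genotypes(gpath, mpath, miss_max=miss_max)
    assert geno.m == expect_m
    if expect_m == 2:
        assert geno.mask[0, 1] and geno.mask.sum() == 1


def test_monomorphic_removed_by_maf(tmp_path):
    gpath, mpath = _write_raw(tmp_path, [(2, 2), (1, 2), (0, 2)])
    geno = read_genotypes(gpath, mpath, maf_min=0.0)
    assert geno.snp_ids == ["s1"]


def test_tsv_dialect_equals_raw(tmp_path, tiny_geno):
    write_genotypes(tiny_geno, tmp_path / "g.tsv", tmp_path / "m.tsv")
    back = read_genotypes(tmp_path / "g.tsv", tmp_path / "m.tsv")
    assert back.snp_ids == tiny_geno.snp_ids
    assert back.individual_ids == tiny_geno.individual_ids
    np.testing.assert_array_equal(back.counts, tiny_geno.counts)
    np.testing.assert_array_equal(back.freqs, tiny_geno.freqs)


def test_roundtrip_with_missing(tmp_path):
    counts = np.array([[2.0, np.nan], [1.0, 1.0], [0.0, 2.0], [1.0, 0.0]])
    geno = GenotypeData(["a", "b", "c", "d"], ["s1", "s2"],
                        np.array(["1", "1"], dtype=object), np.array([1, 2]), counts)
    write_genotypes(geno, tmp_path / "g.tsv", tmp_path / "m.tsv")
    back = read_genotypes(tmp_path / "g.tsv", tmp_path / "m.tsv", miss_max=0.5)
    np.testing.assert_array_equal(np.isnan(back.counts), np.isnan(counts))
    np.testing.assert_array_equal(back.counts[~np.isnan(counts)], counts[~np.isnan(counts)])


def test_filtering_idempotent(random_geno_factory):
    geno = random_geno_factory(20, 30, seed=1)
    once = filter_genotypes(geno, maf_min=0.05, miss_max=0.1)
    twice = filter_genotypes(once, maf_min=0.05, miss_max=0.1)
    assert once.snp_ids == twice.snp_ids
    np.testing.assert_array_equal(once.counts, twice.counts)


@pytest.mark.parametrize(
    "case", ["map_mismatch", "bad_cell", "dup_iid", "dup_snp"],
)
def test_genotype_errors(tmp_path, case):
    if case == "map_mismatch":
        gpath, _ = _write_raw(tmp_path, [(2, 0), (1, 1), (0, 2)])
        mpath = tmp_path / "short_map.tsv"
        pd.DataFrame({"snp": ["s1"], "chrom": ["1"], "pos": [100]}).to_csv(
            mpath, sep="\t", index=False)
        with pytest.raises(GenioError, match="map"):
            read_genotypes(gpath, mpath)
    elif case == "bad_cell":
        gpath, mpath = _write_raw(tmp_path, [(2, 3), (1, 1), (0, 2)])
        with pytest.raises(GenioError, match="0/1/2"):
            read_genotypes(gpath, mpath)
    elif case == "dup_iid":
        with pytest.raises(GenioError, match="duplicate individual"):
            GenotypeData(["a", "a"], ["s1"], np.array(["1"], dtype=object),
                         np.array([1]), np.array([[1.0], [2.0]]))
    else:
        with pytest.raises(GenioError, match="duplicate SNP"):
            GenotypeData(["a", "b"], ["s1", "s1"], np.array(["1", "1"], dtype=object),
                         np.array([1, 2]), np.array([[1.0, 0.0], [2.0, 1.0]]))


# ---------------------------------------------------------------------------
# phenotypes


def test_read_phenotypes_missing_split(tmp_path, tiny_geno):
    (tmp_path / "ph.tsv").write_text(
        "iid\ttrait\tbatch\na\t1.2\tA\nb\tNA\tB\nc\t0.7\tA\n")
    ph = read_phenotypes(tmp_path / "ph.tsv", "trait", ["batch"], geno=tiny_geno)
    assert ph.n1 == 2 and ph.n0 == 1
    assert ph.missing_mask.tolist() == [False, True, False]
    assert ph.fixed["batch"].nunique() == 2


def test_read_phenotypes_unknown_id(tmp_path, tiny_geno):
    (tmp_path / "ph.tsv").write_text("iid\ttrait\nX9\t1.0\na\t2.0\n")
    with pytest.raises(GenioError, match="X9"):
        read_phenotypes(tmp_path / "ph.tsv", "trait", geno=tiny_geno)


def test_read_phenotypes_all_missing(tmp_path, tiny_geno):
    (tmp_path / "ph.tsv").write_text("iid\ttrait\na\tNA\nb\tNA\n")
    with pytest.raises(GenioError, match="missing"):
        read_phenotypes(tmp_path / "ph.tsv", "trait", geno=tiny_geno)


# ---------------------------------------------------------------------------
# haplotypes


def _hap_files(tmp_path, geno, rows, blocks):
    hpath = tmp_path / "haps.tsv"
    pd.DataFrame(rows, columns=["iid", "block", "hapA", "hapB"]).to_csv(
        hpath, sep="\t", index=False)
    bpath = tmp_path / "blocks.tsv"
    pd.DataFrame(blocks, columns=["chrom", "start_index", "end_index"]).to_csv(
        bpath, sep="\t", index=False)
    return hpath, bpath


def test_haplotype_tsv_readoff_and_freqs(tmp_path, random_geno_factory):
    geno = random_geno_factory(3, 4, seed=2, n_chrom=2)
    rows = [("i0", 0, "10", "01"), ("i1", 0, "10", "10"), ("i2", 0, "01", "10")]
    hpath, bpath = _hap_files(tmp_path, geno, rows, [("c1", 0, 2)])
    hap = read_haplotypes(hpath, bpath, geno, rare_min=0.0)
    assert hap.n_blocks == 1
    a_i0 = [hap.alleles[0][k] for k in hap.diplotypes[0][0]]
    assert a_i0 == ["10", "01"]
    # hap "10" seen 4 times in 6 chromosomes
    p10 = hap.freqs[0][hap.alleles[0].index("10")]
    assert p10 == pytest.approx(4 / 6)
    assert hap.freqs[0].sum() == pytest.approx(1.0, abs=1e-12)


def test_rare_pooling_keeps_frequency_mass(tmp_path, random_geno_factory):
    geno = random_geno_factory(5, 4, seed=3, n_chrom=2)
    rows = [("i0", 0, "11", "11"), ("i1", 0, "11", "11"), ("i2", 0, "11", "10"),
            ("i3", 0, "10", "10"), ("i4", 0, "10", "01")]
    hpath, bpath = _hap_files(tmp_path, geno, rows, [("c1", 0, 2)])
    hap = read_haplotypes(hpath, bpath, geno, rare_min=0.2)
    assert "rare" in hap.alleles[0] and "01" not in hap.alleles[0]
    assert hap.freqs[0].sum() == pytest.approx(1.0, abs=1e-12)
    assert hap.freqs[0][hap.alleles[0].index("rare")] == pytest.approx(0.1)


def test_phased_vcf_roundtrip(tmp_path, random_geno_factory):
    geno = random_geno_factory(3, 4, seed=4, n_chrom=2)
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=c1>\n##contig=<ID=c2>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ti0\ti1\ti2\n"
    )
    gts = {"s0": ["1|0", "0|0", "1|1"], "s1": ["0|1", "1|0", "0|0"],
           "s2": ["1|1", "0|1", "1|0"], "s3": ["0|0", "1|1", "0|1"]}
    body = ""
    for j, sid in enumerate(["s0", "s1", "s2", "s3"]):
        chrom = "c1" if j < 2 else "c2"
        body += f"{chrom}\t{j + 1}\t{sid}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts[sid]) + "\n"
    vcf = tmp_path / "phased.vcf"
    vcf.write_text(header + body)
    bpath = tmp_path / "blocks.tsv"
    pd.DataFrame([("c1", 0, 2)], columns=["chrom", "start_index", "end_index"]).to_csv(
        bpath, sep="\t", index=False)
    hap = read_haplotypes(vcf, bpath, geno, rare_min=0.0)
    # i0 gametes at c1 SNPs: 1,0 | 0,1
    assert [hap.alleles[0][k] for k in hap.diplotypes[0][0]] == ["10", "01"]


def test_unphased_vcf_rejected(tmp_path, random_geno_factory):
    geno = random_geno_factory(2, 4, seed=5, n_chrom=2)
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=c1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ti0\ti1\n"
        "c1\t1\ts0\tA\tT\t.\tPASS\t.\tGT\t1/0\t0|0\n"
    )
    vcf = tmp_path / "unphased.vcf"
    vcf.write_text(header)
    bpath = tmp_path / "blocks.tsv"
    pd.DataFrame([("c1", 0, 1)], columns=["chrom", "start_index", "end_index"]).to_csv(
        bpath, sep="\t", index=False)
    with pytest.raises(GenioError, match="unphased"):
        read_haplotypes(vcf, bpath, geno)


def test_block_validation(tmp_path, random_geno_factory):
    geno = random_geno_factory(3, 4, seed=6, n_chrom=2)
    rows = [("i0", 0, "1", "0"), ("i1", 0, "1", "1"), ("i2", 0, "0", "0")]
    hpath, bpath = _hap_files(tmp_path, geno, rows, [("c1", 1, 1)])
    with pytest.raises(GenioError, match="invalid block"):
        read_haplotypes(hpath, bpath, geno)
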