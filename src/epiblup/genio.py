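"""Readers and containers for genotype, phenotype, and phased-haplotype inputs.

Genotypes arrive as 0/1/2 allele-count tables (PLINK ``.raw`` dialect or a
headered TSV) with a companion SNP map; phenotypes and fixed-effect covariates
as TSV with ``NA`` marking validation individuals; phased haplotypes either as
a ``|``-phased VCF or a per-individual diplotype TSV together with a
haplotype-block definition file.  Everything downstream (model-matrix coding,
relationship matrices, REML, prediction) works off the three containers
defined here.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeData",
    "PhenotypeData",
    "HaplotypeData",
    "read_genotypes",
    "read_phenotypes",
    "read_haplotypes",
    "write_genotypes",
]

RAW_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class GenioError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class GenotypeData:
    """Individuals x SNPs allele counts with chromosome map and frequencies.

    ``counts`` holds the number of copies of the counted allele (0/1/2) as
    float64 with NaN for missing cells; ``mask`` is True where missing.
    ``freqs`` is the frequency of the counted allele computed from the
    non-missing cells, strictly inside (0, 1) after filtering.
    """

    individual_ids: list[str]
    snp_ids: list[str]
    chromosomes: np.ndarray  # per-SNP label, dtype object/str
    positions: np.ndarray  # per-SNP bp, int64
    counts: np.ndarray  # n x m float64, NaN = missing
    freqs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        n, m = self.counts.shape
        if n < 2 or m < 1:
            raise GenioError(f"need n >= 2 individuals and m >= 1 SNPs, got {n} x {m}")
        if len(self.individual_ids) != n or len(self.snp_ids) != m:
            raise GenioError("id lists do not match the counts matrix shape")
        if len(set(self.individual_ids)) != n:
            raise GenioError("duplicate individual id")
        if len(set(self.snp_ids)) != m:
            raise GenioError("duplicate SNP id")
        ok = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise GenioError(
                f"genotype cell ({self.individual_ids[bad[0]]}, {self.snp_ids[bad[1]]}) "
                "is not one of 0/1/2/NA"
            )
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.freqs is None:
            with np.errstate(invalid="ignore"):
                self.freqs = np.nanmean(self.counts, axis=0) / 2.0
        self.freqs = np.asarray(self.freqs, dtype=np.float64)

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean missingness mask (True = missing)."""
        return np.isnan(self.counts)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeData":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeData(
            individual_ids=list(self.individual_ids),
            snp_ids=[self.snp_ids[j] for j in idx],
            chromosomes=self.chromosomes[idx],
            positions=self.positions[idx],
            counts=self.counts[:, idx],
            freqs=self.freqs[idx],
        )


@dataclass
class PhenotypeData:
    """Trait observations plus fixed-effect covariates, aligned to genotypes.

    ``y`` is NaN for validation individuals (the n0 set); ``fixed`` keeps the
    raw factor/covariate columns — design-matrix expansion happens in the
    mixed-model builder.
    """

    individual_ids: list[str]
    y: np.ndarray
    fixed: pd.DataFrame

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.y.shape[0] != len(self.individual_ids):
            raise GenioError("trait vector length does not match individual ids")
        if np.isnan(self.y).all():
            raise GenioError("all trait observations are missing")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.y)

    @property
    def n1(self) -> int:
        return int((~self.missing_mask).sum())

    @property
    def n0(self) -> int:
        return int(self.missing_mask.sum())


@dataclass
class HaplotypeData:
    """Per-block haplotype-allele catalogs and per-individual diplotypes.

    blocks: list of (chromosome, start, stop) with 0-based half-open SNP-index
    intervals; alleles[b]: catalog of distinct haplotype strings for block b;
    diplotypes[b]: n x 2 integer array of catalog indices (ordered pair);
    freqs[b]: catalog frequencies summing to 1.
    """

    individual_ids: list[str]
    blocks: list[tuple[str, int, int]]
    alleles: list[list[str]]
    diplotypes: list[np.ndarray]
    freqs: list[np.ndarray]

    def __post_init__(self) -> None:
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, a, b in self.blocks:
            if b <= a:
                raise GenioError(f"empty or inverted block [{a}, {b}) on {chrom}")
            for x, y in seen.setdefault(chrom, []):
                if a < y and x < b:
                    raise GenioError(f"overlapping blocks on chromosome {chrom}")
            seen[chrom].append((a, b))
        for b, f in enumerate(self.freqs):
            if abs(float(np.sum(f)) - 1.0) > 1e-12:
                raise GenioError(f"block {b} haplotype frequencies do not sum to 1")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


# ---------------------------------------------------------------------------
# genotype reading


def _parse_genotype_table(path: str | os.PathLike | io.TextIOBase) -> tuple[list[str], list[str], np.ndarray]:
    """Parse a PLINK .raw dialect or headered TSV into ids, snp column names, counts."""
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"], dtype=str)
    cols = list(df.columns)
    if cols[: len(RAW_META_COLS)] == RAW_META_COLS:
        ids = df["IID"].tolist()
        snp_cols = cols[len(RAW_META_COLS):]
    else:
        ids = df.iloc[:, 0].tolist()
        snp_cols = cols[1:]
    raw = df[snp_cols].to_numpy(dtype=object)
    counts = np.full(raw.shape, np.nan)
    notna = pd.notna(raw)
    try:
        counts[notna] = raw[notna].astype(np.float64)
    except ValueError as exc:
        raise GenioError(f"non-numeric genotype cell: {exc}") from exc
    return ids, snp_cols, counts


def read_genotypes(
    path: str | os.PathLike,
    map_path: str | os.PathLike,
    maf_min: float = 0.001,
    miss_max: float = 0.100,
) -> GenotypeData:
    """Read an allele-count table plus SNP map and apply MAF/missingness filters.

    SNPs with minor allele frequency <= ``maf_min`` (including monomorphic
    SNPs) or with a missing-genotype proportion > ``miss_max`` are removed;
    the column order of the survivors is preserved.
    """
    ids, snp_cols, counts = _parse_genotype_table(path)
    snp_map = pd.read_csv(map_path, sep=r"\s+", dtype={"snp": str, "chrom": str})
    for col in ("snp", "chrom", "pos"):
        if col not in snp_map.columns:
            raise GenioError(f"SNP map is missing column '{col}'")
    if len(snp_map) != len(snp_cols):
        raise GenioError(
            f"SNP map has {len(snp_map)} rows but genotype table has {len(snp_cols)} SNP columns"
        )
    # .raw appends the counted allele to the column name (snp_A); accept both
    snp_ids = []
    for col, mapped in zip(snp_cols, snp_map["snp"]):
        base = col.rsplit("_", 1)[0] if col.rsplit("_", 1)[0] == mapped else col
        if base != mapped:
            raise GenioError(f"genotype column '{col}' does not match map SNP '{mapped}'")
        snp_ids.append(mapped)

    geno = GenotypeData(
        individual_ids=ids,
        snp_ids=snp_ids,
        chromosomes=snp_map["chrom"].to_numpy(dtype=object),
        positions=snp_map["pos"].to_numpy(dtype=np.int64),
        counts=counts,
    )
    return filter_genotypes(geno, maf_min=maf_min, miss_max=miss_max)


def filter_genotypes(geno: GenotypeData, maf_min: float = 0.001, miss_max: float = 0.100) -> GenotypeData:
    """Drop SNPs failing the MAF or missingness threshold (idempotent)."""
    miss_rate = geno.mask.mean(axis=0)
    p = geno.freqs
    maf = np.minimum(p, 1.0 - p)
    keep = (miss_rate <= miss_max) & (maf > maf_min) & (p > 0.0) & (p < 1.0)
    if not keep.any():
        raise GenioError("no SNP passes the MAF/missingness filters")
    idx = np.flatnonzero(keep)
    return GenotypeData(
        individual_ids=list(geno.individual_ids),
        snp_ids=[geno.snp_ids[j] for j in idx],
        chromosomes=geno.chromosomes[idx],
        positions=geno.positions[idx],
        counts=geno.counts[:, idx],
    )


def write_genotypes(geno: GenotypeData, path: str | os.PathLike, map_path: str | os.PathLike) -> None:
    """Write a headered TSV (iid + SNP columns) and the companion SNP map."""
    with np.errstate(invalid="ignore"):
        body = pd.DataFrame(geno.counts, columns=geno.snp_ids)
    out = pd.concat([pd.Series(geno.individual_ids, name="iid"), body], axis=1)
    # integers where present, NA where missing
    out.to_csv(path, sep="\t", index=False, na_rep="NA",
               float_format="%.0f")
    pd.DataFrame(
        {"snp": geno.snp_ids, "chrom": geno.chromosomes, "pos": geno.positions}
    ).to_csv(map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotype reading


def read_phenotypes(
    path: str | os.PathLike,
    trait: str,
    fixed: list[str] | None = None,
    geno: GenotypeData | None = None,
) -> PhenotypeData:
    """Read a phenotype/fixed-effects TSV; ``NA`` trait cells mark validation individuals."""
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"], dtype={0: str})
    id_col = df.columns[0]
    ids = df[id_col].astype(str).tolist()
    if trait not in df.columns:
        raise GenioError(f"trait column '{trait}' not found")
    if geno is not None:
        known = set(geno.individual_ids)
        for iid in ids:
            if iid not in known:
                raise GenioError(f"phenotyped individual '{iid}' absent from genotype data")
    fixed = fixed or []
    for col in fixed:
        if col not in df.columns:
            raise GenioError(f"fixed-effect column '{col}' not found")
    return PhenotypeData(
        individual_ids=ids,
        y=df[trait].to_numpy(dtype=np.float64),
        fixed=df[fixed].copy(),
    )


# ---------------------------------------------------------------------------
# haplotype reading


def _read_blocks(blocks_path: str | os.PathLike, geno: GenotypeData) -> list[tuple[str, int, int]]:
    df = pd.read_csv(blocks_path, sep=r"\s+", dtype={"chrom": str})
    blocks = []
    chrom_index: dict[str, np.ndarray] = {}
    for c in pd.unique(geno.chromosomes):
        chrom_index[str(c)] = np.flatnonzero(geno.chromosomes == c)
    for _, row in df.iterrows():
        chrom, a, b = str(row["chrom"]), int(row["start_index"]), int(row["end_index"])
        if chrom not in chrom_index:
            raise GenioError(f"block chromosome '{chrom}' absent from genotype map")
        if b <= a or b > len(chrom_index[chrom]):
            raise GenioError(f"invalid block [{a}, {b}) on chromosome {chrom}")
        blocks.append((chrom, a, b))
    return blocks


def _block_snp_indices(geno: GenotypeData, block: tuple[str, int, int]) -> np.ndarray:
    chrom, a, b = block
    on_chrom = np.flatnonzero(geno.chromosomes == chrom)
    return on_chrom[a:b]


def _catalog_block(
    hapA: list[str], hapB: list[str], rare_min: float
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Build the allele catalog, diplotype index pairs, and pooled frequencies."""
    strings = hapA + hapB
    cat, counts = np.unique(strings, return_counts=True)
    freqs = counts / counts.sum()
    rare = freqs < rare_min
    alleles = [str(a) for a in cat[~rare]]
    out_freqs = list(freqs[~rare])
    index = {a: i for i, a in enumerate(alleles)}
    if rare.any():
        alleles.append("rare")
        out_freqs.append(float(freqs[rare].sum()))
        for a in cat[rare]:
            index[str(a)] = len(alleles) - 1
    n = len(hapA)
    diplo = np.empty((n, 2), dtype=np.int64)
    for j in range(n):
        diplo[j, 0] = index[hapA[j]]
        diplo[j, 1] = index[hapB[j]]
    return alleles, diplo, np.asarray(out_freqs)


def read_haplotypes(
    path: str | os.PathLike,
    blocks_path: str | os.PathLike,
    geno: GenotypeData,
    rare_min: float = 0.01,
) -> HaplotypeData:
    """Read phased haplotypes from a ``|``-phased VCF or a diplotype TSV.

    Haplotype alleles with frequency below ``rare_min`` are pooled into one
    "rare" pseudo-allele per block; frequencies are renormalized to sum 1.
    """
    blocks = _read_blocks(blocks_path, geno)
    path = os.fspath(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        gametes = _phased_from_vcf(path, geno)
        hapAB = None
    else:
        hapAB = _diplotypes_from_tsv(path, geno, len(blocks))
        gametes = None

    alleles_all, diplo_all, freqs_all = [], [], []
    for b, block in enumerate(blocks):
        if gametes is not None:
            idx = _block_snp_indices(geno, block)
            hapA = ["".join(str(x) for x in gametes[0][j, idx]) for j in range(geno.n)]
            hapB = ["".join(str(x) for x in gametes[1][j, idx]) for j in range(geno.n)]
        else:
            hapA, hapB = hapAB[b]
        cat, diplo, fr = _catalog_block(hapA, hapB, rare_min)
        alleles_all.append(cat)
        diplo_all.append(diplo)
        freqs_all.append(fr)
    return HaplotypeData(
        individual_ids=list(geno.individual_ids),
        blocks=blocks,
        alleles=alleles_all,
        diplotypes=diplo_all,
        freqs=freqs_all,
    )


def _phased_from_vcf(path: str, geno: GenotypeData) -> tuple[np.ndarray, np.ndarray]:
    """Extract the two gamete allele matrices (n x m of 0/1) from a phased VCF."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_pos = {s: i for i, s in enumerate(vcf.samples)}
    missing = [iid for iid in geno.individual_ids if iid not in sample_pos]
    if missing:
        raise GenioError(f"VCF lacks samples: {missing[:3]}")
    order = [sample_pos[iid] for iid in geno.individual_ids]
    by_id: dict[str, np.ndarray] = {}
    for var in vcf:
        gts = np.asarray(var.genotype.array())
        if not np.all(gts[:, 2] == 1):
            raise GenioError(f"unphased genotype at {var.ID or var.POS}")
        by_id[str(var.ID)] = gts[order, :2]
    cols = []
    for sid in geno.snp_ids:
        if sid not in by_id:
            raise GenioError(f"SNP '{sid}' missing from phased VCF")
        cols.append(by_id[sid])
    stacked = np.stack(cols, axis=1)  # n x m x 2
    return stacked[:, :, 0], stacked[:, :, 1]


def _diplotypes_from_tsv(
    path: str, geno: GenotypeData, n_blocks: int
) -> list[tuple[list[str], list[str]]]:
    """Read a (iid, block, hapA, hapB) TSV into per-block haplotype string lists."""
    df = pd.read_csv(path, sep=r"\s+", dtype={"iid": str, "hapA": str, "hapB": str})
    out = []
    pos = {iid: j for j, iid in enumerate(geno.individual_ids)}
    for b in range(n_blocks):
        sub = df[df["block"] == b]
        if len(sub) != geno.n:
            raise GenioError(f"block {b}: expected {geno.n} diplotype rows, got {len(sub)}")
        hapA = [""] * geno.n
        hapB = [""] * geno.n
        for _, row in sub.iterrows():
            j = pos[str(row["iid"])]
            hapA[j] = str(row["hapA"])
            hapB[j] = str(row["hapB"])
        out.append((hapA, hapB))
    return out
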