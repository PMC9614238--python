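"""Seeded synthetic data: genotypes near HWE, haplotype blocks, phenotypes.

Genotypes are drawn as two independent gametes per individual per SNP at a
uniform-random allele frequency (Hardy-Weinberg, no linkage disequilibrium),
stored phased so haplotype blocks can be read off directly.  Phenotypes are a
sum of per-effect-type genetic values plus Gaussian residuals:

    y = mu + sum_i u_i + e

For SNP additive, SNP dominance, and haplotype types the effects are drawn
per column on the normalized T_i scale (so the nominal variance fraction is
the effect-type heritability); for epistasis types the genetic-value vector
is drawn from N(0, sigma_i^2 S_i) using the exact (distinct-locus)
relationship matrix — distributionally identical to drawing per-column
epistasis effects without materializing the pair/triple model matrix.  Every
u_i and the residual are rescaled to their exact target sample variances, so
the realized variance composition equals the nominal one.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import ModelMatrix, additive_W, dominance_W, haplotype_W
from .genio import (
    GenotypeData,
    HaplotypeData,
    PhenotypeData,
    _catalog_block,
    write_genotypes,
)
from .grm import egerm, intra_inter

__all__ = ["SimConfig", "simulate_genotypes", "simulate_phenotypes", "write_dataset"]


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n: int = 300
    chromosomes: tuple[int, ...] = (30, 30)  # SNPs per chromosome
    freq_range: tuple[float, float] = (0.05, 0.95)
    block_len: int = 2
    fractions: dict[str, float] = field(default_factory=dict)  # effect_type -> h2
    residual: float | None = None  # default: 1 - sum(fractions)
    sigma_y2: float = 1.0
    mu: float = 0.0
    n_validation: int = 0
    rare_min: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if any(v < 0 for v in self.fractions.values()) or total > 1.0 + 1e-12:
            raise ValueError("variance fractions must be >= 0 and sum to <= 1")
        if self.residual is None:
            self.residual = 1.0 - total
        needs_two = any(t.endswith(("_intra", "_inter")) for t in self.fractions)
        if needs_two and len(self.chromosomes) < 2:
            raise ValueError("intra/inter effect types need at least 2 chromosomes")
        if self.n_validation >= self.n:
            raise ValueError("n_validation must leave at least one training individual")


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeData, HaplotypeData]:
    """Draw phased HWE genotypes and tile haplotype blocks per chromosome."""
    rng = np.random.default_rng(cfg.seed)
    m = int(sum(cfg.chromosomes))
    p = rng.uniform(*cfg.freq_range, size=m)
    g0 = (rng.random((cfg.n, m)) < p).astype(np.int8)
    g1 = (rng.random((cfg.n, m)) < p).astype(np.int8)
    # resample monomorphic columns so downstream frequencies stay in (0, 1)
    for _ in range(100):
        counts = g0 + g1
        mono = (counts.min(axis=0) == counts.max(axis=0))
        if not mono.any():
            break
        idx = np.flatnonzero(mono)
        g0[:, idx] = rng.random((cfg.n, idx.size)) < p[idx]
        g1[:, idx] = rng.random((cfg.n, idx.size)) < p[idx]

    chroms = np.concatenate(
        [np.full(mc, f"chr{c + 1}", dtype=object) for c, mc in enumerate(cfg.chromosomes)]
    )
    positions = np.concatenate([1000 * (np.arange(mc) + 1) for mc in cfg.chromosomes])
    snp_ids: list[str] = []
    for c, mc in enumerate(cfg.chromosomes):
        snp_ids += [f"chr{c + 1}_snp{j}" for j in range(mc)]
    ids = [f"ind{j:05d}" for j in range(cfg.n)]
    geno = GenotypeData(
        individual_ids=ids,
        snp_ids=snp_ids,
        chromosomes=chroms,
        positions=positions,
        counts=(g0 + g1).astype(np.float64),
    )

    blocks: list[tuple[str, int, int]] = []
    for c, mc in enumerate(cfg.chromosomes):
        for start in range(0, mc - cfg.block_len + 1, cfg.block_len):
            blocks.append((f"chr{c + 1}", start, start + cfg.block_len))
    offset = dict(zip([f"chr{c + 1}" for c in range(len(cfg.chromosomes))],
                      np.cumsum([0] + list(cfg.chromosomes[:-1]))))
    alleles_all, diplo_all, freqs_all = [], [], []
    for chrom, a, b in blocks:
        lo, hi = offset[chrom] + a, offset[chrom] + b
        hapA = ["".join(map(str, g0[j, lo:hi])) for j in range(cfg.n)]
        hapB = ["".join(map(str, g1[j, lo:hi])) for j in range(cfg.n)]
        cat, diplo, fr = _catalog_block(hapA, hapB, cfg.rare_min)
        alleles_all.append(cat)
        diplo_all.append(diplo)
        freqs_all.append(fr)
    hap = HaplotypeData(ids, blocks, alleles_all, diplo_all, freqs_all)
    return geno, hap


def _genetic_value(
    effect_type: str,
    geno: GenotypeData,
    hap: HaplotypeData,
    rng: np.random.Generator,
    cache: dict,
) -> tuple[np.ndarray, np.ndarray | None]:
    """One unscaled genetic-value vector; returns (u, tau-or-None)."""
    def mm_a() -> ModelMatrix:
        if "A" not in cache:
            cache["A"] = additive_W(geno)
        return cache["A"]

    def mm_d() -> ModelMatrix:
        if "D" not in cache:
            cache["D"] = dominance_W(geno)
        return cache["D"]

    if effect_type in ("A", "D", "H"):
        mm = {"A": mm_a, "D": mm_d, "H": lambda: haplotype_W(hap)}[effect_type]()
        tau = rng.standard_normal(mm.m)
        return mm.T @ tau, tau
    # epistasis: draw from N(0, S_i) via eigendecomposition of the exact S_i
    if effect_type.endswith(("_intra", "_inter")):
        base, scope = effect_type.rsplit("_", 1)
        Wd = mm_d().W if "D" in base else None
        gi, ge = intra_inter(mm_a().W, Wd, geno.chromosomes, base, method="egerm")
        S = gi.S if scope == "intra" else ge.S
    else:
        Wd = mm_d().W if "D" in effect_type else None
        S = egerm(mm_a().W, Wd, effect_type).S
    vals, vecs = np.linalg.eigh(S)
    vals = np.clip(vals, 0.0, None)
    u = vecs @ (np.sqrt(vals) * rng.standard_normal(len(vals)))
    return u, None


def simulate_phenotypes(
    cfg: SimConfig, geno: GenotypeData, hap: HaplotypeData
) -> tuple[PhenotypeData, dict]:
    """Phenotypes with the configured variance composition plus a truth record."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7919)))
    n = geno.n
    cache: dict = {}
    u_store: dict[str, np.ndarray] = {}
    tau_store: dict[str, list[float]] = {}
    g = np.zeros(n)
    for t, frac in cfg.fractions.items():
        if frac == 0.0:
            continue
        u, tau = _genetic_value(t, geno, hap, rng, cache)
        sd = float(np.std(u, ddof=1))
        if sd == 0.0:
            raise ValueError(f"degenerate genetic values for effect type {t}")
        scale = np.sqrt(frac * cfg.sigma_y2) / sd
        u = (u - u.mean()) * scale
        u_store[t] = u
        if tau is not None:
            tau_store[t] = (tau * scale).tolist()
        g += u
    e = rng.standard_normal(n)
    e = (e - e.mean()) / np.std(e, ddof=1) * np.sqrt(cfg.residual * cfg.sigma_y2)
    y_full = cfg.mu + g + e
    y = y_full.copy()
    if cfg.n_validation:
        y[-cfg.n_validation:] = np.nan
    pheno = PhenotypeData(
        individual_ids=list(geno.individual_ids),
        y=y,
        fixed=pd.DataFrame(index=range(n)),
    )
    truth = {
        "seed": cfg.seed,
        "fractions": dict(cfg.fractions),
        "residual": cfg.residual,
        "u": {t: v.tolist() for t, v in u_store.items()},
        "tau": tau_store,
        "g": g.tolist(),
        "y_full": y_full.tolist(),
        "realized_var": {t: float(np.var(v, ddof=1)) for t, v in u_store.items()},
    }
    return pheno, truth


def write_dataset(
    outdir: str | os.PathLike,
    cfg: SimConfig,
    geno: GenotypeData,
    hap: HaplotypeData,
    pheno: PhenotypeData,
    truth: dict,
) -> None:
    """Write the dataset in the formats the readers accept, plus the truth JSON."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    write_genotypes(geno, os.path.join(outdir, "genotypes.tsv"),
                    os.path.join(outdir, "snp_map.tsv"))
    pd.DataFrame({"iid": pheno.individual_ids, "trait": pheno.y}).to_csv(
        os.path.join(outdir, "phenotypes.tsv"), sep="\t", index=False, na_rep="NA"
    )
    rows = []
    for b, (cat, diplo) in enumerate(zip(hap.alleles, hap.diplotypes)):
        for j, iid in enumerate(hap.individual_ids):
            rows.append((iid, b, cat[diplo[j, 0]], cat[diplo[j, 1]]))
    pd.DataFrame(rows, columns=["iid", "block", "hapA", "hapB"]).to_csv(
        os.path.join(outdir, "haplotypes.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        [(c, a, b) for c, a, b in hap.blocks], columns=["chrom", "start_index", "end_index"]
    ).to_csv(os.path.join(outdir, "blocks.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh)
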