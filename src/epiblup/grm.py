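"""Genomic relationship matrices for all effect types of Model-I and Model-II.

Epistasis relationship matrices are built from the additive and dominance
numerators N_A = W_aW_a' and N_D = W_dW_d' without ever forming the epistasis
model matrices, by either of two constructions:

* AGERM (approximate): entrywise Hadamard products of the numerators
  (N_A o N_A for A x A, N_A o N_D for A x D, ...), the genomic analogue of
  Henderson's products of pedigree relationship matrices.  The Hadamard
  product sums locus products over ALL index tuples, so it contains spurious
  same-locus ("intra-locus") terms.

* EGERM (exact): sums the Cockerham locus products over DISTINCT loci only.
  Writing x_i = w_a,ji * w_a,ki and y_i = w_d,ji * w_d,ki for one entry (j,k),
  the distinct-locus sums are elementary symmetric polynomials in the x_i and
  y_i and reduce to power sums:

      AA : e2(x) = (s_x^2 - p_20) / 2
      DD : e2(y)
      AD : s_x s_y - p_11                      (ordered distinct pairs)
      AAA: e3(x) = (s_x^3 - 3 s_x p_20 + 2 p_30) / 6
      DDD: e3(y)
      AAD: e2(x) s_y - s_x p_11 + p_21
      ADD: e2(y) s_x - s_y p_11 + p_12

  with s_x = sum_i x_i and p_ab = sum_i x_i^a y_i^b.  Every p_ab is itself an
  n x n cross-product of an elementwise power of W_a and W_d, so the whole
  construction stays O(n^2 m).  All formulas are gated by the brute-force
  explicit-model-matrix oracle in the test suite.

The intra-/inter-chromosome partition computes the intra numerator
chromosome-by-chromosome, obtains the inter numerator as whole minus intra,
and normalizes each part by its own mean diagonal.

Every relationship matrix is normalized to mean diagonal exactly 1, so the
variance attached to it reads as the average per-individual genetic variance
of that effect type.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import (
    EPISTASIS_TYPES,
    PAIRWISE_TYPES,
    THIRD_ORDER_TYPES,
    ModelMatrix,
    additive_W,
    dominance_W,
    haplotype_W,
)
from .genio import GenotypeData, HaplotypeData

__all__ = [
    "GRM",
    "GRMSet",
    "grm_direct",
    "agerm_numerator",
    "egerm_numerator",
    "agerm",
    "egerm",
    "intra_inter",
    "assemble",
    "write_grm",
    "read_grm",
    "write_grm_tsv",
    "read_grm_tsv",
    "MODEL_I_TYPES",
    "MODEL_II_TYPES",
]

# effect-type order of the 10-type and 13-type models
MODEL_I_TYPES = ["A", "D", "H", "AA", "AD", "DD", "AAA", "AAD", "ADD", "DDD"]
MODEL_II_TYPES = [
    "A", "D", "H",
    "AA_intra", "AD_intra", "DD_intra",
    "AA_inter", "AD_inter", "DD_inter",
    "AAA", "AAD", "ADD", "DDD",
]


@dataclass
class GRM:
    """A normalized genomic relationship matrix with its provenance."""

    effect_type: str
    S: np.ndarray
    k: float  # mean diagonal of the numerator, used as normalizer
    method: str  # "direct" | "agerm" | "egerm"
    scope: str = "whole"  # "whole" | "intra" | "inter"
    ids: list[str] | None = None
    numerator: np.ndarray | None = None  # pre-normalization matrix, when retained

    @property
    def n(self) -> int:
        return self.S.shape[0]


@dataclass
class GRMSet:
    """An ordered collection of relationship matrices defining a model."""

    model: str  # "Model-I" | "Model-II" | "custom"
    grms: list[GRM] = field(default_factory=list)

    @property
    def effect_types(self) -> list[str]:
        return [g.effect_type for g in self.grms]

    def __iter__(self):
        return iter(self.grms)

    def __len__(self) -> int:
        return len(self.grms)

    def __getitem__(self, key: int | str) -> GRM:
        if isinstance(key, str):
            return self.grms[self.effect_types.index(key)]
        return self.grms[key]


def _normalize(numerator: np.ndarray, effect_type: str, method: str, scope: str,
               ids: list[str] | None = None) -> GRM:
    k = float(np.trace(numerator)) / numerator.shape[0]
    if k <= 0.0:
        raise ValueError(f"{effect_type} numerator has non-positive mean diagonal")
    return GRM(effect_type, numerator / k, k, method, scope, ids, numerator)


def grm_direct(mm: ModelMatrix, ids: list[str] | None = None) -> GRM:
    """S = WW'/k from an explicit model matrix (mean diagonal 1)."""
    return _normalize(mm.W @ mm.W.T, mm.effect_type, "direct", "whole", ids)


# ---------------------------------------------------------------------------
# AGERM


_AGERM_RECIPE = {
    "AA": (2, 0), "AD": (1, 1), "DD": (0, 2),
    "AAA": (3, 0), "AAD": (2, 1), "ADD": (1, 2), "DDD": (0, 3),
}


def agerm_numerator(N_A: np.ndarray, N_D: np.ndarray | None, effect_type: str) -> np.ndarray:
    """Hadamard-product numerator from additive/dominance numerators."""
    if effect_type not in _AGERM_RECIPE:
        raise ValueError(f"unknown epistasis type '{effect_type}'")
    a, d = _AGERM_RECIPE[effect_type]
    if d and N_D is None:
        raise ValueError(f"type {effect_type} needs the dominance numerator")
    out = np.ones_like(N_A)
    for _ in range(a):
        out = out * N_A
    for _ in range(d):
        out = out * N_D
    return out


def agerm(N_A: np.ndarray, N_D: np.ndarray | None, effect_type: str,
          ids: list[str] | None = None) -> GRM:
    return _normalize(agerm_numerator(N_A, N_D, effect_type), effect_type, "agerm", "whole", ids)


# ---------------------------------------------------------------------------
# EGERM


def _power_products(W_a: np.ndarray, W_d: np.ndarray | None, needed: set[tuple[int, int]]
                    ) -> dict[tuple[int, int], np.ndarray]:
    """Cross-products p_ab[j,k] = sum_i (w_a,ji w_a,ki)^a (w_d,ji w_d,ki)^b."""
    out = {}
    for a, b in needed:
        U = np.ones_like(W_a)
        if a:
            U = U * W_a ** a
        if b:
            U = U * W_d ** b
        out[(a, b)] = U @ U.T
    return out


def egerm_numerator(W_a: np.ndarray, W_d: np.ndarray | None, effect_type: str) -> np.ndarray:
    """Distinct-locus (exact) epistasis numerator via power-sum identities."""
    if effect_type not in EPISTASIS_TYPES:
        raise ValueError(f"unknown epistasis type '{effect_type}'")
    if "D" in effect_type and W_d is None:
        raise ValueError(f"type {effect_type} needs the dominance matrix")
    order = 3 if effect_type in THIRD_ORDER_TYPES else 2
    if W_a.shape[1] < order:
        return np.zeros((W_a.shape[0], W_a.shape[0]))

    if effect_type == "AA":
        p = _power_products(W_a, W_d, {(1, 0), (2, 0)})
        s = p[(1, 0)]
        return 0.5 * (s * s - p[(2, 0)])
    if effect_type == "DD":
        p = _power_products(W_a, W_d, {(0, 1), (0, 2)})
        s = p[(0, 1)]
        return 0.5 * (s * s - p[(0, 2)])
    if effect_type == "AD":
        p = _power_products(W_a, W_d, {(1, 0), (0, 1), (1, 1)})
        return p[(1, 0)] * p[(0, 1)] - p[(1, 1)]
    if effect_type == "AAA":
        p = _power_products(W_a, W_d, {(1, 0), (2, 0), (3, 0)})
        s = p[(1, 0)]
        return (s ** 3 - 3.0 * s * p[(2, 0)] + 2.0 * p[(3, 0)]) / 6.0
    if effect_type == "DDD":
        p = _power_products(W_a, W_d, {(0, 1), (0, 2), (0, 3)})
        s = p[(0, 1)]
        return (s ** 3 - 3.0 * s * p[(0, 2)] + 2.0 * p[(0, 3)]) / 6.0
    if effect_type == "AAD":
        p = _power_products(W_a, W_d, {(1, 0), (2, 0), (0, 1), (1, 1), (2, 1)})
        sx, sy = p[(1, 0)], p[(0, 1)]
        e2x = 0.5 * (sx * sx - p[(2, 0)])
        return e2x * sy - sx * p[(1, 1)] + p[(2, 1)]
    # ADD
    p = _power_products(W_a, W_d, {(1, 0), (0, 1), (0, 2), (1, 1), (1, 2)})
    sx, sy = p[(1, 0)], p[(0, 1)]
    e2y = 0.5 * (sy * sy - p[(0, 2)])
    return e2y * sx - sy * p[(1, 1)] + p[(1, 2)]


def egerm(W_a: np.ndarray, W_d: np.ndarray | None, effect_type: str,
          ids: list[str] | None = None) -> GRM:
    return _normalize(egerm_numerator(W_a, W_d, effect_type), effect_type, "egerm", "whole", ids)


# ---------------------------------------------------------------------------
# intra-/inter-chromosome partition


def intra_inter(
    W_a: np.ndarray,
    W_d: np.ndarray | None,
    chromosomes: np.ndarray,
    effect_type: str,
    method: str = "agerm",
    ids: list[str] | None = None,
) -> tuple[GRM, GRM]:
    """Split a pairwise epistasis numerator into intra- and inter-chromosome parts.

    The intra numerator sums the per-chromosome numerators; the inter
    numerator is the whole-genome numerator minus the intra numerator; each
    part is normalized by its own mean diagonal.
    """
    if effect_type not in PAIRWISE_TYPES:
        raise ValueError("intra/inter partition is defined for pairwise types (AA, AD, DD)")
    chromosomes = np.asarray(chromosomes)
    labels = pd.unique(chromosomes)
    if len(labels) < 2:
        raise ValueError("inter-chromosome part is empty: a single chromosome was supplied")

    def numer(Wa_sub, Wd_sub):
        if method == "agerm":
            N_A = Wa_sub @ Wa_sub.T
            N_D = Wd_sub @ Wd_sub.T if Wd_sub is not None else None
            return agerm_numerator(N_A, N_D, effect_type)
        if method == "egerm":
            return egerm_numerator(Wa_sub, Wd_sub, effect_type)
        raise ValueError(f"unknown method '{method}'")

    whole = numer(W_a, W_d)
    intra = np.zeros_like(whole)
    for c in labels:
        cols = chromosomes == c
        intra += numer(W_a[:, cols], W_d[:, cols] if W_d is not None else None)
    inter = whole - intra
    return (
        _normalize(intra, f"{effect_type}_intra", method, "intra", ids),
        _normalize(inter, f"{effect_type}_inter", method, "inter", ids),
    )


# ---------------------------------------------------------------------------
# model assembly


def assemble(
    model: str | list[str],
    geno: GenotypeData,
    hap: HaplotypeData | None = None,
    method: str = "agerm",
) -> GRMSet:
    """Build the ordered relationship-matrix set for Model-I, Model-II, or a subset.

    Model-I: 10 whole-genome types (A, D, haplotype, AA, AD, DD, AAA, AAD,
    ADD, DDD).  Model-II: 13 types, with the three whole-genome pairwise
    types replaced by their intra- and inter-chromosome versions.  A custom
    list keeps its relative order.
    """
    if isinstance(model, str):
        if model == "Model-I":
            wanted = list(MODEL_I_TYPES)
        elif model == "Model-II":
            wanted = list(MODEL_II_TYPES)
        else:
            raise ValueError(f"unknown model '{model}'")
        name = model
    else:
        wanted = list(model)
        if not wanted:
            raise ValueError("empty effect-type list")
        name = "custom"

    needs_split = [t for t in wanted if t.endswith(("_intra", "_inter"))]
    if needs_split and len(pd.unique(geno.chromosomes)) < 2:
        raise ValueError("intra/inter effect types require at least 2 chromosomes")
    if "H" in wanted and hap is None:
        raise ValueError("haplotype effect type requested but no haplotype data supplied")

    mm_a = additive_W(geno)
    need_dom = any("D" in t for t in wanted)
    mm_d = dominance_W(geno) if need_dom else None
    N_A = mm_a.W @ mm_a.W.T
    N_D = mm_d.W @ mm_d.W.T if mm_d is not None else None
    ids = list(geno.individual_ids)

    split_cache: dict[tuple[str, str], GRM] = {}
    grms: list[GRM] = []
    for t in wanted:
        if t == "A":
            grms.append(grm_direct(mm_a, ids))
        elif t == "D":
            grms.append(grm_direct(mm_d, ids))
        elif t == "H":
            grms.append(grm_direct(haplotype_W(hap), ids))
        elif t in EPISTASIS_TYPES:
            if method == "agerm":
                grms.append(agerm(N_A, N_D, t, ids))
            else:
                grms.append(egerm(mm_a.W, mm_d.W if mm_d is not None else None, t, ids))
        elif t.endswith(("_intra", "_inter")):
            base, scope = t.rsplit("_", 1)
            if (base, scope) not in split_cache:
                gi, ge = intra_inter(
                    mm_a.W, mm_d.W if mm_d is not None else None,
                    geno.chromosomes, base, method, ids,
                )
                split_cache[(base, "intra")] = gi
                split_cache[(base, "inter")] = ge
            grms.append(split_cache[(base, scope)])
        else:
            raise ValueError(f"unknown effect type '{t}'")
    return GRMSet(name, grms)


# ---------------------------------------------------------------------------
# GRM store: lower-triangle binary + id file + metadata, with a TSV fallback


def write_grm(grm: GRM, prefix: str | os.PathLike) -> None:
    """Write lower-triangle float64 binary, id list, and JSON metadata."""
    prefix = os.fspath(prefix)
    n = grm.n
    tri = grm.S[np.tril_indices(n)]
    tri.astype(np.float64).tofile(prefix + ".grm.bin")
    ids = grm.ids if grm.ids is not None else [str(j) for j in range(n)]
    with open(prefix + ".grm.id", "w") as fh:
        fh.write("\n".join(ids) + "\n")
    with open(prefix + ".grm.json", "w") as fh:
        json.dump(
            {"effect_type": grm.effect_type, "method": grm.method,
             "scope": grm.scope, "k": grm.k, "n": n},
            fh, indent=1,
        )


def read_grm(prefix: str | os.PathLike) -> GRM:
    prefix = os.fspath(prefix)
    with open(prefix + ".grm.json") as fh:
        meta = json.load(fh)
    with open(prefix + ".grm.id") as fh:
        ids = fh.read().split()
    n = meta["n"]
    tri = np.fromfile(prefix + ".grm.bin", dtype=np.float64)
    S = np.zeros((n, n))
    S[np.tril_indices(n)] = tri
    S = S + np.tril(S, -1).T
    return GRM(meta["effect_type"], S, meta["k"], meta["method"], meta["scope"], ids)


def write_grm_tsv(grm: GRM, path: str | os.PathLike) -> None:
    """Long-format (i, j, value) TSV over the lower triangle."""
    n = grm.n
    rows, cols = np.tril_indices(n)
    pd.DataFrame({"i": rows, "j": cols, "value": grm.S[rows, cols]}).to_csv(
        path, sep="\t", index=False
    )


def read_grm_tsv(path: str | os.PathLike, effect_type: str = "?",
                 method: str = "?", scope: str = "whole") -> GRM:
    df = pd.read_csv(path, sep="\t")
    n = int(df["i"].max()) + 1
    S = np.zeros((n, n))
    S[df["i"], df["j"]] = df["value"]
    S = np.tril(S) + np.tril(S, -1).T
    return GRM(effect_type, S, float(np.trace(S)) / n, method, scope)
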