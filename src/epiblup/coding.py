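"""Model-matrix coding for every effect type.

Each effect type i has a coded matrix W_i (individuals x effect levels), a
scaling constant k_i = tr(W_iW_i')/n (the average diagonal of W_iW_i'), and a
normalized matrix T_i = W_i/sqrt(k_i) so that the relationship matrix
S_i = T_iT_i' = W_iW_i'/k_i has mean diagonal exactly 1.  With that scaling
the variance attached to S_i is the average genetic variance per individual
for that effect type, which is what makes sigma_i^2 / sigma_y^2 a
heritability.

Codings (counted-allele frequency p, q = 1 - p):

* additive: allele count g coded g - 2p (so 2, 1, 0 -> 2q, q-p, -2p shifted
  forms; zero mean in the coding sample);
* dominance: genotype with count 2, 1, 0 coded -2q^2, 2pq, -2p^2 (zero mean
  under HWE);
* haplotype additive: one column per (block, haplotype allele h), diplotype
  count of h minus 2 p_h;
* epistasis: elementwise products of the parent additive/dominance columns
  over distinct loci (unordered pairs/triples; A x D uses ordered pairs,
  alpha-delta block then delta-alpha block).

Explicit epistasis matrices are exponential in size and exist here for
effect back-solving and as the brute-force oracle that gates the closed-form
relationship constructions in :mod:`epiblup.grm`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .genio import GenotypeData, HaplotypeData

__all__ = [
    "ModelMatrix",
    "additive_W",
    "dominance_W",
    "haplotype_W",
    "epistasis_W",
    "k_of",
    "EPISTASIS_TYPES",
    "PAIRWISE_TYPES",
    "THIRD_ORDER_TYPES",
]

PAIRWISE_TYPES = ("AA", "AD", "DD")
THIRD_ORDER_TYPES = ("AAA", "AAD", "ADD", "DDD")
EPISTASIS_TYPES = PAIRWISE_TYPES + THIRD_ORDER_TYPES


@dataclass
class ModelMatrix:
    """A coded effect-type matrix W with its normalizer k = tr(WW')/n."""

    effect_type: str
    W: np.ndarray
    k: float
    column_labels: list[str]

    def __post_init__(self) -> None:
        if self.W.shape[1] != len(self.column_labels):
            raise ValueError("column label list does not match W")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def m(self) -> int:
        return self.W.shape[1]

    @property
    def T(self) -> np.ndarray:
        """Normalized model matrix T = W / sqrt(k)."""
        return self.W / np.sqrt(self.k)

    def S(self) -> np.ndarray:
        """Relationship matrix S = WW'/k (mean diagonal 1)."""
        return (self.W @ self.W.T) / self.k


def k_of(W: np.ndarray) -> float:
    """Average diagonal of WW' computed without forming WW'."""
    k = float(np.einsum("ij,ij->", W, W)) / W.shape[0]
    if k <= 0.0:
        raise ValueError("all-zero model matrix: k = 0 would leave S undefined")
    return k


def _centered_additive(geno: GenotypeData) -> np.ndarray:
    W = geno.counts - 2.0 * geno.freqs
    W[geno.mask] = 0.0  # mean imputation on the centered scale
    return W


def additive_W(geno: GenotypeData) -> ModelMatrix:
    """SNP additive coding: allele count minus twice the allele frequency."""
    if geno.m == 0:
        raise ValueError("empty SNP set")
    W = _centered_additive(geno)
    return ModelMatrix("A", W, k_of(W), list(geno.snp_ids))


def dominance_W(geno: GenotypeData) -> ModelMatrix:
    """SNP dominance coding: counts 2/1/0 -> (-2q^2, 2pq, -2p^2)."""
    if geno.m == 0:
        raise ValueError("empty SNP set")
    p = geno.freqs
    q = 1.0 - p
    g = geno.counts
    W = np.where(g == 2.0, -2.0 * q * q, np.where(g == 1.0, 2.0 * p * q, -2.0 * p * p))
    W = np.asarray(W, dtype=np.float64)
    W[geno.mask] = 0.0
    return ModelMatrix("D", W, k_of(W), list(geno.snp_ids))


def haplotype_W(hap: HaplotypeData) -> ModelMatrix:
    """Haplotype additive coding: per (block, allele) column, count minus 2 p_h.

    Single-allele blocks produce identically-zero columns and are dropped
    with a warning.
    """
    import warnings

    n = len(hap.individual_ids)
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for b, (block, cat, diplo, fr) in enumerate(
        zip(hap.blocks, hap.alleles, hap.diplotypes, hap.freqs)
    ):
        if len(cat) < 2:
            warnings.warn(f"haplotype block {b} has a single allele; column dropped")
            continue
        for h, (allele, p_h) in enumerate(zip(cat, fr)):
            count = (diplo == h).sum(axis=1).astype(np.float64)
            cols.append(count - 2.0 * p_h)
            labels.append(f"block{b}:{allele}")
    if not cols:
        raise ValueError("no polymorphic haplotype block")
    W = np.column_stack(cols)
    return ModelMatrix("H", W, k_of(W), labels)


def _pair_indices(m: int, chromosomes: np.ndarray | None, chrom_filter: str):
    for i, j in combinations(range(m), 2):
        if chromosomes is not None and chrom_filter != "none":
            same = chromosomes[i] == chromosomes[j]
            if chrom_filter == "intra" and not same:
                continue
            if chrom_filter == "inter" and same:
                continue
        yield i, j


def _triple_indices(m: int):
    yield from combinations(range(m), 3)


def epistasis_W(
    add: ModelMatrix,
    dom: ModelMatrix | None,
    effect_type: str,
    chrom_filter: str = "none",
    chromosomes: np.ndarray | None = None,
) -> ModelMatrix:
    """Explicit epistasis model matrix over distinct loci (oracle / back-solving).

    AA/DD: unordered pairs i < i' of additive (dominance) columns; AD: the
    alpha-delta block (additive_i * dominance_i', i < i') followed by the
    delta-alpha block (dominance_i * additive_i'), 2*C(m,2) columns in total.
    Third-order types run over unordered distinct triples, with mixed types
    (AAD, ADD) assigning the minority role to each member of the triple in
    turn.  ``chrom_filter`` restricts pairs to same-chromosome ("intra") or
    different-chromosome ("inter") index sets; triples are whole-genome only.
    """
    if effect_type not in EPISTASIS_TYPES:
        raise ValueError(f"unknown epistasis type '{effect_type}'")
    order = 3 if effect_type in THIRD_ORDER_TYPES else 2
    A = add.W
    D = dom.W if dom is not None else None
    if "D" in effect_type and D is None:
        raise ValueError(f"type {effect_type} needs a dominance matrix")
    m = A.shape[1]
    if m < order:
        raise ValueError(f"need at least {order} SNPs for {effect_type}")
    if order == 3 and chrom_filter != "none":
        raise ValueError("intra/inter restriction is defined for pairwise types only")
    labels_a = add.column_labels
    cols: list[np.ndarray] = []
    labels: list[str] = []

    if effect_type in ("AA", "DD"):
        M = A if effect_type == "AA" else D
        for i, j in _pair_indices(m, chromosomes, chrom_filter):
            cols.append(M[:, i] * M[:, j])
            labels.append(f"{labels_a[i]}x{labels_a[j]}:{effect_type}")
    elif effect_type == "AD":
        pairs = list(_pair_indices(m, chromosomes, chrom_filter))
        for i, j in pairs:  # alpha-delta block
            cols.append(A[:, i] * D[:, j])
            labels.append(f"{labels_a[i]}x{labels_a[j]}:ad")
        for i, j in pairs:  # delta-alpha block
            cols.append(D[:, i] * A[:, j])
            labels.append(f"{labels_a[i]}x{labels_a[j]}:da")
    elif effect_type in ("AAA", "DDD"):
        M = A if effect_type == "AAA" else D
        for i, j, l in _triple_indices(m):
            cols.append(M[:, i] * M[:, j] * M[:, l])
            labels.append(f"{labels_a[i]}x{labels_a[j]}x{labels_a[l]}:{effect_type}")
    elif effect_type == "AAD":
        # distinct triple {i, j, l}: two additive roles, one dominance role,
        # the dominance role rotating over the three members
        for i, j, l in _triple_indices(m):
            for d_at, (a1, a2) in ((l, (i, j)), (j, (i, l)), (i, (j, l))):
                cols.append(A[:, a1] * A[:, a2] * D[:, d_at])
                labels.append(f"{labels_a[a1]}x{labels_a[a2]}xd{labels_a[d_at]}:AAD")
    elif effect_type == "ADD":
        for i, j, l in _triple_indices(m):
            for a_at, (d1, d2) in ((l, (i, j)), (j, (i, l)), (i, (j, l))):
                cols.append(A[:, a_at] * D[:, d1] * D[:, d2])
                labels.append(f"a{labels_a[a_at]}x{labels_a[d1]}x{labels_a[d2]}:ADD")
    if not cols:
        raise ValueError(f"no SNP {'pair' if order == 2 else 'triple'} satisfies the "
                         f"'{chrom_filter}' restriction for {effect_type}")
    W = np.column_stack(cols)
    label = effect_type if chrom_filter == "none" else f"{effect_type}_{chrom_filter}"
    return ModelMatrix(label, W, k_of(W), labels)
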