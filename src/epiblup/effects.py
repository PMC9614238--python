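"""Back-solving individual SNP, haplotype, and pairwise epistasis effects.

From the conditional-expectation GBLUP machinery, the estimate of the effect
vector of type i is

    tau_hat_i = sigma_i^2 T_i' Z' P y,     T_i = W_i / sqrt(k_i)

which satisfies T_i tau_hat_i = u_hat_i.  The heritability attributed to the
j-th effect of type i is the share of the effect-type heritability carried by
that effect,

    h_hat_ij^2 = (tau_hat_ij^2 / tau_hat_i' tau_hat_i) * h_hat_i^2,

so the per-effect heritabilities of a type sum exactly to the type
heritability.  Third-order types are refused: their effect counts make the
explicit model matrices computationally unfeasible.  Pairwise epistasis
back-solving streams the product columns in blocks and never materializes
the full C(m,2)-column matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.linalg as la

from .coding import THIRD_ORDER_TYPES, ModelMatrix, k_of
from .grm import egerm_numerator
from .greml import MixedModelContext, VarianceFit, build_VP

__all__ = [
    "EffectReport",
    "backsolve",
    "backsolve_pairwise",
    "effect_h2",
    "mme_effect_variance_oracle",
]


class EffectReport:
    """Per-effect estimates and heritabilities for one effect type."""

    def __init__(self, effect_type: str, labels: list[str], tau_hat: np.ndarray,
                 h2_per_effect: np.ndarray, h2_type: float):
        self.effect_type = effect_type
        self.labels = labels
        self.tau_hat = tau_hat
        self.h2_per_effect = h2_per_effect
        self.h2_type = h2_type

    def to_frame(self, top: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"effect_type": self.effect_type, "label": self.labels,
             "tau_hat": self.tau_hat, "h2": self.h2_per_effect}
        ).sort_values("h2", ascending=False, kind="stable").reset_index(drop=True)
        return df.head(top) if top is not None else df


def _is_third_order(effect_type: str) -> bool:
    return effect_type.split("_")[0] in THIRD_ORDER_TYPES


def _ZtPy(ctx: MixedModelContext, fit: VarianceFit | np.ndarray) -> np.ndarray:
    if isinstance(fit, VarianceFit):
        theta = fit.theta
    else:
        theta = np.asarray(fit, dtype=np.float64)
    _, P = build_VP(ctx, theta)
    return ctx.Z.T @ (P @ ctx.y)


def backsolve(
    ctx: MixedModelContext,
    fit: VarianceFit | np.ndarray,
    mm: ModelMatrix,
    effect_index: int,
) -> np.ndarray:
    """tau_hat_i = sigma_i^2 T_i' Z' P y for an explicit model matrix.

    ``effect_index`` selects the variance component in the fit corresponding
    to ``mm``; the model matrix rows must follow the training-individual
    order of the context.
    """
    if _is_third_order(mm.effect_type):
        raise ValueError(
            f"effect-level estimation for third-order type '{mm.effect_type}' is unsupported"
        )
    sigma2 = fit.sigma2 if isinstance(fit, VarianceFit) else np.asarray(fit)[:-1]
    s2 = float(sigma2[effect_index])
    if s2 == 0.0:
        return np.zeros(mm.m)
    v = _ZtPy(ctx, fit)
    return s2 * (mm.T.T @ v)


def backsolve_pairwise(
    ctx: MixedModelContext,
    fit: VarianceFit | np.ndarray,
    W_a: np.ndarray,
    W_d: np.ndarray | None,
    effect_type: str,
    effect_index: int,
    snp_ids: list[str] | None = None,
    max_pairs: int = 50_000_000,
    k: float | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Streamed pairwise-epistasis back-solving without forming the pair matrix.

    Enumerates SNP pairs i < i' in lexicographic order (A x D effects as the
    alpha-delta block followed by the delta-alpha block) and accumulates
    tau_hat = sigma^2 W_pair' (Z'Py) / sqrt(k) one anchor column at a time.
    Unless supplied, ``k`` defaults to the exact (distinct-locus) numerator
    mean diagonal, computed in closed form; pass the normalizer of the
    relationship matrix actually fitted when it differs (Hadamard-built
    matrices).  Refuses requests beyond ``max_pairs`` columns.
    """
    if effect_type not in ("AA", "AD", "DD"):
        raise ValueError("streamed back-solving supports pairwise types AA, AD, DD")
    m = W_a.shape[1]
    n_pairs = m * (m - 1) // 2 * (2 if effect_type == "AD" else 1)
    if n_pairs > max_pairs:
        raise ValueError(
            f"{n_pairs} pair columns exceed max_pairs={max_pairs}; "
            "raise the guard explicitly if this is intended"
        )
    sigma2 = fit.sigma2 if isinstance(fit, VarianceFit) else np.asarray(fit)[:-1]
    s2 = float(sigma2[effect_index])
    if k is None:
        k = float(np.trace(egerm_numerator(W_a, W_d, effect_type))) / W_a.shape[0]
    labels_base = snp_ids or [f"snp{j}" for j in range(m)]
    v = _ZtPy(ctx, fit)

    def half(Wl, Wr, tag):
        taus, labs = [], []
        for i in range(m - 1):
            anchored = Wl[:, i] * v  # n-vector
            taus.append(Wr[:, i + 1:].T @ anchored)
            labs.extend(f"{labels_base[i]}x{labels_base[j]}:{tag}" for j in range(i + 1, m))
        return np.concatenate(taus), labs

    if effect_type == "AA":
        tau, labels = half(W_a, W_a, "AA")
    elif effect_type == "DD":
        tau, labels = half(W_d, W_d, "DD")
    else:
        t1, l1 = half(W_a, W_d, "ad")
        t2, l2 = half(W_d, W_a, "da")
        tau, labels = np.concatenate([t1, t2]), l1 + l2
    return s2 * tau / np.sqrt(k), labels


def effect_h2(tau_hat: np.ndarray, h2_type: float) -> np.ndarray:
    """Per-effect heritabilities: squared-effect shares of the type heritability."""
    tau_hat = np.asarray(tau_hat, dtype=np.float64)
    ss = float(tau_hat @ tau_hat)
    if ss == 0.0:
        if h2_type > 0.0:
            raise ValueError("all-zero effect estimates with positive type heritability")
        return np.zeros_like(tau_hat)
    return (tau_hat ** 2 / ss) * h2_type


def mme_effect_variance_oracle(
    ctx: MixedModelContext,
    fit: VarianceFit | np.ndarray,
    model_matrices: list[ModelMatrix],
) -> list[np.ndarray]:
    """Per-effect variances from the MME coefficient-matrix inverse (tiny fixtures).

    Builds the full mixed-model equations on the normalized scale with
    variance ratios lambda_i = sigma_e^2 / sigma_i^2, inverts the coefficient
    matrix, and returns sigma_hat_ij^2 = tau_hat_ij^2 / [m_i - tr(C^ii)
    lambda_i] for each effect type.  Exists to validate the proportionality
    underlying :func:`effect_h2`.
    """
    sigma2 = fit.sigma2 if isinstance(fit, VarianceFit) else np.asarray(fit)[:-1]
    sigma_e2 = fit.sigma_e2 if isinstance(fit, VarianceFit) else float(np.asarray(fit)[-1])
    active = [i for i, s2 in enumerate(sigma2) if s2 > 0.0]
    Ts = [model_matrices[i].T for i in active]
    lambdas = [sigma_e2 / sigma2[i] for i in active]
    ZT = [ctx.Z @ T for T in Ts]
    blocks_top = [ctx.X.T @ ctx.X] + [ctx.X.T @ zt for zt in ZT]
    rows = [blocks_top]
    for a, zta in enumerate(ZT):
        row = [zta.T @ ctx.X]
        for b, ztb in enumerate(ZT):
            blk = zta.T @ ztb
            if a == b:
                blk = blk + lambdas[a] * np.eye(blk.shape[1])
            row.append(blk)
        rows.append(row)
    M = np.block(rows)
    rhs = np.concatenate([ctx.X.T @ ctx.y] + [zt.T @ ctx.y for zt in ZT])
    try:
        C = la.inv(M)
    except la.LinAlgError:
        warnings.warn("singular MME coefficient matrix; generalized inverse used")
        C = la.pinvh(M)
    sol = C @ rhs
    out: list[np.ndarray] = [np.zeros(mm.m) for mm in model_matrices]
    offset = ctx.X.shape[1]
    for a, i in enumerate(active):
        m_i = Ts[a].shape[1]
        tau = sol[offset: offset + m_i]
        Cii = C[offset: offset + m_i, offset: offset + m_i]
        denom = m_i - np.trace(Cii) * lambdas[a]
        out[i] = tau ** 2 / denom
        offset += m_i
    return out
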