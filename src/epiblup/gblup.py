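"""GBLUP, BLUE, and reliability — conditional-expectation path plus MME oracle.

All production computations run in the n x n conditional-expectation (CE)
form: with P = V^{-1} - V^{-1}X(X'V^{-1}X)^- X'V^{-1},

    u_hat_i1 = sigma_i^2 S_i11 Z1' P y1          (phenotyped individuals)
    u_hat_i0 = sigma_i^2 S_i01 Z1' P y1          (unphenotyped individuals)
    g_hat    = sum_i u_hat_i
    R^2_1j   = [G11 (Z1'PZ1) G11]_jj / G11_jj,   G11 = sum_i sigma_i^2 S_i11
    R^2_0j   = [G01 (Z1'PZ1) G10]_jj / G00_jj    (diagonal of S_i00 only)

The unphenotyped-side formula never inverts S_i11 and never materializes
S_i00 beyond its diagonal, so it scales to large validation sets.  A
block-Gauss-Seidel mixed-model-equations (MME) solver over the effect types
is provided as a small-scale oracle: it solves each effect type against the
phenotypes adjusted for all other effect types and must agree with the CE
path to numerical precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la

from .greml import MixedModelContext, VarianceFit, build_VP

__all__ = [
    "PredictionResult",
    "blue",
    "predict_training",
    "predict_validation",
    "predict_validation_regression",
    "mme_oracle",
]


@dataclass
class PredictionResult:
    """Per-individual GBLUP by effect type, totals, reliabilities, and BLUE."""

    effect_types: list[str]
    b_hat: np.ndarray
    u_train: np.ndarray  # f x n1
    g_train: np.ndarray  # n1
    rel_train: np.ndarray  # n1
    train_ids: list[str] = field(default_factory=list)
    u_val: np.ndarray | None = None  # f x n0
    g_val: np.ndarray | None = None
    rel_val: np.ndarray | None = None
    val_ids: list[str] = field(default_factory=list)
    rel_train_by_type: np.ndarray | None = None  # f x n1

    def to_frame(self) -> pd.DataFrame:
        def block(ids, u, g, rel, tag):
            cols = {"iid": ids, "set": tag}
            for t, row in zip(self.effect_types, u):
                cols[f"u_{t}"] = row
            cols["g_hat"] = g
            cols["reliability"] = rel
            return pd.DataFrame(cols)

        frames = [block(self.train_ids or list(range(self.g_train.size)),
                        self.u_train, self.g_train, self.rel_train, "train")]
        if self.g_val is not None:
            frames.append(block(self.val_ids or list(range(self.g_val.size)),
                                self.u_val, self.g_val, self.rel_val, "validate"))
        return pd.concat(frames, ignore_index=True)


def _theta_of(fit: VarianceFit | np.ndarray) -> tuple[np.ndarray, float]:
    if isinstance(fit, VarianceFit):
        return fit.sigma2, fit.sigma_e2
    arr = np.asarray(fit, dtype=np.float64)
    return arr[:-1], float(arr[-1])


def blue(ctx: MixedModelContext, fit: VarianceFit | np.ndarray) -> np.ndarray:
    """GLS estimate of the fixed effects, b_hat = (X'V^-1 X)^- X'V^-1 y."""
    sigma2, sigma_e2 = _theta_of(fit)
    V, _ = build_VP(ctx, np.append(sigma2, sigma_e2))
    c, low = la.cho_factor(V, lower=True)
    VinvX = la.cho_solve((c, low), ctx.X)
    Vinvy = la.cho_solve((c, low), ctx.y)
    return la.pinvh(ctx.X.T @ VinvX) @ (ctx.X.T @ Vinvy)


def _diag_quad(G_left: np.ndarray, M: np.ndarray, G_right: np.ndarray) -> np.ndarray:
    """diag(G_left M G_right') without the full product."""
    return np.einsum("ij,jk,ik->i", G_left, M, G_right)


def predict_training(
    ctx: MixedModelContext,
    fit: VarianceFit | np.ndarray,
    per_effect_reliability: bool = False,
) -> PredictionResult:
    """GBLUP, total genetic values, and reliabilities for phenotyped individuals."""
    sigma2, sigma_e2 = _theta_of(fit)
    _, P = build_VP(ctx, np.append(sigma2, sigma_e2))
    Py = P @ ctx.y
    ZtPy = ctx.Z.T @ Py
    n1 = ctx.Z.shape[1]
    f = ctx.f
    u = np.zeros((f, n1))
    G11 = np.zeros((n1, n1))
    for i, (s2, S) in enumerate(zip(sigma2, ctx.S_list)):
        if s2 != 0.0:
            u[i] = s2 * (S @ ZtPy)
            G11 += s2 * S
    g_hat = u.sum(axis=0)
    ZPZ = ctx.Z.T @ P @ ctx.Z
    Gjj = np.diag(G11).copy()
    num = _diag_quad(G11, ZPZ, G11)
    rel = np.zeros(n1)
    ok = Gjj > 0
    if not ok.all():
        warnings.warn("individuals with zero genomic variance: reliability reported as 0")
    rel[ok] = num[ok] / Gjj[ok]

    rel_by_type = None
    if per_effect_reliability:
        rel_by_type = np.zeros((f, n1))
        for i, (s2, S) in enumerate(zip(sigma2, ctx.S_list)):
            if s2 == 0.0:
                continue
            Gi = s2 * S
            di = np.diag(Gi)
            good = di > 0
            rel_by_type[i, good] = _diag_quad(Gi, ZPZ, Gi)[good] / di[good]

    return PredictionResult(
        effect_types=list(ctx.effect_types),
        b_hat=blue(ctx, fit),
        u_train=u,
        g_train=g_hat,
        rel_train=rel,
        train_ids=list(ctx.ids),
        rel_train_by_type=rel_by_type,
    )


def predict_validation(
    ctx: MixedModelContext,
    fit: VarianceFit | np.ndarray,
    S01_list: list[np.ndarray],
    S00_diag_list: list[np.ndarray],
    val_ids: list[str] | None = None,
) -> PredictionResult:
    """Two-set GBLUP and reliability for unphenotyped individuals.

    ``S01_list`` holds the n0 x n1 validation-training blocks and
    ``S00_diag_list`` the diagonals of the validation-validation blocks,
    one entry per effect type.  V and P come from the training block alone.
    """
    if len(S01_list) != ctx.f or len(S00_diag_list) != ctx.f:
        raise ValueError("one S01 block and one S00 diagonal required per effect type")
    n0 = S01_list[0].shape[0]
    for S01 in S01_list:
        if S01.shape != (n0, ctx.Z.shape[1]):
            raise ValueError("inconsistent S01 block shape")
    sigma2, sigma_e2 = _theta_of(fit)
    _, P = build_VP(ctx, np.append(sigma2, sigma_e2))
    Py = P @ ctx.y
    ZtPy = ctx.Z.T @ Py
    u0 = np.zeros((ctx.f, n0))
    G01 = np.zeros((n0, ctx.Z.shape[1]))
    G00jj = np.zeros(n0)
    for i, (s2, S01, d00) in enumerate(zip(sigma2, S01_list, S00_diag_list)):
        if s2 != 0.0:
            u0[i] = s2 * (S01 @ ZtPy)
            G01 += s2 * S01
            G00jj += s2 * np.asarray(d00)
    g0 = u0.sum(axis=0)
    ZPZ = ctx.Z.T @ P @ ctx.Z
    rel0 = np.zeros(n0)
    ok = G00jj > 0
    rel0[ok] = _diag_quad(G01, ZPZ, G01)[ok] / G00jj[ok]

    base = predict_training(ctx, fit)
    base.u_val = u0
    base.g_val = g0
    base.rel_val = rel0
    base.val_ids = list(val_ids) if val_ids is not None else [str(j) for j in range(n0)]
    return base


def predict_validation_regression(
    ctx: MixedModelContext,
    fit: VarianceFit | np.ndarray,
    S01_list: list[np.ndarray],
) -> np.ndarray:
    """Regression form u_hat_i0 = S_i01 S_i11^{-1} u_hat_i1 (requires invertible S_i11).

    Returns the f x n0 array of per-type validation GBLUPs; used to verify
    the direct two-set formula on fixtures where S_i11 is invertible.
    """
    res = predict_training(ctx, fit)
    sigma2, _ = _theta_of(fit)
    out = np.zeros((ctx.f, S01_list[0].shape[0]))
    for i, (s2, S01, S11) in enumerate(zip(sigma2, S01_list, ctx.S_list)):
        if s2 == 0.0:
            continue
        out[i] = S01 @ la.solve(S11, res.u_train[i], assume_a="sym")
    return out


def mme_oracle(
    ctx: MixedModelContext,
    fit: VarianceFit | np.ndarray,
    tol: float = 1e-13,
    max_iter: int = 100000,
) -> tuple[np.ndarray, np.ndarray]:
    """Block Gauss-Seidel MME solution over effect types (test oracle).

    Iterates u_hat_i = (Z'Z + sigma_e^2 G_i^{-1})^{-1} Z'(y - X b_hat -
    sum_{j != i} Z u_hat_j) and b_hat = (X'X)^- X'(y - sum_i Z u_hat_i),
    each effect type solved against phenotypes adjusted for all others.
    Returns (u, b_hat) with u of shape f x n.  Small problems only.
    """
    sigma2, sigma_e2 = _theta_of(fit)
    n = ctx.Z.shape[1]
    f = ctx.f
    ZtZ = ctx.Z.T @ ctx.Z
    XtX_pinv = la.pinvh(ctx.X.T @ ctx.X)
    solvers = []
    for s2, S in zip(sigma2, ctx.S_list):
        if s2 == 0.0:
            solvers.append(None)
            continue
        G = s2 * S
        try:
            Ginv = la.inv(G)
        except la.LinAlgError:
            warnings.warn("singular G_i in MME oracle; ridge 1e-10 added")
            Ginv = la.inv(G + 1e-10 * np.eye(n))
        solvers.append(la.lu_factor(ZtZ + sigma_e2 * Ginv))
    u = np.zeros((f, n))
    b = XtX_pinv @ (ctx.X.T @ ctx.y)
    for _ in range(max_iter):
        u_old = u.copy()
        b_old = b.copy()
        for i in range(f):
            if solvers[i] is None:
                continue
            resid = ctx.y - ctx.X @ b - ctx.Z @ (u.sum(axis=0) - u[i])
            u[i] = la.lu_solve(solvers[i], ctx.Z.T @ resid)
        b = XtX_pinv @ (ctx.X.T @ (ctx.y - ctx.Z @ u.sum(axis=0)))
        change = max(np.abs(u - u_old).max(), np.abs(b - b_old).max() if b.size else 0.0)
        if change < tol:
            break
    return u, b
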