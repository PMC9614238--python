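"""Variance-component estimation for the multifactorial mixed model.

The phenotype model is y = Xb + Z sum_i u_i + e with u_i ~ N(0, sigma_i^2 S_i)
and e ~ N(0, sigma_e^2 I), so V = Z (sum_i sigma_i^2 S_i) Z' + sigma_e^2 I.
REML estimation runs on the conditional-expectation (n x n) side, never
through mixed-model equations, using a hybrid of two iterations:

* EM-REML (multiplicative, always moves toward the optimum but slow):
      sigma_i^2 <- sigma_i^2 * [y'P A_i P y / tr(P A_i)],   A_i = Z S_i Z'
      sigma_e^2 <- sigma_e^2 * [y'P P y / tr(P)]
* AI-REML (Newton-like on the average-information matrix, fast but can step
  outside the parameter space):
      theta <- theta + AI^{-1} Delta
      Delta_i = -1/2 tr(P A_i) + 1/2 y'P A_i P y
      AI_ik   =  1/2 y'P A_i P A_k P y            (A_{f+1} = I)

Each iteration attempts AI-REML and falls back to EM-REML when the AI system
is singular or the update leaves the parameter space; components that shrink
below a floor are clamped to zero (and optionally dropped).  The shared fixed
point of both iterations is the REML score equation Delta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la

from .genio import PhenotypeData
from .grm import GRMSet

__all__ = [
    "MixedModelContext",
    "VarianceFit",
    "build_context",
    "design_matrix",
    "build_VP",
    "em_step",
    "ai_step",
    "fit",
]


@dataclass
class MixedModelContext:
    """Observations, designs, and training-block relationship matrices."""

    y: np.ndarray  # N observations
    X: np.ndarray  # N x c fixed-effect design (intercept included)
    Z: np.ndarray  # N x n1 incidence
    S_list: list[np.ndarray]  # training-block S_i11, one per genetic effect type
    effect_types: list[str]
    ids: list[str] = field(default_factory=list)
    # cache of Z S_i Z' terms
    _ZSZ: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        N = self.y.shape[0]
        if self.X.shape[0] != N or self.Z.shape[0] != N:
            raise ValueError("X/Z row count does not match y")
        if len(self.S_list) != len(self.effect_types):
            raise ValueError("one relationship matrix per effect type required")
        if N < self.X.shape[1] + 1:
            raise ValueError("more fixed-effect columns than observations")

    @property
    def N(self) -> int:
        return self.y.shape[0]

    @property
    def f(self) -> int:
        return len(self.S_list)

    def ZSZ(self) -> list[np.ndarray]:
        if self._ZSZ is None:
            self._ZSZ = [self.Z @ S @ self.Z.T for S in self.S_list]
        return self._ZSZ


@dataclass
class VarianceFit:
    """Estimated variance components with heritability bookkeeping."""

    effect_types: list[str]
    sigma2: np.ndarray  # genetic components, one per effect type
    sigma_e2: float
    converged: bool
    iterations: int
    trace: list[dict] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    @property
    def sigma_y2(self) -> float:
        return float(self.sigma2.sum() + self.sigma_e2)

    @property
    def h2(self) -> np.ndarray:
        return self.sigma2 / self.sigma_y2

    @property
    def H2(self) -> float:
        return float(self.h2.sum())

    @property
    def theta(self) -> np.ndarray:
        return np.append(self.sigma2, self.sigma_e2)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"effect_type": t, "sigma2": s, "h2": h}
            for t, s, h in zip(self.effect_types, self.sigma2, self.h2)
        ]
        rows.append({"effect_type": "residual", "sigma2": self.sigma_e2, "h2": np.nan})
        df = pd.DataFrame(rows)
        df["converged"] = self.converged
        return df


def design_matrix(fixed: pd.DataFrame, n_rows: int) -> np.ndarray:
    """Intercept plus dummy-coded factors (drop-first) and numeric covariates."""
    cols = [np.ones(n_rows)]
    for name in fixed.columns:
        col = fixed[name]
        if col.dtype.kind in "biufc":
            cols.append(col.to_numpy(dtype=np.float64))
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=np.float64))
    return np.column_stack(cols)


def build_context(pheno: PhenotypeData, grms: GRMSet) -> MixedModelContext:
    """Training-view context: observed individuals only, Z = I_n1.

    Relationship matrices are subset to the training block S_i11 in the
    phenotype-file order of the observed individuals.
    """
    obs = ~pheno.missing_mask
    ids = [iid for iid, o in zip(pheno.individual_ids, obs) if o]
    S_list = []
    for g in grms:
        if g.ids is None:
            raise ValueError("GRM lacks individual ids; cannot align to phenotypes")
        pos = {iid: j for j, iid in enumerate(g.ids)}
        idx = np.array([pos[iid] for iid in ids])
        S_list.append(g.S[np.ix_(idx, idx)])
    n1 = len(ids)
    X = design_matrix(pheno.fixed.loc[obs].reset_index(drop=True), n1)
    return MixedModelContext(
        y=pheno.y[obs], X=X, Z=np.eye(n1), S_list=S_list,
        effect_types=list(grms.effect_types), ids=ids,
    )


def build_VP(ctx: MixedModelContext, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """V = Z(sum_i sigma_i^2 S_i)Z' + sigma_e^2 I and the REML projector P."""
    theta = np.asarray(theta, dtype=np.float64)
    sigma2, sigma_e2 = theta[:-1], theta[-1]
    V = sigma_e2 * np.eye(ctx.N)
    for s2, ZSZ in zip(sigma2, ctx.ZSZ()):
        if s2 != 0.0:
            V = V + s2 * ZSZ
    try:
        c, low = la.cho_factor(V, lower=True)
    except la.LinAlgError as exc:
        raise ValueError(
            "V is numerically singular; consider a residual-variance floor"
        ) from exc
    Vinv = la.cho_solve((c, low), np.eye(ctx.N))
    VinvX = Vinv @ ctx.X
    XtVinvX = ctx.X.T @ VinvX
    P = Vinv - VinvX @ la.pinvh(XtVinvX) @ VinvX.T
    P = 0.5 * (P + P.T)
    return V, P


def em_step(ctx: MixedModelContext, P: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """One EM-REML multiplicative update; exact zeros stay zero."""
    theta = np.asarray(theta, dtype=np.float64)
    Py = P @ ctx.y
    out = theta.copy()
    for i, ZSZ in enumerate(ctx.ZSZ()):
        if theta[i] == 0.0:
            continue
        denom = float(np.einsum("ij,ji->", P, ZSZ))
        if denom <= 0.0:
            raise ValueError(f"degenerate relationship matrix: tr(P Z S Z') <= 0 "
                             f"for effect type {ctx.effect_types[i]}")
        out[i] = theta[i] * float(Py @ ZSZ @ Py) / denom
    out[-1] = theta[-1] * float(Py @ Py) / float(np.trace(P))
    return out


def ai_step(
    ctx: MixedModelContext,
    P: np.ndarray,
    theta: np.ndarray,
    floor_frac: float = 1e-6,
) -> tuple[np.ndarray, bool]:
    """One AI-REML update; returns (theta_next, ok).

    ``ok`` is False (hybrid fallback signal) when the AI matrix is singular
    or the update drives a component negative beyond the floor.
    """
    theta = np.asarray(theta, dtype=np.float64)
    Py = P @ ctx.y
    terms = [ZSZ @ Py for ZSZ in ctx.ZSZ()] + [Py.copy()]  # A_{f+1} = I
    traces = [float(np.einsum("ij,ji->", P, ZSZ)) for ZSZ in ctx.ZSZ()] + [float(np.trace(P))]
    npar = len(terms)
    delta = np.array(
        [-0.5 * traces[i] + 0.5 * float(Py @ terms[i]) for i in range(npar)]
    )
    Pterms = [P @ t for t in terms]
    AI = 0.5 * np.array([[float(terms[i] @ Pterms[k]) for k in range(npar)] for i in range(npar)])
    AI = 0.5 * (AI + AI.T)
    try:
        step = la.solve(AI, delta, assume_a="sym")
    except la.LinAlgError:
        return theta, False
    if not np.all(np.isfinite(step)) or np.linalg.cond(AI) > 1e12:
        return theta, False
    new = theta + step
    sigma_y2 = float(theta.sum())
    if np.any(new < -floor_frac * sigma_y2):
        return theta, False
    return np.maximum(new, 0.0), True


def fit(
    ctx: MixedModelContext,
    tol: float = 1e-8,
    max_iter: int = 1000,
    floor: float = 1e-6,
    drop_zeroed: bool = False,
    em_only: bool = False,
    theta0: np.ndarray | None = None,
) -> VarianceFit:
    """Hybrid EM/AI-REML fit of all variance components.

    Starting values split half the phenotypic variance into the residual and
    the other half equally across genetic effect types.  Components below
    ``floor * sigma_y^2`` are clamped to zero; with ``drop_zeroed`` they are
    removed from the iteration entirely (reported as zero).
    """
    f = ctx.f
    vary = float(np.var(ctx.y, ddof=1))
    if theta0 is None:
        theta = np.full(f + 1, 0.5 * vary / f)
        theta[-1] = 0.5 * vary
    else:
        theta = np.asarray(theta0, dtype=np.float64).copy()
    trace: list[dict] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, P = build_VP(ctx, theta)
        algo = "em"
        if not em_only:
            new, ok = ai_step(ctx, P, theta, floor_frac=floor)
            if ok:
                algo = "ai"
            else:
                new = em_step(ctx, P, theta)
        else:
            new = em_step(ctx, P, theta)
        sigma_y2 = float(new.sum())
        # clamp vanishing genetic components (residual is never clamped)
        small = new[:-1] < floor * sigma_y2
        new[:-1][small] = 0.0
        rel = np.abs(new - theta) / max(sigma_y2, 1e-300)
        trace.append({"iter": it, "algorithm": algo, "max_rel_change": float(rel.max())})
        theta = new
        if rel.max() < tol:
            converged = True
            break
    dropped = [t for t, s in zip(ctx.effect_types, theta[:-1]) if s == 0.0] if drop_zeroed else []
    return VarianceFit(
        effect_types=list(ctx.effect_types),
        sigma2=theta[:-1],
        sigma_e2=float(theta[-1]),
        converged=converged,
        iterations=it,
        trace=trace,
        dropped=dropped,
    )
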