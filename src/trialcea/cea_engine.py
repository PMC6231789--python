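"""Incremental cost-effectiveness estimation.

The incremental cost (dC) and incremental effect (dE) of the intervention are
the arm coefficients of a two-equation seemingly-unrelated-regression (SUR)
system

    cost_i   = a0 + dC * arm_i + g' z_i   + e1_i
    effect_i = b0 + dE * arm_i + h' w_i   + e2_i,

estimated by two-step feasible GLS so the residuals of the cost and effect
equations may be correlated, with baseline productivity costs (cost equation)
and the baseline score (effect equation) as default adjustment covariates.
The effect is either the responder indicator (a linear probability model, so
dE is a difference in responder rates) or the individual QALY gain.

Uncertainty is propagated by nonparametric bootstrap: participants are
resampled with replacement within each arm, the SUR is refit per resample,
and the (dC, dE) replicates — pooled over multiply-imputed datasets — form
the cost-effectiveness plane cloud from which quadrant shares and
cost-effectiveness acceptability curves (CEACs) are computed.  A point at
willingness-to-pay ceiling lambda counts as cost-effective when its net
monetary benefit lambda * dE - dC is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .missing_data import ImputedDatasets

#: default willingness-to-pay grid, EUR per QALY; spans the guidance range
#: 20,000-80,000 for conditions graded by disability weight
DEFAULT_WTP_GRID = np.arange(0, 80_001, 1_000, dtype=float)


@dataclass
class SureFit:
    """Two-step feasible-GLS fit of the cost/effect SUR system."""

    params_cost: np.ndarray
    params_effect: np.ndarray
    names_cost: tuple[str, ...]
    names_effect: tuple[str, ...]
    resid_cov: np.ndarray  # 2x2, symmetric PSD
    cov_params: np.ndarray  # joint (k1+k2) GLS coefficient covariance
    n: int
    condition_number: float

    @property
    def delta_cost(self) -> float:
        return float(self.params_cost[self.names_cost.index("arm")])

    @property
    def delta_effect(self) -> float:
        return float(self.params_effect[self.names_effect.index("arm")])

    @property
    def var_delta(self) -> tuple[float, float]:
        """(var dC, var dE) from the GLS coefficient covariance."""
        i = self.names_cost.index("arm")
        j = len(self.names_cost) + self.names_effect.index("arm")
        return float(self.cov_params[i, i]), float(self.cov_params[j, j])


def _stack_design(
    arm: np.ndarray, covariates: np.ndarray | None, cov_names: Sequence[str]
) -> tuple[np.ndarray, tuple[str, ...]]:
    cols = [np.ones_like(arm), arm]
    names = ["const", "arm"]
    if covariates is not None and covariates.size:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != len(arm):
            Z = Z.T
        cols.extend(Z[:, j] for j in range(Z.shape[1]))
        names.extend(cov_names)
    return np.column_stack(cols), tuple(names)


def _sure_gls(
    y1: np.ndarray, y2: np.ndarray, X1: np.ndarray, X2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two-step feasible GLS; returns (beta1, beta2, Sigma, cov_params)."""
    n = len(y1)
    b1 = np.linalg.lstsq(X1, y1, rcond=None)[0]
    b2 = np.linalg.lstsq(X2, y2, rcond=None)[0]
    e1 = y1 - X1 @ b1
    e2 = y2 - X2 @ b2
    sigma = np.array(
        [[e1 @ e1, e1 @ e2], [e1 @ e2, e2 @ e2]], dtype=float
    ) / n
    # ridge floor keeps Sigma invertible when a resampled equation is degenerate
    eps = 1e-10 * (np.trace(sigma) / 2.0 + 1.0)
    sigma_r = sigma + eps * np.eye(2)
    S = np.linalg.inv(sigma_r)
    k1, k2 = X1.shape[1], X2.shape[1]
    A = np.empty((k1 + k2, k1 + k2))
    A[:k1, :k1] = S[0, 0] * (X1.T @ X1)
    A[:k1, k1:] = S[0, 1] * (X1.T @ X2)
    A[k1:, :k1] = S[1, 0] * (X2.T @ X1)
    A[k1:, k1:] = S[1, 1] * (X2.T @ X2)
    b = np.concatenate(
        [
            S[0, 0] * (X1.T @ y1) + S[0, 1] * (X1.T @ y2),
            S[1, 0] * (X2.T @ y1) + S[1, 1] * (X2.T @ y2),
        ]
    )
    cov = np.linalg.inv(A)
    beta = cov @ b
    return beta[:k1], beta[k1:], sigma, cov


def fit_sure(
    costs: np.ndarray,
    effects: np.ndarray,
    arm: np.ndarray,
    cost_covariates: np.ndarray | None = None,
    effect_covariates: np.ndarray | None = None,
    cost_covariate_names: Sequence[str] = (),
    effect_covariate_names: Sequence[str] = (),
) -> SureFit:
    """Fit the SUR system; the arm coefficients are (dC, dE).

    With identical regressor sets in both equations the GLS step reproduces
    per-equation least squares exactly (the classical SUR identity), which
    serves as the estimator's oracle in the test suite.
    """
    y1 = np.asarray(costs, dtype=float)
    y2 = np.asarray(effects, dtype=float)
    a = np.asarray(arm, dtype=float)
    X1, names1 = _stack_design(a, cost_covariates, cost_covariate_names)
    X2, names2 = _stack_design(a, effect_covariates, effect_covariate_names)
    if len(y1) <= X1.shape[1] + X2.shape[1]:
        raise ValueError("need more observations than coefficients")
    b1, b2, sigma, cov = _sure_gls(y1, y2, X1, X2)
    cond = float(max(np.linalg.cond(X1), np.linalg.cond(X2)))
    return SureFit(
        params_cost=b1,
        params_effect=b2,
        names_cost=names1,
        names_effect=names2,
        resid_cov=sigma,
        cov_params=cov,
        n=len(y1),
        condition_number=cond,
    )


@dataclass(frozen=True)
class CeaDesign:
    """Column roles for fitting the SUR system on an analysis table."""

    cost_col: str
    effect_col: str
    cost_covariates: tuple[str, ...] = ()
    effect_covariates: tuple[str, ...] = ()
    arm_col: str = "arm"
    effect_kind: str = "responder_rate"  # or "qaly"


def fit_sure_table(df: pd.DataFrame, design: CeaDesign) -> SureFit:
    return fit_sure(
        df[design.cost_col].to_numpy(float),
        df[design.effect_col].to_numpy(float),
        df[design.arm_col].to_numpy(float),
        df[list(design.cost_covariates)].to_numpy(float)
        if design.cost_covariates
        else None,
        df[list(design.effect_covariates)].to_numpy(float)
        if design.effect_covariates
        else None,
        design.cost_covariates,
        design.effect_covariates,
    )


@dataclass
class BootstrapCloud:
    """Joint (dC, dE) bootstrap replicate distribution, pooled over imputations."""

    replicates: np.ndarray  # (B*m, 2) columns (delta_cost, delta_effect)
    B: int
    m: int
    effect_kind: str
    pooled_over_m: bool = True
    n_redraws: int = 0

    @property
    def delta_cost(self) -> np.ndarray:
        return self.replicates[:, 0]

    @property
    def delta_effect(self) -> np.ndarray:
        return self.replicates[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(len(self.replicates)),
                "delta_cost": self.delta_cost,
                "delta_effect": self.delta_effect,
            }
        )


def _batch_sure_arm_coefs(
    y1: np.ndarray,
    y2: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Arm coefficients of the SUR fit for each resample row of ``idx``.

    Vectorized over replicates; mirrors :func:`_sure_gls` exactly (same
    two-step algebra, same ridge floor).
    """
    B, n = idx.shape
    k1, k2 = X1.shape[1], X2.shape[1]
    X1b, X2b = X1[idx], X2[idx]  # (B, n, k)
    y1b, y2b = y1[idx], y2[idx]
    G11 = np.einsum("bni,bnj->bij", X1b, X1b)
    G22 = np.einsum("bni,bnj->bij", X2b, X2b)
    G12 = np.einsum("bni,bnj->bij", X1b, X2b)
    c11 = np.einsum("bni,bn->bi", X1b, y1b)
    c12 = np.einsum("bni,bn->bi", X1b, y2b)
    c21 = np.einsum("bni,bn->bi", X2b, y1b)
    c22 = np.einsum("bni,bn->bi", X2b, y2b)
    b1 = np.linalg.solve(G11, c11[..., None])[..., 0]
    b2 = np.linalg.solve(G22, c22[..., None])[..., 0]
    e1 = y1b - np.einsum("bnk,bk->bn", X1b, b1)
    e2 = y2b - np.einsum("bnk,bk->bn", X2b, b2)
    s11 = np.einsum("bn,bn->b", e1, e1) / n
    s22 = np.einsum("bn,bn->b", e2, e2) / n
    s12 = np.einsum("bn,bn->b", e1, e2) / n
    eps = 1e-10 * ((s11 + s22) / 2.0 + 1.0)
    s11r, s22r = s11 + eps, s22 + eps
    det = s11r * s22r - s12 * s12
    i11, i22, i12 = s22r / det, s11r / det, -s12 / det
    A = np.empty((B, k1 + k2, k1 + k2))
    A[:, :k1, :k1] = i11[:, None, None] * G11
    A[:, :k1, k1:] = i12[:, None, None] * G12
    A[:, k1:, :k1] = i12[:, None, None] * np.swapaxes(G12, 1, 2)
    A[:, k1:, k1:] = i22[:, None, None] * G22
    rhs = np.concatenate(
        [
            i11[:, None] * c11 + i12[:, None] * c12,
            i12[:, None] * c21 + i22[:, None] * c22,
        ],
        axis=1,
    )
    beta = np.linalg.solve(A, rhs[..., None])[..., 0]
    return beta[:, 1], beta[:, k1 + 1]  # arm is column 1 of each equation


def bootstrap_cloud(
    imputed: ImputedDatasets | Iterable[pd.DataFrame],
    design: CeaDesign,
    B: int = 5000,
    seed: int = 0,
    chunk: int = 1000,
) -> BootstrapCloud:
    """Bootstrap the SUR fit within each imputed dataset and pool replicates.

    Resampling is with replacement, stratified by arm so arm sizes are
    preserved (a degenerate single-arm resample therefore cannot occur); each
    imputed dataset gets its own B replicates from its own seed stream, and
    the m*B replicates are pooled into one cloud.  Deterministic per seed.
    """
    datasets = imputed.datasets if isinstance(imputed, ImputedDatasets) else list(imputed)
    m = len(datasets)
    if B < 1:
        raise ValueError("B must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(m)
    out = np.empty((m * B, 2))
    pos = 0
    for df, ss in zip(datasets, streams):
        rng = np.random.default_rng(ss)
        arm = df[design.arm_col].to_numpy(float)
        y1 = df[design.cost_col].to_numpy(float)
        y2 = df[design.effect_col].to_numpy(float)
        X1, _ = _stack_design(
            arm,
            df[list(design.cost_covariates)].to_numpy(float)
            if design.cost_covariates
            else None,
            design.cost_covariates,
        )
        X2, _ = _stack_design(
            arm,
            df[list(design.effect_covariates)].to_numpy(float)
            if design.effect_covariates
            else None,
            design.effect_covariates,
        )
        groups = [np.flatnonzero(arm == g) for g in np.unique(arm)]
        for start in range(0, B, chunk):
            nb = min(chunk, B - start)
            parts = [g[rng.integers(0, len(g), size=(nb, len(g)))] for g in groups]
            idx = np.concatenate(parts, axis=1)
            dc, de = _batch_sure_arm_coefs(y1, y2, X1, X2, idx)
            out[pos : pos + nb, 0] = dc
            out[pos : pos + nb, 1] = de
            pos += nb
    if not np.isfinite(out).all():
        raise FloatingPointError("non-finite bootstrap replicates")
    return BootstrapCloud(
        replicates=out, B=B, m=m, effect_kind=design.effect_kind, pooled_over_m=m > 1
    )


@dataclass(frozen=True)
class IcerResult:
    delta_cost: float
    delta_effect: float
    classification: str  # {"dominant", "dominated", "ratio", "undefined-ratio"}
    ratio_value: float | None = None
    delta_cost_sign: int = 0


def icer(delta_cost: float, delta_effect: float) -> IcerResult:
    """Classify the incremental pair and compute the ratio where meaningful.

    Dominance is reported instead of a ratio: dominant when the intervention
    saves costs and improves effects (SE quadrant), dominated in the mirror
    case (NW).  A ratio is reported only in the NE/SW quadrants; a zero
    effect difference yields classification ``"undefined-ratio"`` with the
    sign of the cost difference.
    """
    if not (np.isfinite(delta_cost) and np.isfinite(delta_effect)):
        raise ValueError("inputs must be finite")
    if delta_effect == 0:
        return IcerResult(
            delta_cost, delta_effect, "undefined-ratio",
            delta_cost_sign=int(np.sign(delta_cost)),
        )
    if delta_cost < 0 and delta_effect > 0:
        return IcerResult(delta_cost, delta_effect, "dominant")
    if delta_cost > 0 and delta_effect < 0:
        return IcerResult(delta_cost, delta_effect, "dominated")
    return IcerResult(
        delta_cost, delta_effect, "ratio", ratio_value=delta_cost / delta_effect
    )


@dataclass(frozen=True)
class QuadrantShares:
    """Percentage of bootstrap replicates per cost-effectiveness-plane quadrant.

    Strict inequalities define cost saving (dC < 0) and effectiveness
    (dE > 0); boundary points count as neither (dC = 0 is not cost-saving,
    dE = 0 is not more effective), so the four shares sum to exactly 100.
    """

    ne: float
    se: float
    sw: float
    nw: float

    def as_dict(self) -> dict[str, float]:
        return {"ne": self.ne, "se": self.se, "sw": self.sw, "nw": self.nw}


def quadrant_shares(cloud: BootstrapCloud) -> QuadrantShares:
    if len(cloud.replicates) == 0:
        raise ValueError("empty cloud")
    dc, de = cloud.delta_cost, cloud.delta_effect
    eff = de > 0
    saving = dc < 0
    n = len(dc)
    pct = lambda mask: 100.0 * mask.sum() / n  # noqa: E731
    return QuadrantShares(
        ne=pct(eff & ~saving),
        se=pct(eff & saving),
        sw=pct(~eff & saving),
        nw=pct(~eff & ~saving),
    )


@dataclass
class CeacCurve:
    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def ceac(cloud: BootstrapCloud, wtp_grid: np.ndarray | None = None) -> CeacCurve:
    """Probability of positive net monetary benefit at each willingness-to-pay.

    At lambda = 0 this is the fraction of cost-saving replicates; as lambda
    grows beyond every |dC/dE| with dE > 0 it approaches the fraction of
    effect-improving replicates.
    """
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    if np.any(grid < 0) or np.any(np.diff(grid) < 0):
        raise ValueError("grid must be non-negative and sorted")
    nmb = grid[:, None] * cloud.delta_effect[None, :] - cloud.delta_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CeacCurve(wtp=grid, probability=prob)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin-style pooling of per-imputation SUR point estimates."""

    delta_cost: float
    delta_effect: float
    var_delta_cost: float
    var_delta_effect: float
    within: tuple[float, float]
    between: tuple[float, float]
    m: int


def pool_point_estimates(fits: Sequence[SureFit]) -> PooledEstimate:
    """Mean coefficients across imputations; total variance = within-mean
    + (1 + 1/m) * between-imputation variance."""
    if not fits:
        raise ValueError("need at least one fit")
    m = len(fits)
    dc = np.array([f.delta_cost for f in fits])
    de = np.array([f.delta_effect for f in fits])
    wc = np.array([f.var_delta[0] for f in fits])
    we = np.array([f.var_delta[1] for f in fits])
    bc = dc.var(ddof=1) if m > 1 else 0.0
    be = de.var(ddof=1) if m > 1 else 0.0
    return PooledEstimate(
        delta_cost=float(dc.mean()),
        delta_effect=float(de.mean()),
        var_delta_cost=float(wc.mean() + (1 + 1 / m) * bc),
        var_delta_effect=float(we.mean() + (1 + 1 / m) * be),
        within=(float(wc.mean()), float(we.mean())),
        between=(float(bc), float(be)),
        m=m,
    )


__all__ = [
    "DEFAULT_WTP_GRID",
    "SureFit",
    "CeaDesign",
    "BootstrapCloud",
    "IcerResult",
    "QuadrantShares",
    "CeacCurve",
    "PooledEstimate",
    "fit_sure",
    "fit_sure_table",
    "bootstrap_cloud",
    "icer",
    "quadrant_shares",
    "ceac",
    "pool_point_estimates",
]
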