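"""Incremental cost-effectiveness engine.

Incremental costs ΔC and effects ΔE are the treatment coefficients of a
two-equation seemingly-unrelated-regression (SUR) system — cost on arm and
effect on arm — estimated by feasible GLS so the residuals of the two
equations may be correlated. Sampling uncertainty is handled by a
nonparametric bootstrap of the patient-level data (stratified within arm by
default), giving percentile confidence intervals, cost-effectiveness-plane
quadrant shares and the cost-effectiveness acceptability curve
p(λ) = P(λ·ΔE − ΔC > 0).

With an identical design matrix in both equations the SUR treatment
coefficients coincide exactly with the per-equation difference in arm means;
the system is still estimated jointly so the cross-equation residual
correlation is available and the bootstrap resamples (ΔE, ΔC) jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SURResult:
    delta_cost: float
    delta_effect: float
    intercept_cost: float
    intercept_effect: float
    residual_correlation: float


def fit_sur(costs, effects, arm_indicator) -> SURResult:
    """Two-equation SUR (cost ~ arm; effect ~ arm) by feasible GLS.

    ``arm_indicator`` is 1 for intervention, 0 for control. The residual
    covariance is estimated from the per-equation OLS residuals; when it is
    singular (degenerate data) the estimator reduces to OLS, which is exact
    for identical regressors.
    """
    c = np.asarray(costs, float)
    e = np.asarray(effects, float)
    a = np.asarray(arm_indicator, float)
    if not (c.shape == e.shape == a.shape):
        raise ValueError("costs, effects and arm indicator must align")
    if np.unique(a).size < 2:
        raise ValueError("arm indicator is constant: both arms are required")
    n = a.size
    X = np.column_stack([np.ones(n), a])
    Y = np.column_stack([c, e])
    XtX = X.T @ X
    beta_ols = np.linalg.solve(XtX, X.T @ Y)  # 2x2: rows (const, arm)
    resid = Y - X @ beta_ols
    sigma = resid.T @ resid / n
    denom = np.sqrt(sigma[0, 0] * sigma[1, 1])
    if denom == 0:
        # zero residual variance in an equation; perfectly coupled data
        corr = 1.0 if np.allclose(resid[:, 0], resid[:, 1]) else np.nan
        beta = beta_ols
    else:
        corr = float(sigma[0, 1] / denom)
        try:
            sigma_inv = np.linalg.inv(sigma)
            A = np.kron(sigma_inv, XtX)
            b = np.concatenate([
                sigma_inv[0, 0] * X.T @ Y[:, 0] + sigma_inv[0, 1] * X.T @ Y[:, 1],
                sigma_inv[1, 0] * X.T @ Y[:, 0] + sigma_inv[1, 1] * X.T @ Y[:, 1],
            ])
            flat = np.linalg.solve(A, b)
            beta = np.column_stack([flat[:2], flat[2:]])
        except np.linalg.LinAlgError:
            beta = beta_ols
    return SURResult(
        delta_cost=float(beta[1, 0]),
        delta_effect=float(beta[1, 1]),
        intercept_cost=float(beta[0, 0]),
        intercept_effect=float(beta[0, 1]),
        residual_correlation=corr,
    )


def incremental_estimates(costs, effects, arm_indicator) -> tuple:
    """(ΔC, ΔE): differences of arm means, intervention minus control."""
    c = np.asarray(costs, float)
    e = np.asarray(effects, float)
    a = np.asarray(arm_indicator, bool)
    if a.sum() == 0 or (~a).sum() == 0:
        raise ValueError("both arms must be non-empty")
    return (float(c[a].mean() - c[~a].mean()),
            float(e[a].mean() - e[~a].mean()))


@dataclass
class BootstrapDistribution:
    """B bootstrap replicates of (ΔE, ΔC)."""

    delta_effects: np.ndarray
    delta_costs: np.ndarray
    seed: int | None
    stratified: bool = True

    @property
    def B(self) -> int:
        return self.delta_effects.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_effect": self.delta_effects,
                             "delta_cost": self.delta_costs})


def bootstrap_cea(costs, effects, arm_indicator, B: int = 2500,
                  seed: int | np.random.Generator | None = 0,
                  stratified: bool = True) -> BootstrapDistribution:
    """Bootstrap the SUR model on resampled patient-level data.

    Each replicate resamples participants with replacement (within arm when
    stratified, preserving the arm sizes) and re-estimates (ΔE_b, ΔC_b) via
    :func:`fit_sur`. Deterministic for a fixed integer seed.
    """
    if B <= 0:
        raise ValueError("number of bootstrap replicates must be positive")
    c = np.asarray(costs, float)
    e = np.asarray(effects, float)
    a = np.asarray(arm_indicator, float)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = a.size
    idx_int = np.flatnonzero(a == 1)
    idx_ctr = np.flatnonzero(a == 0)
    if idx_int.size == 0 or idx_ctr.size == 0:
        raise ValueError("both arms must be non-empty")
    de = np.empty(B)
    dc = np.empty(B)
    for b in range(B):
        if stratified:
            take = np.concatenate([
                rng.choice(idx_int, idx_int.size, replace=True),
                rng.choice(idx_ctr, idx_ctr.size, replace=True),
            ])
        else:
            take = rng.choice(n, n, replace=True)
            if a[take].min() == a[take].max():  # degenerate resample: redraw
                continue_idx = take
                while a[continue_idx].min() == a[continue_idx].max():
                    continue_idx = rng.choice(n, n, replace=True)
                take = continue_idx
        res = fit_sur(c[take], e[take], a[take])
        de[b] = res.delta_effect
        dc[b] = res.delta_cost
    return BootstrapDistribution(
        delta_effects=de, delta_costs=dc,
        seed=(seed if isinstance(seed, (int, np.integer)) else None),
        stratified=stratified)


def icer(delta_cost: float, delta_effect: float) -> float | None:
    """ΔC/ΔE, or None (undefined) when the incremental effect is zero."""
    if delta_effect == 0:
        return None
    return delta_cost / delta_effect


def quadrant_shares(dist: BootstrapDistribution) -> dict:
    """Cost-effectiveness-plane quadrant shares (sum to 1).

    ΔE = 0 is assigned to the east; ΔC = 0 counts as "not more costly"
    (south). NE: more effect at more cost; SE: dominance.
    """
    de, dc = dist.delta_effects, dist.delta_costs
    if de.size == 0:
        raise ValueError("empty bootstrap distribution")
    east = de >= 0
    north = dc > 0
    B = de.size
    return {
        "NE": float((east & north).sum() / B),
        "NW": float((~east & north).sum() / B),
        "SE": float((east & ~north).sum() / B),
        "SW": float((~east & ~north).sum() / B),
    }


@dataclass
class CEACCurve:
    """Probability of cost-effectiveness across willingness-to-pay ceilings."""

    lambdas: np.ndarray
    probabilities: np.ndarray

    def probability_at(self, wtp: float) -> float:
        i = int(np.argmin(np.abs(self.lambdas - wtp)))
        return float(self.probabilities[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.lambdas,
                             "probability": self.probabilities})


def ceac(dist: BootstrapDistribution, lambda_grid) -> CEACCurve:
    """p(λ) = share of replicates with positive net benefit λ·ΔE − ΔC."""
    lam = np.asarray(lambda_grid, float)
    if np.any(lam < 0):
        raise ValueError("willingness-to-pay ceilings must be >= 0")
    if dist.B == 0:
        raise ValueError("empty bootstrap distribution")
    nb = lam[:, None] * dist.delta_effects[None, :] - dist.delta_costs[None, :]
    return CEACCurve(lambdas=lam, probabilities=(nb > 0).mean(axis=1))


def percentile_ci(values, alpha: float = 0.05) -> tuple:
    """Equal-tail percentile interval of a bootstrap statistic."""
    lo, hi = np.quantile(np.asarray(values, float), [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def icer_percentile_ci(dist: BootstrapDistribution,
                       alpha: float = 0.05) -> tuple | None:
    """Percentile interval for the ICER via angular ordering about the origin.

    Replicates are ordered counterclockwise by their angle in the (ΔE, ΔC)
    plane starting from due south (dominance direction); the interval spans
    the central 1−α of that ordering. Returns None when no ray through the
    origin leaves at least α/2 of the replicates strictly on each side —
    operationally, when the α/2 and 1−α/2 percentiles of ΔE bracket zero, no
    dependably accurate interval exists.
    """
    de, dc = dist.delta_effects, dist.delta_costs
    if de.size == 0:
        raise ValueError("empty bootstrap distribution")
    lo_e, hi_e = np.quantile(de, [alpha / 2, 1 - alpha / 2])
    if lo_e < 0 < hi_e:
        return None
    theta = np.arctan2(dc, de)
    theta = np.where(theta < -np.pi / 2, theta + 2 * np.pi, theta)
    order = np.argsort(theta, kind="stable")
    B = de.size
    i_lo = order[int(np.floor(alpha / 2 * (B - 1)))]
    i_hi = order[int(np.ceil((1 - alpha / 2) * (B - 1)))]

    def slope(i):
        return float(dc[i] / de[i]) if de[i] != 0 else float(
            np.sign(dc[i]) * np.inf)

    return slope(i_lo), slope(i_hi)


@dataclass
class IncrementalResult:
    """Point estimates and bootstrap uncertainty for one analysis variant."""

    delta_cost: float
    delta_effect: float
    icer: float | None
    ci_cost: tuple
    ci_effect: tuple
    ci_icer: tuple | None
    quadrants: dict
    residual_correlation: float
    distribution: BootstrapDistribution


def evaluate(costs, effects, arm_indicator, B: int = 2500,
             seed: int | np.random.Generator | None = 0,
             stratified: bool = True, alpha: float = 0.05) -> IncrementalResult:
    """Point SUR estimate plus full bootstrap uncertainty analysis."""
    point = fit_sur(costs, effects, arm_indicator)
    dist = bootstrap_cea(costs, effects, arm_indicator, B=B, seed=seed,
                         stratified=stratified)
    return IncrementalResult(
        delta_cost=point.delta_cost,
        delta_effect=point.delta_effect,
        icer=icer(point.delta_cost, point.delta_effect),
        ci_cost=percentile_ci(dist.delta_costs, alpha),
        ci_effect=percentile_ci(dist.delta_effects, alpha),
        ci_icer=icer_percentile_ci(dist, alpha),
        quadrants=quadrant_shares(dist),
        residual_correlation=point.residual_correlation,
        distribution=dist,
    )
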