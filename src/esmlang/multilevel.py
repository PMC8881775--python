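"""Fast REML estimation of the two-level random-intercept regression.

The momentary association analysis fits, for every emotion x feature pair,
the model

    y_ij = b0 + b1 * x_ij + u_j + e_ij,      u_j ~ N(0, s_u^2),  e_ij ~ N(0, s_e^2)

by restricted maximum likelihood, where j indexes participants.  Because
both variables are standardized within participants, the fixed slope b1 is
interpretable as a pooled within-person correlation.

With a single random intercept the REML criterion can be profiled down to a
one-dimensional search over the variance ratio psi = s_u^2 / s_e^2, using
the Woodbury identity V_j^-1 = I - psi/(1 + psi*n_j) * J per group.  This
makes each fit a few matrix-free O(n) evaluations, which matters because the
association stage fits hundreds of such models per table and the calibration
suites fit tens of thousands.  Agreement with statsmodels' general MixedLM
solver is enforced in the test suite.

p-values use the large-sample normal approximation for the Wald statistic
b1 / SE(b1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = ["RandomInterceptFit", "fit_random_intercept"]


@dataclass(frozen=True)
class RandomInterceptFit:
    """REML fit of y ~ 1 + x with a participant random intercept."""

    slope: float
    slope_se: float
    p_value: float
    intercept: float
    sigma_u2: float      # random-intercept variance
    sigma_e2: float      # residual variance
    n_obs: int
    n_groups: int
    converged: bool

    @property
    def z_value(self) -> float:
        return self.slope / self.slope_se if self.slope_se > 0 else float("nan")


def _group_blocks(groups: np.ndarray) -> list[np.ndarray]:
    codes, _ = pd_factorize(groups)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    boundaries = np.flatnonzero(np.diff(sorted_codes)) + 1
    return [order[s] for s in np.split(np.arange(len(codes)), boundaries)]


def pd_factorize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, codes = np.unique(np.asarray(values), return_inverse=True)
    return codes, uniq


def _reml_pieces(psi: float, X: np.ndarray, y: np.ndarray,
                 blocks: list[np.ndarray]):
    """GLS quantities for V_j = I + psi * J_j (unit residual variance)."""
    p = X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet = 0.0
    for idx in blocks:
        nj = len(idx)
        Xj, yj = X[idx], y[idx]
        w = psi / (1.0 + psi * nj)
        sx = Xj.sum(axis=0)
        sy = yj.sum()
        XtVX += Xj.T @ Xj - w * np.outer(sx, sx)
        XtVy += Xj.T @ yj - w * sx * sy
        ytVy += yj @ yj - w * sy * sy
        logdet += np.log1p(psi * nj)
    return XtVX, XtVy, ytVy, logdet


def _reml_criterion(psi: float, X: np.ndarray, y: np.ndarray,
                    blocks: list[np.ndarray]) -> float:
    n, p = X.shape
    XtVX, XtVy, ytVy, logdet = _reml_pieces(psi, X, y, blocks)
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return np.inf
    rss = ytVy - beta @ XtVy
    if rss <= 0:
        return np.inf
    sign, logdet_xx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    sigma_e2 = rss / (n - p)
    return (n - p) * np.log(sigma_e2) + logdet + logdet_xx


def fit_random_intercept(y, x, groups) -> RandomInterceptFit:
    """REML fit of ``y ~ 1 + x + (1 | group)``.

    Parameters are plain 1-d arrays; rows with NaN in y or x must be removed
    by the caller.  Requires at least two groups and two observations in at
    least two groups.
    """
    y = np.asarray(y, dtype=float)
    xv = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    if len(y) != len(xv) or len(y) != len(groups):
        raise ValueError("y, x and groups must have equal length")
    if np.isnan(y).any() or np.isnan(xv).any():
        raise ValueError("NaNs must be removed before fitting")
    blocks = _group_blocks(groups)
    if len(blocks) < 2:
        raise ValueError("need at least two participants")
    n = len(y)
    X = np.column_stack([np.ones(n), xv])
    if np.allclose(xv.std(), 0.0):
        raise ValueError("feature column is constant")

    res = minimize_scalar(
        lambda t: _reml_criterion(np.exp(t), X, y, blocks),
        bounds=(-14.0, 10.0), method="bounded",
        options={"xatol": 1e-8},
    )
    psi = float(np.exp(res.x))
    # boundary check: psi ~ 0 (no between-group variance) may beat interior
    if _reml_criterion(0.0, X, y, blocks) <= _reml_criterion(psi, X, y, blocks):
        psi = 0.0

    XtVX, XtVy, ytVy, _ = _reml_pieces(psi, X, y, blocks)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - beta @ XtVy
    sigma_e2 = rss / (n - X.shape[1])
    cov = sigma_e2 * np.linalg.inv(XtVX)
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    if se > 0:
        z = beta[1] / se
        p = float(2.0 * norm.sf(abs(z)))
    else:                       # perfect fit: zero residual variance
        p = 0.0 if beta[1] != 0 else 1.0
    return RandomInterceptFit(
        slope=float(beta[1]), slope_se=se, p_value=p,
        intercept=float(beta[0]),
        sigma_u2=float(psi * sigma_e2), sigma_e2=float(sigma_e2),
        n_obs=n, n_groups=len(blocks),
        converged=bool(res.success),
    )
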