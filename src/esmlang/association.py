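"""Pairwise emotion x language-feature associations with Holm correction.

Two analysis levels mirror the study design:

* momentary -- the slope of a multilevel simple regression (participant
  random intercept, REML) of the within-person standardized emotion on the
  standardized feature; with both variables standardized the slope is a
  pooled within-person correlation;
* trait -- Spearman rank correlation across the per-participant aggregates.

Each displayed table (level x feature family) forms one multiple-testing
family, corrected by Holm's step-down procedure.  Holm controls the
family-wise error rate; the literature this package follows labels the same
procedure an "FDR correction", but the implementation is the classical
step-down Holm test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .multilevel import fit_random_intercept

__all__ = [
    "AssociationResult",
    "momentary_slope",
    "trait_spearman",
    "holm_adjust",
    "correlation_table",
]


@dataclass(frozen=True)
class AssociationResult:
    """One emotion x feature cell of a correlation table."""

    level: str              # "momentary" | "trait"
    emotion: str
    feature: str
    estimate: float         # standardized slope or Spearman rho
    raw_p: float
    significant: bool       # Holm-adjusted flag within the family
    family: str             # table identifier
    n: int
    failed: bool = False


def momentary_slope(data: pd.DataFrame, emotion: str, feature: str,
                    group_col: str = "participant_id"
                    ) -> tuple[float, float, int]:
    """Fixed slope and p-value of the two-level random-intercept regression.

    Rows with a missing emotion or feature value are dropped; at least two
    participants with two or more observations are required.  Returns
    ``(estimate, raw_p, n_used)``.
    """
    sub = data[[group_col, emotion, feature]].dropna()
    counts = sub[group_col].value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >=2 participants with >=2 observations")
    fit = fit_random_intercept(sub[emotion].to_numpy(),
                               sub[feature].to_numpy(),
                               sub[group_col].to_numpy())
    return fit.slope, fit.p_value, fit.n_obs


def trait_spearman(data: pd.DataFrame, outcome: str, feature: str
                   ) -> tuple[float, float, int]:
    """Spearman rho (mid-ranks for ties) with the t-approximation p-value."""
    sub = data[[outcome, feature]].dropna()
    if len(sub) < 5:
        raise ValueError("need >=5 participants for a trait correlation")
    if sub[outcome].nunique() < 2 or sub[feature].nunique() < 2:
        raise ValueError("constant column: Spearman undefined")
    rho, p = stats.spearmanr(sub[outcome], sub[feature])
    return float(rho), float(p), len(sub)


def holm_adjust(p_values, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm significance flags for one family of p-values.

    Sorted ascending, p_(k) is significant iff p_(j) <= alpha / (m - j + 1)
    for every j <= k; the procedure stops at the first failure.
    """
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for k, idx in enumerate(order):
        if p[idx] <= alpha / (m - k):
            flags[idx] = True
        else:
            break
    return flags


def correlation_table(data: pd.DataFrame, emotions, features, level: str,
                      family: str | None = None, alpha: float = 0.05,
                      group_col: str = "participant_id") -> pd.DataFrame:
    """Full emotion x feature grid at one level, Holm-corrected as one family.

    Returns a tidy DataFrame with columns level, emotion, feature, estimate,
    raw_p, significant, family, n, failed.  Cells whose fit fails (constant
    column, too few observations) are retained with ``failed=True`` and are
    excluded from the Holm family.
    """
    if level not in ("momentary", "trait"):
        raise ValueError("level must be 'momentary' or 'trait'")
    family = family or f"{level}"
    rows: list[AssociationResult] = []
    for emo in emotions:
        for feat in features:
            try:
                if level == "momentary":
                    est, p, n = momentary_slope(data, emo, feat, group_col)
                else:
                    est, p, n = trait_spearman(data, emo, feat)
                rows.append(AssociationResult(level, emo, feat, est, p,
                                              False, family, n))
            except (ValueError, np.linalg.LinAlgError):
                rows.append(AssociationResult(level, emo, feat,
                                              float("nan"), float("nan"),
                                              False, family, 0, failed=True))
    table = pd.DataFrame([r.__dict__ for r in rows])
    ok = ~table["failed"] & table["raw_p"].notna()
    if ok.any():
        flags = holm_adjust(table.loc[ok, "raw_p"].to_numpy(), alpha=alpha)
        table.loc[ok, "significant"] = flags
    return table
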