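"""Predictive modelling: CV feature selection and resampled predictive R².

For each emotion and feature set the procedure mirrors the analysis this
package reimplements:

1. candidate predictors are the Holm-significant features of the
   association stage (fallback: the 3 most highly correlated);
2. the data are split 80/20 into training and test sets -- momentary splits
   are observation-level stratified by participant (so nearly every
   participant keeps training rows), trait splits are participant-level;
3. a 10-fold cross-validation on the training set keeps candidates whose
   coefficient's average p-value is < .05 (fallback: the 2 best, to limit
   overfitting);
4. the final model -- a mixed model with participant random intercept and
   per-participant random slopes at the momentary level, OLS at the trait
   level -- is fit on the full training set and scored on the test set with

       predictive R^2 = 1 - MSE(test) / Var(test outcomes),

   population (n) variance convention; values below zero are kept (a model
   worse than the test-set mean);
5. steps 2-4 repeat over 50 independent splits; the mean and SD over splits
   are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate.config import qualified_features

__all__ = [
    "SplitPlan",
    "PredictiveResult",
    "feature_sets",
    "make_splits",
    "select_candidates",
    "cv_feature_select",
    "fit_final_and_score",
    "predictive_r2",
    "resample_splits",
    "combine_feature_sets",
]


def feature_sets() -> dict[str, list[str]]:
    """Named predictor pools: the four families and their combinations."""
    qf = qualified_features()
    sets = dict(qf)
    sets["speech_combined"] = qf["speech_content"] + qf["speech_form"]
    sets["writing_combined"] = qf["writing_content"] + qf["writing_form"]
    sets["all"] = (qf["speech_content"] + qf["speech_form"]
                   + qf["writing_content"] + qf["writing_form"])
    return sets


@dataclass(frozen=True)
class SplitPlan:
    """One 80/20 train/test split (positional row indices)."""

    split_id: int
    level: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self):
        inter = np.intersect1d(self.train_idx, self.test_idx)
        if len(inter):
            raise ValueError("train and test overlap")


@dataclass
class PredictiveResult:
    """Per-split predictive R² for one emotion x feature set."""

    emotion: str
    feature_set: str
    level: str
    r2_per_split: list[float] = field(default_factory=list)
    predictors_per_split: list[list[str]] = field(default_factory=list)
    n_failed: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.r2_per_split)) if self.r2_per_split else float("nan")

    @property
    def sd(self) -> float:
        return (float(np.std(self.r2_per_split, ddof=1))
                if len(self.r2_per_split) > 1 else float("nan"))

    @property
    def unreliable(self) -> bool:
        total = len(self.r2_per_split) + self.n_failed
        return total == 0 or self.n_failed > 0.2 * total


def make_splits(data: pd.DataFrame, level: str, n_splits: int, seed: int,
                group_col: str = "participant_id",
                test_frac: float = 0.2) -> list[SplitPlan]:
    """Seeded 80/20 splits.

    Momentary: observation-level, stratified by participant so that every
    participant with >= 2 rows keeps at least one training row; the global
    test count is exact to within one row.  Trait: participant-level, each
    participant wholly in train or test.
    """
    n = len(data)
    plans = []
    for s in range(n_splits):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101, s]))
        if level == "trait":
            pos = rng.permutation(n)
            n_test = max(1, int(round(test_frac * n)))
            n_test = min(n_test, n - 1)
            plans.append(SplitPlan(s, level, np.sort(pos[n_test:]),
                                   np.sort(pos[:n_test]), seed))
            continue
        groups = data[group_col].to_numpy()
        uniq = np.unique(groups)
        target = int(round(test_frac * n))
        base, remainders, test_parts = {}, [], []
        for g in uniq:
            rows = np.flatnonzero(groups == g)
            cap = len(rows) - 1 if len(rows) >= 2 else 0
            b = min(int(np.floor(test_frac * len(rows))), cap)
            base[g] = (rows, b, cap)
            remainders.append((test_frac * len(rows) - b, g))
        extra = target - sum(b for (_, b, _) in base.values())
        order = sorted(remainders, key=lambda t: (-t[0], str(t[1])))
        for _, g in order:
            if extra <= 0:
                break
            rows, b, cap = base[g]
            if b < cap:
                base[g] = (rows, b + 1, cap)
                extra -= 1
        test_idx = []
        for g in uniq:
            rows, b, _ = base[g]
            pick = rng.permutation(len(rows))[:b]
            test_parts.append(rows[pick])
        test_idx = (np.sort(np.concatenate(test_parts))
                    if test_parts else np.array([], dtype=int))
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        plans.append(SplitPlan(s, level, train_idx, test_idx, seed))
    return plans


def select_candidates(table: pd.DataFrame, emotion: str,
                      features: list[str]) -> list[str]:
    """Holm-flagged features for the emotion; fallback to the top 3 |estimate|.

    Ties (and ordering generally) are broken by the fixed feature order of
    ``features``.  With fewer than 3 features available, all are taken.
    """
    sub = table[(table["emotion"] == emotion)
                & table["feature"].isin(features) & ~table["failed"]]
    sub = sub.set_index("feature").reindex([f for f in features
                                            if f in set(sub["feature"])])
    flagged = [f for f in sub.index[sub["significant"].astype(bool)]]
    if flagged:
        return flagged
    est = sub["estimate"].abs()
    ranked = sorted(est.index, key=lambda f: (-est[f], features.index(f)))
    return ranked[: min(3, len(ranked))]


def _ols_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """p-values of the non-intercept coefficients of an OLS fit."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    if dof <= 0:
        return np.full(p - 1, np.nan)
    s2 = resid @ resid / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(s2 * np.diag(xtx_inv), 1e-300))
    t = beta / se
    return 2.0 * stats.t.sf(np.abs(t[1:]), dof)


def cv_feature_select(data: pd.DataFrame, train_idx: np.ndarray,
                      candidates: list[str], emotion: str,
                      seed: int, n_folds: int = 10) -> list[str]:
    """10-fold CV over the training rows: keep candidates with mean p < .05.

    Per fold, the full candidate model is fit by OLS on the fold's training
    part and each coefficient's p-value recorded; candidates with average p
    below .05 are retained.  If none qualify, the 2 candidates with the
    smallest mean p are kept (all, if fewer than 2 exist).  Folds are fully
    determined by (rows, seed).
    """
    if not candidates:
        raise ValueError("no candidate predictors")
    rows = data.iloc[train_idx][[emotion, *candidates]].dropna()
    if len(rows) < n_folds:
        raise ValueError("too few training rows for 10-fold CV")
    y = rows[emotion].to_numpy()
    X = np.column_stack([np.ones(len(rows)), rows[candidates].to_numpy()])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 211]))
    perm = rng.permutation(len(rows))
    folds = np.array_split(perm, n_folds)
    pvals = []
    for k in range(n_folds):
        fit_rows = np.concatenate([folds[j] for j in range(n_folds) if j != k])
        p = _ols_pvalues(X[fit_rows], y[fit_rows])
        if np.all(np.isfinite(p)):
            pvals.append(p)
    if not pvals:
        raise ValueError("all CV folds failed")
    mean_p = np.mean(pvals, axis=0)
    kept = [c for c, p in zip(candidates, mean_p) if p < 0.05]
    if kept:
        return kept
    order = sorted(range(len(candidates)), key=lambda i: (mean_p[i], i))
    return [candidates[i] for i in order[: min(2, len(candidates))]]


def predictive_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """1 - MSE / Var with the population (n) variance convention."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    mse = float(np.mean((y_true - y_pred) ** 2))
    var = float(np.mean((y_true - y_true.mean()) ** 2))
    if var == 0:
        return float("nan")
    return 1.0 - mse / var


def _fit_mixed_random_slopes(y, X, groups, re_cols):
    """MixedLM with random intercept + slopes; returns (fe, re_dict, used)."""
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups, exog_re=X[:, re_cols])
        res = model.fit(reml=True, method="lbfgs", maxiter=200)
    if not np.all(np.isfinite(res.fe_params)):
        raise np.linalg.LinAlgError("non-finite fixed effects")
    re = {g: np.asarray(v, dtype=float) for g, v in res.random_effects.items()}
    return np.asarray(res.fe_params), re


def fit_final_and_score(data: pd.DataFrame, train_idx: np.ndarray,
                        test_idx: np.ndarray, predictors: list[str],
                        emotion: str, level: str,
                        group_col: str = "participant_id"
                        ) -> tuple[float, list[str]]:
    """Fit the final model on the training rows and score the test rows.

    Momentary: mixed model with a participant random intercept and varying
    slopes; test predictions add the participant's estimated effects when
    the participant appeared in training, population-level effects
    otherwise.  A singular fit drops random slopes one at a time (last
    first) down to a random intercept; if even that fails the split fails.
    Trait: OLS.  Returns (predictive R², random-effect columns used).
    """
    if not predictors:
        raise ValueError("no predictors retained")
    cols = [emotion, *predictors, group_col]
    train = data.iloc[train_idx][cols].dropna()
    test = data.iloc[test_idx][cols].dropna()
    if len(train) < len(predictors) + 2 or len(test) < 2:
        raise ValueError("too few rows after NA removal")
    y_tr = train[emotion].to_numpy()
    X_tr = np.column_stack([np.ones(len(train)), train[predictors].to_numpy()])
    y_te = test[emotion].to_numpy()
    X_te = np.column_stack([np.ones(len(test)), test[predictors].to_numpy()])

    if level == "trait":
        beta, *_ = np.linalg.lstsq(X_tr, y_tr, rcond=None)
        return predictive_r2(y_te, X_te @ beta), []

    groups_tr = train[group_col].to_numpy()
    groups_te = test[group_col].to_numpy()
    n_re_full = X_tr.shape[1]
    last_err: Exception | None = None
    for n_re in range(n_re_full, 0, -1):
        re_cols = list(range(n_re))      # intercept first, slopes in order
        try:
            fe, re = _fit_mixed_random_slopes(y_tr, X_tr, groups_tr, re_cols)
        except Exception as err:   # noqa: BLE001 - solver failures vary
            last_err = err
            continue
        yhat = X_te @ fe
        for i, g in enumerate(groups_te):
            if g in re:
                yhat[i] += X_te[i, re_cols] @ re[g]
        used = ["intercept"] + predictors[: n_re - 1]
        return predictive_r2(y_te, yhat), used
    raise RuntimeError(f"mixed model unfittable: {last_err}")


def combine_feature_sets(data: pd.DataFrame, set_names: list[str],
                         candidates_by_set: dict[str, list[str]]
                         ) -> tuple[pd.DataFrame, list[str]]:
    """Row intersection and candidate union for combined models.

    Rows are restricted to observations carrying *every* requested family
    (voice and keyboard streams do not always co-occur, so this shrinks the
    data); the candidate pool is the union of the per-set candidates in
    set order.
    """
    qf = feature_sets()
    keep = pd.Series(True, index=data.index)
    for name in set_names:
        fam_cols = [c for c in qf[name] if c in data.columns]
        keep &= data[fam_cols].notna().any(axis=1)
    rows = data[keep].reset_index(drop=True)
    if len(rows) == 0:
        raise ValueError("no observations carry all requested feature families")
    pool: list[str] = []
    for name in set_names:
        for c in candidates_by_set[name]:
            if c not in pool:
                pool.append(c)
    return rows, pool


def resample_splits(data: pd.DataFrame, emotion: str, candidates: list[str],
                    level: str, n_splits: int = 50, seed: int = 0,
                    feature_set: str = "", group_col: str = "participant_id"
                    ) -> PredictiveResult:
    """The full select -> CV -> fit -> score chain over seeded 80/20 splits."""
    rows = data[data[emotion].notna()].reset_index(drop=True)
    result = PredictiveResult(emotion=emotion, feature_set=feature_set,
                              level=level)
    plans = make_splits(rows, level, n_splits, seed, group_col=group_col)
    for plan in plans:
        try:
            kept = cv_feature_select(rows, plan.train_idx, candidates,
                                     emotion, seed=seed + plan.split_id)
            r2, _ = fit_final_and_score(rows, plan.train_idx, plan.test_idx,
                                        kept, emotion, level, group_col)
            result.r2_per_split.append(r2)
            result.predictors_per_split.append(kept)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            result.n_failed += 1
    return result
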