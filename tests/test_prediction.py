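"""Predictive stage: splits, candidate selection, CV filtering, R² scoring."""

import numpy as np
import pandas as pd
import pytest

from esmlang.prediction import (combine_feature_sets, cv_feature_select,
                                feature_sets, fit_final_and_score, make_splits,
                                predictive_r2, resample_splits,
                                select_candidates)


def panel(n_groups=12, n_per=25, effects=(0.5,), n_noise=2, seed=0):
    """Standardized panel: y driven by the first len(effects) features."""
    rng = np.random.default_rng(seed)
    frames = []
    for g in range(n_groups):
        cols = {}
        y = np.zeros(n_per)
        for j, b in enumerate(effects):
            x = rng.standard_normal(n_per)
            cols[f"x{j}"] = x
            y = y + b * x
        y = y + np.sqrt(max(1 - sum(b * b for b in effects), 0.05)) \
            * rng.standard_normal(n_per)
        for j in range(n_noise):
            cols[f"n{j}"] = rng.standard_normal(n_per)
        cols["emo"] = (y - y.mean()) / y.std(ddof=1)
        cols["participant_id"] = f"p{g:03d}"
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


# -------------------------------------------------------------------- splits

@pytest.mark.parametrize("level", ["momentary", "trait"])
def test_splits_disjoint_exhaustive_and_near_80_20(level):
    if level == "momentary":
        data = panel(n_groups=9, n_per=13)
    else:
        data = pd.DataFrame({"participant_id": [f"p{i}" for i in range(23)],
                             "emo": np.random.default_rng(0).normal(size=23)})
    plans = make_splits(data, level, n_splits=8, seed=3)
    n = len(data)
    for p in plans:
        both = np.concatenate([p.train_idx, p.test_idx])
        assert len(np.unique(both)) == n
        assert abs(len(p.test_idx) - 0.2 * n) <= 1


def test_momentary_split_keeps_training_rows_per_participant():
    data = panel(n_groups=10, n_per=7)
    for p in make_splits(data, "momentary", 10, seed=1):
        train_groups = set(data.iloc[p.train_idx]["participant_id"])
        assert train_groups == set(data["participant_id"])


def test_trait_split_is_participant_level():
    data = pd.DataFrame({"participant_id": [f"p{i}" for i in range(30)]})
    for p in make_splits(data, "trait", 5, seed=2):
        assert set(p.train_idx).isdisjoint(p.test_idx)


def test_splits_deterministic_under_seed():
    data = panel()
    a = make_splits(data, "momentary", 5, seed=9)
    b = make_splits(data, "momentary", 5, seed=9)
    for p, q in zip(a, b):
        assert np.array_equal(p.train_idx, q.train_idx)


# ---------------------------------------------------------------- candidates

def assoc_table(rows):
    return pd.DataFrame([{"emotion": "emo", "feature": f, "estimate": e,
                          "significant": s, "failed": False}
                         for f, e, s in rows])


def test_flagged_candidates_taken_verbatim():
    tab = assoc_table([("a", 0.1, True), ("b", 0.5, False), ("c", 0.2, True)])
    assert select_candidates(tab, "emo", ["a", "b", "c"]) == ["a", "c"]


def test_single_flag_is_not_padded():
    tab = assoc_table([("a", 0.1, True), ("b", 0.5, False)])
    assert select_candidates(tab, "emo", ["a", "b"]) == ["a"]


def test_fallback_top3_with_fixed_tie_order():
    tab = assoc_table([("a", 0.2, False), ("b", -0.2, False),
                       ("c", 0.3, False), ("d", 0.1, False)])
    assert select_candidates(tab, "emo", ["a", "b", "c", "d"]) == ["c", "a", "b"]


def test_fewer_than_three_features_takes_all():
    tab = assoc_table([("a", 0.2, False), ("b", -0.1, False)])
    assert select_candidates(tab, "emo", ["a", "b"]) == ["a", "b"]


# ------------------------------------------------------------------------ cv

def test_cv_retains_strong_planted_effect():
    data = panel(effects=(0.6,), n_noise=3, seed=4)
    plans = make_splits(data, "momentary", 1, seed=5)
    kept = cv_feature_select(data, plans[0].train_idx,
                             ["x0", "n0", "n1", "n2"], "emo", seed=6)
    assert "x0" in kept


def test_cv_pure_noise_fallback_returns_two():
    data = panel(effects=(), n_noise=5, seed=7)
    plans = make_splits(data, "momentary", 1, seed=8)
    kept = cv_feature_select(data, plans[0].train_idx,
                             [f"n{j}" for j in range(5)], "emo", seed=9)
    assert len(kept) == 2


def test_cv_deterministic():
    data = panel(effects=(0.3,), seed=10)
    plans = make_splits(data, "momentary", 1, seed=11)
    args = (data, plans[0].train_idx, ["x0", "n0", "n1"], "emo")
    assert cv_feature_select(*args, seed=12) == cv_feature_select(*args, seed=12)


# -------------------------------------------------------------------- scoring

def test_predictive_r2_reference_points():
    y = np.array([0.0, 1.0, 2.0])
    assert predictive_r2(y, np.full(3, y.mean())) == pytest.approx(0.0)
    assert predictive_r2(y, y) == pytest.approx(1.0)
    # MSE 5/3 against population variance 2/3
    assert predictive_r2(y, np.zeros(3)) == pytest.approx(-1.5)


def test_predictive_r2_matches_direct_formula():
    rng = np.random.default_rng(1)
    for _ in range(50):
        y = rng.normal(size=40)
        yhat = rng.normal(size=40)
        direct = 1 - np.mean((y - yhat) ** 2) / np.mean((y - y.mean()) ** 2)
        assert abs(predictive_r2(y, yhat) - direct) < 1e-12


def test_trait_scoring_equals_numpy_ols():
    rng = np.random.default_rng(13)
    x = rng.standard_normal(40)
    data = pd.DataFrame({"participant_id": [f"p{i}" for i in range(40)],
                         "x0": x,
                         "emo": 0.5 * x + rng.standard_normal(40)})
    plans = make_splits(data, "trait", 1, seed=14)
    r2, used = fit_final_and_score(data, plans[0].train_idx,
                                   plans[0].test_idx, ["x0"], "emo", "trait")
    tr = data.iloc[plans[0].train_idx]
    te = data.iloc[plans[0].test_idx]
    X = np.column_stack([np.ones(len(tr)), tr["x0"]])
    beta, *_ = np.linalg.lstsq(X, tr["emo"], rcond=None)
    yhat = np.column_stack([np.ones(len(te)), te["x0"]]) @ beta
    assert r2 == pytest.approx(predictive_r2(te["emo"].to_numpy(), yhat),
                               abs=1e-12)


def test_momentary_mixed_model_beats_null_on_strong_signal():
    data = panel(n_groups=15, n_per=40, effects=(0.6,), seed=15)
    res = resample_splits(data, "emo", ["x0", "n0"], "momentary",
                          n_splits=6, seed=16, feature_set="demo")
    assert res.n_failed == 0
    assert res.mean > 0.15


def test_resampling_preserves_negative_r2():
    data = panel(n_groups=8, n_per=10, effects=(), n_noise=3, seed=17)
    res = resample_splits(data, "emo", ["n0", "n1", "n2"], "momentary",
                          n_splits=8, seed=18)
    assert min(res.r2_per_split) < 0          # noise models score below mean


# ------------------------------------------------------------------ combined

def test_combined_sets_union_and_row_intersection():
    qf = feature_sets()
    assert qf["speech_combined"] == qf["speech_content"] + qf["speech_form"]
    n = 30
    rng = np.random.default_rng(19)
    data = pd.DataFrame({
        "participant_id": "p0",
        "speech_content.posemo": rng.normal(size=n),
        "speech_form.f0_mean": rng.normal(size=n),
        "writing_form.typing_speed": rng.normal(size=n)})
    data.loc[:9, "speech_content.posemo"] = np.nan
    data.loc[:9, "speech_form.f0_mean"] = np.nan
    data.loc[20:, "writing_form.typing_speed"] = np.nan
    rows, pool = combine_feature_sets(
        data, ["speech_combined", "writing_form"],
        {"speech_combined": ["speech_content.posemo", "speech_form.f0_mean"],
         "writing_form": ["writing_form.typing_speed"]})
    assert len(rows) == 10                      # rows 10..19 carry everything
    assert pool == ["speech_content.posemo", "speech_form.f0_mean",
                    "writing_form.typing_speed"]


def test_combined_sets_disjoint_rows_error():
    data = pd.DataFrame({
        "participant_id": "p0",
        "speech_form.f0_mean": [1.0, np.nan],
        "writing_form.typing_speed": [np.nan, 2.0]})
    with pytest.raises(ValueError):
        combine_feature_sets(
            data, ["speech_form", "writing_form"],
            {"speech_form": ["speech_form.f0_mean"],
             "writing_form": ["writing_form.typing_speed"]})
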