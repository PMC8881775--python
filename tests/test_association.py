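"""Multilevel slopes, trait Spearman and the Holm step-down procedure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from esmlang.association import (correlation_table, holm_adjust,
                                 momentary_slope, trait_spearman)
from esmlang.multilevel import fit_random_intercept

from conftest import balanced_panel


def brute_force_holm(p, alpha=0.05):
    """Literal step-down enumeration, independent of the implementation."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for k in range(m):
        thresholds_ok = all(
            p[order[j]] <= alpha / (m - j) for j in range(k + 1))
        if thresholds_ok:
            flags[order[k]] = True
        else:
            break
    return flags


def spearman_rank_formula(x, y):
    """Brute-force Spearman via mid-ranks and the Pearson-of-ranks identity."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


# ---------------------------------------------------------------- multilevel

def test_reml_agrees_with_statsmodels_mixedlm():
    import statsmodels.api as sm
    rng = np.random.default_rng(3)
    for rep in range(3):
        g = np.repeat(np.arange(12), 15 + 5 * rep)
        n = len(g)
        x = rng.standard_normal(n)
        y = (0.3 * x + np.repeat(rng.standard_normal(12) * 0.7,
                                 15 + 5 * rep) + rng.standard_normal(n))
        fit = fit_random_intercept(y, x, g)
        ref = sm.MixedLM(y, np.column_stack([np.ones(n), x]), groups=g
                         ).fit(reml=True)
        assert fit.slope == pytest.approx(ref.fe_params[1], abs=1e-5)
        assert fit.slope_se == pytest.approx(ref.bse_fe[1], rel=1e-3)
        assert fit.sigma_u2 == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]),
                                             abs=2e-3)


def test_self_regression_slope_is_one():
    data = balanced_panel(r=0.5, seed=1)
    data["same"] = data["emo"]
    est, p, n = momentary_slope(data, "emo", "same")
    assert est == pytest.approx(1.0, abs=1e-8)
    assert p < 1e-10


def test_recovers_planted_within_person_correlation():
    data = balanced_panel(n_groups=60, n_per=80, r=0.25, seed=5)
    est, p, _ = momentary_slope(data, "emo", "feat")
    assert est == pytest.approx(0.25, abs=0.04)


def test_null_slope_pvalues_are_calibrated():
    # plug-in REML Wald p-values are mildly anticonservative on tiny panels
    # (~0.067 at nominal 0.05 for 10 participants x 12 beeps); the band
    # covers that behaviour while still catching gross miscalibration
    hits = 0
    for seed in range(100):
        data = balanced_panel(n_groups=10, n_per=12, r=0.0, seed=100 + seed)
        _, p, _ = momentary_slope(data, "emo", "feat")
        hits += p < 0.05
    assert 1 <= hits <= 15


def test_slope_matches_pooled_within_person_pearson():
    # on standardized balanced panels the REML slope is the pooled
    # within-person correlation up to small-sample reweighting
    for seed in (2, 3, 4):
        data = balanced_panel(n_groups=30, n_per=40, r=0.3, seed=seed)
        est, _, _ = momentary_slope(data, "emo", "feat")
        pooled = np.corrcoef(data["feat"], data["emo"])[0, 1]
        assert est == pytest.approx(pooled, abs=0.02)


def test_momentary_slope_requires_replication():
    data = pd.DataFrame({"participant_id": ["a", "b"],
                         "emo": [0.1, 0.2], "feat": [0.3, 0.4]})
    with pytest.raises(ValueError):
        momentary_slope(data, "emo", "feat")


# ------------------------------------------------------------------ spearman

def test_spearman_extremes():
    df = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0) ** 2})
    rho, p, _ = trait_spearman(df, "a", "b")
    assert rho == pytest.approx(1.0)
    df["c"] = -df["b"]
    assert trait_spearman(df, "a", "c")[0] == pytest.approx(-1.0)


def test_spearman_six_point_hand_example():
    df = pd.DataFrame({"a": [1, 2, 3, 4, 5, 6], "b": [2, 1, 4, 3, 6, 5]})
    rho, _, _ = trait_spearman(df, "a", "b")
    assert rho == pytest.approx(spearman_rank_formula(df["a"], df["b"]))
    # classical no-tie formula: 1 - 6*sum(d^2)/(n(n^2-1)) with d = 1 each
    assert rho == pytest.approx(1 - 6 * 6 / (6 * 35))


def test_spearman_monotone_invariance():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"a": rng.standard_normal(40),
                       "b": rng.standard_normal(40)})
    base = trait_spearman(df, "a", "b")[0]
    df["a"] = np.exp(3 * df["a"])               # strictly monotone transform
    assert trait_spearman(df, "a", "b")[0] == pytest.approx(base)


def test_spearman_guards():
    df = pd.DataFrame({"a": [1.0] * 8, "b": np.arange(8.0)})
    with pytest.raises(ValueError):
        trait_spearman(df, "a", "b")
    with pytest.raises(ValueError):
        trait_spearman(df.head(3), "b", "b")


# ---------------------------------------------------------------------- holm

def test_holm_hand_examples():
    assert not holm_adjust([1.0, 1.0, 1.0]).any()
    assert holm_adjust([0.01, 0.02, 0.05]).all()
    assert not holm_adjust([0.02, 0.03, 0.04]).any()


def test_holm_rejects_invalid_p():
    with pytest.raises(ValueError):
        holm_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        holm_adjust([])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=20),
       st.sampled_from([0.01, 0.05, 0.1]))
def test_holm_matches_brute_force_and_is_subset_of_raw(p, alpha):
    flags = holm_adjust(p, alpha=alpha)
    assert np.array_equal(flags, brute_force_holm(p, alpha=alpha))
    assert np.all(~flags | (np.asarray(p) < alpha + 1e-12))
    # monotone in alpha
    flags_big = holm_adjust(p, alpha=min(1.0, 2 * alpha))
    assert np.all(~flags | flags_big)


# --------------------------------------------------------------------- table

def test_correlation_table_family_and_flags():
    rng = np.random.default_rng(8)
    frames = []
    for g in range(20):
        n = 30
        d = {"participant_id": f"p{g:02d}"}
        strong = rng.standard_normal(n)
        d["emo_a"] = (strong - strong.mean()) / strong.std(ddof=1)
        for j in range(5):
            x = (0.9 * strong if j == 0 else rng.standard_normal(n))
            x = x + 0.3 * rng.standard_normal(n)
            d[f"f{j}"] = (x - x.mean()) / x.std(ddof=1)
        frames.append(pd.DataFrame(d))
    data = pd.concat(frames, ignore_index=True)
    tab = correlation_table(data, ["emo_a"], [f"f{j}" for j in range(5)],
                            "momentary", family="demo")
    assert len(tab) == 5
    assert (tab["family"] == "demo").all()
    strong_row = tab[tab.feature == "f0"].iloc[0]
    assert strong_row["significant"] and strong_row["estimate"] > 0.7
    # failed cells are retained but not flagged
    data["const"] = 1.0
    tab2 = correlation_table(data, ["emo_a"], ["f0", "const"], "momentary")
    assert tab2[tab2.feature == "const"].iloc[0]["failed"]
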