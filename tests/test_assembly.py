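"""Linkage, inclusion accounting, standardization and trait aggregation."""

import numpy as np
import pandas as pd
import pytest

from esmlang.assembly import (aggregate_traits, apply_inclusion,
                              compliance_stats, link_voice, participant_flow,
                              standardize_within)

MIN = 60_000


def surveys_at(times, pid="p000"):
    return pd.DataFrame({"participant_id": pid,
                         "timestamp_ms": [t * MIN for t in times]})


def recordings_at(times, pid="p000"):
    return pd.DataFrame({"participant_id": pid,
                         "recording_ms": [int(t * MIN) for t in times]})


# ------------------------------------------------------------------- linkage

def test_recording_within_window_links():
    res = link_voice(surveys_at([100]), recordings_at([104]))
    assert len(res.linked) == 1 and res.linked.iloc[0]["gap_ms"] == 4 * MIN


def test_recording_outside_window_unlinked():
    res = link_voice(surveys_at([100]), recordings_at([106.5]))
    assert len(res.linked) == 0
    assert res.unlinked.iloc[0]["reason"] == "no survey within window"


def test_competing_recordings_keep_nearer_log_other():
    res = link_voice(surveys_at([100]), recordings_at([102, 104]))
    assert len(res.linked) == 1
    assert res.linked.iloc[0]["recording_ms"] == 102 * MIN
    assert res.unlinked.iloc[0]["recording_ms"] == 104 * MIN
    assert res.unlinked.iloc[0]["reason"] == "competing recording was nearer"


def test_exact_match_takes_precedence():
    res = link_voice(surveys_at([100, 103]), recordings_at([100, 101]))
    by_rec = res.linked.set_index("recording_ms")["survey_ms"]
    assert by_rec[100 * MIN] == 100 * MIN
    assert by_rec[101 * MIN] == 103 * MIN


def test_linkage_is_injective_both_ways():
    rng = np.random.default_rng(2)
    surv = surveys_at(sorted(rng.choice(np.arange(0, 2000, 10), 60,
                                        replace=False)))
    recs = recordings_at(sorted(rng.uniform(0, 2000, 90)))
    res = link_voice(surv, recs)
    assert res.linked["recording_ms"].is_unique
    assert res.linked["survey_ms"].is_unique
    assert len(res.linked) + len(res.unlinked) == 90
    assert (res.linked["gap_ms"] <= 5 * MIN).all()


# ---------------------------------------------------------------- accounting

def test_recruitment_flow_worked_example():
    flow = participant_flow(screened=230, screen_excluded=116, agreed=69,
                            consent_refused=2, install_failed=2)
    assert flow["eligible"] == 114
    assert flow["enrolled"] == 65


def test_recruitment_flow_rejects_inconsistency():
    with pytest.raises(ValueError):
        participant_flow(100, 120, 10, 0, 0)


def test_inclusion_threshold_boundary():
    answered = pd.Series({"a": 29, "b": 30, "c": 90})
    linked = pd.Series({"a": 5, "b": 1, "c": 0})
    out = apply_inclusion(answered, linked)
    assert out["retained"] == ["b"]
    rep = out["report"]
    assert rep["excluded_low_response"] == 1      # a
    assert rep["excluded_no_stream"] == 1         # c
    assert rep["input"] == rep["retained"] + rep["excluded_low_response"] \
        + rep["excluded_no_stream"]


def test_inclusion_empty_cohort_raises():
    with pytest.raises(ValueError):
        apply_inclusion(pd.Series(dtype=float), pd.Series(dtype=float))


# ------------------------------------------------------------ standardization

def test_standardize_two_values_hand_example():
    df = pd.DataFrame({"participant_id": ["a", "a"], "x": [40.0, 60.0]})
    out, log = standardize_within(df, ["x"])
    assert out["x"].tolist() == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])
    assert len(log) == 0


def test_standardize_constant_and_singleton_flagged():
    df = pd.DataFrame({"participant_id": ["a", "a", "b"],
                       "x": [50.0, 50.0, 1.0]})
    out, log = standardize_within(df, ["x"])
    assert out["x"].isna().all()
    reasons = set(log["reason"])
    assert reasons == {"zero within-person variance",
                       "fewer than 2 observations"}


def test_standardize_postcondition_and_idempotence():
    rng = np.random.default_rng(4)
    df = pd.DataFrame({
        "participant_id": np.repeat([f"p{i}" for i in range(5)], 20),
        "x": rng.normal(50, 10, 100), "y": rng.normal(0, 1, 100)})
    z1, _ = standardize_within(df, ["x", "y"])
    for _, g in z1.groupby("participant_id"):
        assert abs(g["x"].mean()) < 1e-9
        assert abs(g["x"].std(ddof=1) - 1) < 1e-9
    z2, _ = standardize_within(z1, ["x", "y"])
    assert np.allclose(z1["x"], z2["x"], atol=1e-9)


# ---------------------------------------------------------------------- trait

@pytest.mark.parametrize("items, expected", [
    ((0, 0, 0, 0, 0, 0, 0), 0.0),
    ((0, 1, 1, 0, 2, 1, 2), 1.0),
    ((3, 3, 3, 3, 3, 3, 3), 3.0),
])
def test_dass_depression_subscale_mean(items, expected):
    df = pd.DataFrame({"participant_id": ["a", "a"], "x": [1.0, 3.0]})
    dass = pd.DataFrame([{"participant_id": "a",
                          **{f"dass_{i+1}": v for i, v in enumerate(items)}}])
    out = aggregate_traits(df, ["x"], dass_items=dass)
    assert out.iloc[0]["depression"] == pytest.approx(expected)
    assert out.iloc[0]["x"] == pytest.approx(2.0)


def test_missing_dass_items_yield_missing_depression():
    df = pd.DataFrame({"participant_id": ["a", "b"], "x": [1.0, 2.0]})
    dass = pd.DataFrame([
        {"participant_id": "a", **{f"dass_{i}": 1 for i in range(1, 8)}}])
    out = aggregate_traits(df, ["x"], dass_items=dass).set_index("participant_id")
    assert out.loc["a", "depression"] == 1.0
    assert np.isnan(out.loc["b", "depression"])


def test_trait_dataset_single_row_per_participant(small_datasets):
    trait = small_datasets["trait"]
    assert trait["participant_id"].is_unique


# ----------------------------------------------------------------- compliance

def test_full_compliance_is_one():
    sched = pd.DataFrame({"participant_id": ["a"] * 6, "day": [1, 1, 2, 2, 3, 3],
                          "answered": True})
    stats = compliance_stats(sched, activity_cols=())
    assert stats["mean_compliance"] == 1.0
    assert stats["mean_answered"] == 6
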