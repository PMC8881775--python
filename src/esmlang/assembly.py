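"""Linking, inclusion filtering and analysis-dataset construction.

The raw streams -- ESM surveys, voice-derived feature rows and keyboard
entries -- are joined into one observation table: a voice recording links to
the nearest survey within 5 minutes (exact matches first, injectively both
ways), keyboard entries pool into the hour around each survey.  Participants
enter the analysis cohorts only with at least 30 answered surveys and at
least one linked observation of the relevant stream.

Two analysis datasets follow: the momentary dataset standardizes every
variable within participant over that participant's linked observations
(sample SD, n-1), so multilevel slopes read as pooled within-person
correlations; the trait dataset aggregates each participant to one row of
means plus the DASS depression subscale (mean of 7 items scored 0-3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LinkResult",
    "link_voice",
    "participant_flow",
    "apply_inclusion",
    "standardize_within",
    "aggregate_traits",
    "compliance_stats",
]

VOICE_LINK_WINDOW_MS = 5 * 60 * 1000
MIN_RESPONSES = 30


@dataclass(frozen=True)
class LinkResult:
    """Voice-to-survey linkage with provenance."""

    linked: pd.DataFrame      # participant_id, recording_ms, survey_ms, gap_ms, exact
    unlinked: pd.DataFrame    # recordings left without a survey + reason


def link_voice(surveys: pd.DataFrame, recordings: pd.DataFrame,
               window_ms: int = VOICE_LINK_WINDOW_MS) -> LinkResult:
    """Injective nearest-neighbour linkage of recordings to surveys.

    Exact timestamp matches take precedence; remaining recordings link to
    the nearest free survey of the same participant within the window.
    When two recordings compete for one survey the nearer wins and the
    other is logged as unlinked.
    """
    linked_rows, unlinked_rows = [], []
    survey_keys = surveys[["participant_id", "timestamp_ms"]]
    for pid, recs in recordings.groupby("participant_id", sort=True):
        surv_ts = survey_keys.loc[survey_keys["participant_id"] == pid,
                                  "timestamp_ms"].to_numpy()
        pairs = []
        for rec_ms in recs["recording_ms"].to_numpy():
            if len(surv_ts) == 0:
                continue
            gaps = np.abs(surv_ts - rec_ms)
            order = np.argsort(gaps, kind="stable")
            for j in order[:4]:
                if gaps[j] <= window_ms:
                    pairs.append((int(gaps[j]), int(rec_ms), int(surv_ts[j])))
        pairs.sort()
        used_rec, used_surv = set(), set()
        for gap, rec_ms, s_ms in pairs:
            if rec_ms in used_rec or s_ms in used_surv:
                continue
            used_rec.add(rec_ms)
            used_surv.add(s_ms)
            linked_rows.append({"participant_id": pid, "recording_ms": rec_ms,
                                "survey_ms": s_ms, "gap_ms": gap,
                                "exact": gap == 0})
        for rec_ms in recs["recording_ms"].to_numpy():
            if int(rec_ms) not in used_rec:
                reason = ("no survey within window"
                          if len(surv_ts) == 0
                          or np.min(np.abs(surv_ts - rec_ms)) > window_ms
                          else "competing recording was nearer")
                unlinked_rows.append({"participant_id": pid,
                                      "recording_ms": int(rec_ms),
                                      "reason": reason})
    return LinkResult(
        linked=pd.DataFrame(linked_rows, columns=[
            "participant_id", "recording_ms", "survey_ms", "gap_ms", "exact"]),
        unlinked=pd.DataFrame(unlinked_rows, columns=[
            "participant_id", "recording_ms", "reason"]),
    )


def participant_flow(screened: int, screen_excluded: int, agreed: int,
                     consent_refused: int, install_failed: int) -> dict:
    """Recruitment accounting: screening -> eligibility -> enrolment.

    Pure arithmetic over the recruitment stages, with conservation checks,
    e.g. 230 screened - 116 excluded = 114 eligible; 69 attendees minus 2
    consent refusals and 2 failed installations = 65 enrolled.
    """
    eligible = screened - screen_excluded
    if eligible < 0 or agreed > eligible:
        raise ValueError("inconsistent recruitment counts")
    enrolled = agreed - consent_refused - install_failed
    if enrolled < 0:
        raise ValueError("inconsistent laboratory counts")
    return {"screened": screened, "screen_excluded": screen_excluded,
            "eligible": eligible, "agreed": agreed,
            "consent_refused": consent_refused,
            "install_failed": install_failed, "enrolled": enrolled}


def apply_inclusion(answered_counts: pd.Series, linked_counts: pd.Series,
                    min_responses: int = MIN_RESPONSES) -> dict:
    """Retain participants with >= min_responses answered surveys and >= 1
    linked observation of the stream; emit stage-by-stage accounting.

    ``answered_counts`` and ``linked_counts`` are indexed by participant.
    """
    if len(answered_counts) == 0:
        raise ValueError("empty cohort")
    linked = linked_counts.reindex(answered_counts.index, fill_value=0)
    enough = answered_counts >= min_responses
    any_stream = linked >= 1
    retained = answered_counts.index[enough & any_stream]
    report = {
        "input": int(len(answered_counts)),
        "excluded_low_response": int((~enough).sum()),
        "excluded_no_stream": int((enough & ~any_stream).sum()),
        "retained": int(len(retained)),
    }
    assert report["input"] == (report["retained"]
                               + report["excluded_low_response"]
                               + report["excluded_no_stream"])
    return {"retained": list(retained), "report": report}


def standardize_within(data: pd.DataFrame, columns: list[str],
                       group_col: str = "participant_id"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-participant z-scores over each variable's observed rows.

    Each column is centred and scaled per participant with the sample
    (n-1) SD over that participant's non-missing values.  Variables with
    fewer than two observations or zero variance for a participant become
    missing and are logged.  Returns (standardized copy, log table).
    """
    out = data.copy()
    log_rows = []
    grouped = data.groupby(group_col)
    for col in columns:
        g = grouped[col]
        mean = g.transform("mean")
        sd = g.transform("std")     # pandas default ddof=1
        count = g.transform("count")
        bad_few = count < 2
        bad_sd = ~bad_few & ((sd == 0) | ~np.isfinite(sd))
        z = (data[col] - mean) / sd
        z[bad_few | bad_sd] = np.nan
        out[col] = z
        if bad_few.any() or bad_sd.any():
            stats = pd.DataFrame({"few": bad_few, "flat": bad_sd,
                                  group_col: data[group_col]})
            per = stats.groupby(group_col)[["few", "flat"]].any()
            for pid, row in per.iterrows():
                if row["few"]:
                    log_rows.append({"participant_id": pid, "variable": col,
                                     "reason": "fewer than 2 observations"})
                elif row["flat"]:
                    log_rows.append({"participant_id": pid, "variable": col,
                                     "reason": "zero within-person variance"})
    log = pd.DataFrame(log_rows, columns=["participant_id", "variable", "reason"])
    return out, log


def aggregate_traits(data: pd.DataFrame, columns: list[str],
                     dass_items: pd.DataFrame | None = None,
                     group_col: str = "participant_id") -> pd.DataFrame:
    """One row per participant: means over linked observations (+ DASS).

    ``dass_items`` carries columns dass_1..dass_7 (each 0-3); the depression
    score is their mean.  Participants with missing items get a missing
    depression value.
    """
    agg = data.groupby(group_col)[columns].mean().reset_index()
    if dass_items is not None:
        item_cols = [f"dass_{i}" for i in range(1, 8)]
        missing = [c for c in item_cols if c not in dass_items.columns]
        if missing:
            raise ValueError(f"missing DASS item columns: {missing}")
        dass = dass_items[[group_col, *item_cols]].copy()
        bad = ~dass[item_cols].isin([0, 1, 2, 3]).all(axis=1)
        dep = dass[item_cols].mean(axis=1)
        dep[bad | dass[item_cols].isna().any(axis=1)] = np.nan
        dass["depression"] = dep
        agg = agg.merge(dass[[group_col, "depression"]], on=group_col, how="left")
    return agg


def compliance_stats(schedule: pd.DataFrame,
                     activity_cols: tuple[str, ...] = ("has_voice", "has_keyboard")
                     ) -> dict:
    """Compliance summary plus within-person day-vs-activity correlations.

    ``schedule`` needs participant_id, day, answered and the activity flag
    columns.  The day correlation pools per-participant-centred daily counts
    (a within-person Pearson correlation of study day with daily activity).
    """
    per = schedule.groupby("participant_id")["answered"].agg(["sum", "count"])
    frac = per["sum"] / per["count"]
    out = {
        "mean_compliance": float(frac.mean()),
        "sd_compliance": float(frac.std(ddof=1)) if len(frac) > 1 else float("nan"),
        "min_compliance": float(frac.min()),
        "max_compliance": float(frac.max()),
        "mean_answered": float(per["sum"].mean()),
        "scheduled_per_participant": int(per["count"].iloc[0]) if len(per) else 0,
    }
    for col in activity_cols:
        if col not in schedule.columns:
            continue
        daily = (schedule.groupby(["participant_id", "day"])[col]
                 .sum().reset_index())
        centred = daily.copy()
        for v in ("day", col):
            centred[v] = daily.groupby("participant_id")[v].transform(
                lambda s: s - s.mean())
        num = (centred["day"] * centred[col]).sum()
        den = np.sqrt((centred["day"] ** 2).sum() * (centred[col] ** 2).sum())
        out[f"day_corr_{col}"] = float(num / den) if den > 0 else float("nan")
    return out
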