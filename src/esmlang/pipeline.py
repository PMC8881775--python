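"""End-to-end feature extraction and analysis-dataset construction.

Bridges the raw study artifacts (transcripts, WAV clips, keystroke logs,
surveys) and the statistical stages: it extracts the four feature families,
links them to surveys, applies the inclusion filters and produces the
momentary (within-person standardized) and trait (aggregated) datasets that
the association and prediction modules consume.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly, keyboard as kb
from .acoustics import extract_acoustic_features, read_wav
from .lexicon import (SPEECH_CONTENT_FEATURES, WRITING_CONTENT_FEATURES,
                      Lexicon, extract_content_features, load_demo_lexicon)
from .simulate.config import EMOTIONS, qualified_features
from .simulate.study import SimulatedStudy

__all__ = [
    "extract_voice_features",
    "extract_keyboard_features",
    "build_datasets",
    "datasets_from_truth",
]


def extract_voice_features(study: SimulatedStudy | None = None,
                           voice_dir: str | Path | None = None,
                           lexicon: Lexicon | None = None,
                           with_audio: bool = True) -> pd.DataFrame:
    """Speech content + form features, one row per recording.

    Works from an in-memory study or from a ``voice/`` directory of
    ``<pid>_<ms>.wav`` / ``.txt`` pairs.
    """
    lexicon = lexicon or (study.lexicon if study else None) or load_demo_lexicon()
    rows = []
    if study is not None:
        keys = sorted(set(study.transcripts) | set(study.clips))
        for pid, ms in keys:
            row = {"participant_id": pid, "recording_ms": ms}
            text = study.transcripts.get((pid, ms))
            if text is not None:
                cv = extract_content_features(text, lexicon)
                row.update({f"speech_content.{k}": v
                            for k, v in cv.as_dict().items()})
                row["recognized_fraction"] = cv.recognized_fraction
            if with_audio and (pid, ms) in study.clips:
                av = extract_acoustic_features(study.get_clip((pid, ms)))
                row.update({f"speech_form.{k}": v
                            for k, v in av.as_dict().items()})
            rows.append(row)
    else:
        voice_dir = Path(voice_dir)
        for txt in sorted(voice_dir.glob("*.txt")):
            pid, ms = txt.stem.rsplit("_", 1)
            row = {"participant_id": pid, "recording_ms": int(ms)}
            cv = extract_content_features(txt.read_text("utf-8"), lexicon)
            row.update({f"speech_content.{k}": v for k, v in cv.as_dict().items()})
            row["recognized_fraction"] = cv.recognized_fraction
            wav = txt.with_suffix(".wav")
            if with_audio and wav.exists():
                av = extract_acoustic_features(read_wav(wav))
                row.update({f"speech_form.{k}": v for k, v in av.as_dict().items()})
            rows.append(row)
    return pd.DataFrame(rows)


def extract_keyboard_features(surveys: pd.DataFrame, entries: pd.DataFrame,
                              keystrokes: pd.DataFrame,
                              lexicon: Lexicon | None = None) -> pd.DataFrame:
    """Writing form + content features, one row per survey with a non-empty bin.

    Typing dynamics come from the keystroke events via per-entry summaries
    pooled into the +-30 min bin; writing content from the concatenated
    entry messages of the same bin.
    """
    lexicon = lexicon or load_demo_lexicon()
    summaries = kb.summarize_entries(keystrokes)
    msg = entries[["participant_id", "entry_id", "message"]]
    summaries = summaries.merge(msg, on=["participant_id", "entry_id"], how="left")
    rows = []
    for pid, surv in surveys.groupby("participant_id", sort=True):
        ent = summaries[summaries["participant_id"] == pid]
        for ts in surv["timestamp_ms"].to_numpy():
            vec = kb.bin_keyboard(ent, int(ts))
            if vec is None:
                continue
            row = {"participant_id": pid, "timestamp_ms": int(ts)}
            row.update({f"writing_form.{k}": v for k, v in vec.as_dict().items()})
            first = ent["first_press_ms"]
            in_bin = ent[(first >= ts - kb.HALF_WINDOW_MS)
                         & (first < ts + kb.HALF_WINDOW_MS)]
            text = " ".join(str(m) for m in in_bin.sort_values("first_press_ms")
                            ["message"].fillna(""))
            cv = extract_content_features(text, lexicon)
            row.update({f"writing_content.{k}": v
                        for k, v in cv.as_dict(include_exclam=True).items()})
            row["writing_content.pos_emojis"] = cv.pos_emojis
            row["writing_content.neg_emojis"] = cv.neg_emojis
            rows.append(row)
    return pd.DataFrame(rows)


def _inclusion_accounting(schedule: pd.DataFrame, obs: pd.DataFrame) -> dict:
    answered = schedule.groupby("participant_id")["answered"].sum()
    voice_counts = obs.groupby("participant_id")["has_voice_obs"].sum()
    kb_counts = obs.groupby("participant_id")["has_keyboard_obs"].sum()
    voice = assembly.apply_inclusion(answered, voice_counts)
    keybd = assembly.apply_inclusion(answered, kb_counts)
    union = assembly.apply_inclusion(answered, (voice_counts.reindex(answered.index, fill_value=0)
                                                + kb_counts.reindex(answered.index, fill_value=0)))
    return {"voice": voice, "keyboard": keybd, "union": union}


def build_datasets(surveys: pd.DataFrame, schedule: pd.DataFrame,
                   voice_features: pd.DataFrame | None,
                   keyboard_features: pd.DataFrame | None,
                   dass: pd.DataFrame | None = None
                   ) -> dict:
    """Link, filter, standardize and aggregate into analysis datasets.

    Returns a dict with ``momentary`` (within-person standardized),
    ``trait`` (per-participant aggregates + DASS depression), ``cohorts``
    (per-stream retained participants), ``accounting`` and the
    standardization ``log``.
    """
    obs = surveys.copy()
    feat_cols: list[str] = []

    if voice_features is not None and len(voice_features):
        link = assembly.link_voice(
            surveys[["participant_id", "timestamp_ms"]],
            voice_features[["participant_id", "recording_ms"]])
        vf = voice_features.merge(
            link.linked[["participant_id", "recording_ms", "survey_ms"]],
            on=["participant_id", "recording_ms"], how="inner")
        vf = vf.rename(columns={"survey_ms": "timestamp_ms"})
        vf = vf.drop(columns=["recording_ms", "recognized_fraction"],
                     errors="ignore")
        obs = obs.merge(vf, on=["participant_id", "timestamp_ms"], how="left")
        feat_cols += [c for c in vf.columns if c.startswith("speech_")]
        link_log = link.unlinked
    else:
        link_log = pd.DataFrame()

    if keyboard_features is not None and len(keyboard_features):
        obs = obs.merge(keyboard_features, on=["participant_id", "timestamp_ms"],
                        how="left")
        feat_cols += [c for c in keyboard_features.columns
                      if c.startswith("writing_")]

    speech_cols = [c for c in feat_cols if c.startswith("speech_")]
    writing_cols = [c for c in feat_cols if c.startswith("writing_")]
    obs["has_voice_obs"] = (obs[speech_cols].notna().any(axis=1)
                            if speech_cols else False)
    obs["has_keyboard_obs"] = (obs[writing_cols].notna().any(axis=1)
                               if writing_cols else False)
    obs = obs[obs["has_voice_obs"] | obs["has_keyboard_obs"]].reset_index(drop=True)
    if len(obs) == 0:
        raise ValueError("no linked observations")

    accounting = _inclusion_accounting(schedule, obs)
    cohorts = {k: v["retained"] for k, v in accounting.items()}
    union = set(cohorts["union"])
    obs = obs[obs["participant_id"].isin(union)].reset_index(drop=True)

    analysis_cols = list(EMOTIONS) + feat_cols
    momentary, log = assembly.standardize_within(obs, analysis_cols)
    trait = assembly.aggregate_traits(obs, analysis_cols, dass_items=dass)

    return {"momentary": momentary, "trait": trait, "cohorts": cohorts,
            "accounting": {k: v["report"] for k, v in accounting.items()},
            "standardization_log": log, "link_log": link_log,
            "observations": obs}


def datasets_from_truth(study: SimulatedStudy, dass: pd.DataFrame | None = None
                        ) -> dict:
    """Analysis datasets using the latent feature values as features.

    For calibration experiments: skips rendering and extraction entirely,
    the ground-truth latent x of each observed stream stands in for the
    extracted feature vector.
    """
    lat = study.latents
    qf = qualified_features()
    voice_cols = qf["speech_content"] + qf["speech_form"]
    kb_cols = qf["writing_content"] + qf["writing_form"]
    keep = ["participant_id", "timestamp_ms"]
    present = [c for c in voice_cols + kb_cols if c in lat.columns]
    obs = study.surveys.merge(lat[keep + present], on=keep, how="left")

    feat_cols = present
    speech_cols = [c for c in feat_cols if c.startswith("speech_")]
    writing_cols = [c for c in feat_cols if c.startswith("writing_")]
    obs["has_voice_obs"] = (obs[speech_cols].notna().any(axis=1)
                            if speech_cols else False)
    obs["has_keyboard_obs"] = (obs[writing_cols].notna().any(axis=1)
                               if writing_cols else False)
    obs = obs[obs["has_voice_obs"] | obs["has_keyboard_obs"]].reset_index(drop=True)
    accounting = _inclusion_accounting(study.schedule, obs)
    cohorts = {k: v["retained"] for k, v in accounting.items()}
    obs = obs[obs["participant_id"].isin(set(cohorts["union"]))].reset_index(drop=True)
    analysis_cols = list(EMOTIONS) + feat_cols
    momentary, log = assembly.standardize_within(obs, analysis_cols)
    trait = assembly.aggregate_traits(obs, analysis_cols,
                                      dass_items=dass if dass is not None
                                      else study.dass_table)
    return {"momentary": momentary, "trait": trait, "cohorts": cohorts,
            "accounting": {k: v["report"] for k, v in accounting.items()},
            "standardization_log": log, "observations": obs}
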