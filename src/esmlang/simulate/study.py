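"""End-to-end synthetic study generation and file export.

``simulate_study`` assembles the full study: per participant a beep
schedule, a stable profile, a latent emotion trajectory, and -- for each
answered beep -- optional voice (WAV + transcript) and keyboard (entries +
keystroke events) observations whose features couple to the emotion state
through the planted loading matrix.  Everything is reproducible from the
configuration seed alone; identical configurations give byte-identical
exports.

Rendering levels trade realism for speed:

* ``"full"``    -- transcripts, waveforms and keystroke logs;
* ``"text"``    -- transcripts and keystroke logs, no audio synthesis;
* ``"truth"``   -- no rendering at all; the latent feature values stand in
  for extracted features (used for large calibration experiments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from ..acoustics import ACOUSTIC_FEATURES, AudioClip
from ..lexicon import Lexicon, load_demo_lexicon
from .config import EMOTIONS, SimulationConfig, qualified_features
from .emotions import EmotionTrajectory, ParticipantProfile, draw_profile, simulate_emotions
from .language import (_content_attenuation, draw_feature_latents,
                       render_keyboard_bin, render_transcript, render_waveform)
from .schedule import build_schedule

__all__ = ["SimulatedStudy", "simulate_study", "write_study"]


def _logit(p):
    return np.log(p / (1.0 - p))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulatedStudy:
    """All artifacts of one synthetic study."""

    config: SimulationConfig
    profiles: list[ParticipantProfile]
    trajectories: list[EmotionTrajectory]
    schedule: pd.DataFrame        # beep-level flags
    surveys: pd.DataFrame         # answered beeps with ratings
    voice_index: pd.DataFrame     # recording timestamps vs survey timestamps
    transcripts: dict = field(default_factory=dict)   # (pid, rec_ms) -> text
    clips: dict = field(default_factory=dict)         # (pid, rec_ms) -> int16 samples
    entries: pd.DataFrame | None = None
    keystrokes: pd.DataFrame | None = None
    latents: pd.DataFrame | None = None               # z and x per observed beep
    acoustic_truth: pd.DataFrame | None = None        # ground-truth parameters
    lexicon: Lexicon | None = None

    def get_clip(self, key) -> AudioClip:
        return AudioClip(samples=self.clips[key] / 32768.0,
                         sample_rate=self.config.sample_rate)

    @property
    def dass_table(self) -> pd.DataFrame:
        rows = [{"participant_id": p.participant_id,
                 **{f"dass_{i+1}": v for i, v in enumerate(p.dass_items)}}
                for p in self.profiles]
        return pd.DataFrame(rows)


def simulate_study(config: SimulationConfig, render: str = "full",
                   include_voice: bool = True, include_keyboard: bool = True,
                   lexicon: Lexicon | None = None) -> SimulatedStudy:
    """Generate a complete synthetic study under one configuration."""
    if render not in ("full", "text", "truth"):
        raise ValueError("render must be 'full', 'text' or 'truth'")
    lexicon = lexicon or load_demo_lexicon()
    qf = qualified_features()
    att_speech = _content_attenuation(config, "speech") if render != "truth" else None
    att_writing = _content_attenuation(config, "writing") if render != "truth" else None

    profiles, trajectories = [], []
    sched_rows, survey_rows, latent_rows = [], [], []
    voice_rows, truth_rows = [], []
    transcripts, clips = {}, {}
    entry_frames, event_frames = [], []
    next_entry_id = 0

    for i in range(config.n_participants):
        profile = draw_profile(config, i)
        schedule = build_schedule(config, i)
        traj = simulate_emotions(config, profile, schedule)
        profiles.append(profile)
        trajectories.append(traj)
        rng = np.random.default_rng(
            np.random.SeedSequence([config.rng_seed, 53, i]))
        pid = profile.participant_id

        v_base = _logit(config.voice_response_base) + profile.voice_offset
        k_base = _logit(config.keyboard_use_base) + profile.keyboard_offset
        for t in range(len(schedule)):
            day = int(traj.day[t])
            answered = bool(traj.answered[t])
            ts = int(traj.timestamps_ms[t])
            has_voice = has_kb = False
            if answered:
                if include_voice:
                    p_v = _sigmoid(v_base - config.voice_response_decay * (day - 1))
                    has_voice = bool(rng.random() < p_v)
                if include_keyboard:
                    p_k = _sigmoid(k_base - config.keyboard_use_decay * (day - 1))
                    has_kb = bool(rng.random() < p_k)
            sched_rows.append({
                "participant_id": pid, "day": day, "beep_index": t,
                "timestamp_ms": ts, "answered": answered,
                "has_voice": has_voice, "has_keyboard": has_kb})
            if not answered:
                continue
            survey_rows.append({
                "participant_id": pid, "timestamp_ms": ts,
                **{e: traj.ratings[t, j] for j, e in enumerate(EMOTIONS)}})
            z = traj.z[t]
            lat = {"participant_id": pid, "timestamp_ms": ts,
                   **{f"z_{e}": z[j] for j, e in enumerate(EMOTIONS)}}

            if has_voice:
                # most recordings start within a few minutes of the survey;
                # a small share misses the 5-minute linkage window
                if rng.random() < 0.03:
                    offset = int(rng.uniform(320_000, 600_000))
                else:
                    offset = int(rng.uniform(0, 240_000))
                rec_ms = ts + offset
                voice_rows.append({"participant_id": pid,
                                   "recording_ms": rec_ms, "survey_ms": ts})
                x_sc = draw_feature_latents(config, z, qf["speech_content"],
                                            rng, att_speech)
                x_sf = draw_feature_latents(config, z, qf["speech_form"], rng)
                lat.update(x_sc)
                lat.update(x_sf)
                if render in ("full", "text"):
                    base_x = {k.split(".", 1)[1]: v for k, v in x_sc.items()}
                    text, _ = render_transcript(config, base_x, "speech",
                                                rng, lexicon)
                    transcripts[(pid, rec_ms)] = text
                if render == "full":
                    base_xf = {k.split(".", 1)[1]: v for k, v in x_sf.items()}
                    voiced = render_waveform(config, base_xf,
                                             profile.base_f0_hz, rng)
                    clips[(pid, rec_ms)] = np.rint(
                        voiced.clip.samples * 32768.0).astype(np.int16)
                    truth_rows.append({"participant_id": pid,
                                       "recording_ms": rec_ms,
                                       **voiced.truth})
            if has_kb:
                x_wf = draw_feature_latents(config, z, qf["writing_form"], rng)
                x_wc = draw_feature_latents(config, z, qf["writing_content"],
                                            rng, att_writing)
                lat.update(x_wf)
                lat.update(x_wc)
                if render in ("full", "text"):
                    base_xc = {k.split(".", 1)[1]: v for k, v in x_wc.items()}
                    base_xf = {k.split(".", 1)[1]: v for k, v in x_wf.items()}
                    entries, events, next_entry_id = render_keyboard_bin(
                        config, base_xf, base_xc, profile.base_typing_speed,
                        ts, next_entry_id, rng, lexicon)
                    for e in entries:
                        e["participant_id"] = pid
                    entry_frames.extend(entries)
                    event_frames.append(pd.DataFrame(
                        events, columns=["entry_id", "key_class",
                                         "press_ms", "release_ms"]
                    ).assign(participant_id=pid))
            latent_rows.append(lat)

    study = SimulatedStudy(
        config=config, profiles=profiles, trajectories=trajectories,
        schedule=pd.DataFrame(sched_rows),
        surveys=pd.DataFrame(survey_rows),
        voice_index=pd.DataFrame(voice_rows, columns=[
            "participant_id", "recording_ms", "survey_ms"]),
        transcripts=transcripts, clips=clips,
        entries=pd.DataFrame(entry_frames) if entry_frames else pd.DataFrame(
            columns=["entry_id", "start_ms", "message", "esm_ms", "participant_id"]),
        keystrokes=(pd.concat(event_frames, ignore_index=True) if event_frames
                    else pd.DataFrame(columns=["entry_id", "key_class",
                                               "press_ms", "release_ms",
                                               "participant_id"])),
        latents=pd.DataFrame(latent_rows),
        acoustic_truth=pd.DataFrame(truth_rows) if truth_rows else None,
        lexicon=lexicon,
    )
    return study


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict:
    """Export a study to CSV / WAV / text / JSON files.

    Layout: ``surveys.csv``, ``schedule.csv``, ``dass.csv``,
    ``voice_index.csv``, ``entries.csv``, ``keystrokes.csv``,
    ``voice/<pid>_<ms>.wav`` + ``.txt`` and ``ground_truth.json``.
    """
    out = Path(out_dir)
    (out / "voice").mkdir(parents=True, exist_ok=True)
    study.surveys.to_csv(out / "surveys.csv", index=False)
    study.schedule.to_csv(out / "schedule.csv", index=False)
    study.dass_table.to_csv(out / "dass.csv", index=False)
    study.voice_index.to_csv(out / "voice_index.csv", index=False)
    study.entries.to_csv(out / "entries.csv", index=False)
    study.keystrokes.to_csv(out / "keystrokes.csv", index=False)
    for (pid, ms), text in study.transcripts.items():
        (out / "voice" / f"{pid}_{ms}.txt").write_text(text, encoding="utf-8")
    for (pid, ms), samples in study.clips.items():
        wavfile.write(out / "voice" / f"{pid}_{ms}.wav",
                      study.config.sample_rate, samples)
    truth = {
        "rng_seed": study.config.rng_seed,
        "latents": study.latents.to_dict(orient="list") if study.latents is not None else {},
    }
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh)
    return {"out_dir": str(out), "n_surveys": len(study.surveys),
            "n_voice": len(study.voice_index), "n_entries": len(study.entries)}
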