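"""Typing-dynamics features from soft-keyboard keystroke logs.

Keystroke events (key class ``character`` or ``backspace``, press/release
timestamps in milliseconds) are first summarized per entry (one message or
note), then pooled into one bin per ESM survey covering the hour around the
survey: counts and durations are summed, typing speed and key-press duration
are averaged unweighted over entries.  Backspaces and typing duration are
additionally expressed relative to the total number of keystrokes in the bin
(characters + backspaces).

Binning uses a closed-left / open-right window ``[esm - 30 min, esm + 30
min)`` and assigns an entry by its first press time only; entries are never
split across bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TYPING_FEATURES",
    "EntrySummary",
    "TypingFeatureVector",
    "summarize_entry",
    "summarize_entries",
    "bin_keyboard",
]

#: The 6 writing-form feature columns, in reporting order.
TYPING_FEATURES = (
    "n_characters", "typing_speed", "avg_key_press_duration",
    "n_entries", "backspaces_rel", "typing_duration_rel",
)

HALF_WINDOW_MS = 30 * 60 * 1000

#: Expected columns of a keystroke event table.
EVENT_COLUMNS = ("participant_id", "entry_id", "key_class", "press_ms", "release_ms")


@dataclass(frozen=True)
class EntrySummary:
    """Per-entry typing dynamics."""

    entry_id: object
    first_press_ms: int
    n_characters: int
    n_backspaces: int
    duration_s: float                 # last release - first press
    typing_speed: float               # characters / duration; NaN if duration 0
    avg_key_press_duration_ms: float  # over all events


@dataclass(frozen=True)
class TypingFeatureVector:
    """Bin-level writing-form features around one ESM survey."""

    n_characters: int
    n_backspaces: int
    typing_speed: float
    avg_key_press_duration: float
    n_entries: int
    total_duration_s: float
    backspaces_rel: float
    typing_duration_rel: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_characters": float(self.n_characters),
            "typing_speed": float(self.typing_speed),
            "avg_key_press_duration": float(self.avg_key_press_duration),
            "n_entries": float(self.n_entries),
            "backspaces_rel": float(self.backspaces_rel),
            "typing_duration_rel": float(self.typing_duration_rel),
        }


def summarize_entry(events: pd.DataFrame) -> EntrySummary:
    """Summarize the keystroke events of a single entry.

    ``events`` needs columns ``key_class``, ``press_ms``, ``release_ms``.
    Raises on an empty event list.  A zero-duration entry with characters
    yields a missing (NaN) typing speed rather than infinity.
    """
    if len(events) == 0:
        raise ValueError("entry without keystroke events")
    if (events["release_ms"] < events["press_ms"]).any():
        raise ValueError("release before press in keystroke events")
    n_char = int((events["key_class"] == "character").sum())
    n_back = int((events["key_class"] == "backspace").sum())
    first = int(events["press_ms"].min())
    last = int(events["release_ms"].max())
    duration = (last - first) / 1000.0
    if duration > 0 and n_char > 0:
        speed = n_char / duration
    else:
        speed = float("nan")
    press_dur = float((events["release_ms"] - events["press_ms"]).mean())
    entry_id = events["entry_id"].iloc[0] if "entry_id" in events else None
    return EntrySummary(
        entry_id=entry_id, first_press_ms=first,
        n_characters=n_char, n_backspaces=n_back,
        duration_s=duration, typing_speed=speed,
        avg_key_press_duration_ms=press_dur,
    )


def summarize_entries(events: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-entry summaries of a keystroke event table.

    Groups by (participant_id, entry_id); returns one row per entry.
    """
    if len(events) == 0:
        return pd.DataFrame(columns=[
            "participant_id", "entry_id", "first_press_ms", "n_characters",
            "n_backspaces", "duration_s", "typing_speed",
            "avg_key_press_duration_ms"])
    if (events["release_ms"] < events["press_ms"]).any():
        raise ValueError("release before press in keystroke events")
    ev = events.assign(
        _char=(events["key_class"] == "character").astype(int),
        _back=(events["key_class"] == "backspace").astype(int),
        _dur=events["release_ms"] - events["press_ms"],
    )
    g = ev.groupby(["participant_id", "entry_id"], sort=True)
    out = g.agg(
        first_press_ms=("press_ms", "min"),
        last_release_ms=("release_ms", "max"),
        n_characters=("_char", "sum"),
        n_backspaces=("_back", "sum"),
        avg_key_press_duration_ms=("_dur", "mean"),
    ).reset_index()
    out["duration_s"] = (out["last_release_ms"] - out["first_press_ms"]) / 1000.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out["typing_speed"] = np.where(
            (out["duration_s"] > 0) & (out["n_characters"] > 0),
            out["n_characters"] / out["duration_s"], np.nan)
    return out.drop(columns="last_release_ms")


def bin_keyboard(entries: pd.DataFrame, esm_ms: int,
                 half_window_ms: int = HALF_WINDOW_MS
                 ) -> TypingFeatureVector | None:
    """Pool entry summaries into the bin ``[esm - w, esm + w)``.

    Counts and durations are summed; typing speed and average key-press
    duration are unweighted means over entries (NaN speeds from degenerate
    entries are skipped).  Returns None for an empty bin: the survey simply
    has no keyboard observation.
    """
    first = entries["first_press_ms"]
    in_bin = entries[(first >= esm_ms - half_window_ms) & (first < esm_ms + half_window_ms)]
    if len(in_bin) == 0:
        return None
    n_char = int(in_bin["n_characters"].sum())
    n_back = int(in_bin["n_backspaces"].sum())
    total_dur = float(in_bin["duration_s"].sum())
    keystrokes = n_char + n_back
    speed = float(np.nanmean(in_bin["typing_speed"])) if in_bin["typing_speed"].notna().any() else float("nan")
    press = float(in_bin["avg_key_press_duration_ms"].mean())
    return TypingFeatureVector(
        n_characters=n_char, n_backspaces=n_back,
        typing_speed=speed, avg_key_press_duration=press,
        n_entries=int(len(in_bin)),
        total_duration_s=total_dur,
        backspaces_rel=n_back / keystrokes if keystrokes else float("nan"),
        typing_duration_rel=total_dur / keystrokes if keystrokes else float("nan"),
    )
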