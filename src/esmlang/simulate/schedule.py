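"""Semi-random daily beep schedules.

The emulated protocol sends 10 notifications a day: the first at a uniform
random time between 10:00 and 11:00, the remaining 9 one each in 9 equal
blocks dividing 11:00-22:00.  Timestamps are milliseconds since the Unix
epoch on a single local clock.
"""

from __future__ import annotations

import numpy as np

from .config import ConfigurationError, SimulationConfig

__all__ = ["build_schedule"]

_MS_PER_DAY = 86_400_000
_MS_PER_HOUR = 3_600_000


def build_schedule(config: SimulationConfig, participant_index: int,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Beep timestamps (ms) for one participant, strictly increasing.

    Only the 10-beeps-per-day protocol has a built-in block structure;
    any other ``beeps_per_day`` raises a configuration error.
    """
    if config.beeps_per_day != 10:
        raise ConfigurationError(
            "beeps_per_day != 10 requires an explicit block definition; "
            "the default protocol schedules 10 beeps per day")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.rng_seed, 11, participant_index]))
    out = np.empty(config.n_days * 10, dtype=np.int64)
    block_ms = 11 * _MS_PER_HOUR / 9.0   # 11:00-22:00 split into 9 blocks
    for d in range(config.n_days):
        day0 = config.start_epoch_ms + d * _MS_PER_DAY
        first = day0 + 10 * _MS_PER_HOUR + int(rng.uniform(0, _MS_PER_HOUR))
        beeps = [first]
        for b in range(9):
            lo = day0 + 11 * _MS_PER_HOUR + b * block_ms
            beeps.append(int(lo + rng.uniform(0, block_ms)))
        out[d * 10:(d + 1) * 10] = beeps
    if not np.all(np.diff(out) > 0):   # block edges guarantee this
        raise AssertionError("schedule not strictly increasing")
    return out
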