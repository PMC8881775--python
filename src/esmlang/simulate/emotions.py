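"""Participant profiles and latent emotion trajectories.

Momentary emotion is modelled as a participant trait mean plus a
unit-variance AR(1) deviation.  Cross-emotion covariance comes from one
shared latent factor: valence and happiness load positively, the negative
emotions negatively, arousal near zero.  Ratings are the latent value scaled
by the within-person SD, shifted by the trait mean and clipped to the 0-100
VAS range (clipping, rather than truncated sampling, is a documented
simplification that mildly biases emotions with extreme trait means).

Answering behaviour: each beep is answered with a per-day probability whose
log-odds decline linearly over the study; participants carry a persistent
engagement offset, and a small subgroup is distinctly poorly engaged, which
reproduces the compliance mean/SD/range and the below-threshold exclusions
of the emulated cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import EMOTIONS, SimulationConfig

__all__ = ["ParticipantProfile", "EmotionTrajectory", "draw_profile", "simulate_emotions"]


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class ParticipantProfile:
    """Stable between-person characteristics of one simulated participant."""

    participant_id: str
    trait_means: dict[str, float]       # VAS units per emotion
    dass_items: tuple[int, ...]         # 7 items, each 0-3
    base_f0_hz: float
    base_typing_speed: float            # characters / second
    engagement_offset: float            # log-odds, survey compliance
    voice_offset: float                 # log-odds, voice prompts
    keyboard_offset: float              # log-odds, keyboard use

    def __post_init__(self):
        if len(self.dass_items) != 7 or any(i not in (0, 1, 2, 3) for i in self.dass_items):
            raise ValueError("DASS depression subscale needs 7 items in {0,1,2,3}")
        if self.base_f0_hz <= 0:
            raise ValueError("base F0 must be positive")
        for emo, mu in self.trait_means.items():
            if not 0.0 <= mu <= 100.0:
                raise ValueError(f"trait mean for {emo} outside VAS range")

    @property
    def dass_depression(self) -> float:
        return float(np.mean(self.dass_items))


@dataclass(frozen=True)
class EmotionTrajectory:
    """Latent states and answering flags over one participant's schedule."""

    participant_id: str
    timestamps_ms: np.ndarray       # (n_beeps,)
    day: np.ndarray                 # 1-based study day per beep
    z: np.ndarray                   # (n_beeps, 7) standardized latent states
    ratings: np.ndarray             # (n_beeps, 7) clipped VAS values
    answered: np.ndarray            # bool

    def __post_init__(self):
        if not np.all(np.diff(self.timestamps_ms) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.ratings < 0) or np.any(self.ratings > 100):
            raise ValueError("ratings outside the VAS range")


def draw_profile(config: SimulationConfig, participant_index: int) -> ParticipantProfile:
    """Draw one participant's stable characteristics."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 23, participant_index]))
    traits = {}
    for emo in EMOTIONS:
        mu = rng.normal(config.trait_means[emo], config.between_person_sd[emo])
        traits[emo] = float(np.clip(mu, 0.0, 100.0))
    # right-skewed depression severity: most subscale means land in [0, 0.75]
    severity = rng.beta(0.8, 4.8)
    items = tuple(int(v) for v in rng.binomial(3, severity, size=7))
    if rng.random() < 0.72:          # cohort was 72% female
        f0 = rng.normal(200.0, 20.0)
    else:
        f0 = rng.normal(120.0, 15.0)
    f0 = float(np.clip(f0, 80.0, 320.0))
    speed = float(np.clip(rng.normal(2.1, 0.5), 0.8, 5.0))
    engagement = float(rng.normal(0.0, config.compliance_sd))
    if rng.random() < config.low_engagement_frac:
        engagement += config.low_engagement_shift
    return ParticipantProfile(
        participant_id=f"p{participant_index:03d}",
        trait_means=traits, dass_items=items,
        base_f0_hz=f0, base_typing_speed=speed,
        engagement_offset=engagement,
        voice_offset=float(rng.normal(0.0, config.voice_response_sd)),
        keyboard_offset=float(rng.normal(0.0, config.keyboard_use_sd)),
    )


def simulate_emotions(config: SimulationConfig, profile: ParticipantProfile,
                      schedule_ms: np.ndarray) -> EmotionTrajectory:
    """AR(1) latent emotion states plus answering flags along a schedule.

    The shared factor g_t and the emotion-specific residuals are independent
    stationary AR(1) processes with unit variance at the beep lag;
    z_e = w_e * g + sqrt(1 - w_e^2) * u_e has unit variance and the
    cross-emotion correlation w_e * w_f.
    """
    pidx = int(profile.participant_id.lstrip("p"))
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 37, pidx]))
    n = len(schedule_ms)
    phi = config.emotion_ar_coefficient
    innov_sd = np.sqrt(1.0 - phi ** 2)

    g = np.empty(n)
    u = np.empty((n, len(EMOTIONS)))
    g[0] = rng.standard_normal()
    u[0] = rng.standard_normal(len(EMOTIONS))
    for t in range(1, n):
        g[t] = phi * g[t - 1] + innov_sd * rng.standard_normal()
        u[t] = phi * u[t - 1] + innov_sd * rng.standard_normal(len(EMOTIONS))
    w = np.array([config.shared_factor_loadings.get(e, 0.0) for e in EMOTIONS])
    z = w * g[:, None] + np.sqrt(1.0 - w ** 2) * u

    mu = np.array([profile.trait_means[e] for e in EMOTIONS])
    sd = np.array([config.within_person_sd[e] for e in EMOTIONS])
    ratings = np.clip(mu + sd * z, 0.0, 100.0)

    day = 1 + (schedule_ms - config.start_epoch_ms) // 86_400_000
    day = day.astype(int)
    base = _logit(config.compliance_base) + profile.engagement_offset
    p_answer = _sigmoid(base - config.compliance_decay * (day - 1))
    answered = rng.random(n) < p_answer

    return EmotionTrajectory(
        participant_id=profile.participant_id,
        timestamps_ms=np.asarray(schedule_ms, dtype=np.int64),
        day=day, z=z, ratings=ratings, answered=answered,
    )
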