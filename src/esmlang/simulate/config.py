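"""Simulation configuration, direction priors and planted-effect defaults.

The generator emulates the study protocol this package analyzes: 10 ESM
beeps a day for 2 weeks, declining compliance, voice prompts answered far
less often than surveys, passive keyboard logging around the surveys, and
language streams whose features covary weakly with the momentary emotional
state.  Planted effects are expressed as standardized loadings -- the target
within-person correlation between a feature and an emotion -- with default
signs taken from the expected-direction literature summarized in the study's
background tables and default magnitude 0.15, the middle of the weak-effect
band (|r| 0.05-0.25) the study reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EMOTIONS",
    "FEATURE_FAMILIES",
    "DirectionPrior",
    "SimulationConfig",
    "ConfigurationError",
    "default_direction_priors",
    "default_loading_matrix",
    "qualified_features",
]

EMOTIONS = ("valence", "arousal", "anger", "anxiety", "sadness", "stress", "happiness")

#: Outcome used only at the trait level.
TRAIT_OUTCOMES = EMOTIONS + ("depression",)

FEATURE_FAMILIES = ("speech_content", "speech_form", "writing_content", "writing_form")


class ConfigurationError(ValueError):
    """Invalid simulation or run configuration."""


@dataclass(frozen=True)
class DirectionPrior:
    """Expected sign of one emotion x feature correlation.

    ``sign`` is one of ``+``, ``-``, ``+-`` (direction unclear; not planted
    by default) or ``0`` (no expected relation).
    """

    emotion: str
    feature: str     # qualified name, e.g. "speech_form.loudness_mean"
    sign: str

    def __post_init__(self):
        if self.sign not in ("+", "-", "+-", "0"):
            raise ConfigurationError(f"invalid sign {self.sign!r}")


# Expected directions for content features (shared by the spoken and written
# streams; exclamation marks exist only for writing).  Reconstructed from the
# prior-work literature on emotion word use: higher valence/happiness goes
# with more positive-emotion words, fewer negative-emotion words, fewer
# negations and sadness words and a higher word count (plus first-person
# plural for happiness and exclamation marks in writing); negative emotions
# go with more negative-emotion, anxiety-, anger- and sadness-related words.
_CONTENT_PRIORS: dict[str, dict[str, str]] = {
    "valence":   {"wc": "+", "negate": "-", "posemo": "+", "negemo": "-",
                  "sad": "-", "exclam": "+"},
    "arousal":   {},
    "anger":     {"you": "+", "negemo": "+", "anx": "+", "anger": "+"},
    "anxiety":   {"negemo": "+", "sad": "+", "anger": "+"},
    "sadness":   {"negemo": "+", "sad": "+", "anger": "+"},
    "stress":    {"negemo": "+", "anger": "+", "anx": "+"},
    "happiness": {"wc": "+", "we": "+", "posemo": "+", "negemo": "-",
                  "negate": "-", "exclam": "+"},
    "depression": {"i": "+", "negemo": "+", "swear": "+", "negate": "+"},
}

# Expected directions for the 13 acoustic parameters (high-arousal emotions
# raise pitch, loudness and speech rate and shorten pauses; sadness lowers
# them; jitter rises with anger/anxiety/sadness).
_SPEECH_FORM_PRIORS: dict[str, dict[str, str]] = {
    "valence": {},
    "arousal": {"f0_mean": "+", "f0_sd_norm": "+", "f0_range": "+",
                "f0_rise_slope": "+", "f0_fall_slope": "+",
                "loudness_mean": "+", "loudness_rise_slope": "+",
                "loudness_fall_slope": "+",
                "voiced_segments_per_second": "+",
                "mean_unvoiced_segment_length": "-"},
    "anger":   {"f0_mean": "+", "f0_sd_norm": "+", "f0_range": "+",
                "f0_rise_slope": "+", "f0_fall_slope": "+",
                "loudness_mean": "+", "loudness_rise_slope": "+",
                "loudness_fall_slope": "+", "jitter_mean": "+",
                "shimmer_mean": "+", "hnr_mean": "+",
                "voiced_segments_per_second": "+-",
                "mean_unvoiced_segment_length": "-"},
    "anxiety": {"f0_mean": "+", "f0_sd_norm": "+-", "f0_range": "+",
                "f0_rise_slope": "+-", "f0_fall_slope": "+-",
                "loudness_mean": "+", "jitter_mean": "+",
                "shimmer_mean": "+", "hnr_mean": "-",
                "voiced_segments_per_second": "+-",
                "mean_unvoiced_segment_length": "+-"},
    "sadness": {"f0_mean": "-", "f0_sd_norm": "-", "f0_range": "-",
                "f0_rise_slope": "-", "f0_fall_slope": "-",
                "loudness_mean": "-", "loudness_rise_slope": "-",
                "loudness_fall_slope": "-", "jitter_mean": "+",
                "hnr_mean": "-",
                "voiced_segments_per_second": "-",
                "mean_unvoiced_segment_length": "+"},
    "stress":  {"f0_mean": "+", "f0_sd_norm": "+", "f0_range": "+",
                "f0_rise_slope": "+", "f0_fall_slope": "+",
                "loudness_mean": "+", "loudness_rise_slope": "+",
                "loudness_fall_slope": "+",
                "voiced_segments_per_second": "+",
                "mean_unvoiced_segment_length": "-"},
    "happiness": {"f0_mean": "+", "f0_sd_norm": "+", "f0_range": "+",
                  "f0_rise_slope": "+", "f0_fall_slope": "+",
                  "loudness_mean": "+", "loudness_rise_slope": "+",
                  "loudness_fall_slope": "+", "jitter_mean": "+",
                  "shimmer_mean": "+", "hnr_mean": "+",
                  "voiced_segments_per_second": "+",
                  "mean_unvoiced_segment_length": "-"},
}

# Expected directions for typing dynamics.
_WRITING_FORM_PRIORS: dict[str, dict[str, str]] = {
    "valence":   {"n_characters": "+"},
    "arousal":   {"typing_speed": "+", "avg_key_press_duration": "-",
                  "typing_duration_rel": "-"},
    "stress":    {"typing_speed": "+", "avg_key_press_duration": "-",
                  "n_entries": "-", "backspaces_rel": "-",
                  "typing_duration_rel": "-"},
    "happiness": {"n_characters": "+"},
    "depression": {"avg_key_press_duration": "-"},
}


def default_direction_priors() -> list[DirectionPrior]:
    """The default expected-direction entries with qualified feature names."""
    priors: list[DirectionPrior] = []
    for emo, feats in _CONTENT_PRIORS.items():
        for feat, sign in feats.items():
            if feat != "exclam":
                priors.append(DirectionPrior(emo, f"speech_content.{feat}", sign))
            priors.append(DirectionPrior(emo, f"writing_content.{feat}", sign))
    for emo, feats in _SPEECH_FORM_PRIORS.items():
        for feat, sign in feats.items():
            priors.append(DirectionPrior(emo, f"speech_form.{feat}", sign))
    for emo, feats in _WRITING_FORM_PRIORS.items():
        for feat, sign in feats.items():
            priors.append(DirectionPrior(emo, f"writing_form.{feat}", sign))
    seen = set()
    for p in priors:
        key = (p.emotion, p.feature)
        if key in seen:
            raise ConfigurationError(f"duplicate direction prior {key}")
        seen.add(key)
    return priors


def default_loading_matrix(magnitude: float = 0.15,
                           include_depression: bool = False,
                           marginal_cap: float = 0.25
                           ) -> dict[tuple[str, str], float]:
    """Planted loadings from the direction priors.

    ``+``/``-`` entries become ``+-magnitude``; undirected (``+-``) and
    absent entries are not planted.  Because the emotions are correlated
    through the shared factor, loadings on several emotions accumulate into
    larger marginal correlations; each feature's loading vector is rescaled
    so its largest implied marginal correlation stays at ``marginal_cap``
    (the top of the weak-effect band).  Depression rows describe
    trait-level expectations and are excluded from the momentary planting
    by default.
    """
    loadings: dict[tuple[str, str], float] = {}
    for p in default_direction_priors():
        if p.emotion == "depression" and not include_depression:
            continue
        if p.sign == "+":
            loadings[(p.feature, p.emotion)] = magnitude
        elif p.sign == "-":
            loadings[(p.feature, p.emotion)] = -magnitude
    w = np.array([_default_factor_loadings()[e] for e in EMOTIONS])
    corr = np.outer(w, w)
    np.fill_diagonal(corr, 1.0)
    features = {feat for feat, _ in loadings}
    for feat in features:
        lam = np.array([loadings.get((feat, e), 0.0) for e in EMOTIONS])
        worst = float(np.max(np.abs(corr @ lam)))
        if worst > marginal_cap:
            scale = marginal_cap / worst
            for e in EMOTIONS:
                if (feat, e) in loadings:
                    loadings[(feat, e)] *= scale
    return loadings


def qualified_features() -> dict[str, list[str]]:
    """Qualified feature column names per family."""
    from ..acoustics import ACOUSTIC_FEATURES
    from ..keyboard import TYPING_FEATURES
    from ..lexicon import SPEECH_CONTENT_FEATURES, WRITING_CONTENT_FEATURES
    return {
        "speech_content": [f"speech_content.{c}" for c in SPEECH_CONTENT_FEATURES],
        "speech_form": [f"speech_form.{c}" for c in ACOUSTIC_FEATURES],
        "writing_content": [f"writing_content.{c}" for c in WRITING_CONTENT_FEATURES],
        "writing_form": [f"writing_form.{c}" for c in TYPING_FEATURES],
    }


def _default_trait_means() -> dict[str, float]:
    return {"valence": 56.2, "arousal": 44.7, "anger": 10.6, "anxiety": 12.5,
            "sadness": 13.1, "stress": 27.6, "happiness": 56.4}


def _default_between_sd() -> dict[str, float]:
    return {"valence": 11.3, "arousal": 11.4, "anger": 9.1, "anxiety": 12.6,
            "sadness": 9.4, "stress": 15.2, "happiness": 11.3}


def _default_within_sd() -> dict[str, float]:
    return {"valence": 14.0, "arousal": 14.0, "anger": 9.0, "anxiety": 10.0,
            "sadness": 9.0, "stress": 13.0, "happiness": 14.0}


def _default_factor_loadings() -> dict[str, float]:
    # one shared latent factor drives the valence/happiness vs negative
    # emotion covariance pattern
    return {"valence": 0.70, "happiness": 0.70, "arousal": 0.10,
            "anger": -0.50, "anxiety": -0.50, "sadness": -0.55,
            "stress": -0.50}


def _default_speech_baseline() -> dict[str, float]:
    # baseline category proportions of spoken tokens
    return {"i": 0.0944, "we": 0.0058, "you": 0.0006, "negate": 0.0129,
            "posemo": 0.0354, "negemo": 0.0098, "anx": 0.0036,
            "anger": 0.0027, "sad": 0.0016, "certain": 0.0159,
            "swear": 0.0002}


def _default_writing_baseline() -> dict[str, float]:
    # written text shows different base rates (more swearing and negative
    # emotion words, far fewer positive emotion words)
    return {"i": 0.0321, "we": 0.0057, "you": 0.0221, "negate": 0.0144,
            "posemo": 0.0100, "negemo": 0.0348, "anx": 0.0085,
            "anger": 0.0012, "sad": 0.0026, "certain": 0.0024,
            "swear": 0.0231}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level knobs of the synthetic ESM study.

    Defaults reproduce the protocol and cohort statistics of the emulated
    study: 10 beeps/day for 14 days, ~78% survey compliance declining over
    days, voice prompts answered ~19% of the time, keyboard activity around
    ~60% of surveys, weak planted feature-emotion couplings.
    """

    n_participants: int = 65
    n_days: int = 14
    beeps_per_day: int = 10

    # survey compliance: per-day Bernoulli with logit =
    #   logit(compliance_base) + participant offset - compliance_decay*(day-1)
    compliance_base: float = 0.858
    compliance_decay: float = 0.03          # log-odds per day
    compliance_sd: float = 0.9              # participant offset SD (log-odds)
    low_engagement_frac: float = 0.08       # small poorly-engaged subgroup
    low_engagement_shift: float = -2.8      # their extra log-odds offset

    # voice prompts are actively initiated and answered far less often
    voice_response_base: float = 0.223
    voice_response_decay: float = 0.11
    voice_response_sd: float = 1.5

    # passive keyboard use around surveys
    keyboard_use_base: float = 0.679
    keyboard_use_decay: float = 0.05
    keyboard_use_sd: float = 1.0

    # emotion dynamics
    emotion_ar_coefficient: float = 0.5
    trait_means: dict = field(default_factory=_default_trait_means)
    between_person_sd: dict = field(default_factory=_default_between_sd)
    within_person_sd: dict = field(default_factory=_default_within_sd)
    shared_factor_loadings: dict = field(default_factory=_default_factor_loadings)

    # planted feature-emotion couplings: (qualified feature, emotion) -> r
    planted_loading_matrix: dict = field(default_factory=default_loading_matrix)

    # language rendering
    speech_word_count_mean: float = 60.0
    words_per_entry_mean: float = 8.0
    entries_per_bin_mean: float = 4.0
    content_logodds_gain: float = 0.9
    speech_category_baseline: dict = field(default_factory=_default_speech_baseline)
    writing_category_baseline: dict = field(default_factory=_default_writing_baseline)
    exclam_rate: float = 0.5                # per writing bin
    pos_emoji_rate: float = 0.4             # per writing bin
    neg_emoji_rate: float = 0.05
    clip_duration_s: float = 3.0
    sample_rate: int = 16_000
    backspace_prob: float = 0.20            # per typed character

    # epoch of day 1 (ms since Unix epoch); a Monday, local clock only
    start_epoch_ms: int = 1_609_718_400_000   # 2021-01-04 00:00:00
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("compliance_base", "voice_response_base",
                     "keyboard_use_base", "low_engagement_frac",
                     "backspace_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.emotion_ar_coefficient < 1.0:
            raise ConfigurationError("AR coefficient must be in [0, 1)")
        if self.n_days < 1 or self.beeps_per_day < 1 or self.n_participants < 1:
            raise ConfigurationError("study dimensions must be positive")
        for (feat, emo), lam in self.planted_loading_matrix.items():
            if not np.isfinite(lam):
                raise ConfigurationError(f"non-finite loading for ({feat}, {emo})")
            if emo not in EMOTIONS:
                raise ConfigurationError(f"loading references unknown emotion {emo!r}")
        known = {f for cols in qualified_features().values() for f in cols}
        for (feat, _), _lam in self.planted_loading_matrix.items():
            if feat not in known:
                raise ConfigurationError(f"loading references unknown feature {feat!r}")
        budgets: dict[str, float] = {}
        for (feat, _), lam in self.planted_loading_matrix.items():
            budgets[feat] = budgets.get(feat, 0.0) + lam * lam
        for feat, ss in budgets.items():
            if ss > 1.0:
                raise ConfigurationError(
                    f"squared loadings for {feat} sum to {ss:.2f} > 1")

    @property
    def schedule_length(self) -> int:
        return self.n_days * self.beeps_per_day

    def loadings_for(self, feature: str) -> np.ndarray:
        """Loading vector over EMOTIONS for one qualified feature."""
        return np.array([
            self.planted_loading_matrix.get((feature, emo), 0.0)
            for emo in EMOTIONS])
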