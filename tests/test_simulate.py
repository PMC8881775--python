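"""Synthetic study generator: schedules, emotion dynamics, rendering parity."""

import numpy as np
import pandas as pd
import pytest

from esmlang.acoustics import extract_acoustic_features
from esmlang.assembly import compliance_stats
from esmlang.lexicon import extract_content_features, load_demo_lexicon
from esmlang.simulate import (ConfigurationError, SimulationConfig,
                              build_schedule, default_direction_priors,
                              default_loading_matrix, draw_profile,
                              render_transcript, render_waveform,
                              simulate_emotions, simulate_study)
from esmlang.simulate.config import EMOTIONS

MS_H = 3_600_000


def fast_cfg(**kw):
    base = dict(n_participants=4, n_days=2, rng_seed=1)
    base.update(kw)
    return SimulationConfig(**base)


# ------------------------------------------------------------------ schedule

def test_schedule_protocol_shape():
    cfg = SimulationConfig(n_days=14, rng_seed=0)
    ts = build_schedule(cfg, 0)
    assert len(ts) == 140
    assert np.all(np.diff(ts) > 0)


def test_first_beep_and_blocks_within_day():
    cfg = fast_cfg(n_days=3, rng_seed=9)
    ts = build_schedule(cfg, 2)
    for d in range(3):
        day = ts[d * 10:(d + 1) * 10] - (cfg.start_epoch_ms + d * 24 * MS_H)
        assert 10 * MS_H <= day[0] < 11 * MS_H
        block = 11 * MS_H / 9
        for b in range(9):
            lo = 11 * MS_H + b * block
            assert lo <= day[b + 1] < lo + block


def test_schedule_deterministic_under_seed():
    cfg = fast_cfg(rng_seed=5)
    assert np.array_equal(build_schedule(cfg, 1), build_schedule(cfg, 1))


def test_nonstandard_beeps_require_block_definition():
    with pytest.raises(ConfigurationError):
        build_schedule(fast_cfg(beeps_per_day=5), 0)


# ------------------------------------------------------------------ emotions

def test_zero_within_sd_pins_ratings_to_trait_mean():
    cfg = fast_cfg(within_person_sd={e: 0.0 for e in EMOTIONS})
    profile = draw_profile(cfg, 0)
    traj = simulate_emotions(cfg, profile, build_schedule(cfg, 0))
    for j, e in enumerate(EMOTIONS):
        assert np.allclose(traj.ratings[:, j], profile.trait_means[e])


def test_ratings_clipped_and_timestamps_increasing():
    cfg = fast_cfg(rng_seed=3)
    traj = simulate_emotions(cfg, draw_profile(cfg, 1), build_schedule(cfg, 1))
    assert traj.ratings.min() >= 0 and traj.ratings.max() <= 100
    assert np.all(np.diff(traj.timestamps_ms) > 0)


def test_latent_states_have_unit_variance_and_factor_structure():
    cfg = SimulationConfig(n_participants=1, n_days=14, rng_seed=11)
    zs = []
    for i in range(30):
        traj = simulate_emotions(cfg, draw_profile(cfg, i),
                                 build_schedule(cfg, i))
        zs.append(traj.z)
    z = np.concatenate(zs)
    sd = z.std(axis=0)
    assert np.all(np.abs(sd - 1.0) < 0.1)
    corr = np.corrcoef(z.T)
    iv, ih = EMOTIONS.index("valence"), EMOTIONS.index("happiness")
    isad = EMOTIONS.index("sadness")
    assert corr[iv, ih] > 0.3                # shared-factor positive pair
    assert corr[iv, isad] < -0.15            # valence vs negative emotion


def test_compliance_decay_gives_negative_day_correlation():
    cfg = SimulationConfig(n_participants=40, n_days=14,
                           compliance_decay=0.15, rng_seed=21)
    study = simulate_study(cfg, render="truth",
                           include_voice=False, include_keyboard=False)
    sched = study.schedule.assign(answered_int=study.schedule["answered"].astype(int))
    stats = compliance_stats(sched.rename(columns={"answered_int": "has_ans"}),
                             activity_cols=("has_ans",))
    assert stats["day_corr_has_ans"] < -0.1


def test_default_compliance_distribution_matches_cohort_range():
    cfg = SimulationConfig(n_participants=120, rng_seed=13)
    study = simulate_study(cfg, render="truth",
                           include_voice=False, include_keyboard=False)
    per = study.schedule.groupby("participant_id")["answered"].mean()
    # the observed cohort spanned answered fractions 0.26-0.99
    assert per.min() < 0.4 and per.max() > 0.9
    assert 0.6 < per.mean() < 0.9


# ----------------------------------------------------------------- rendering

def test_transcript_counts_match_extractor_exactly(lexicon):
    cfg = fast_cfg()
    rng = np.random.default_rng(5)
    for _ in range(20):
        x = {c: rng.normal() for c in ("posemo", "negemo", "i", "wc")}
        text, counts = render_transcript(cfg, x, "speech", rng, lexicon)
        vec = extract_content_features(text, lexicon)
        assert vec.wc == counts["wc"]
        for cat in ("posemo", "negemo", "i", "sad", "anger"):
            assert vec.percentages[cat] == pytest.approx(
                100.0 * counts[cat] / counts["wc"])


def test_writing_transcript_carries_exclamations(lexicon):
    cfg = fast_cfg(exclam_rate=3.0)
    rng = np.random.default_rng(8)
    text, counts = render_transcript(cfg, {}, "writing", rng, lexicon)
    assert text.count("!") == counts["exclam"]


def test_waveform_f0_recovery_against_truth():
    cfg = SimulationConfig()
    rng = np.random.default_rng(17)
    rv = render_waveform(cfg, {"hnr_mean": 4.0}, 220.0, rng)
    f = extract_acoustic_features(rv.clip)
    assert f.f0_mean == pytest.approx(rv.truth["f0_mean"], abs=0.5)
    assert f.voiced_segments_per_second == pytest.approx(
        rv.truth["voiced_segments_per_second"], rel=0.25)


def test_waveform_planted_jitter_recovery():
    # clean voice: high HNR, low shimmer so period marks are unperturbed
    cfg = SimulationConfig()
    rng = np.random.default_rng(3)
    vals, truths = [], []
    for _ in range(6):
        rv = render_waveform(cfg, {"hnr_mean": 6.0, "jitter_mean": -0.6,
                                   "shimmer_mean": -8.0}, 200.0, rng)
        vals.append(extract_acoustic_features(rv.clip).jitter_mean)
        truths.append(rv.truth["jitter_mean"])
    assert np.mean(vals) == pytest.approx(np.mean(truths), rel=0.2)


def test_unknown_planted_feature_rejected():
    with pytest.raises(ConfigurationError):
        fast_cfg(planted_loading_matrix={("speech_content.bogus", "valence"): 0.2})
    with pytest.raises(ConfigurationError):
        fast_cfg(planted_loading_matrix={("speech_content.posemo", "joy"): 0.2})


def test_direction_priors_unique_and_well_formed():
    priors = default_direction_priors()
    keys = {(p.emotion, p.feature) for p in priors}
    assert len(keys) == len(priors)
    assert all(p.sign in ("+", "-", "+-", "0") for p in priors)
    mat = default_loading_matrix(0.15)
    assert mat[("speech_content.posemo", "valence")] > 0
    assert mat[("speech_form.loudness_mean", "sadness")] < 0
    assert ("speech_form.voiced_segments_per_second", "anger") not in mat
    # implied marginal correlations stay inside the weak-effect band
    from esmlang.simulate.config import _default_factor_loadings
    w = np.array([_default_factor_loadings()[e] for e in EMOTIONS])
    corr = np.outer(w, w)
    np.fill_diagonal(corr, 1.0)
    for feat in {f for f, _ in mat}:
        lam = np.array([mat.get((feat, e), 0.0) for e in EMOTIONS])
        assert np.max(np.abs(corr @ lam)) <= 0.25 + 1e-9


def test_null_loadings_give_null_within_person_correlation():
    cfg = SimulationConfig(n_participants=30, n_days=6, rng_seed=29,
                           planted_loading_matrix={})
    study = simulate_study(cfg, render="truth", include_keyboard=False)
    lat = study.latents.dropna(subset=["speech_content.posemo"])
    r = np.corrcoef(lat["z_valence"], lat["speech_content.posemo"])[0, 1]
    assert abs(r) < 0.05


def test_planted_direction_signs_recovered_in_large_sample():
    cfg = SimulationConfig(n_participants=80, n_days=6, rng_seed=31)
    study = simulate_study(cfg, render="truth")
    lat = study.latents
    checks = [("speech_content.posemo", "z_valence", +1),
              ("speech_content.negemo", "z_valence", -1),
              ("speech_form.loudness_mean", "z_arousal", +1),
              ("speech_form.loudness_mean", "z_sadness", -1),
              ("writing_form.typing_speed", "z_arousal", +1)]
    for feat, z, sign in checks:
        sub = lat.dropna(subset=[feat])
        r = np.corrcoef(sub[z], sub[feat])[0, 1]
        assert np.sign(r) == sign and abs(r) > 0.03, (feat, z, r)


def test_simulation_fully_deterministic():
    cfg = fast_cfg(rng_seed=77)
    a = simulate_study(cfg, render="full")
    b = simulate_study(cfg, render="full")
    pd.testing.assert_frame_equal(a.surveys, b.surveys)
    pd.testing.assert_frame_equal(a.latents, b.latents)
    pd.testing.assert_frame_equal(a.keystrokes, b.keystrokes)
    assert a.transcripts == b.transcripts
    for key in a.clips:
        assert np.array_equal(a.clips[key], b.clips[key])


def test_write_study_roundtrip(tmp_path, small_rendered_study):
    from esmlang.simulate import write_study
    info = write_study(small_rendered_study, tmp_path)
    assert (tmp_path / "surveys.csv").exists()
    assert info["n_voice"] == len(small_rendered_study.voice_index)
    wavs = list((tmp_path / "voice").glob("*.wav"))
    txts = list((tmp_path / "voice").glob("*.txt"))
    assert len(wavs) == len(small_rendered_study.clips)
    assert len(txts) == len(small_rendered_study.transcripts)


def test_dass_items_valid_and_right_skewed():
    cfg = SimulationConfig(n_participants=200, rng_seed=41)
    scores = [draw_profile(cfg, i).dass_depression for i in range(200)]
    scores = np.array(scores)
    assert scores.min() >= 0 and scores.max() <= 3
    assert np.median(scores) < scores.mean() + 0.2      # right skew
    assert (scores <= 0.75).mean() > 0.6                # concentration low end
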