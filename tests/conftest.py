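"""Shared fixtures: small simulated studies reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from esmlang.lexicon import load_demo_lexicon
from esmlang.pipeline import (build_datasets, datasets_from_truth,
                              extract_keyboard_features, extract_voice_features)
from esmlang.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def lexicon():
    return load_demo_lexicon()


@pytest.fixture(scope="session")
def small_rendered_study():
    """A small fully rendered study (audio + text + keystrokes)."""
    cfg = SimulationConfig(n_participants=6, n_days=4, rng_seed=42)
    return simulate_study(cfg, render="full")


@pytest.fixture(scope="session")
def small_datasets(small_rendered_study):
    """Momentary + trait datasets extracted from the small rendered study."""
    study = small_rendered_study
    vf = extract_voice_features(study)
    kf = extract_keyboard_features(study.surveys, study.entries,
                                   study.keystrokes, study.lexicon)
    return build_datasets(study.surveys, study.schedule, vf, kf,
                          study.dass_table)


@pytest.fixture(scope="session")
def truth_study_null():
    """Loadings all zero; latent features stand in for extracted ones."""
    cfg = SimulationConfig(
        n_participants=15, n_days=4, rng_seed=7,
        compliance_base=0.99, compliance_decay=0.0, compliance_sd=0.0,
        low_engagement_frac=0.0,
        voice_response_base=0.99, voice_response_decay=0.0,
        voice_response_sd=0.0, planted_loading_matrix={})
    study = simulate_study(cfg, render="truth")
    return study, datasets_from_truth(study)


def balanced_panel(n_groups=25, n_per=30, r=0.3, seed=0):
    """Simple standardized panel with a known within-person correlation."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        x = rng.standard_normal(n_per)
        y = r * x + np.sqrt(1 - r * r) * rng.standard_normal(n_per)
        rows.append(pd.DataFrame({
            "participant_id": f"p{g:03d}",
            "feat": (x - x.mean()) / x.std(ddof=1),
            "emo": (y - y.mean()) / y.std(ddof=1)}))
    return pd.concat(rows, ignore_index=True)
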