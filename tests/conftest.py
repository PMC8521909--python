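"""Shared fixtures: seeded synthetic cohorts at various scales.

Audio rates are scaled well below the clinical 100 kHz (the click band is
scaled into the reduced Nyquist range accordingly) so the whole suite runs
in minutes; the pipeline itself is rate-agnostic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from jae.features import FeatureMatrix, build_feature_matrix
from jae.synthetic import ClassProfile, CohortSpec, followup_from, generate_cohort

SMALL_FS = 4000.0
SMALL_CLICK_BAND = (600.0, 1700.0)


def make_profiles(click_amplitude: float, clicks_per_cycle: float = 6.0,
                  click_band: tuple[float, float] = SMALL_CLICK_BAND):
    healthy = ClassProfile(label="healthy")
    jia = ClassProfile(label="jia", clicks_per_cycle=clicks_per_cycle,
                       click_amplitude=click_amplitude,
                       click_freq_range=click_band)
    return {"healthy": healthy, "jia": jia}


def make_cohort_X(n_jia=8, n_healthy=8, n_followup=0, cycles=10, channels=2,
                  fs_audio=SMALL_FS, click_amplitude=12.0, clicks_per_cycle=6.0,
                  seed=0, followup_attenuation=5.0, cycle_period=4.0,
                  click_band=SMALL_CLICK_BAND) -> FeatureMatrix:
    """Generate a cohort and extract its feature matrix in one step."""
    profiles = make_profiles(click_amplitude, clicks_per_cycle, click_band)
    spec = CohortSpec(
        n_jia=n_jia, n_healthy=n_healthy, n_followup=n_followup,
        cycles_per_recording=cycles, cycle_period=cycle_period,
        fs_audio=fs_audio, channels_per_subject=channels,
        profiles=profiles,
        followup_profile=followup_from(profiles["jia"], followup_attenuation),
        seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # desk-scale band clamp
        return build_feature_matrix(generate_cohort(spec),
                                    cycle_period=cycle_period)


@pytest.fixture(scope="session")
def strong_cohort_X() -> FeatureMatrix:
    """16 subjects, 4 channels, strong click effect, at the default
    desk-scale 25 kHz rate and 2-8 kHz click band."""
    return make_cohort_X(n_jia=8, n_healthy=8, channels=4, fs_audio=25_000.0,
                         click_amplitude=12.0, click_band=(2000.0, 8000.0),
                         seed=11)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
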