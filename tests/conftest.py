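import numpy as np
import pytest

from seizalign import (LabelingConfig, StftConfig, SynthConfig,
                       generate_cohort, subsample_windows,
                       windows_from_recording)

#: STFT settings used by the desk-scale experiments: 1-s Hann frames,
#: 50% overlap, 0-32 Hz retained (the synthetic signal lives below 48 Hz).
DESK_STFT = StftConfig(freq_crop_hz=(0.0, 32.0))


@pytest.fixture(scope="session")
def desk_stft():
    return DESK_STFT


from functools import lru_cache


@lru_cache(maxsize=16)
def build_cohort(seed: int, per_class: int = 160, preictal_effect: float = 1.0):
    """Balanced, thinned window sets for a 4-patient synthetic cohort.

    Cached: several acceptance tests evaluate different properties of the
    same seeded cohorts, and generation dominates their runtime.
    """
    recs = generate_cohort(SynthConfig(seed=seed,
                                       preictal_effect=preictal_effect))
    cohort = {}
    for rec in recs:
        ws = windows_from_recording(rec, LabelingConfig(),
                                    balance_seed=seed + 1)
        cohort[rec.patient_id] = subsample_windows(ws, per_class, seed + 2)
    return cohort


@pytest.fixture(scope="session")
def cohort_seed1():
    """One full-signal cohort shared by the cheaper end-to-end tests."""
    return build_cohort(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
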