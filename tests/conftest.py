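"""Shared fixtures: small synthetic cohorts and feature tables.

Session-scoped so the expensive generation work is done once; every fixture
is fully seeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hypocause.features import featurize_cohort
from hypocause.simulate import CohortConfig, EffectProfile, generate_cohort

#: a compact, group-covering feature subset used where the full 83-column
#: experiment would be disproportionate to what the test asserts
CORE_FEATURES = [
    "age", "gender", "y_w_diab",
    "cos_tod", "sin_tod", "wake_up_offset", "is_bday",
    "bgi_mean", "bgi_slope", "bgi_min",
    "pre_g_val", "pre_g_offset", "post_g_offset",
    "pre_ins_dosage", "pre_ins_offset", "post_ins_dosage", "post_ins_offset",
    "pre_bas_dosage", "pre_bas_offset",
    "pre_car_dosage", "pre_car_offset", "post_car_dosage", "post_car_offset",
    "glu_mean", "glu_std", "neg_slopes_mean", "ins_mean_x", "cnc_ansnum",
]


@pytest.fixture(scope="session")
def default_cohort():
    """Study-conditions cohort: 54 subjects, ~15 episodes each, default
    cause-conditional effects."""
    return generate_cohort(CohortConfig(seed=20240917))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    diaries, _ = default_cohort
    return featurize_cohort(diaries)


@pytest.fixture(scope="session")
def null_cohort():
    """Same sampling frame with every cause-conditional mechanism removed."""
    cfg = CohortConfig(seed=20240918, effect_profile=EffectProfile.zeroed())
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_features(null_cohort):
    diaries, _ = null_cohort
    return featurize_cohort(diaries)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 8-subject cohort for I/O and plumbing tests."""
    return generate_cohort(
        CohortConfig(n_subjects=8, days=120, episodes_per_subject=6.0, seed=7)
    )
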