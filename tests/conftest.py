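from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from radstab import NoduleMask, QuantisedVolume, RaterModel, generate_cohort


def qvol(levels, n_levels) -> QuantisedVolume:
    """Wrap an integer array (levels 1..Ng) as a quantised volume."""
    arr = np.asarray(levels, dtype=np.int64)
    if arr.ndim < 3:
        arr = arr.reshape(arr.shape + (1,) * (3 - arr.ndim))
    return QuantisedVolume(levels=arr, n_levels=n_levels)


def mask_of(shape_or_array) -> NoduleMask:
    """Full mask for a shape, or a mask from a boolean array."""
    if isinstance(shape_or_array, tuple):
        return NoduleMask(values=np.ones(shape_or_array, dtype=bool))
    arr = np.asarray(shape_or_array, dtype=bool)
    if arr.ndim < 3:
        arr = arr.reshape(arr.shape + (1,) * (3 - arr.ndim))
    return NoduleMask(values=arr)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 5-nodule, 4-rater phantom cohort with realistic jitter."""
    out = tmp_path_factory.mktemp("cohort_small")
    return generate_cohort(
        5, out, seed=42,
        model=RaterModel(n_raters=4, boundary_jitter_sigma=1.0, min_dice=0.7),
    )


@pytest.fixture(scope="session")
def identical_rater_cohort(tmp_path_factory):
    """A 4-nodule cohort whose raters all equal the base mask."""
    out = tmp_path_factory.mktemp("cohort_ident")
    return generate_cohort(
        4, out, seed=7,
        model=RaterModel(n_raters=4, boundary_jitter_sigma=0.0, dilation_bias=0.0),
    )
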