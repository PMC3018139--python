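"""Shared fixtures: scaled-down enzyme families and calibrated profiles.

Unit tests use shortened family lengths so the full pipeline stays fast;
the acceptance tests build the default-length families themselves.
"""

from __future__ import annotations

import numpy as np
import pytest

from shikscreen.screening import build_profiles
from shikscreen.synthetic import make_default_families

# Shortened stand-ins for the default enzyme families (same structure:
# isoforms, two-model enzymes, fusions, alternatives).
SMALL_LENGTHS = {
    "aroG": 80,
    "aroB_type1": 70,
    "aroB_type2": 70,
    "aroD": 60,
    "aroE": 60,
    "ydiB": 60,
    "aroK_model1": 60,
    "aroK_model2": 60,
    "aroA": 80,
    "aroC": 70,
    "kdpgal": 60,
    "ghmp": 70,
}


def small_calib_lengths(rng: np.random.Generator, size: int) -> np.ndarray:
    """Short calibration lengths matched to the small test proteomes."""
    lengths = np.rint(rng.lognormal(np.log(120.0), 0.4, size=size)).astype(int)
    return np.maximum(lengths, 30)


@pytest.fixture(scope="session")
def small_families():
    return make_default_families(seed=11, lengths=SMALL_LENGTHS)


@pytest.fixture(scope="session")
def small_profiles(small_families):
    return build_profiles(
        small_families.alignments,
        seed=12,
        length_distribution=small_calib_lengths,
    )


@pytest.fixture(scope="session")
def uniform_bg():
    return np.full(20, 0.05)
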