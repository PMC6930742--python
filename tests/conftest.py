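"""Shared fixtures: small synthetic tables and configs for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from tinnisel.cohort import CohortConfig, RegionDistribution, ThiModel


def small_signal_regions(n: int = 3, delta: float = 30.0):
    """A few well-separated signal regions for miniature cohorts."""
    return tuple(
        RegionDistribution(
            f"sig_{i}", 300.0 + 10 * i, 40.0, 300.0 + 10 * i + delta, 40.0
        )
        for i in range(n)
    )


@pytest.fixture
def tiny_config() -> CohortConfig:
    """12 + 12 subjects, 3 signal + 3 null regions: fast but non-trivial."""
    return CohortConfig(
        n_patients=12,
        n_controls=12,
        signal_regions=small_signal_regions(3, delta=60.0),
        n_null_regions=3,
        thi_model=ThiModel(),
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
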