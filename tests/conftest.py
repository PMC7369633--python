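"""Shared fixtures: the session-scoped phantom and helper constructors."""

from __future__ import annotations

import numpy as np
import pytest

import splitfilter as sf


@pytest.fixture(scope="session")
def phantom_spec() -> sf.PhantomSpec:
    return sf.PhantomSpec()


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    """Default six-sector stepped-resolution phantom (truth, sector masks)."""
    return sf.generate_phantom(phantom_spec)


@pytest.fixture(scope="session")
def full_mask(phantom_spec) -> sf.MaskVolume:
    return sf.ring_mask(phantom_spec)


@pytest.fixture(scope="session")
def noisy_pair(phantom, phantom_spec, full_mask) -> sf.HalfMapPair:
    truth, _ = phantom
    return sf.make_half_pair(truth, phantom_spec.noise_sigma, 11, full_mask)


@pytest.fixture(scope="session")
def filter_result(noisy_pair) -> sf.FilterResult:
    """One end-to-end filter run on the default phantom pair."""
    return sf.run_filter(noisy_pair)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_volume(box: int, seed: int, voxel_size: float = 1.0) -> sf.DensityVolume:
    data = np.random.default_rng(seed).normal(0.0, 1.0, (box,) * 3)
    return sf.DensityVolume(data, voxel_size)


def ones_mask(box: int) -> sf.MaskVolume:
    return sf.MaskVolume(data=np.ones((box,) * 3))
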