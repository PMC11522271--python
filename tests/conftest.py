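"""Shared fixtures: cached phantom generations and full pipeline runs.

Phantom generation and analysis of a 32-frame 256x256 sequence take a
few seconds each, so specs used by several tests are generated once per
session and reused.
"""

from __future__ import annotations

import numpy as np
import pytest

from dtwstrain import PhantomSpec, analyze, generate_phantom_sequence
from dtwstrain.types import RunConfig


@pytest.fixture(scope="session")
def phantom_factory():
    """Cached (spec, masks, truth) for a given phantom parameterization."""
    cache = {}

    def get(**kwargs):
        key = tuple(sorted(kwargs.items()))
        if key not in cache:
            spec = PhantomSpec(**kwargs)
            masks, truth = generate_phantom_sequence(spec)
            cache[key] = (spec, masks, truth)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def analyzed_factory(phantom_factory):
    """Cached full pipeline result for a given phantom parameterization."""
    cache = {}

    def get(**kwargs):
        key = tuple(sorted(kwargs.items()))
        if key not in cache:
            spec, masks, truth = phantom_factory(**kwargs)
            cache[key] = (spec, masks, truth, analyze(masks, RunConfig()))
        return cache[key]

    return get


@pytest.fixture(scope="session")
def deforming_run(analyzed_factory):
    """The workhorse sequence: one cycle, 20% shortening, 32 frames."""
    return analyzed_factory(shortening_amplitude=0.2, n_frames=32)


@pytest.fixture(scope="session")
def static_run(analyzed_factory):
    """A static (zero-shortening) sequence: every frame identical."""
    return analyzed_factory(shortening_amplitude=0.0, n_frames=8)


def straight_band(length=100, thickness=20, width=200):
    """A horizontal rectangular band mask: analytically known medial line."""
    h = thickness + 40
    mask = np.zeros((h, width), dtype=bool)
    y0 = 20
    mask[y0 : y0 + thickness, 10 : 10 + length] = True
    return mask
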