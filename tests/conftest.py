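"""Shared fixtures: random rotations/frames, toy structures, tiny families."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rnaforge.geometry import FrameSet, random_rotation
from rnaforge.synthdata import FamilySpec, build_toy_structure, sample_structure_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_frames(rng):
    def make(L=8, spread=10.0, seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        return FrameSet(np.stack([random_rotation(local) for _ in range(L)]),
                        local.normal(0.0, spread, size=(L, 3)))
    return make


@pytest.fixture
def hairpin_spec():
    """A 20-nt hairpin with a 6-pair stem."""
    return FamilySpec(20, tuple((i, 19 - i) for i in range(6)))


@pytest.fixture
def hairpin_structure(hairpin_spec):
    return build_toy_structure(hairpin_spec, "GGCGCGAUAACCGCGCGCCA"[:20])


@pytest.fixture
def nested_structure():
    spec = sample_structure_spec(30, 8, seed=4)
    return spec, build_toy_structure(spec)
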