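"""Shared fixtures and small random-instance generators."""

from __future__ import annotations

import numpy as np
import pytest

from haplomix import FragmentSet, PhaseParams, PhaseVector, SNPFragment


def random_fragment_set(
    rng: np.random.Generator,
    num_sites: int = 8,
    n_fragments: int = 6,
    min_len: int = 2,
    max_len: int = 4,
) -> FragmentSet:
    """Small random fragment set with possibly non-contiguous spans."""
    frags = []
    for i in range(n_fragments):
        length = int(rng.integers(min_len, max_len + 1))
        sites = np.sort(rng.choice(num_sites, size=length, replace=False)) + 1
        alleles = rng.integers(0, 2, size=length)
        frags.append(SNPFragment(f"f{i}", sites, alleles))
    return FragmentSet(frags, num_sites=num_sites)


def random_params(rng: np.random.Generator, num_sites: int, alpha: float = 0.1) -> PhaseParams:
    p = rng.random((num_sites, 1))
    return PhaseParams(np.hstack([p, 1.0 - p]), alpha)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def truth10() -> PhaseVector:
    """Fixed 10-site truth with a mix of both phases."""
    return PhaseVector.from_codes([0, 1, 1, 0, 0, 0, 1, 0, 1, 1])
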