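from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from echolv.phantom import (
    PhantomParams,
    barrier_perturbation_harness,
    generate_phantom,
    true_initial_barrier,
)
from echolv.preprocess import preprocess_cycle
from echolv.segment import segment_sequence

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    # Function-scoped so every test sees the same deterministic stream
    # regardless of execution order.
    return np.random.default_rng(1234)


class PhantomRun:
    """A phantom plus its (cached) preprocessing and segmentation runs."""

    def __init__(self, seed: int, **overrides):
        self.params = PhantomParams(seed=seed, **overrides)
        self.seq, self.gt = generate_phantom(self.params)
        self.barrier = true_initial_barrier(self.gt, self.params)
        self._pre = None
        self._results = {}

    @property
    def preprocessed(self):
        if self._pre is None:
            self._pre = preprocess_cycle(self.seq)
        return self._pre

    def results(self, apply_barrier: bool = True):
        if apply_barrier not in self._results:
            self._results[apply_barrier] = segment_sequence(
                self.seq,
                self.barrier,
                preprocessed=self.preprocessed,
                apply_barrier=apply_barrier,
            )
        return self._results[apply_barrier]


@pytest.fixture(scope="session")
def phantom_runs():
    """Factory giving cached full pipeline runs keyed by seed."""
    cache: dict[int, PhantomRun] = {}

    def get(seed: int) -> PhantomRun:
        if seed not in cache:
            cache[seed] = PhantomRun(seed)
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def default_run(phantom_runs) -> PhantomRun:
    """The reference study conditions: default phantom, seed 1, true barrier."""
    return phantom_runs(1)
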