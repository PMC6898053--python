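"""Shared fixtures: synthetic structures and cheap engine configurations."""

import numpy as np
import pytest

from contactsr import (
    DistillerConfig,
    make_bundle_fixture,
    make_coil,
    make_helix,
    make_unique_contact_bundle,
)
from contactsr.reconstruct import ReconstructionResult


@pytest.fixture(scope="session")
def helix30():
    return make_helix(30)


@pytest.fixture(scope="session")
def bundle():
    """Two-helix bundle, ~53 residues, contacts in all three range classes."""
    return make_bundle_fixture(n_segments=2, seg_length=25, seed=0)


@pytest.fixture(scope="session")
def unique_bundle():
    """Two compressed spirals bridged by exactly one long-range contact."""
    return make_unique_contact_bundle(seg_length=14, seed=0)


@pytest.fixture(scope="session")
def coil40():
    return make_coil(40, seed=3)


@pytest.fixture(scope="session")
def fast_config():
    """Engine configuration small enough for test-suite turnaround."""
    return DistillerConfig(
        redundancy=3, n_candidates=4, top_k=3, refine_steps=500, seed=7
    )


def constant_engine(cmap, sse, native, config, seed):
    """Stub engine: identical output regardless of input."""
    return ReconstructionResult(
        models=[], energies=np.array([]), rmsd=5.0, tm=0.3, satisfied_fraction=1.0
    )


def make_affine_engine(planted, coefficient=0.1, base=5.0):
    """Stub whose RMSD is affine in the indicator of one planted contact."""

    def engine(cmap, sse, native, config, seed):
        rmsd = base - coefficient * (planted in cmap)
        return ReconstructionResult(
            models=[], energies=np.array([]), rmsd=rmsd, tm=1.0 / rmsd,
            satisfied_fraction=1.0,
        )

    return engine


def make_sr_sum_engine(sr_of, base=5.0, coefficient=0.01):
    """Stub whose RMSD decreases with the summed relevance of chosen contacts."""

    def engine(cmap, sse, native, config, seed):
        total = sum(sr_of.get(c, 0.0) for c in cmap.contacts)
        rmsd = base - coefficient * total
        return ReconstructionResult(
            models=[], energies=np.array([]), rmsd=rmsd, tm=1.0 / max(rmsd, 0.1),
            satisfied_fraction=1.0,
        )

    return engine


class CountingEngine:
    """Instrumented constant engine recording every invocation."""

    def __init__(self):
        self.calls = []

    def __call__(self, cmap, sse, native, config, seed):
        self.calls.append((frozenset(cmap.contacts), seed))
        return ReconstructionResult(
            models=[], energies=np.array([]), rmsd=4.2, tm=0.5, satisfied_fraction=1.0
        )
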