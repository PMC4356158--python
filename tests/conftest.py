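"""Shared fixtures and brute-force oracles for the test suite."""

import numpy as np
import pytest

from macroepi.population import GenotypeClass, PopulationState


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_population(counts, ws, states=None, generation=0):
    states = states or [None] * len(counts)
    classes = [
        GenotypeClass(class_id=i, w=w, count=c, state=s)
        for i, (w, c, s) in enumerate(zip(ws, counts, states))
    ]
    return PopulationState(generation=generation, classes=classes, N=int(sum(counts)))


def naive_selection(w_individuals: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-individual Wright-Fisher selection: the brute-force oracle.

    Each of the N offspring picks a parent with probability proportional to
    the parent's fitness.
    """
    p = w_individuals / w_individuals.sum()
    idx = rng.choice(len(w_individuals), size=len(w_individuals), p=p)
    return w_individuals[idx]
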