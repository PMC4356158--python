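"""Genotype-class representation of an asexual population.

A population of N individuals is stored as a set of genotype classes, each
holding a fitness value, an abundance, and a model-specific payload (empty
for the two fitness-indexed models, the set of mutated sites for the
finite-sites model, a phenotype vector for Fisher's geometric model).  The
class representation keeps N = 10^6 populations tractable while remaining
statistically equivalent to a per-individual simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .errors import DomainError, StateError


@dataclass
class GenotypeClass:
    """One genotype class: fitness, abundance and model-specific state."""

    class_id: int
    w: float
    count: int
    state: Any = None

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise DomainError(f"fitness must be > 0, got {self.w}")
        if self.count < 0:
            raise DomainError(f"count must be >= 0, got {self.count}")


@dataclass
class PopulationState:
    """A population of N individuals partitioned into genotype classes.

    Invariants: class counts sum to N; classes with count 0 are pruned.
    """

    generation: int
    classes: list[GenotypeClass] = field(default_factory=list)
    N: int = 0

    def __post_init__(self) -> None:
        self.classes = [c for c in self.classes if c.count > 0]
        total = sum(c.count for c in self.classes)
        if total != self.N:
            raise StateError(f"class counts sum to {total}, expected N={self.N}")
        if self.N < 1:
            raise StateError(f"population size must be >= 1, got {self.N}")

    def mean_fitness(self) -> float:
        return sum(c.count * c.w for c in self.classes) / self.N
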