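"""Wright-Fisher dynamics of asexual populations under macroscopic epistasis.

Discrete, non-overlapping generations: each generation N offspring are drawn
by multinomial resampling with probabilities proportional to count * fitness
(selection), then mutants are drawn binomially per genotype class with the
model's per-individual beneficial rate, each founding a new class
(mutation).  With N = 10^6 and mu = 10^-5 the supply N*mu = 10 of new
beneficial mutations per generation puts the population squarely in the
clonal-interference regime, where several beneficial lineages segregate and
compete at once.

The population is represented by genotype classes rather than individuals;
the two representations are statistically equivalent (a tested property) and
the class form keeps large-N simulation tractable.  Multiple mutations in
one individual in one generation are ignored: at rates <= 1e-4 doubles are
of order 1e-8 per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InputError, StateError
from .models import ModelSpec, beneficial_rates, spawn_children
from .population import GenotypeClass, PopulationState
from .standardization import FitnessRecord

__all__ = [
    "SimConfig",
    "FitnessTrajectory",
    "GenotypeClass",
    "PopulationState",
    "selection_step",
    "mutation_step",
    "run",
    "run_experiment",
    "fixation_fraction",
    "kimura_fixation_probability",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation run or replicate set.

    The mutation rate lives inside ``model`` (accessible as ``model.mu``);
    population size N and mutation rate 1e-5 default to the
    clonal-interference conditions used throughout.
    """

    N: int = 1_000_000
    T: int = 500
    model: ModelSpec | None = None
    seed: int = 0
    record_every: int = 10
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.N < 1:
            raise InputError(f"N must be >= 1, got {self.N}")
        if self.T < 1:
            raise InputError(f"T must be >= 1, got {self.T}")
        if self.record_every < 1:
            raise InputError(f"record_every must be >= 1, got {self.record_every}")
        if self.replicates < 1:
            raise InputError(f"replicates must be >= 1, got {self.replicates}")
        if self.seed is None:
            raise InputError("an RNG seed is mandatory")


@dataclass(frozen=True)
class FitnessTrajectory:
    """Population mean fitness at the recorded generations of one run."""

    generations: np.ndarray
    mean_w: np.ndarray

    def __post_init__(self) -> None:
        if len(self.generations) != len(self.mean_w):
            raise StateError("generations and mean_w must have equal length")

    @property
    def final_w(self) -> float:
        return float(self.mean_w[-1])


# ---------------------------------------------------------------------------
# Array-level engine (internal): classes as parallel arrays + state list
# ---------------------------------------------------------------------------


def _select(w, counts, states, N, rng):
    weights = counts * w
    total = weights.sum()
    if total <= 0:
        raise StateError("population has no individuals with positive weight")
    new_counts = rng.multinomial(N, weights / total)
    keep = new_counts > 0
    return w[keep], new_counts[keep], [s for s, k in zip(states, keep) if k]


def _mutate(w, counts, states, model, rng):
    rates = beneficial_rates(model, w)
    m = rng.binomial(counts, rates)
    total = int(m.sum())
    if total == 0:
        return w, counts, states
    parent_idx = np.repeat(np.arange(len(w)), m)
    child_w, child_states = spawn_children(model, w, states, parent_idx, rng)
    counts = counts - m
    # a no-op mutation (exhausted finite-sites parent) stays in its class
    if model.kind == "finite_sites":
        stay = np.fromiter(
            (child_states[k] is states[parent_idx[k]] for k in range(total)),
            dtype=bool,
            count=total,
        )
    else:
        stay = np.zeros(total, dtype=bool)
    if stay.any():
        np.add.at(counts, parent_idx[stay], 1)
    keep_children = ~stay
    w = np.concatenate([w, child_w[keep_children]])
    counts = np.concatenate([counts, np.ones(int(keep_children.sum()), dtype=counts.dtype)])
    states = states + [child_states[k] for k in range(total) if keep_children[k]]
    alive = counts > 0
    if not alive.all():
        w, counts = w[alive], counts[alive]
        states = [s for s, a in zip(states, alive) if a]
    return w, counts, states


def _to_arrays(pop: PopulationState):
    w = np.array([c.w for c in pop.classes], dtype=float)
    counts = np.array([c.count for c in pop.classes], dtype=np.int64)
    states = [c.state for c in pop.classes]
    return w, counts, states


def _to_population(w, counts, states, generation, N) -> PopulationState:
    classes = [
        GenotypeClass(class_id=i, w=float(wi), count=int(ci), state=si)
        for i, (wi, ci, si) in enumerate(zip(w, counts, states))
    ]
    return PopulationState(generation=generation, classes=classes, N=N)


# ---------------------------------------------------------------------------
# Public stepping operations
# ---------------------------------------------------------------------------


def selection_step(pop: PopulationState, rng: np.random.Generator) -> PopulationState:
    """Multinomial Wright-Fisher resampling of N offspring.

    Class i contributes offspring with probability count_i * w_i / sum_j
    count_j * w_j; N is conserved exactly.  The generation counter advances
    only after the paired mutation step.
    """
    if not pop.classes:
        raise StateError("cannot select from an empty population")
    w, counts, states = _to_arrays(pop)
    w, counts, states = _select(w, counts, states, pop.N, rng)
    return _to_population(w, counts, states, pop.generation, pop.N)


def mutation_step(
    pop: PopulationState, model: ModelSpec, rng: np.random.Generator
) -> PopulationState:
    """Draw mutants binomially per class and found new classes for them.

    Advances the generation counter, completing the selection-mutation pair.
    """
    w, counts, states = _to_arrays(pop)
    w, counts, states = _mutate(w, counts, states, model, rng)
    return _to_population(w, counts, states, pop.generation + 1, pop.N)


def run(config: SimConfig, founder: GenotypeClass) -> FitnessTrajectory:
    """Evolve a population founded by N copies of ``founder`` for T generations.

    Mean fitness is recorded at generation 0, every ``record_every``
    generations, and at T.  Identical seed and configuration give a
    bit-identical trajectory.
    """
    if config.model is None:
        raise InputError("config.model is required")
    if founder.count != config.N:
        raise InputError(
            f"founder count {founder.count} must equal N={config.N} (clonal start)"
        )
    rng = np.random.default_rng(config.seed)
    model = config.model
    if model.kind == "finite_sites" and model.params.site_effects is None:
        if founder.state:
            raise InputError(
                "a finite-sites founder with pre-mutated sites requires site_effects "
                "fixed in the model params (see nested_finite_sites_founders)"
            )
        model = replace(model, params=model.params.realized(rng))

    w = np.array([founder.w], dtype=float)
    counts = np.array([config.N], dtype=np.int64)
    states = [founder.state]
    N = config.N

    gens = [0]
    means = [float(np.dot(counts, w) / N)]
    for t in range(1, config.T + 1):
        w, counts, states = _select(w, counts, states, N, rng)
        w, counts, states = _mutate(w, counts, states, model, rng)
        if t % config.record_every == 0 or t == config.T:
            gens.append(t)
            means.append(float(np.dot(counts, w) / N))
    return FitnessTrajectory(np.array(gens), np.array(means))


def run_experiment(
    founders: list[GenotypeClass],
    config: SimConfig,
    reps: int | None = None,
    per_replicate: bool = False,
) -> list[FitnessRecord]:
    """Replicated evolution from a ladder of founders, as fitness records.

    Each founder is evolved ``reps`` times independently (replicate r of
    founder i uses seed ``config.seed + i * reps + r``).  By default one
    record per founder is returned with w_final the across-replicate mean
    final fitness; with ``per_replicate=True`` every replicate yields its
    own record.  The output feeds standardization and regression unchanged.
    """
    if not founders:
        raise InputError("founders must be non-empty")
    reps = config.replicates if reps is None else reps
    if reps < 1:
        raise InputError(f"reps must be >= 1, got {reps}")
    records = []
    for i, founder in enumerate(founders):
        clonal = replace(founder, count=config.N)
        finals = []
        for r in range(reps):
            cfg = replace(config, seed=config.seed + i * reps + r)
            finals.append(run(cfg, clonal).final_w)
        if per_replicate:
            records.extend(
                FitnessRecord(
                    genotype_id=f"founder{i:02d}_rep{r:03d}",
                    w_start=founder.w,
                    w_final=wf,
                    generations=config.T,
                    scale="relative",
                )
                for r, wf in enumerate(finals)
            )
        else:
            records.append(
                FitnessRecord(
                    genotype_id=f"founder{i:02d}",
                    w_start=founder.w,
                    w_final=float(np.mean(finals)),
                    generations=config.T,
                    scale="relative",
                )
            )
    return records


# ---------------------------------------------------------------------------
# Fixation of a single mutant (two-class special case, batched over replicates)
# ---------------------------------------------------------------------------


def fixation_fraction(
    N: int,
    s: float,
    replicates: int,
    rng: np.random.Generator | int,
    init_count: int = 1,
) -> float:
    """Fraction of replicates in which a mutant of advantage s reaches fixation.

    Runs ``replicates`` independent two-class Wright-Fisher populations
    (mutant fitness 1+s versus resident 1, no further mutation) to
    absorption.  This is the same multinomial resampling law as
    :func:`selection_step`, specialized to two classes (where the
    multinomial reduces to a binomial) and batched across replicates.
    """
    if N < 2 or not 0 < init_count < N:
        raise InputError("need N >= 2 and 0 < init_count < N")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    counts = np.full(replicates, init_count, dtype=np.int64)
    active = np.ones(replicates, dtype=bool)
    fixed = 0
    w_mut = 1.0 + s
    while active.any():
        c = counts[active]
        p = c * w_mut / (c * w_mut + (N - c))
        c = rng.binomial(N, p)
        done_fixed = c == N
        done_lost = c == 0
        fixed += int(done_fixed.sum())
        idx = np.flatnonzero(active)
        counts[idx] = c
        active[idx[done_fixed | done_lost]] = False
    return fixed / replicates


def kimura_fixation_probability(N: int, s: float) -> float:
    """Diffusion approximation to the fixation probability of a single mutant.

    (1 - e^(-2s)) / (1 - e^(-2Ns)); the neutral limit s -> 0 is 1/N.
    """
    if s == 0:
        return 1.0 / N
    return float(-np.expm1(-2.0 * s) / -np.expm1(-2.0 * N * s))
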