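"""The four macroscopic-epistasis models.

Macroscopic epistasis means that the distribution of fitness effects (DFE)
of available mutations — its rate and/or its effect sizes — depends on the
current fitness of the background, regardless of gene-level interactions.
Four mechanisms are implemented:

``diminishing_effects``
    Beneficial effects are exponential with rate alpha_w = alpha0 * w**g, so
    the mean effect 1/alpha_w shrinks as fitness w grows; the mutation rate
    is constant.
``declining_rate``
    The DFE is a constant exponential (rate alpha) but the per-individual
    beneficial mutation rate declines with adaptation: mu_w = mu0 * w**(-g).
``finite_sites``
    L sites, each with a fixed beneficial effect s_j drawn once per run from
    an exponential distribution; a mutation flips a uniformly chosen
    not-yet-mutated site and fitness composes multiplicatively as
    w * prod(1 + s_j).  This is the only model without microscopic
    epistasis: macroscopic epistasis emerges purely from the depletion of
    available sites.
``fgm``
    Fisher's geometric model: phenotypes are points in an n-dimensional
    trait space with a single optimum at the origin, fitness decays with
    distance (Gaussian by default, w(z) = exp(-||z||^2 / 2)), and mutations
    are isotropic normal displacements.  Beneficial and deleterious
    mutations both arise; none are filtered.

In models A-C effects compose multiplicatively, child w = parent w * (1+s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import DomainError, InputError, ModelError, StateError
from .population import GenotypeClass

MODEL_KINDS = ("diminishing_effects", "declining_rate", "finite_sites", "fgm")


@dataclass(frozen=True)
class DiminishingEffectsParams:
    """Constant rate mu; beneficial DFE Exponential(alpha0 * w**g)."""

    mu: float = 1e-5
    alpha0: float = 50.0
    g: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.mu <= 1:
            raise InputError(f"mu must be in (0, 1], got {self.mu}")
        if self.alpha0 <= 0:
            raise InputError(f"alpha0 must be > 0, got {self.alpha0}")
        if self.g < 0:
            raise InputError(f"g must be >= 0, got {self.g}")


@dataclass(frozen=True)
class DecliningRateParams:
    """Rate mu0 * w**(-g); constant beneficial DFE Exponential(alpha)."""

    mu0: float = 1e-5
    alpha: float = 50.0
    g: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.mu0 <= 1:
            raise InputError(f"mu0 must be in (0, 1], got {self.mu0}")
        if self.alpha <= 0:
            raise InputError(f"alpha must be > 0, got {self.alpha}")
        if self.g < 0:
            raise InputError(f"g must be >= 0, got {self.g}")


@dataclass
class FiniteSitesParams:
    """L sites with fixed per-site effects; constant per-individual rate mu.

    ``site_effects`` may be supplied explicitly; otherwise each run draws the
    L effects once from Exponential(rate=alpha) with its own seeded
    generator and they stay fixed for that run.
    """

    mu: float = 1e-5
    L: int = 100
    alpha: float = 50.0
    site_effects: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.mu <= 1:
            raise InputError(f"mu must be in (0, 1], got {self.mu}")
        if self.L < 1:
            raise InputError(f"L must be >= 1, got {self.L}")
        if self.alpha <= 0:
            raise InputError(f"alpha must be > 0, got {self.alpha}")
        if self.site_effects is not None:
            arr = np.asarray(self.site_effects, dtype=float)
            if arr.shape != (self.L,):
                raise InputError(
                    f"site_effects must have length L={self.L}, got shape {arr.shape}"
                )
            if np.any(arr <= 0):
                raise InputError("site_effects must all be > 0")
            self.site_effects = arr

    def realized(self, rng: np.random.Generator) -> "FiniteSitesParams":
        """Return a copy with site effects drawn if not already fixed."""
        if self.site_effects is not None:
            return self
        effects = rng.exponential(1.0 / self.alpha, size=self.L)
        return FiniteSitesParams(self.mu, self.L, self.alpha, effects)


@dataclass(frozen=True)
class FgmParams:
    """Fisher's geometric model: n traits, isotropic normal steps of sd sigma."""

    mu: float = 1e-5
    n: int = 10
    sigma: float = 0.05
    decay: str = "gaussian"

    def __post_init__(self) -> None:
        if not 0 < self.mu <= 1:
            raise InputError(f"mu must be in (0, 1], got {self.mu}")
        if self.n < 1:
            raise InputError(f"n must be >= 1, got {self.n}")
        if self.sigma <= 0:
            raise InputError(f"sigma must be > 0, got {self.sigma}")
        if self.decay != "gaussian":
            raise InputError(f"unknown decay form {self.decay!r}")


@dataclass(frozen=True)
class ModelSpec:
    """One of the four macroscopic-epistasis model parameterizations."""

    kind: str
    params: Any

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise InputError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")
        expected = _PARAM_TYPES[self.kind]
        if not isinstance(self.params, expected):
            raise InputError(
                f"model kind {self.kind!r} requires {expected.__name__}, "
                f"got {type(self.params).__name__}"
            )

    @property
    def mu(self) -> float:
        """Baseline per-individual mutation rate of the model."""
        return self.params.mu0 if self.kind == "declining_rate" else self.params.mu


_PARAM_TYPES = {
    "diminishing_effects": DiminishingEffectsParams,
    "declining_rate": DecliningRateParams,
    "finite_sites": FiniteSitesParams,
    "fgm": FgmParams,
}


def diminishing_effects(mu: float = 1e-5, alpha0: float = 50.0, g: float = 1.0) -> ModelSpec:
    return ModelSpec("diminishing_effects", DiminishingEffectsParams(mu, alpha0, g))


def declining_rate(mu0: float = 1e-5, alpha: float = 50.0, g: float = 1.0) -> ModelSpec:
    return ModelSpec("declining_rate", DecliningRateParams(mu0, alpha, g))


def finite_sites(
    mu: float = 1e-5, L: int = 100, alpha: float = 50.0, site_effects=None
) -> ModelSpec:
    return ModelSpec("finite_sites", FiniteSitesParams(mu, L, alpha, site_effects))


def fgm(mu: float = 1e-5, n: int = 10, sigma: float = 0.05, decay: str = "gaussian") -> ModelSpec:
    return ModelSpec("fgm", FgmParams(mu, n, sigma, decay))


def fgm_fitness(z: np.ndarray) -> float:
    """Gaussian fitness function of the geometric model, w(z) = exp(-||z||^2/2)."""
    z = np.asarray(z, dtype=float)
    return float(np.exp(-0.5 * np.dot(z, z)))


# ---------------------------------------------------------------------------
# Core model operations
# ---------------------------------------------------------------------------


def beneficial_rate(model: ModelSpec, w: float) -> float:
    """Per-individual beneficial mutation rate on a background of fitness w.

    Constant for the diminishing-effects, finite-sites and geometric models;
    mu0 * w**(-g) for the declining-rate model.  A computed rate above 1 is
    a model error (the caller must reduce mu0), never silently clipped.
    """
    if w <= 0:
        raise DomainError(f"fitness must be > 0, got {w}")
    if model.kind == "declining_rate":
        rate = model.params.mu0 * w ** (-model.params.g)
    else:
        rate = model.params.mu
    if not 0 <= rate <= 1:
        raise ModelError(
            f"mutation rate {rate} outside [0, 1] for kind={model.kind} at w={w}"
        )
    return float(rate)


def beneficial_rates(model: ModelSpec, w: np.ndarray) -> np.ndarray:
    """Vectorized :func:`beneficial_rate` over an array of class fitnesses."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise DomainError("fitness must be > 0")
    if model.kind == "declining_rate":
        rates = model.params.mu0 * w ** (-model.params.g)
    else:
        rates = np.full(w.shape, model.params.mu)
    if np.any(rates < 0) or np.any(rates > 1):
        raise ModelError(f"mutation rate outside [0, 1] for kind={model.kind}")
    return rates


def spawn_children(
    model: ModelSpec,
    parent_w: np.ndarray,
    parent_states: list,
    parent_idx: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list]:
    """Draw one mutant child per entry of ``parent_idx``.

    ``parent_idx`` indexes into ``parent_w``/``parent_states`` with
    repetition (several mutants may share a parent class).  Returns the
    child fitnesses and child states.  For the finite-sites model a parent
    with every site already mutated yields a child identical to the parent
    (the supply of beneficial mutations is exhausted).
    """
    m = len(parent_idx)
    pw = np.asarray(parent_w, dtype=float)[parent_idx]

    if model.kind == "diminishing_effects":
        rates = model.params.alpha0 * pw ** model.params.g
        s = rng.standard_exponential(m) / rates
        return pw * (1.0 + s), [None] * m

    if model.kind == "declining_rate":
        s = rng.standard_exponential(m) / model.params.alpha
        return pw * (1.0 + s), [None] * m

    if model.kind == "finite_sites":
        params = model.params
        if params.site_effects is None:
            raise StateError(
                "finite_sites site effects not realized; call params.realized(rng) first"
            )
        all_sites = frozenset(range(params.L))
        child_w = np.empty(m)
        child_states: list = []
        for k, idx in enumerate(parent_idx):
            mutated = parent_states[idx]
            if mutated is None:
                raise StateError("finite_sites parent state must be a site set")
            avail = sorted(all_sites - mutated)
            if not avail:
                child_w[k] = pw[k]
                child_states.append(mutated)
                continue
            j = avail[rng.integers(len(avail))]
            child_w[k] = pw[k] * (1.0 + params.site_effects[j])
            child_states.append(mutated | {j})
        return child_w, child_states

    # fgm
    params = model.params
    z = np.vstack([np.asarray(parent_states[i], dtype=float) for i in parent_idx])
    if z.shape[1] != params.n:
        raise StateError(f"fgm phenotype dimension {z.shape[1]} != n={params.n}")
    z_child = z + rng.normal(0.0, params.sigma, size=z.shape)
    w_child = np.exp(-0.5 * np.einsum("ij,ij->i", z_child, z_child))
    return w_child, [z_child[k] for k in range(m)]


def draw_mutant(model: ModelSpec, parent: GenotypeClass, rng: np.random.Generator) -> GenotypeClass:
    """Found a new genotype class from one mutation event on ``parent``."""
    w, states = spawn_children(model, np.array([parent.w]), [parent.state], np.array([0]), rng)
    return GenotypeClass(class_id=-1, w=float(w[0]), count=1, state=states[0])


def founder_at_fitness(model: ModelSpec, w0: float, class_id: int = 0, count: int = 1) -> GenotypeClass:
    """Construct a founder genotype class with fitness exactly w0.

    For the fitness-indexed models and finite sites the fitness is assigned
    directly with a fresh state.  For the geometric model the phenotype is
    placed at distance sqrt(-2 ln w0) from the optimum along the first axis,
    so the Gaussian fitness function returns w0 exactly (requires w0 <= 1).
    """
    if w0 <= 0:
        raise DomainError(f"founder fitness must be > 0, got {w0}")
    if model.kind == "fgm":
        if w0 > 1:
            raise DomainError(f"fgm fitness is bounded by 1, got w0={w0}")
        z = np.zeros(model.params.n)
        z[0] = math.sqrt(-2.0 * math.log(w0)) if w0 < 1 else 0.0
        return GenotypeClass(class_id=class_id, w=w0, count=count, state=z)
    if model.kind == "finite_sites":
        return GenotypeClass(class_id=class_id, w=w0, count=count, state=frozenset())
    return GenotypeClass(class_id=class_id, w=w0, count=count, state=None)


def nested_finite_sites_founders(
    params: FiniteSitesParams,
    n_founders: int,
    rng: np.random.Generator,
    max_fraction: float = 0.9,
    count: int = 1,
) -> list[GenotypeClass]:
    """Founder ladder for the finite-sites model as snapshots of one adaptive walk.

    Under finite sites the available mutations — and hence adaptability — are
    determined by which sites remain unmutated, not by the fitness value
    itself, so a graded founder ladder must pre-fix sites.  Founder j fixes
    the first ``round(j * max_fraction * L / (n_founders - 1))`` sites of a
    random site permutation (shared across the ladder, so founders are
    nested like successive snapshots of a single lineage); its fitness is
    the product of (1 + s_j) over the pre-fixed sites.
    """
    if n_founders < 2:
        raise InputError(f"need at least 2 founders, got {n_founders}")
    if not 0 < max_fraction <= 1:
        raise InputError(f"max_fraction must be in (0, 1], got {max_fraction}")
    params = params.realized(rng)
    order = rng.permutation(params.L)
    founders = []
    for j in range(n_founders):
        k = round(j * max_fraction * params.L / (n_founders - 1))
        fixed = frozenset(int(i) for i in order[:k])
        w = float(np.prod(1.0 + params.site_effects[order[:k]])) if k else 1.0
        founders.append(GenotypeClass(class_id=j, w=w, count=count, state=fixed))
    return founders, params


def founder_ladder(
    model: ModelSpec,
    w_targets: list[float] | np.ndarray,
    count: int = 1,
) -> list[GenotypeClass]:
    """Founders at the requested fitness values (fitness-indexed models and FGM)."""
    return [
        founder_at_fitness(model, float(w0), class_id=j, count=count)
        for j, w0 in enumerate(w_targets)
    ]
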