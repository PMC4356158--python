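"""Composed founder-ladder experiments: simulate, standardize, summarize.

The central in-silico experiment evolves a ladder of founders of graded
initial fitness under one of the four macroscopic-epistasis models, with
many replicates per founder, then feeds the resulting fitness records
through standardization and the adaptability regression.  Declining
adaptability appears as a negative rank correlation between founder fitness
and standardized excess gain, and (for a model with a genuine power-law
regime) a good log-log fit.

Default problem size is a scaled-down clonal-interference configuration,
N = 1e5 and mu = 1e-4 (N*mu = 10, the same supply of new beneficial
mutations per generation as the N = 1e6, mu = 1e-5 headline conditions).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import InputError, InsufficientDataError
from .models import (
    MODEL_KINDS,
    declining_rate,
    diminishing_effects,
    fgm,
    finite_sites,
    founder_ladder,
    nested_finite_sites_founders,
)
from .regression import RegressionResult, fit_loglog
from .simulator import SimConfig, run_experiment
from .standardization import FitnessRecord, standardize


def default_model(kind: str, mu: float = 1e-4):
    """The documented default parameterization of each model at rate mu."""
    if kind == "diminishing_effects":
        return diminishing_effects(mu=mu, alpha0=50.0, g=1.0)
    if kind == "declining_rate":
        return declining_rate(mu0=mu, alpha=50.0, g=1.0)
    if kind == "finite_sites":
        return finite_sites(mu=mu, L=100, alpha=50.0)
    if kind == "fgm":
        return fgm(mu=mu, n=10, sigma=0.05)
    raise InputError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def default_founders(model, n_founders: int, T: int, seed: int):
    """A founder ladder of graded initial fitness appropriate to the model.

    Fitness-indexed models use targets geomspaced on [0.6, 1.0].  The
    geometric model places founders at per-generation deficits spanning
    5e-4 to 5e-3 over the T generations of the experiment.  For finite
    sites, where adaptability is set by the unmutated sites rather than the
    fitness value, the ladder consists of nested pre-adapted genotypes
    (see :func:`macroepi.models.nested_finite_sites_founders`); the realized
    site effects are fixed into the returned model.
    """
    if model.kind == "finite_sites":
        rng = np.random.default_rng(seed)
        founders, params = nested_finite_sites_founders(model.params, n_founders, rng)
        return founders, replace(model, params=params)
    if model.kind == "fgm":
        targets = np.exp(-np.linspace(5e-4, 5e-3, n_founders) * T)
    else:
        targets = np.geomspace(0.6, 1.0, n_founders)
    return founder_ladder(model, targets), model


def aggregate_founder_means(records: list[FitnessRecord]) -> list[FitnessRecord]:
    """Collapse per-replicate records to one mean-final-fitness record per founder."""
    groups: dict[str, list[FitnessRecord]] = defaultdict(list)
    for rec in records:
        groups[rec.genotype_id.split("_rep")[0]].append(rec)
    return [
        FitnessRecord(
            genotype_id=gid,
            w_start=rs[0].w_start,
            w_final=float(np.mean([r.w_final for r in rs])),
            generations=rs[0].generations,
            scale=rs[0].scale,
        )
        for gid, rs in sorted(groups.items())
    ]


@dataclass(frozen=True)
class AdaptabilitySummary:
    """Outcome of one four-model-experiment arm."""

    kind: str
    records: list[FitnessRecord]
    spearman_rho: float
    spearman_pvalue: float
    loglog: RegressionResult | None


def adaptability_experiment(
    kind: str,
    seed: int,
    N: int = 100_000,
    mu: float = 1e-4,
    n_founders: int = 8,
    reps: int = 100,
    T: int = 500,
) -> AdaptabilitySummary:
    """Run one model's founder-ladder experiment and summarize adaptability.

    The rank correlation is computed between founder fitness and the
    per-replicate standardized excess gain (one-sided, negative
    alternative); the log-log regression is fitted to the founder-mean
    records.
    """
    model = default_model(kind, mu)
    founders, model = default_founders(model, n_founders, T, seed)
    cfg = SimConfig(N=N, T=T, model=model, seed=seed, replicates=reps)
    records = run_experiment(founders, cfg, per_replicate=True)

    points = standardize(records)
    w_start = [r.w_start for r in records]
    y = [p.y for p in points]
    rho, pvalue = stats.spearmanr(w_start, y, alternative="less")

    means = aggregate_founder_means(records)
    try:
        loglog = fit_loglog(standardize(means))
    except InsufficientDataError:
        loglog = None
    return AdaptabilitySummary(
        kind=kind,
        records=records,
        spearman_rho=float(rho),
        spearman_pvalue=float(pvalue),
        loglog=loglog,
    )
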