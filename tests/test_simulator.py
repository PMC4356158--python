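"""Wright-Fisher engine: selection, mutation, trajectories, fixation."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from conftest import make_population, naive_selection

from macroepi.errors import InputError
from macroepi.models import diminishing_effects, declining_rate, finite_sites, fgm, founder_at_fitness
from macroepi.population import GenotypeClass
from macroepi.simulator import (
    FitnessTrajectory,
    SimConfig,
    fixation_fraction,
    kimura_fixation_probability,
    mutation_step,
    run,
    run_experiment,
    selection_step,
)


class TestSelectionStep:
    def test_conserves_population_size(self, rng):
        pop = make_population([50, 30, 20], [1.0, 1.1, 0.9])
        for _ in range(20):
            pop = selection_step(pop, rng)
            assert sum(c.count for c in pop.classes) == 100

    def test_single_class_is_identity(self, rng):
        pop = make_population([100], [1.3])
        out = selection_step(pop, rng)
        assert len(out.classes) == 1 and out.classes[0].count == 100

    def test_equal_fitness_preserves_expected_counts(self, rng):
        pop = make_population([50, 30, 20], [1.0, 1.0, 1.0])
        totals = np.zeros(3)
        reps = 10_000
        for _ in range(reps):
            out = selection_step(pop, rng)
            by_id = {c.class_id: c.count for c in out.classes}
            totals += [by_id.get(i, 0) for i in range(3)]
        means = totals / reps
        for mean, c0 in zip(means, (50, 30, 20)):
            se = math.sqrt(c0 * (100 - c0) / 100) / math.sqrt(reps)
            assert abs(mean - c0) < 3 * se

    def test_three_class_frequencies_match_closed_form(self, rng):
        counts, ws = np.array([50, 30, 20]), np.array([1.0, 1.1, 0.9])
        expected = counts * ws / (counts * ws).sum()
        pop = make_population(counts, ws)
        totals = np.zeros(3)
        reps = 10_000
        for _ in range(reps):
            out = selection_step(pop, rng)
            by_id = {c.class_id: c.count for c in out.classes}
            totals += [by_id.get(i, 0) for i in range(3)]
        freqs = totals / reps / 100
        for f, p in zip(freqs, expected):
            se = math.sqrt(p * (1 - p) / 100) / math.sqrt(reps)
            assert abs(f - p) < 3 * se

    def test_matches_naive_per_individual_engine(self, rng):
        # five generations of pure selection at N=200, class engine versus the
        # brute-force per-individual oracle; final mean fitness distributions
        # must be statistically indistinguishable
        counts, ws = [120, 50, 30], [1.0, 1.15, 0.85]
        reps = 2_000
        finals_class = np.empty(reps)
        for r in range(reps):
            pop = make_population(counts, ws)
            for _ in range(5):
                pop = selection_step(pop, rng)
            finals_class[r] = pop.mean_fitness()
        finals_naive = np.empty(reps)
        individuals0 = np.repeat(ws, counts)
        for r in range(reps):
            ind = individuals0
            for _ in range(5):
                ind = naive_selection(ind, rng)
            finals_naive[r] = ind.mean()
        assert stats.ks_2samp(finals_class, finals_naive).pvalue > 0.01

    def test_fisher_fundamental_theorem(self, rng):
        # E[delta mean fitness] under pure selection = Var(w) / mean(w)
        counts, ws = np.array([40, 35, 25]), np.array([1.0, 1.2, 0.8])
        p = counts / counts.sum()
        mean_w = float(p @ ws)
        var_w = float(p @ ws**2 - mean_w**2)
        expected_delta = var_w / mean_w
        pop = make_population(counts, ws)
        reps = 10_000
        deltas = np.empty(reps)
        for r in range(reps):
            deltas[r] = selection_step(pop, rng).mean_fitness() - mean_w
        se = deltas.std(ddof=1) / math.sqrt(reps)
        assert abs(deltas.mean() - expected_delta) < 3 * se


class TestMutationStep:
    def test_zero_effective_rate_keeps_population(self, rng):
        # declining_rate with huge g at w>1 drives the rate to ~0
        model = declining_rate(mu0=1e-300, alpha=50.0)
        pop = make_population([100], [1.0])
        out = mutation_step(pop, model, rng)
        assert len(out.classes) == 1 and out.classes[0].count == 100
        assert out.generation == pop.generation + 1

    def test_expected_mutation_events(self, rng):
        # N * mu = 10 expected events per generation at N=1e6, mu=1e-5
        model = diminishing_effects(mu=1e-5, alpha0=100.0)
        pop = make_population([1_000_000], [1.0])
        reps = 1_000
        events = np.empty(reps)
        for r in range(reps):
            out = mutation_step(pop, model, rng)
            events[r] = sum(c.count for c in out.classes if c.class_id != 0)
        se = events.std(ddof=1) / math.sqrt(reps)
        assert abs(events.mean() - 10.0) < 3 * se

    def test_conserves_population_size(self, rng):
        model = fgm(mu=0.05, n=3, sigma=0.1)
        pop = make_population([500], [0.8], states=[founder_at_fitness(model, 0.8).state])
        for _ in range(10):
            pop = mutation_step(selection_step(pop, rng), model, rng)
            assert sum(c.count for c in pop.classes) == 500


class TestRun:
    def _config(self, **kw):
        defaults = dict(N=500, T=50, model=diminishing_effects(mu=1e-3, alpha0=50.0), seed=7)
        defaults.update(kw)
        return SimConfig(**defaults)

    def test_no_mutation_keeps_fitness_constant(self):
        model = declining_rate(mu0=1e-300)
        cfg = self._config(model=model)
        founder = replace(founder_at_fitness(model, 0.9), count=500)
        traj = run(cfg, founder)
        assert np.all(traj.mean_w == pytest.approx(0.9))

    def test_deterministic_under_seed(self):
        cfg = self._config(seed=123)
        founder = replace(founder_at_fitness(cfg.model, 0.8), count=500)
        t1, t2 = run(cfg, founder), run(cfg, founder)
        assert np.array_equal(t1.mean_w, t2.mean_w)
        t3 = run(replace(cfg, seed=124), founder)
        assert not np.array_equal(t1.mean_w, t3.mean_w)

    def test_founder_count_must_equal_n(self):
        cfg = self._config()
        with pytest.raises(InputError):
            run(cfg, founder_at_fitness(cfg.model, 1.0, count=10))

    def test_recording_cadence(self):
        cfg = self._config(T=55, record_every=20)
        founder = replace(founder_at_fitness(cfg.model, 1.0), count=500)
        traj = run(cfg, founder)
        assert list(traj.generations) == [0, 20, 40, 55]
        assert traj.final_w == traj.mean_w[-1]

    def test_beneficial_only_models_gain_fitness(self):
        # models A-C draw beneficial effects only; mean fitness rises
        for model in (
            diminishing_effects(mu=2e-3, alpha0=30.0),
            declining_rate(mu0=2e-3, alpha=30.0),
            finite_sites(mu=2e-3, L=50, alpha=30.0),
        ):
            cfg = self._config(model=model, T=100)
            founder = replace(founder_at_fitness(model, 1.0), count=500)
            traj = run(cfg, founder)
            assert traj.final_w > 1.0

    def test_finite_sites_adaptation_halts_at_exhaustion(self):
        # tiny landscape: once every site is mutated in the whole population
        # the trajectory goes flat at the global maximum
        effects = np.array([0.5, 0.4, 0.3])
        model = finite_sites(mu=0.02, L=3, site_effects=effects)
        cfg = SimConfig(N=1000, T=300, model=model, seed=5, record_every=50)
        founder = replace(founder_at_fitness(model, 1.0), count=1000)
        traj = run(cfg, founder)
        w_max = float(np.prod(1 + effects))
        assert traj.final_w == pytest.approx(w_max, rel=1e-9)
        assert np.all(traj.mean_w <= w_max + 1e-9)

    def test_fgm_fitness_bounded_by_one(self):
        model = fgm(mu=5e-3, n=4, sigma=0.1)
        cfg = SimConfig(N=1000, T=200, model=model, seed=9)
        founder = replace(founder_at_fitness(model, 0.4), count=1000)
        traj = run(cfg, founder)
        assert np.all(traj.mean_w <= 1.0)
        assert traj.final_w > 0.4


class TestFixation:
    def test_kimura_formula_neutral_limit(self):
        assert kimura_fixation_probability(100, 0.0) == pytest.approx(1 / 100)
        assert kimura_fixation_probability(1000, 0.05) == pytest.approx(
            (1 - math.exp(-0.1)) / (1 - math.exp(-100)), rel=1e-12
        )

    def test_batched_runner_matches_selection_step_engine(self, rng):
        # the batched two-class runner and the generic class engine implement
        # the same law; compare fixation fractions on a small toy
        N, s, init = 50, 0.1, 5
        reps_engine = 800
        fixed = 0
        for r in range(reps_engine):
            pop = make_population([N - init, init], [1.0, 1.0 + s])
            while len(pop.classes) > 1:
                pop = selection_step(pop, rng)
            fixed += pop.classes[0].w == 1.0 + s
        f_engine = fixed / reps_engine
        f_batched = fixation_fraction(N, s, 20_000, rng, init_count=init)
        se = math.sqrt(f_batched * (1 - f_batched) / reps_engine)
        assert abs(f_engine - f_batched) < 4 * se

    def test_batched_runner_validates_input(self):
        with pytest.raises(InputError):
            fixation_fraction(1, 0.1, 10, 0)
        with pytest.raises(InputError):
            fixation_fraction(100, 0.1, 10, 0, init_count=100)


class TestRunExperiment:
    def test_single_founder_no_mutation(self):
        model = declining_rate(mu0=1e-300)
        cfg = SimConfig(N=200, T=20, model=model, seed=3)
        founder = founder_at_fitness(model, 0.75)
        (rec,) = run_experiment([founder], cfg, reps=1)
        assert rec.w_start == 0.75 and rec.w_final == pytest.approx(0.75)
        assert rec.generations == 20

    def test_identical_founders_agree_within_error(self):
        model = diminishing_effects(mu=1e-3, alpha0=50.0)
        cfg = SimConfig(N=500, T=50, model=model, seed=11)
        founders = [founder_at_fitness(model, 0.9, class_id=i) for i in range(3)]
        recs = run_experiment(founders, cfg, reps=40, per_replicate=True)
        gains = {}
        for r in recs:
            gains.setdefault(r.genotype_id.split("_")[0], []).append(
                math.log(r.w_final / r.w_start)
            )
        means = [np.mean(v) for v in gains.values()]
        ses = [np.std(v, ddof=1) / math.sqrt(len(v)) for v in gains.values()]
        for m in means:
            assert abs(m - np.mean(means)) < 4 * max(ses)

    def test_per_replicate_record_count(self):
        model = diminishing_effects(mu=1e-3)
        cfg = SimConfig(N=100, T=5, model=model, seed=2)
        founders = [founder_at_fitness(model, w, class_id=i) for i, w in enumerate((0.8, 1.0))]
        assert len(run_experiment(founders, cfg, reps=3)) == 2
        assert len(run_experiment(founders, cfg, reps=3, per_replicate=True)) == 6

    def test_empty_founders_rejected(self):
        with pytest.raises(InputError):
            run_experiment([], SimConfig(N=10, T=1, model=fgm(), seed=0))


def test_trajectory_length_invariant():
    with pytest.raises(Exception):
        FitnessTrajectory(np.array([0, 1]), np.array([1.0]))
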