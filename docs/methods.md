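# Methods

## Standardization

Fitness measurements enter on one of three declared scales: `relative`
(a per-generation multiplier, the usual competition-assay statistic),
`growth_rate_ratio` (a ratio accumulated over a multi-generation assay,
converted by the root `value**(1/assay_generations)`), or `malthusian_exp`
(e raised to a per-generation Malthusian difference; numerically an
identity).  After conversion, the natural log of any value is a Malthusian
difference per generation, the scale on which population genetics composes
fitness additively.

Coordinates are taken against the fittest founder of the collection
(ties broken to the lexicographically smallest genotype id):

    x_i = ln(w_i_start / w_ref_start) / G
    y_i = [ln(w_i_final / w_i_start) - ln(w_ref_final / w_ref_start)] / G

Division by the elapsed generations G makes collections evolved for
different durations comparable; G may be set per record or overridden per
collection.  The reference maps to (0, 0) by construction, and both
coordinates are invariant under multiplying every fitness in a collection
by one positive constant — a property the test suite checks to 1e-12.

The initial ratio is computed from the *starting* fitness.  An alternative
convention that uses the final fitness in the numerator is exposed as
`standardize(..., x_from_final=True)` for comparison; it breaks the
anchoring of the reference at the origin and is not the default.

## The simulation engine

Reproduction is discrete-generation Wright–Fisher: each generation, N
offspring are drawn by multinomial resampling with class probabilities
p_i = c_i w_i / Σ_j c_j w_j, then the number of mutating individuals per
class is binomial with the model's per-individual beneficial rate, each
mutant founding a new genotype class.  Moran or overlapping-generation
schemes would change time scaling but not the comparative statements made
here; discrete generations match serial-transfer experimental designs.

The population is stored as genotype classes (fitness, count, model state),
not individuals.  Equivalence with a brute-force per-individual simulator
is a tested property (KS-indistinguishable mean-fitness distributions on
N = 200 toys), not an assumption.  Further engine choices:

- Multiple mutations in one individual in one generation are ignored; at
  the rates used (≤ 1e-4) doubles are of order 1e-8 per individual.
- Classes with zero count are pruned every generation.
- Recording is of population mean fitness; the per-replicate "final
  fitness" is the population mean at generation T (a random clone would
  add sampling noise but no bias at the effect sizes used).
- A run's RNG is `default_rng(seed)`; replicate r of founder i in an
  experiment uses `seed + i*reps + r`, so experiments are reproducible and
  replicates independent.
- Fixation probabilities use a two-class specialization of the same
  multinomial law (a multinomial over two classes is a binomial), batched
  across replicates; a test cross-checks it against the generic engine.

Headline conditions are N = 1e6, mu = 1e-5.  The composed experiments and
the acceptance script run a scaled-down configuration, N = 1e5 and
mu = 1e-4 with 8-founder ladders, 25–100 replicates and T = 500
generations, preserving the clonal-interference supply N·mu = 10 while
keeping a full four-model experiment to a few CPU-minutes.

## The four macroscopic-epistasis models

All four share the engine and differ only in `beneficial_rate(w)` and
`draw_mutant`:

- **Diminishing effects** — constant rate mu; effects s ~ Exponential with
  rate alpha_w = alpha0 * w**g, so the mean effect 1/alpha_w decays with
  fitness.  Child fitness w(1+s).
- **Declining rate** — constant DFE Exponential(alpha); rate
  mu_w = mu0 * w**(-g).  A computed rate outside [0, 1] raises an error;
  silent clipping is forbidden.
- **Finite sites** — L sites with effects s_j drawn once per run from
  Exponential(alpha) and then fixed (the standard finite-sites reading; a
  fresh-effect-per-event variant would be a different landscape).  A
  mutation flips a uniformly chosen unmutated site; with all sites mutated
  it is a no-op, so adaptation halts at the global maximum
  ∏(1+s_j) — a tested invariant.  Mutation is irreversible and
  beneficial-only.
- **Fisher's geometric model** — n traits, optimum at the origin, Gaussian
  fitness w(z) = exp(-||z||²/2) (the decay form is tagged so alternatives
  can be added), isotropic normal mutation steps of sd sigma per axis.
  Beneficial and deleterious mutations both occur and none are filtered;
  the beneficial fraction falls toward the optimum (tested), which is the
  model's native source of declining adaptability.

Effects compose multiplicatively as w·(1+s) in models A–C for
comparability; the beneficial-only DFE in A–C reflects that these models
parameterize the *beneficial* tail directly.

Defaults (documented, not canonical): g = 1, alpha0 = alpha = 50 (mean
effect 2% at w = 1), L = 100, n = 10, sigma = 0.05.  They are chosen to
keep typical effect sizes in the 1–10% range observed in microbial
evolution experiments; every one is exposed through the model constructors
and the `model.*` config keys.

### Founder ladders

Founders for the fitness-indexed models use target fitnesses geomspaced on
[0.6, 1.0]; geometric-model founders sit at per-generation deficits of
5e-4 to 5e-3 (placed on the first trait axis at distance sqrt(-2 ln w0),
so the fitness function inverts exactly).

Finite sites needs care: with multiplicative effects and a fixed site DFE,
two founders with *fresh* states but different fitness values have
identical available mutations and therefore identical expected log-gains —
assigning a low fitness alone creates no declining adaptability in this
model.  Adaptability under finite sites is carried by the unmutated sites,
so the ladder is built from **nested pre-adapted genotypes**: a shared
random site permutation is truncated at increasing depths (up to 90% of L),
each founder's fitness being the product over its pre-fixed sites.  This
mirrors sampling founders along one adaptive trajectory, which is how a
fitness gradient arises in a finite-sites world.

## Regression

Ordinary least squares (statsmodels) on natural logs — log-log:
ln y on ln(-x); exponential: ln y on x.  OLS rather than total least
squares because the reported statistics (r, r², F-test p-value) are the
standard regression ones; errors-in-variables correction for noise in x is
out of scope.  The reference point (x = 0) and any genotype with y ≤ 0
cannot enter the log-log fit; they are excluded *and logged with reasons*
in the result.  Both r and r² are reported and labelled, since published
figures are sometimes ambiguous about which is quoted.  Model comparison
prefers the higher r²; numerically identical r² (within 1e-12) is a
flagged tie resolved toward the log-log form.

## Extrapolation

With slope magnitude beta, per-interval gains decay geometrically, giving

    ln(w_t / w_0) = ln(w_1 / w_0) * (1 - (1 - beta)^t) / beta

and the plateau ln(w_1/w_0)/beta as t → ∞.  The exponent reading (1-beta)^t
is required for internal consistency: a product (1-beta)·t yields no
plateau.  The domain is restricted to beta ∈ (0, 2), where |1-beta| < 1
guarantees convergence (monotone below 1, oscillating above); beta = 1 and
the beta → 0 limit (t·first_gain) are continuous extensions.  Small-beta
evaluation uses expm1/log1p to avoid cancellation.  t counts abstract
fitting intervals (e.g. 250-generation measurement windows), not
necessarily single generations.

## Synthetic data

The generator inverts the standardization + power-law model: deficits |x|
uniform on a range (the paper-like datasets give no within-study
distribution of initial fitness, so uniform is the least-informative
choice), one genotype pinned at deficit 0 as reference, expected gains
gain_scale·|x|^beta, and Gaussian noise on ln y — the conventional error
model for relative-fitness assays, where assay error is roughly
multiplicative.  The reference's own per-generation gain defaults to the
power-law value at the lower deficit edge (continuity), and is
configurable.  With zero noise the round trip
standardize(generate(...)) is exact to floating precision (tested at
1e-12), which pins the coordinate conventions.

Presets mirror the *designs* of published founder collections — 187
deletion mutants, 64 diverged lines at 250 and 500 generations, 8
antibiotic-resistance point mutants, 23 hypermutator lineages, 8 phage
strains; generation counts within the 240–640 range such experiments span.
Their deficit ranges and noise levels are structural defaults, not fits to
any real dataset; the hypermutator preset emulates its steeper
adaptability only through a larger default generating exponent (1.2
versus 0.8), not through mutation-rate mechanics.  Consequently, passing
tests demonstrate that the pipeline recovers known structure at realistic
sizes and noise levels — not that any particular published slope is
reproduced, which would require the original compiled measurements.

## Known limitations

- No recombination, demographic bottlenecks, or explicit neutral
  diversity; mutation-accumulation designs are emulated only through
  low-fitness founders.
- Models A–C have no deleterious tail; estimates of declining adaptability
  from them cannot show gain reversals (y < 0), which real collections
  containing loss-of-function founders do show.
- Forecast uncertainty is not propagated: confidence bands would require
  an error model for the regression near x → 0, where experimental
  resolution is genuinely limited.
- Rank-correlation significance in the composed experiments treats
  replicates as independent points; founder-level clustering makes this
  anti-conservative for marginal effects (the effects tested are far from
  marginal).
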