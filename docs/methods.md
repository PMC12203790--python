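# Methods

## The model

`staplecycle` tracks, per staple species, two numbers: the moles of
full-length strand *F* and of truncated strand *T* in the staple pool.
Everything else follows from four model components.

**Synthesis purity.** Solid-phase synthesis couples one base at a time with
stepwise yield *y*; a strand of *n* nucleotides is full length with
probability *y*<sup>*n*−1</sup>. Default *y* = 0.99, typical of unpurified
commercial oligos; a 42-mer then starts at 66.2% purity. Truncations are
lumped into a single class per species — the model never needs to know
*where* a strand is short, only that it cannot carry its terminal feature.
A truncated strand is assumed entirely functionless (a strand missing its
5′ cargo counts as truncated even if it could still hybridize).

**Biased folding.** One fold consumes exactly one scaffold-equivalent of
every species. Each consumed copy is drawn from the species' (F, T) pool
with a multiplicative weight β ≥ 1 on full-length copies, so the
probability that a scaffold position displays a full-length staple (its
*occupancy*) is βF/(βF + T). β is this package's parametrization of the
observed preference for full-length strands during folding; it has no
direct experimental readout and is meant to be calibrated. The default
β = 4 places the occupancy of an unpurified 42-mer in the 50–95%
incorporation window reported for 3′ features at 10-fold excess
(4·0.662/(4·0.662 + 0.338) = 0.887).

Expectation mode consumes deterministic fractions (capped at the available
full-length stock near exhaustion). Stochastic mode converts amounts to
integer copies — physically via Avogadro's number, or coarse-grained via
`copies_per_equivalent` — and draws the consumed full-length count from
Wallenius' noncentral hypergeometric distribution (sampling without
replacement with odds β, `scipy.stats.nchypergeom_wallenius`) when a
species has ≤ 10⁵ copies, else from the binomial approximation with
p = βF/(βF + T). Mass is conserved exactly in both modes; sampling without
replacement matters because demand is a large fraction of the pool at
2-fold excess.

**Recovery.** Ethanol precipitation of the post-PEG supernatant is modelled
as a composition-neutral scaling: both F and T are multiplied by the
recovery yield (scalar or per-cycle list), leaving purity unchanged.
Precipitation is not length-selective over 20–60-nt oligos, so no
selectivity parameter is exposed. The 260/230 QC rule flags ratios
strictly above the threshold (default 2.2) for repeat precipitation;
exactly at the threshold passes, since only ratios *much larger* than the
guideline indicate problematic salt carryover.

**Replenishment.** The *typical* policy adds, per species, fresh stock in
the volume `original_volume × (1 − r + r/E)` for recovery yield *r* and
fold-excess *E* — replacing the consumed equivalent plus the recovery
loss; at any *r* this restores the species to exactly *E* equivalents.
Species with a `replenish_fraction_override` instead receive that fixed
fraction of their originally used amount (the labeling-strand rule). The
*alternative* policy, for designs with one shared excess, tops the pool up
to its original total amount in the design's original per-species
proportions. Fresh-strand purity follows its own synthesis model, so
replenishing with purified (y = 1) or unpurified (y = 0.99) stock are both
expressible.

## Campaigns, cost, and the quality score

A campaign is fold → recover → replenish repeated; "*k* rounds of reuse"
means *k* + 1 total folds. The purchase ledger records the full fresh pool
at cycle 0 plus each cycle's top-up, in scaffold-equivalents; the cost
report prices it against the baseline of buying the full excess fresh for
every fold (that is the comparison behind the headline savings numbers).
With uniform excess *E* and ideal recovery the closed form is

> savings(k) = 1 − (E + k) / ((k + 1) E)  →  (E − 1)/E,

which the simulator reproduces to floating precision; one reuse round at
E = 10 takes the unit cost from 10 to 5.5 equivalents per batch (45%), and
ten rounds reach 81.8%. Recovery losses raise the per-cycle purchase to
E(1 − r) + 1 equivalents and lower savings accordingly.

The **quality score** is the product of occupancies over
functional-category species (all species when the design has none). It is
a construct of this package — a joint display probability for the critical
features — used for trend comparison and calibration, not an experimentally
defined yield.

**Fixed points.** Under the typical policy the pool total is pinned at *E*
equivalents, and the purity recursion has a fixed point where the
occupancy removed per cycle equals the purity of the equivalent added:
occupancy(p\*) = f_fresh. Consequently the steady-state quality score
*equals the fresh stock's full-length fraction* — with unpurified 42-mers
(f = 0.662) quality drifts slowly from 0.887 down toward 0.662 (the drift
is ~1% per cycle early on and vanishes geometrically; verified numerically
to 6×10⁻⁸ after 150 cycles), while replenishing with purified stock drives
quality monotonically toward 1. Without replenishment at 2-fold excess the
quality collapses below half its starting value within two cycles for
β ≥ 4 and the pool is exhausted at the third fold — the qualitative
behaviour seen experimentally.

**Volume bookkeeping.** Under replenishment the reaction volume is held
constant. Without replenishment the recorded volume shrinks in proportion
to the remaining pool (reactions are scaled down to keep relative excess),
but the scaffold demand per fold is held constant at one equivalent of the
original scaffold amount, so the equivalents arithmetic — and the
exhaustion cycle — is volume-independent.

**Bias calibration** is 1-D grid least squares: simulate the
expectation-mode quality trajectory at each candidate β, sum squared
deviations from the observations, take the minimizing grid point (ties and
plateaus resolve to the smallest β). Trajectories cut short by exhaustion
pay the full squared observation for unmatched cycles. A flat observed
trajectory under a replenishing policy is flagged unidentifiable. Grid
search is used deliberately: the problem is one-dimensional and bounded,
the objective is cheap, and the result is exactly reproducible.

## Occupancy inference

The cargo-count model is two independent Bernoulli handles per particle; no
handle–handle correlation parameter is offered (steric or avidity effects
are acknowledged confounders, outside scope). Equal handles: each particle
contributes two trials, so p̂ = (n₁ + 2n₂)/(2N); the Wilson score interval
is used on the 2N trials (better behaved than Wald at small counts and
extreme p̂), and the trinomial log-likelihood at p̂ is reported. Unequal
handles: the observed fractions identify the elementary symmetric
functions p₁+p₂ and p₁p₂, so the probabilities are the quadratic roots —
a closed-form moment estimate rather than a full MLE, matching how such
counts are reduced in practice. A negative discriminant (more doubles than
independence permits given the singles) or roots outside [0, 1] yield
`feasible=False` with an explanatory message rather than an exception.

Numerical caveat: recovering (p₁, p₂) from exact forward probabilities is
accurate to ≥ 10 significant digits when the probabilities are separated,
but the discriminant cancels catastrophically as p₁ → p₂ (error ~√ε); the
equal-handle reduction covers that regime.

Homogeneity across cycles uses the chi-square test on the samples × {0,1,2}
table; when any expected cell is below 5 the p-value is computed by seeded
multinomial resampling under the pooled null (2000 replicates by default,
add-one corrected).

## Densitometry

Lane profiles are 1-D traces with position increasing toward faster
migration. Yield = (band-window integral) / (integral over all positions
at or slower than the staple cutoff), i.e. everything heavier than free
staples, after background subtraction. The background is a rolling-minimum
baseline: a median prefilter (window/4 samples) followed by a grey opening
(moving minimum then moving maximum, default window 10% of the profile) —
the 1-D analogue of rolling-ball subtraction. The prefilter matters: a raw
rolling minimum tracks the downward noise excursions and sits ~2–3σ below
the true floor, biasing every integral upward by σ × profile length; with
the prefilter, residuals are zero-mean and are deliberately *not* clipped
at zero so noise cancels on integration. At 1%-of-peak noise the estimator
recovers a 60:40 band-area split within 0.8%. Integration bounds are user
inputs (band windows differ per gel); degenerate inputs (no intensity
above the cutoff, windows outside the profile or straddling the cutoff)
raise errors.

## Synthetic data

The generators produce the three observables the analysis consumes, at the
study's conditions by default, with one explicit RNG stream per call:

* `gen_cargo_counts(p1, p2, N, seed)` — two independent Bernoulli draws per
  particle; sample sizes in tests mirror the 500–1800-particle range of
  real TEM counting experiments.
* `gen_lane_profile(bands, noise_sigma, seed)` — Gaussian bands of known
  area on a flat baseline (default level 2, ~17% of a typical band peak)
  with additive Gaussian noise, clipped at zero; truth (areas, fractions)
  is returned alongside.
* `gen_yield_trajectory(config, true_bias, noise_sigma, seed)` — the
  expectation-mode quality trajectory plus i.i.d. Gaussian noise clipped to
  [0, 1]; σ = 0.02 in recovery tests, a plausible densitometry
  repeatability.

What these emulate — and what they do not: independent handles (no steric
interference between neighbouring cargoes), Gaussian bands on a flat
baseline (no smile, streaking, or well artifacts), i.i.d. yield noise (no
cycle-correlated drift such as progressive depurination). Tests passing on
these fixtures demonstrate that the estimators invert their own generative
models at realistic sizes and noise; they do not certify performance on
real micrograph counts or gel images.

## Problem sizes and determinism

Simulated campaigns in the test suite use 1–150 cycles of a 1–4-species
design; stochastic-mode checks use 10³–10⁶ copies per species and
200–1000 seeded replicates; calibration recovery uses 20 replicates of a
6-cycle trajectory on a 29-point grid; resampling tests use 200–400
replicates of N = 1000-particle samples. These sizes make every
distributional check tight enough to be meaningful while keeping the whole
suite fast. All randomness flows through explicit
`numpy.random.default_rng` seeds; campaign folds derive per-cycle seeds
from the campaign seed, so every result in the package is bit-reproducible
given its configuration.

## Known limitations

* β is a single global weight: no species-specific or cycle-dependent
  incorporation bias, and no thermal-damage (depurination) accumulation —
  the config reserves no-op room for the latter but the model omits it.
* The model consumes one full equivalent of *every* species per fold, so a
  fractional-override label strand is progressively depleted (at excess E,
  after ~E/(1 − override) cycles); in reality labeling strands are not
  consumed stoichiometrically. Give label species adequate excess when
  simulating long campaigns.
* Recovery is composition-neutral and species-uniform per cycle; there is
  no salt-carryover mass model behind the 260/230 rule, which is a pure
  threshold check.
* Cost accounting covers oligonucleotides only (no scaffold, labour, or
  consumables), priced per scaffold-equivalent.
* No sequence-level modelling anywhere: strand lengths suffice.
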