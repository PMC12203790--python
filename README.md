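# staplecycle

Quantitative modelling for **reusing excess DNA-origami staple strands**.

Folding a DNA origami mixes a long scaffold (typically 50 nM) with a large
molar excess of short synthetic staple oligonucleotides; each fold consumes
only one scaffold-equivalent of every staple and the rest is discarded —
the dominant material cost of making therapeutic-scale origami, especially
with chemically modified staples. Recovering the leftover staples and
reusing them, topped up each cycle with a small amount of fresh strand,
can cut oligo costs dramatically. `staplecycle` is for nanotechnology labs
and process modellers who want to reason about that workflow before (or
alongside) running it:

* **Pool-purity dynamics.** Commercial synthesis leaves a strand of length
  *n* full-length with probability *y*<sup>*n*−1</sup> (*y* ≈ 0.99 per
  coupling), so ~⅓ of a typical 42-mer is truncated. Folding preferentially
  incorporates full-length strands; we model this with a multiplicative
  weight β ≥ 1, giving per-position occupancy
  *βF*/(*βF* + *T*) for full-length amount *F* and truncated amount *T*,
  and simulate multi-cycle fold → recover → replenish campaigns in
  expectation or as exact biased sampling without replacement
  (Wallenius' noncentral hypergeometric).
* **Replenishment policies and cost accounting.** The per-species top-up
  volume `original_volume × (1 − recovery_yield + recovery_yield/excess)`,
  the concentration-matching alternative policy, fractional overrides for
  labeling strands, a 260/230 salt-contamination QC rule, and a purchase
  ledger priced against the all-fresh baseline. With uniform excess *E*,
  ideal recovery and *k* reuse rounds, savings are
  1 − (*E* + *k*)/((*k* + 1)*E*) → (*E* − 1)/*E*.
* **Bias calibration.** `BiasCalibration(observed, config, grid).fit()`
  recovers β from a noisy per-cycle yield trajectory by grid least squares.
* **Cargo-occupancy inference.** From counts of particles bearing 0/1/2
  cargoes, `CargoOccupancyModel(counts).fit()` estimates per-handle
  incorporation probabilities under two independent Bernoulli handles —
  equal-*p* MLE *p̂* = (*n*₁ + 2*n*₂)/(2*N*) with Wilson interval, or the
  unequal pair (*p*₁, *p*₂) as roots of
  *x*² − (*P*₁ + 2*P*₂)*x* + *P*₂ = 0 — plus a chi-square homogeneity test
  across reuse cycles.
* **Gel densitometry.** Monomer yield from a 1-D lane profile as the
  band-window integral over everything migrating slower than the free
  staples, after rolling-minimum background subtraction.
* **Synthetic data.** Seeded generators for cargo-count tables, gel-lane
  profiles and noisy yield trajectories, each returning its ground truth.

## Worked example

```python
import staplecycle as sc

design = [
    sc.StapleSpecies("core",   42, sc.StapleCategory.CORE,       fold_excess=5.0,  price_per_equivalent=1.0),
    sc.StapleSpecies("handle", 58, sc.StapleCategory.HANDLE,     fold_excess=10.0, price_per_equivalent=2.0),
    sc.StapleSpecies("cpg",    42, sc.StapleCategory.FUNCTIONAL, fold_excess=20.0, price_per_equivalent=6.0, modified=True),
]
cfg = sc.CampaignConfig(
    design=design, n_reuse_cycles=10,
    policy=sc.ReplenishmentPolicy(kind="typical", fresh_purity_source=sc.SynthesisModel(0.99)),
    recovery=sc.RecoveryConfig(recovery_yield=0.95),
)
res = sc.run_campaign(cfg)
rep = sc.cost_report(res)
print(res.quality_scores)        # [0.887 0.882 0.878 ... 0.849]
print(rep.unit_cost_reuse)       # 27.55
print(rep.unit_cost_fresh)       # 145.0
print(rep.percent_savings)       # 81.0
```

Eleven folds with reuse and typical replenishment at 95% recovery keep the
quality score (joint probability that the CpG feature positions display
full-length strands) at 0.85–0.89, while the oligo cost per batch falls
from 145 to 27.6 currency units — an 81% saving versus folding every batch
from fresh stock.

Occupancy inference on three simulated TEM counting samples
(per-handle truth p₁ = 0.797, p₂ = 0.113):

```python
counts = [sc.gen_cargo_counts(0.797, 0.113, n, seed=s, sample_id=f"SQB{c}", cycle=c)
          for s, (c, n) in enumerate([(0, 570), (6, 612), (11, 549)])]
print(sc.CargoOccupancyModel(counts).fit(kind="unequal").summary())
```

```
Cargo occupancy model (unequal handles)
============================================
sample_id  cycle  n_particles  p_equal  ci_low  ci_high  log_likelihood  feasible     p1     p2
     SQB0      0          570   0.4640  0.4353   0.4931        -78.5038      True 0.8138 0.1143
     SQB6      6          612   0.4502  0.4225   0.4781        -87.7832      True 0.8026 0.0977
    SQB11     11          549   0.4599  0.4306   0.4895        -57.8610      True 0.7853 0.1345
homogeneity across samples: chi2 = 3.658, p = 0.4542 (asymptotic)
```

The moment solution recovers the generating handle probabilities within
sampling error at N ≈ 600 particles per sample, and the homogeneity test
correctly finds no difference across reuse cycles.

A `staplecycle` console script exposes the same operations from the shell
(`simulate`, `cost`, `infer-occupancy`, `gel-yield`, `synth ...`); run
`staplecycle --help`.

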