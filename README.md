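# nichetransfer

Accuracy and temporal transferability of presence–background
environmental niche models (ENMs) built from decadal survey data.

## The problem

Niche models are routinely trained on occurrences from one period and
projected to another — forecasting ranges under climate change, or
hindcasting them for biogeography. The working assumption is that a
model accurate in its own decade stays accurate when transferred. This
package implements a complete, testable framework for measuring that
assumption on serial survey data:

1. **Interpolative models (Im)** — a maxent niche model fitted from one
   decade's occurrences and that decade's climate.
2. **Extrapolative models (Em)** — each Im projected forward onto a
   later decade's climate (with covariate clamping and MESS novel-climate
   diagnostics), then validated against the occurrence data of that
   target decade.
3. **Transferability and mismatch statistics** comparing every Em(s→t)
   with the target decade's own Im(t).
4. **Trait analyses** relating per-species accuracy/transferability
   summaries to life-history categories (range, migration, habitat,
   conservation status, trend, body mass).

Because long-run survey archives are not redistributable, the package
ships a synthetic survey world — fixed circles revisited yearly with
detection error and rare misidentifications, smooth decadal climate
grids that drift but stay analogous, and species with known
climate niches in four range archetypes (widespread/narrow ×
common/rare) — so every stage runs end-to-end against known truth.

## The model and the statistics

The maxent core places a Gibbs density over background cells,
q<sub>λ</sub>(x) ∝ exp(λ·f(x)), with features f spanning linear,
quadratic, product and hinge transforms of the climate covariates, and
minimizes the L1-penalized negative presence log-likelihood

&nbsp;&nbsp;−(1/m) Σ<sub>presences</sub> λ·f(x) + log Σ<sub>background</sub> exp(λ·f(b)) + Σ<sub>j</sub> β<sub>j</sub>|λ<sub>j</sub>|.

At β = 0 the optimum matches presence feature means to their
expectations under q (the maximum-entropy moment conditions); the
default β follows the published sample-size-interpolated multipliers
per feature class.

For each model pair the package computes, from test/train AUC and
thresholded (equal sensitivity–specificity) binary range maps:

| statistic | definition | reading |
|---|---|---|
| IE | AUC_test / AUC_train | > 1 flags over-parameterization |
| AUC_Diff | AUC_train − AUC_test | > 0 flags over-fit |
| TI_H | AUC(Em) / AUC(Im) | < 1: transfer loses accuracy |
| TI_W | (1 − AUC_Diff(Em)) / (1 − AUC_Diff(Im)) | calibration-aware transfer index |
| RRS | Em/Im − 1 if Im < Em, else −(Im/Em − 1) on range areas | ± over/under-prediction |
| OI | \|Im ∩ Em\| / \|Im\| | overlap of predicted ranges |

Supporting machinery: the 19 bioclim summaries from monthly climate
normals, VIF collinearity screening, MESS extrapolation surfaces, the
5 %-of-surveyed-years misidentification filter, per-cell spatial
thinning, uniform pseudo-absence sampling, and a 25 % random test
holdout. The trait battery covers contingency chi-square,
Gaussian-identity GLMs with single-term deletion, Wilcoxon rank-sum and
Kruskal–Wallis tests; a 37-species trait table ships as a fixture.

## Worked example

Build a zero-drift world (identical climates in every decade — the
regime where transfer should be near-perfect) and run the full design:

```python
import nichetransfer as nt

cfg = nt.LandscapeConfig(decadal_drift_sd=0.0, rng_seed=7)
specs = [{"species_id": f"sp{i:02d}",
          "range_class": ["WC", "WR", "NEC", "NER"][i % 4],
          "trend": "stable"} for i in range(8)]
world = nt.build_world(cfg, species_specs=specs)
metrics = nt.run_pipeline(world, n_background=1500, n_hinge_knots=10, seed=7)

em = metrics[metrics.task == "Em"]
print(f"{len(metrics)} models ({len(em)} projections)")
print(f"mean test AUC (Im): {metrics[metrics.task=='Im'].auc_test.mean():.3f}")
print(f"mean TI_H: {em.ti_h.mean():.3f}   mean TI_W: {em.ti_w.mean():.3f}")
print(f"mean RRS: {em.rrs.mean():+.3f}   mean OI: {em.oi.mean():.3f}")
print(nt.species_summaries(metrics).round(3).head(4).to_string(index=False))
```

prints

```
120 models (80 projections)
mean test AUC (Im): 0.881
mean TI_H: 1.019   mean TI_W: 1.026
mean RRS: +0.019   mean OI: 0.862
species  auc_avg  ti_h_avg  ti_w_avg  rrs_avg  oi_avg
   sp00    0.845     1.035     1.039   -0.011   0.903
   sp01    0.925     1.010     1.014    0.023   0.897
   sp02    0.973     1.003     1.012    0.088   0.894
   sp03    0.882     1.005     1.010   -0.010   0.850
```

Eight species over five decades give 5 Im + 10 Em = 15 tasks each
(120 rows). Interpolative models discriminate well (mean test
AUC 0.88) and, with identical climates, the transfer indices sit within
a few percent of 1 while range mismatch stays small (RRS near 0,
overlap near 0.86) — the behaviour the indices are meant to certify.

A `nichetransfer` CLI wraps the same stages
(`simulate`, `plan`, `run-all`, `extent-experiment`, `fit`, `project`).

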