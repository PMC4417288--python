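# lrfdr — likelihood-ratio based false discovery rate control

`lrfdr` implements an empirical-Bayes multiple-testing procedure for very
large families of two-group comparisons — the motivating scale is voxelwise
neuroimaging, where a group contrast produces 10⁵–10⁶ simultaneous tests.
Instead of thresholding p-values, the method models the per-test effect
sizes, thresholds a likelihood ratio, and calibrates the threshold so the
model-based false discovery rate estimate hits a target level.  Among rules
with the same expected number of discoveries, the likelihood-ratio rule
minimizes the false non-discovery rate (FNDR), so at a fixed FDR budget it
finds more of the true signal than the Benjamini–Hochberg (BH) step-up
procedure — in the bundled simulations, 20+ percentage points of FNDR at
moderate effect sizes.

## Model

For test *v* (*v* = 1, …, *N*) with control responses *y<sub>vj1</sub>* and
case responses *y<sub>vj2</sub>*,

- *y<sub>vj1</sub>* = ξ*<sub>v</sub>* + *e<sub>vj1</sub>*,
  *y<sub>vj2</sub>* = ξ*<sub>v</sub>* + *w<sub>v</sub>* + *e<sub>vj2</sub>*,
  with *e<sub>vjk</sub>* ~ N(0, φ*<sub>vk</sub>*);
- the difference of group means *d<sub>v</sub>* | *w<sub>v</sub>* ~
  N(*w<sub>v</sub>*, ψ*<sub>v</sub>*), ψ*<sub>v</sub>* =
  φ*<sub>v1</sub>*/n₁ + φ*<sub>v2</sub>*/n₂ (estimated unbiasedly per test);
- a latent state *o<sub>v</sub>* ∈ {−1, 0, 1} marks each test as an
  interesting negative / uninteresting / interesting positive case, with
  probabilities (p₋₁, p₀, p₁), and the effect is
  *w<sub>v</sub>* | *o<sub>v</sub>* ~ N(*o<sub>v</sub>* μ, σ²) for the null
  state (μ·0 = 0) and N(±μ, τ²) for the alternatives.  The null keeps
  σ² > 0: point nulls are never exactly true at this scale.

The parameters θ = (p₀, p₁, p₋₁, μ, σ², τ²) are estimated by maximizing the
marginal likelihood of the *d<sub>v</sub>* (a heteroscedastic normal
mixture, since every test carries its own ψ̂*<sub>v</sub>*) with a
generalized EM algorithm.  The one-sided test rejects test *v* when the
prior-weighted likelihood ratio

&nbsp;&nbsp;&nbsp;&nbsp;R(*d<sub>v</sub>*; θ) = p₁ f₁(*d<sub>v</sub>*) / (p₀ f₀(*d<sub>v</sub>*)) ≥ α,

equivalently when *d<sub>v</sub>* falls in an explicit per-test rejection
region with cutoffs solved from R(*d*) = α.  The expected number of false
discoveries of that rule is a sum of normal tail masses,
Ê(V)(α) = Σ*<sub>v</sub>* p₀ [Φ(c<sup>L</sup><sub>v</sub>/s₀<sub>v</sub>) + 1 −
Φ(c<sup>U</sup><sub>v</sub>/s₀<sub>v</sub>)], and the FDR estimate is
FDR̂(α) = Ê(V)/max{D, Ê(V)} with D the realized discovery count.  Searching
the observed ratios for the smallest α with FDR̂(α) ≤ κ gives the calibrated
test.  The two-sided version takes three actions — declare negative, null,
or positive — with independently calibrated levels per direction (e.g. 0.05
positive, 0.01 negative), which matters when effects are heavily asymmetric
(all-hypometabolic patient contrasts, for instance).

## Worked example

```python
from lrfdr import (EMConfig, SimConfig, em_fit, generate_dataset,
                   one_sided_test, outcome_counts, summarize_groups)

cfg = SimConfig(p1=0.8, mu=3.0, grid=(100, 100), n_reps=1)
grouped, truth = generate_dataset(cfg, rep_seed=0)
ts = summarize_groups(grouped)
fit = em_fit(ts, model="one_sided", direction="pos", cfg=EMConfig(seed=0))
decisions = one_sided_test(ts, fit.theta, kappa=0.05, direction="pos")
oc = outcome_counts(decisions.delta, truth)
```

which prints (see `examples/one_sided_testing.py`):

```
tests: 10000, truly null: 2000
calibrated cost alpha = 1.431 (reject when the likelihood ratio is at least alpha)
discoveries D = 8046, estimated FDR = 0.0499
realized false discovery proportion = 0.0524
realized false non-discovery proportion = 0.1924
```

The calibration chose the likelihood-ratio cutoff α = 1.431 whose estimated
FDR is just below the 0.05 target; the realized false discovery proportion
(known here because the data are simulated) lands at 0.052.  The
`examples/` directory has one short script per capability: mixture fitting,
one-sided and three-action testing, the BH comparison, and goodness-of-fit
resampling.  A thin CLI exposes the same pipelines
(`lrfdr simulate|fit|test|compare --help`).

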