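# Methods

## The model

Each of N tests compares a control group (n₁ subjects) with a case group
(n₂ subjects).  Responses are normal with a shared per-test baseline ξ_v,
an effect w_v added in the case group, and within-group error variances
φ_v1, φ_v2.  All inference conditions on the per-test difference of means
d_v, which is N(w_v, ψ_v) given the effect, with ψ_v = φ_v1/n₁ + φ_v2/n₂.
The baseline ξ_v cancels in d_v and is never estimated.  ψ_v is replaced by
its unbiased plug-in ψ̂_v from the per-group sample variances and then
treated as known; this sidesteps the downward bias that jointly maximizing
over N nuisance variances would cause.

Effects follow a discrete mixture indexed by the latent state o_v:

| state | meaning | effect distribution |
|---|---|---|
| 0 | uninteresting | w_v ~ N(0, σ²) |
| +1 | interesting, positive | w_v ~ N(+μ, τ²) |
| −1 | interesting, negative | w_v ~ N(−μ, τ²) |

with P(o_v = s) = p_s.  μ is stored nonnegative; direction lives in the
state, and a one-sided analysis fixes p₁ or p₋₁ to zero.  The null variance
σ² is kept strictly positive — at 10⁵⁺ tests, exact point nulls are a
fiction, and modeling the null as "near zero" rather than "exactly zero" is
part of the method.  Both alternative components share μ and τ²; fitting
separate means or variances per direction is not supported (the asymmetry
that matters in practice — effects all on one side — is carried by
p₁ ≠ p₋₁).

Marginally d_v | o_v = s is normal with mean s·μ and variance σ² + ψ_v
(null) or τ² + ψ_v (alternative).  All densities are evaluated in log
space; ratios are exponentiated log-differences.  The source text available
to us garbles the inline formulas around the joint density f_θ(d_v, o_v);
the implementation follows this reconstruction, which is the one consistent
with the surrounding derivations.

## Estimation

θ = (p₀, p₁, p₋₁, μ, σ², τ²) maximizes the marginal log-likelihood
Σ_v log Σ_s p_s f_s(d_v; ψ̂_v).  Because ψ̂_v varies across tests there is
no closed-form M-step for μ, σ², τ²; each EM sweep does

1. E-step: posterior state responsibilities;
2. exact update of the p_s (responsibility means, clipped to
   [10⁻¹⁰, 1−10⁻¹⁰] before renormalizing);
3. exact weighted-mean update of μ given the current τ² (the +μ and −μ
   components pool with signed residuals);
4. bracketed Brent solves of the scalar score equations for τ² and σ²
   (weights 1/(component variance + ψ̂_v)).

Each sweep is a generalized EM step.  Plain sweeps converge slowly when the
components overlap (μ = 1 settings need on the order of 10³ sweeps), so the
driver wraps them in a squared-extrapolation accelerator: two sweeps give
first/second differences r, v in unconstrained coordinates (log-odds
against the null, raw μ, log variances); the extrapolated point
θ₀ − 2a·r + a²·v with a = −‖r‖/‖v‖ clipped to [−32, −1] is accepted only
if it does not lower the log-likelihood, otherwise the plain double sweep
stands.  The recorded trace is therefore non-decreasing by construction
(asserted to 10⁻⁹), and convergence is declared when the scale-free change
|Δℓ|/(|ℓ|+1) drops below `rel_tol` (default 10⁻⁸).

Mixture likelihoods with free component variances are unbounded; the
estimator targets a good interior local maximum instead of the global
supremum.  Two guards implement this: a floor ε = 10⁻⁸ on σ² and τ², and
multi-start — restart 0 uses deterministic moment/quantile starting values
(null fraction from standardized |d| below 1, μ from the extreme quartile,
variances from excess spread over the mean ψ̂), later restarts jitter them
by seeded Uniform(0.5, 2) factors.  The returned fit is the best final
log-likelihood among restarts whose variances ended clear of the floor.  If
every restart collapses onto the floor, the fit fails (`EMError`) rather
than returning a boundary solution: σ̂² ≈ 0 contradicts the model's premise
and marks a spurious maximum, not an interior one.  The study runner counts
such replicates, logs them, and excludes them from averaged error rates —
in the bundled study they are rare (order one per few hundred fits,
concentrated in the heavy-overlap μ = 1 settings at desk scale) and absent
at the full 400 × 400 size.

Two estimation facts worth knowing:

- On data with no alternatives at all, the ridge p₁ → 0 is unidentified
  (a component with μ ≈ 0, τ² ≈ σ² is the null), so individual parameters
  on that ridge are arbitrary even though the fitted marginal is right.
  The identifiable situation — a three-component fit on data whose
  alternatives are all one-signed — does collapse the empty direction's
  mass to zero.
- Treating the plug-in ψ̂_v as known leaves an O(1/n) bias on σ̂², τ̂²
  from the chi-square noise of the sample variances (≈ 0.05 at
  n₁ = n₂ = 30 on the simulation scale).  It does not shrink with N; it
  would shrink with more subjects.

## Testing

With a cost of α per false discovery against 1 per false non-discovery,
the risk-optimal one-sided rule rejects exactly when the prior-weighted
ratio R(d_v) = p₁f₁(d_v)/(p₀f₀(d_v)) ≥ α (ties reject).  log R is quadratic
in d, so each test's rejection set is explicit: for τ² > σ² the complement
of an interval (c^L, c^U) — both tails reject, because extreme d in either
direction favors the wider alternative component — for τ² < σ² an
interval, and linear/degenerate cases are handled in closed form.  Cutoffs
come from the quadratic formula on the log-ratio coefficients; the
decisions themselves are made by direct ratio thresholding, with the
region solver cross-checked against them in the tests and used where the
regions are needed analytically:

- Ê(V)(α) = Σ_v p₀ [Φ(c^L_v/s₀_v) + 1 − Φ(c^U_v/s₀_v)], s₀_v = √(σ²+ψ̂_v):
  the null-component mass of every rejection region.
- FDR̂(α) = Ê(V)(α)/max{D(α), Ê(V)(α)}.  The max guard matters at very
  large N, where the realized D can undershoot Ê(V) and the raw ratio
  would exceed 1; the raw estimator stays available behind `guard=False`.

Calibration scans the observed ratios (the only α values at which the
rejection set changes) for the smallest α with FDR̂(α) ≤ κ.  Up to 4096
candidates the scan is exhaustive.  Above that, a bisection over the
sorted candidates locates the level crossing, followed by a local linear
fix-up; this assumes the FDR̂ path crosses κ once, which holds up to
discreteness wiggles of order 1/D — the estimate can dip by at most the
denominator's unit jump, so any non-monotonicity is O(1/D) and the
bisection is checked against the exhaustive scan in the tests.

The two-sided test takes three actions.  Each direction's α is calibrated
independently against its own ratio (R_P or R_N) and its own level κ₊, κ₋
(they may differ); a test clearing its threshold is assigned the direction
with the larger ratio (ties go positive; with μ > 0 the two rejection
regions are disjoint in practice and the comparison rarely binds).  In
outcome accounting, a discovery with the wrong sign counts as false in the
direction it was assigned — the three-action loss charges misassignments,
not only null rejections — with a flag to relax to null-only counting.

## The synthetic study

`generate_dataset` emulates a smoothed group-comparison image reduced to
independent pixels: a rows × cols lattice, exactly round(p₁N) uniformly
placed alternative pixels with w ~ N(μ, τ²), null pixels with
w ~ N(0, σ²), and per-subject responses with error variance φ in both
groups.  The standard design is a 400 × 400 grid (160,000 tests),
p₁ ∈ {0.8, 0.6}, μ ∈ {1, 3, 5}, σ² = 0.3, τ² = 0.5, n₁ = n₂ = 30,
κ = 0.05, 100 replicates; `figure_grid()` also provides the desk profile
(200 × 200, 20 replicates) that the test suite and the acceptance script
use, trading Monte-Carlo error for a grid sweep that finishes in minutes.

The within-group error variance φ is a free design choice (the study
design fixes everything else); the package sets φ = 15, so
ψ = 15/30 + 15/30 = 1 and the standardized effect sizes are essentially
μ.  On that scale μ = 1 is a heavy-overlap regime (both methods miss most
alternatives — FNDR above 0.5), μ = 3 is mid-power where the methods
separate, and μ = 5 is near-perfect power.  FNDR comparisons between
methods are sensitive to φ: reported gaps (≈ 20 percentage points vs BH at
μ = 3, p₁ = 0.8; ≈ 5 at μ = 3, p₁ = 0.6) hold under this calibration, the
ordering itself is robust.

The per-replicate pipeline matches the real-data pipeline: raw responses →
summaries with estimated ψ̂_v → EM fit (the study profile uses one
jittered restart; the deterministic start lands in the correct basin for
data from this generator) → calibrated test → realized error proportions
against the known truth.  BH runs on one-sided Welch t-tests in the
positive direction (t reference distribution; a normal-approximation
option exists).  Replicate streams come from a counter-based seed split
(master seed, scenario index, replicate index), so results are bit-identical
for a given master seed regardless of execution order.

What the generator does not emulate: spatial correlation between pixels
(real smoothed images are strongly correlated; both methods here assume
independence, and the calibration guarantee is about the independent
case), non-normal effect distributions, unequal group error variances, and
registration/normalization artifacts.  Passing tests therefore demonstrate
correctness of the method under its own model, not robustness to those
violations.

Calibration quality depends on θ̂.  At the full 160,000-test size the
maximum-likelihood estimates are accurate in every scenario and the
realized FDR sits tight around κ.  At desk scale the μ = 1 settings are
only weakly identified — the likelihood occasionally has its global
maximum far from the generating values (verified by starting EM at the
truth), and the calibrated test inherits the error as mild
anti-conservatism in those scenarios.  This is a property of maximum
likelihood at that sample size and overlap, not of the optimizer; the
desk-profile FDR summaries should be read with it in mind.

One systematic consequence of σ² > 0 is worth flagging: the t-statistic's
null reference (variance ψ) is narrower than the model's null (variance
σ² + ψ), so BH on t p-values is not exactly level-κ under this generator.
With large p₁ its step-up conservatism dominates and BH lands well below
κ; in the heavy-overlap μ = 1 settings the two effects can nearly cancel,
putting BH's realized FDR close to (or slightly above) κ while the
likelihood-ratio test stays calibrated.

## Numerical choices

- Variance floor ε = 10⁻⁸; probabilities clipped at 10⁻¹⁰ before
  normalization; EM ascent asserted to −10⁻⁹ per accepted step.
- Brent solves bracket from the floor (score ≤ 0 at the floor returns the
  floor) to a doubling upper bound; tolerance 10⁻¹² absolute.
- Cutoff solver: |quadratic coefficient| < 10⁻¹⁴ switches to the linear
  branch; boundary residuals satisfy |R(c) − α| ≤ 10⁻⁸ α.
- Tie-break at R = α: reject.  This makes the candidate-scan calibration
  exact (the chosen candidate is itself attained).
- Zero ψ̂_v (both groups constant in a row) is an error naming the test,
  not a silent repair.
- `estimate_fdr` returns 0 when both D and Ê(V) are zero; with D = 0 and
  Ê(V) > 0 the guarded estimator saturates at 1 by its own formula.

## Limitations

- Independence across tests is assumed everywhere; no spatial model.
- The common-(μ, τ²) two-sided parameterization cannot represent
  directions with genuinely different effect scales.
- FDR control is model-based: a misspecified mixture voids the guarantee.
  The resampling goodness-of-fit check (`simulate_from_fitted` + KS) is the
  intended first diagnostic.
- No standard errors for θ̂ are produced (point estimates only).
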