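# Methods

## Model

Per gene, observed log-scale expression in group *i* at times x_i is
modeled as y_i = f(x_i − Δt_i) + ε_i with a shared latent function
f ~ GP(0, k) under the squared-exponential kernel
k(t,t') = σ_f² exp(−(t−t')²/(2l²)) and i.i.d. Gaussian noise
ε ~ N(0, σ²). The three structures compared are the independence model
(each group its own unrelated GP draw; the cross-group covariance is
identically zero), the no-shift model (Δt ≡ 0), and the shift model
(free Δt_i for every non-reference group; the first group is the
reference with Δt = 0). The observation covariance is assembled over
the pooled samples, so groups may have arbitrary, unmatched designs and
replicates (tied times stay nonsingular through the σ²I term).

The GP is zero-mean, while expression is not: each gene is centered by
its pooled mean before fitting, and the mean is stored on the fit for
trajectory reconstruction. One (σ_f, l, σ) triple is shared across
groups within each model — including the independence model, whose
joint likelihood is the sum of per-group GP likelihoods under the
shared triple optimized jointly. Sharing keeps LLRshape a comparison of
correlation *structure* rather than of model flexibility; per-group
triples would hand the independence model 2(G−1) extra parameters and
bias shape calls.

## Likelihood, gradients, optimization

log p(y) = −½ yᵀK⁻¹y − ½ log|K| − (N/2) log 2π, computed by Cholesky
factorization. Gradients use the standard trace identity
∂ log p/∂θ = ½ tr[(ααᵀ − K⁻¹) ∂K/∂θ] with α = K⁻¹y; for the shift
parameters, ∂K_ab/∂Δt_i = k(u_a,u_b)·(u_a−u_b)/l²·(1[g(a)=i] −
1[g(b)=i]) on the adjusted times u. Optimization is L-BFGS-B over
(log σ_f, log l, log σ) and raw Δt, so positivity is automatic.

Quasi-Newton searches on GP likelihoods find local maxima; a short
length scale can "connect the dots" of a shifted trajectory and trap
Δt near 0. Three deterministic safeguards address this:

1. restarts from three length-scale inits spanning the observed time
   range (span/4, span/2, span — the largest is the smooth start that
   avoids such overfitting), keeping the best optimum;
2. coarse grid-profile starting values for the shifts: each
   non-reference group's Δt is scanned pairwise against the reference
   (points subsampled, hyperparameters guessed from the data scale),
   and the joint search restarts from the per-group argmins;
3. a post-fit coordinate-profile polish: each Δt is re-scanned on a
   coarse grid at the joint optimum, and the fit re-optimizes whenever
   a dominating basin appears.

Shift-model fits run inside the per-gene orchestration with an extra
warm start at the no-shift optimum with Δt = 0, which enforces the
nesting bound logL(shift) ≥ logL(no-shift) numerically (LLRshift ≥
−10⁻³ is an always-on test invariant). All starts form a deterministic
ladder — fitting involves no randomness, so a fixed input table always
yields byte-identical results regardless of execution order; the user
seed drives the simulators only.

Shifts are bounded to ±0.6 × the pooled time span
(``shift_bound_factor``, adjustable). Far beyond half a span a group
barely overlaps the others and its offset stops being identifiable:
the marginal likelihood then *rewards* degenerate optima that slide
the group outside the shared support (its block decouples and fits
itself), and periodic trajectories alias at whole periods (for the
sine benchmark the period equals the span, so Δt and Δt − 10 are
indistinguishable by likelihood alone). The 0.6-span bound excludes
those failure modes while leaving headroom above the largest shifts
the overlap can actually identify; widen it only for data whose groups
genuinely overlap across larger offsets. When two basins are
statistically tied (within a few nats), the fit reports the
minimal-magnitude shift — the canonical representative of an offset
identified modulo a period.

Numerical guards: diagonal jitter 10⁻⁸ σ_f² before factorization; σ
floored at 10⁻⁴ × (per-gene data sd) so noiseless genes stay well
conditioned; log σ_f and log l get wide data-scaled bounds purely to
keep exponentials finite. Optimizer tolerances are L-BFGS-B defaults
with gtol 10⁻⁶ and ≤ 300 iterations; a gene whose restarts all fail is
flagged non-converged, never raised.

## Classification

LLRshape = logL(shift) − logL(independence); LLRshift = logL(shift) −
logL(no-shift). Both are plain log-likelihood differences (no factor of
2), and the thresholds are interpreted on that scale. Fixed mode labels
DiffShape when LLRshape < Λshape (default 50), shift when LLRshape ≥
Λshape and LLRshift > Λshift (default 50), else no-shift. Adaptive mode
derives cutoffs from the analyzed cohort: DiffShape below mean − 2 sd
of LLRshape (sample sd, n−1), shift above the mean with LLRshift > 10.
Ties at any threshold resolve toward the less extreme class (no-shift),
recorded in the output metadata. The adaptive mean/sd are taken over
all genes with defined LLRs in the table handed to the classifier.

## Pre-selection

Real-data workflows first keep temporally dynamic genes: per gene, OLS
of expression on {1, t, t², t³} pooled across all groups (time for
developmental series is log2 of post-conceptional days), retaining
genes with R² ≥ 0.5 by default. R² of a constant-expression gene is
defined as 0 and such genes are never retained, including at threshold
0. Time is centered and scaled inside the fit for conditioning only;
R² is invariant to that and to affine rescaling of expression.

## Simulators

The three generators reproduce the benchmark study conditions and are
the package's test bed:

- **gp** — f drawn multivariate-normal from the kernel covariance
  (σ_f = 5, l = 3) assembled under the generating structure
  (independence: per-group draws; no-shift: one pooled draw; shift:
  pooled draw at shifted times), plus noise σ ∈ {0.5, 1};
- **periodic** — y = sin(2π(x − Δt)/10) + ε, ε ~ N(0, sd 0.3). Over a
  full period the sine has variance ½, so the noise fraction is
  0.09/0.59 ≈ 15% of total variance;
- **polynomial** — y = a + b(u−10) + c(u−10)², u = x − Δt, ε ~ N(0,
  sd 3). The coefficients are not fixed by the source conditions;
  defaults a = 0, b = 1.5, c = 1.0 give Var(bu) = 18.75 and
  Var(cu²) = 55.6 for u ~ U(−5,5), hence a noise fraction
  9/83.3 ≈ 10.8% ≈ the stated ≈10%. They are spec fields and can be
  overridden.

Everywhere "N(0, s)" is interpreted with s as the *standard deviation*,
not the variance — the interpretation under which the stated ≈15% and
≈10% residual-variance fractions come out right.

Common conditions: 100 genes per scenario, 100 time points per group
drawn uniform on [5, 15]; the grid is drawn once per scenario per group
and shared across that scenario's genes (per-gene redraw is available
via `redraw_times_per_gene=True`); two-group true shift fixed at 2;
three-group shifts drawn per gene from N(2, 1) for group 2 and
N(−2, 1) for group 3 (means cycle with sign alternating for more
groups). Noise realizations are retained per gene so the generator's
residual-variance fraction (Var(ε)/Var(y), pooled, n−1 denominators)
is computed from the actual draws rather than from nominal values.

What the simulators do *not* emulate: count noise (negative binomial),
dropout, batch effects, or gene–gene correlation. Passing benchmarks
therefore demonstrates correct shift recovery and model separation
under Gaussian noise with smooth trajectories, not robustness to
technical artifacts of real sequencing data.

## Scoring shift recovery

The benchmark harness reports, per non-reference group, the mean
squared prediction error (MSPE) of estimated versus true shifts across
genes. For the sine generator the offset is identified only modulo the
period — a trajectory shifted by a whole period is the same
trajectory, and the fitted likelihoods of Δt and Δt ± 10 are equal to
within noise — so the harness folds periodic-scenario errors into
(−period/2, period/2] before squaring. The estimator itself always
reports the minimal-magnitude representative of a tied offset. The
other generators are aperiodic and use plain differences.

## Benchmark problem sizes

The acceptance script and the study-scale tests use the full scenario
size (100 genes × 100 points per group, two- and three-group); a
two-group scenario fits in well under a minute and a three-group one in
a couple of minutes. Unit tests use 10–40 point genes, where one fit
takes milliseconds.

## Known limitations

- LLR thresholds are heuristics, not calibrated test statistics; no
  FDR control is attempted.
- The shift model captures one global offset per group; time-varying
  (windowed) shifts and shape-plus-shift mixtures are out of scope.
- Only the squared-exponential kernel is implemented; strongly periodic
  data are still fit well enough for shift recovery (the sine
  benchmark), but extrapolation beyond the data range is not meaningful.
- Marginal-likelihood maximization is local; the restart ladder makes
  Δt ≈ true-shift basins reliably reachable in the benchmarks, but
  pathological multi-modal genes can still converge to a local optimum
  (periodic trajectories have aliased optima at Δt ± period).
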