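# Methods

`lineagegrowth` analyses long-term single-cell buoyant-mass traces from
ancestral lineages (one retained daughter per division, as recorded by a
suspended microchannel resonator, SMR) and asks where cell-to-cell growth
variability comes from: cell-size control, division events, or continuous
growth-rate noise.  This note documents the models, estimators, default
parameters and the design choices that were genuinely open.

## Signal model

For a lineage, per-cell log masses are pasted into one continuous signal

    f(t) = ln M_i(t)/M_i^b + sum_{j<i} ln M_j^d / M_j^b,

(`stitched_log_mass`), with the last `mitosis_window` hours of each cycle
excised (default 0.5 h; mitotic mass dynamics are not modelled, and the
source analyses likewise drop mitoses without stating a duration).  Divisions
are detected either from explicit cell markers or from a fractional mass drop
between consecutive samples (default threshold 0.25); the first and last
segments of a trace are flagged partial and excluded from statistics, except
that a leading segment spanning at least 0.9 of a doubling is accepted as a
complete cycle (a trace that genuinely starts at birth).  Units are fixed to
hours and picograms.

The decomposition (`gp_decomposition`) is an additive Gaussian process

    f(t) = lambda0 t + f_trend(u(t)) + f_flucs(t) + eps(t),

with

- a Gaussian prior on the lineage drift rate lambda0 (a broad, fixed prior
  variance of 1e-2 (1/h)^2; the posterior concentrates within iterations and
  the exact value is immaterial),
- a squared-exponential kernel on the *relative cell age* u = (t - t_birth)/tau,
  shared by all cells of the lineage — the age trend is a property of the
  cycle, not of absolute time.  The kernel is centred against the observed age
  distribution so the trend integrates to zero over the cycle, removing the
  additive degeneracy with the drift;
- an integrated-Ornstein-Uhlenbeck kernel in absolute time for f_flucs,
  cov(A_s, A_t) with A the integral of a stationary OU process pinned at
  A_0 = 0.  This choice makes lambda_flucs = f_flucs' *exactly* an OU process,
  so the decomposition and the downstream null model share one law;
- white Gaussian measurement noise eps.

Sums and derivatives of GPs are GPs, so the component posteriors and the
derivative posteriors (lambda_trend through the 1/tau age chain rule;
lambda_flucs directly) are analytic.  Component posterior means plus the
residual reproduce the input signal identically.

Hyperparameters (trend amplitude and lengthscale, OU stationary variance and
relaxation rate, noise variance) are chosen by multi-start L-BFGS ascent of
the log marginal likelihood in log-parameter space.  Cholesky factorizations
escalate jitter geometrically from 1e-10 to 1e-4 of the mean diagonal before
declaring the covariance non-PSD.  Grids larger than `n_exact` (default 4000)
are thinned to an evenly strided training subset (subset-of-data
approximation) from which the posterior is evaluated on every input point;
hyperparameter optimization runs on an at most `n_opt`-point subset (default
600).  On medium grids the thinned and exact posteriors agree to r > 0.98
(tested).

Identifiability caveats: (i) the lineage-mean of lambda_flucs is absorbed by
the drift posterior — fluctuation series are therefore only defined up to an
additive constant, and recovery statistics are computed after mean-centring;
(ii) the trend kernel's amplitude and lengthscale are only jointly
identified on single-lineage data (a likelihood ridge), so self-consistency
checks compare the identifiable set (gamma, OU variance, noise variance).

## Two-parameter null model

lambda_flucs follows d lambda = -gamma lambda dt + sqrt(2D) dW, optionally
perturbed at each division by an independent Normal(0, sigma_z^2) kick.
Closed forms used throughout (all verified against brute-force simulation in
the test suite):

- stationary variance D/gamma; ACF exp(-gamma tau);
- exact var(A_t) = (2D/gamma^2) (t - (1 - e^{-gamma t})/gamma) for a
  stationary start;
- asymptotes for the variance of the time-averaged growth rate
  var(lambda_bar_t): continuous part 2D/(gamma^2 t) (slope -1 in log-log),
  kick part sigma_z^2/(gamma t)^2 (slope -2), valid for t >> 1/gamma.

`fit_variance_matching` estimates (gamma, D) by least squares between the
empirical and exact var(A_t) on an age grid, on the log-variance scale.  The
empirical curve pools integration windows starting at origins spaced 0.2 h
apart within each cell (stationarity makes every origin equivalent to birth);
this tightens the short-age end of the curve, which carries the curvature
that identifies gamma, and roughly halves the error of one-window-per-cell
estimation.  Two estimator pitfalls worth recording: requiring cells to span
the whole age grid selects long-generation-time cells, whose fluctuation
level is low under adder feedback, and biases the variance down ~15% — each
age therefore uses every window that fits; and an absolute-scale loss lets
the (noisy) large-age variances dominate, so the loss is logarithmic.  Even
so, the statistic carries limited information per lineage: at 29 cells of
~10 h the median relative error of gamma and D is ~20-30% (each lineage
contributes on the order of tau/(2/gamma) independent fluctuation patches,
and the ridge between gamma and D leaves the shape weakly determined).  This
is an information floor of the variance-matching statistic, not an optimizer
artefact; per-lineage estimates should be treated as ~25%-accurate and
pooled across lineages where possible.

`predict_cv` simulates pure-OU (sigma_z = 0) fluctuation paths over the
observed cell structure and returns the across-cell SD of lambda_bar —
the null model's prediction of within-lineage growth variability.

The MSD suite splits mean-squared displacements of lambda_flucs into pairs
confined to one cell and pairs spanning exactly one consecutive-cell
boundary; the ratio between/(between+within), averaged over lags up to 4 h,
is ~0.5 when displacements share one law (division-blind noise) and
approaches 1 when divisions inject kicks.  Lags are counted in sample steps
and mapped to hours via the median sampling interval; excised mitotic gaps
are not special-cased.  `msd_ratio_calibration` builds the reference curve by
apportioning a fixed var(lambda_bar) between the two sources — the OU share
via the exact var(A_t)/t^2 at t = <tau>, the kick share via its asymptote —
and running simulated lineages through the full GP + MSD pipeline.

## Size control and division statistics

The autoregressive model Mf = 2(1-a) M0 + 2a E[M0] + xi relates birth masses
across generations; with only one daughter observed, Mf is taken as twice
the retained daughter's birth mass, which keeps partitioning noise inside
xi.  a = 1 - slope/2; the covariance form alpha = -cov(x, lambda_bar tau)/var(x)
(x = ln M0) agrees with a when noise is small, and
alpha_lambda = -E[tau] cov(x, lambda_bar)/var(x) isolates the growth-rate
share of the correction.  Per-lineage estimates carry the usual
autoregression small-sample bias (order (1+3 phi)/n toward weaker mean
reversion, i.e. alpha biased up by ~0.1-0.2 on 10-15-cell lineages); pooled
summaries weight lineages by their number of complete cycles.

Division asymmetry is 100 |M_b^daughter - M_d^mother/2| / (M_d^mother/2) — the
deviation from a perfectly symmetric mass split — and the growth-rate change
at division is the absolute percent change of lambda_bar with the mother as
baseline.  Autocorrelations use the plug-in estimator with the global series
mean and population SD, so ACF(0) = 1 exactly.

## Synthetic data generator

`synthetic_data.generate_dataset` emulates the experimental conditions the
analyses were designed for.  Defaults and their provenance:

| parameter | default | why |
|---|---|---|
| lambda0 | 0.068 1/h | base rate; implies mean tau = ln2/lambda0 ~ 10.2 h |
| lineage_rate_cv | 0.11 | ~11% lineage-to-lineage CV of the mean rate |
| trend amplitude / peak | 0.028 1/h at age 0.5 | birth-to-peak rise of the cell-age trend |
| 1/gamma | 5 h | fluctuation relaxation time |
| D | 1.0e-5 1/h^3 | chosen so within-lineage CV(lambda_bar) ~ 8% given gamma and tau (stationary fluctuation SD 0.007 1/h) |
| sigma_z | 0 | division-blind noise is the default (the supported model) |
| added-mass noise | SD = 0.25 x mean added mass | reproduces tau = 10.2 +/- 2.0 h together with the growth noise |
| asymmetry SD | 0.0376 | folded-normal mean |asymmetry| ~ 3% |
| measurement CV | 0.001 | ~0.1% multiplicative mass precision |
| sampling dt | 1 min | trap measurement cadence |
| mitosis gap | 0 h | see below |

The simulator integrates dM/dt = (lambda0 + lambda_trend(u) + lambda_flucs) M
on the sampling grid with the exact OU discretization, divides at the first
sample where the autoregressive mass target is reached (parameter a,
default 0.5 = adder; a fixed-tau mode exists for controlled experiments),
passes a Normal near-half fraction to the daughter, and adds multiplicative
observation noise.  Because tau is emergent under the adder rule, the trend's
age argument uses a provisional tau computed at birth from the division
target; the discrepancy is O(CV(lambda_bar)) and the generated trend values
are stored in the ground truth exactly as used.  Traces start and end
mid-cycle (as real traps do) so segmentation sees a partial cycle at each
end.  A `mitosis_gap` knob withholds the observations just before each
division; it defaults to 0 because the pipeline's own mitosis handling is the
excision window, and a nonzero gap makes sub-sample division-time recovery
impossible by construction.

What the generator does *not* emulate: mitotic mass dynamics, measurement
drift (a knob exists for the noise CV only), volume regulation, sister-cell
correlations, and any size-coupling of division noise.  Passing recovery
tests therefore demonstrates correctness of the estimators under the stated
generative assumptions, not robustness to every artefact of real traces.

## Numerical and testing choices

- All stochastic routines take explicit seeds (NumPy `SeedSequence`
  spawning); identical seeds give identical datasets.
- Relaxation-time fits use lags where ACF > 0.2 (threshold configurable);
  the ACF of a finite series is noisy beyond that point.
- The variance-matching age grid is log-spaced below 3 h and linear up to
  0.9 of the median cell span; origins are spaced 0.2 h.
- Degenerate inputs: a fluctuation series with no variance returns D = 0
  with a warning (gamma is then unidentifiable and set to 1/h); constant
  series make the MSD ratio undefined (0/0) and regressions on constant
  covariates report zero slope with an undefined p-value.
- Acceptance-style checks run at reduced problem sizes chosen to keep the
  whole suite inside a normal CI budget: calibration sweeps use 6-cell
  lineages at 3-min sampling with a reduced GP optimization budget, and the
  OU-recovery checks use 29-cell lineages (the longest-lineage scale of the
  study conditions) at 2-min sampling.

## Known limitations

- Per-lineage (gamma, D) from variance matching sit at a ~25% error floor
  (above); the GP stage adds shrinkage that the densified training subset
  mitigates but does not remove, and at 1/gamma ~ tau (slow fluctuations)
  part of the fluctuation variance is absorbed by the drift and trend
  components, biasing gamma high by ~10-30%.
- The ACF of the *posterior-mean* fluctuation series decays faster than the
  latent process, because posterior shrinkage suppresses the slow spectral
  components that compete with the drift; relaxation times read off that ACF
  are short by up to a factor ~2 on 100-150 h lineages.  The
  marginal-likelihood estimate of 1/gamma (the fitted OU kernel) and the
  variance-matching fit do not share this bias and are the preferred
  estimators.
- The alternative relaxation-time estimator based on the variance of the
  fluctuation magnitude, multi-timescale variability analyses, and
  sister-cell asymmetry are out of scope.
- The GP is fitted per lineage; there is no hierarchical sharing of trends
  across lineages and no fully Bayesian treatment of hyperparameters.
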