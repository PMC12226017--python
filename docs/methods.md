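# Methods

## Model

`varxnet` fits the vector autoregression with exogenous input

    y_i(t) = Σ_{j=1..d_y} Σ_{τ=1..n_a}   A_ij(τ) y_j(t−τ)
           + Σ_{j=1..d_x} Σ_{τ=0..n_b−1} B_ij(τ) x_j(t−τ) + e_i(t)

to a d_y-channel signal `y` sampled at rate `fs` with d_x time-aligned
stimulus features `x`. The innovation `e(t)` is modeled as temporally
white noise; the recurrent filters `A` color it into the observed
spectrum, and the feed-forward filters `B` inject filtered stimulus.
The estimation objective is the innovation power `σ² = mean_t e(t)²`,
minimized by ordinary least squares, optionally with a ridge penalty.

Key conventions, chosen where more than one reading was possible:

- **Lag conventions.** `n_a` recurrent taps at lags 1..n_a; `n_b`
  input taps at lags 0..n_b−1. `n_b` counts taps, so 36 taps at 60 Hz
  span 0–583 ms ("600 ms filters"). Defaults follow common practice
  for 60 Hz neural data: `n_a=6` (100 ms), `n_b=36`, `λ=0.3`.
- **Intercept.** The recurrence has no constant term. Per-channel
  means of `y` and `x` are subtracted before fitting instead of
  estimating an intercept; predictions add the mean back.
- **Ridge scaling.** The penalty must be meaningful across signals
  with arbitrary units. Predictor columns are standardized to unit
  root-mean-square internally, the penalty `λ·T_eff` is applied to the
  standardized coefficients, and coefficients are mapped back. `λ` is
  therefore dimensionless; `λ=0` reproduces plain OLS exactly.
  (Whether external VARX implementations standardize before applying
  their `λ` is not documented; users matching results across tools
  should check this convention first.)
- **Sample alignment.** The first `max(n_a, n_b−1)` samples are
  dropped (no zero padding), so `T_eff = T − max(n_a, n_b−1)` and no
  edge bias enters the Gram matrix.
- **Degenerate inputs.** Zero-variance channels are rejected at fit
  time with a named error. All-zero *feature* columns are tolerated:
  they receive a unit diagonal in the standardized Gram matrix and a
  pinned zero coefficient, so a silent stimulus behaves exactly like
  no stimulus.
- **Rank deficiency.** With `λ=0` a singular design raises an error
  advising `λ>0` rather than silently pseudo-inverting.

## Granger deviance statistics

For each (target i, source j) the full model's innovation power
`σ_f²(i)` is compared with the reduced model omitting all of source
j's lag columns when predicting channel i:

    D_ij = T_eff · log(σ_r²(i,j) / σ_f²(i))
    p_ij = upper tail of χ²(dof) at D_ij
    R²_ij = 1 − exp(−D_ij / T_eff)

with `dof` equal to the number of omitted parameters — `n_a` for a
recurrent source, `n_b` for an input feature. This is the classical
likelihood-ratio asymptotics for nested Gaussian regressions; the
null-calibration study (below) verifies that the resulting p-values
are uniform under the null. The generalized `R²` serves as the
per-connection effect size.

Reduced models reuse the full fit's standardized Gram matrix: removing
one source's block of columns and re-solving the normal equations by
(Cholesky) block elimination gives a whole column of the map per
solve, `d_y + d_x` solves in total, and agrees with naive refitting to
machine precision (tested). The same `λ` and the same column scaling
are used in full and reduced solves, so the deviance reflects only the
omitted predictors. At `λ=0` the nesting guarantees `σ_r² ≥ σ_f²` and
hence `D ≥ 0`; with `λ>0` tiny negative values can arise numerically
and are clipped at zero (asserted to exceed −1e−6·T_eff first).

Self-connections (i=j) are computed but excluded from "fraction
significant" and mean-R² summaries, which are taken over off-diagonal
entries only; input maps summarize over all entries. Multiplicity
corrections (Bonferroni, Benjamini–Hochberg FDR) operate on the tested
entries. All significance thresholds are function arguments with the
conventional defaults (10⁻⁴ for connection fractions, 10⁻³ for
connection plots, Bonferroni 0.01 for responsiveness, FDR 0.05 for
channel selection); none is hard-coded.

## Total system response

The fitted model factorizes the total stimulus response as
`H = (1 − A)⁻¹ B` (z-domain). `compute_H` realizes this in the time
domain by running the noiseless recurrence with a unit impulse on each
feature, truncated at `L` samples (default `n_b`, so `B` and `H` are
directly comparable; raise `L` for slow dynamics). A stability check
(companion-matrix spectral radius < 1) precedes the recursion. The
time-domain recursion is tested against an independent FFT evaluation
of the z-domain transfer function.

On data generated by a stable VARX process, a directly estimated
moving-average encoding model (the mTRF) converges to `H`; the
equivalence study below quantifies the agreement.

**Response metrics.** Power is the mean squared kernel over the
analysis window (default 0–0.6 s). Duration is the full width at half
maximum: the peak is the largest-prominence local maximum of the
absolute kernel within the window (a window-edge maximum qualifies for
monotone kernels), the baseline is the median of the absolute kernel
over the window, and the width is measured where the kernel crosses
baseline + (peak − baseline)/2, linearly interpolated. Widths
truncated by the window edge are reported one-sided as measured;
kernels with no peak above baseline yield NaN. The baseline is taken
on the absolute kernel (not the signed kernel) so the half-height
level always lies between baseline and peak.

## Comparative analyses

- **VARX vs VAR control.** The control refits the identical design
  with every feature circularly shifted by ⌊T/2⌋ samples, which
  preserves each feature's marginal distribution and circular
  autocovariance exactly (hence the parameter count and input
  covariance) while destroying stimulus alignment. Differences in the
  fraction of significant recurrent connections and mean off-diagonal
  R² therefore isolate stimulus-induced (spurious) connectivity.
- **Feature ladder.** Features are un-shuffled cumulatively; excluded
  features remain in the design as shuffled copies. Per-step ΔR² is
  tested across datasets by signed rank with BH-FDR correction.
- **Condition contrasts** require equal-duration segments (equal
  `T_eff`, enforced) and estimate the condition effect with a REML
  linear mixed model (condition fixed, dataset random intercept, via
  statsmodels MixedLM). If the mixed model fails to fit — small or
  degenerate designs — the code falls back to within-dataset averaging
  plus a paired signed-rank test and labels the report accordingly.
- **Directionality.** With targets on rows and sources on columns,
  the column mean of `R² − R²ᵀ` is positive for net-sender channels;
  the asymmetries sum to zero exactly (antisymmetry). Channel
  asymmetries can be aggregated into parcels and related to a
  per-parcel covariate (e.g. a myelination index) by rank correlation
  and regression slope.
- **Noise quenching.** Per channel and condition, relative innovation
  power is `10·log₁₀(σ² / signal power)` in dB, with signal power the
  mean square of the fitted (centered) targets; for OLS fits the ratio
  cannot exceed 0 dB (asserted). The stimulus-minus-rest difference is
  summarized per dataset as the median over stimulus-responsive
  channels (from the input Granger map; Bonferroni p<0.01 by default,
  an uncorrected stricter threshold is available as an option) and
  separately over the rest.

## Synthetic data

The generator produces everything the analyses consume:

- **Stimulus features.** Pulse trains are Bernoulli/Poisson event
  sequences at a given rate (one sample per event); continuous
  regressors are unit-variance AR(1) noise with exponential
  autocorrelation of a given time constant. Correlated pairs — a
  sound-envelope-like feature plus its "acoustic edges" — are built by
  thresholding peaks of the continuous feature's derivative. Real
  event statistics (saccadic refractoriness, scene-cut clustering) are
  *not* emulated; pulse trains are memoryless.
- **VARX processes** simulate the exact recurrence with Gaussian
  innovations, discarding a 10·n_a burn-in. Ground-truth containers
  enforce stability (companion spectral radius < 1; generated specs
  keep a margin below 0.98, rescaling lag-τ filters by s^τ, which
  scales all eigenvalues by s exactly).
- **`oscillator_ground_truth`** builds channels as damped AR(2)
  resonances (complex pole pair, channel-specific frequency) with
  sparse lag-1 cross-coupling — a reasonable caricature of rhythmic
  neural signals that keeps the lagged design well conditioned.
- **`recovery_ground_truth`** concentrates self-feedback at the
  deepest recurrent lag, making each channel's lagged copies mutually
  uncorrelated while still amplifying the innovation. This minimizes
  and equalizes coefficient standard errors and is used for the
  identifiability study, where the contract is a small *elementwise*
  error bound over all coefficients.
- **Gain adaptation.** The mechanism behind stimulus-induced noise
  quenching is implemented as divisive normalization: the linear drive
  `z(t)` (recurrence + input + innovation) is divided by an
  exponentially tracked estimate of its own RMS, scaled to a target
  power (single time-constant parameter, default 2 s at 60 Hz). The
  running power is initialized at the target, so the infinite
  time-constant limit reduces exactly to the plain simulation. This is
  the simplest mechanism that holds output power constant — an
  interpretation, not a fitted biophysical model: with constant output
  power, stimulus-injected power necessarily displaces innovation
  power, and only in stimulus-driven channels.
- **Structural-recovery benchmark.** A sparse distance-dependent
  weighted graph on a ring of nodes (lognormal weights, density 0.25)
  is embedded in a stable VAR(2); an `asymmetry` parameter in [0,1]
  mixes the directed draw with its symmetrization. VARX recurrent R²
  and the absolute off-diagonal sparse inverse covariance (graphical
  lasso with cross-validated penalty, scikit-learn) are each
  rank-correlated (Spearman) with the true off-diagonal weights. With
  asymmetric truth, the sign of `R²_ij − R²_ji` is scored against the
  true directionality — a comparison the symmetric precision matrix
  cannot make at all. This is a generic linear-network surrogate: it
  tests the *ordering* claim (lag-aware recovery beats instantaneous
  covariance methods, and directionality is recoverable), not any
  particular correlation value from a specific biophysical simulator.

All randomness flows through explicit integer seeds; identical calls
are bit-identical. The generator emulates linear Gaussian dynamics
only — no spiking nonlinearities, no hemodynamics, no measurement
noise distinct from the innovation — so passing tests demonstrate
correctness of the estimator and analysis logic, not robustness to the
nonlinearities of real recordings.

## Validation studies and problem sizes

Each study in `varxnet.validation` is sized to give stable statistics
on one CPU in seconds:

| study | design | size |
|---|---|---|
| parameter recovery | recovery ground truth, near-white inputs, OLS refit | d_y=5, d_x=2, T=50,000 |
| null calibration | white channels + inert input, pooled off-diagonal p | 500 fits, T=2,000 |
| spurious connectivity | 3 uncoupled channels, shared pulse drive, VAR vs VARX at p<10⁻⁴ | 100 seeds, T=5,000 |
| H/mTRF equivalence | stable VARX ground truth vs MA-only refit, nMSE | T=100,000, L=36 |
| response factorization | scalar pole 0.95, two-tap B, closed-form checks | deterministic |
| noise quenching | gain-adapted networks, half the channels driven | 20 patients, T=8,000 |
| directionality | feed-forward chain 0→1→2, asymmetry ordering | 50 seeds, T=8,000 |
| network recovery | 20-node graph, VARX vs graphical lasso, symmetric + asymmetric | 10 seeds each, T=30,000 |

`scripts/acceptance.py` runs all of them with seeds derived from one
command-line seed and writes the metrics as JSON.

## Known limitations

- The chi-square p-values are asymptotic; at very short `T` (a few
  hundred samples) they become conservative/anticonservative in the
  usual LR-test ways. The calibration study covers T=2,000 and up.
- With `λ>0` the deviance is no longer an exact likelihood ratio;
  p-values at the default `λ=0.3` should be read as a ranking
  heuristic (as is standard practice), with exact calibration
  available at `λ=0`.
- `H` truncated at `L=n_b` under-represents very slow recurrent
  dynamics; raise `L` when the companion spectral radius is close
  to 1.
- The mixed-effects route needs several datasets per condition;
  degenerate designs silently use the documented signed-rank fallback
  (flagged in the report's `method` field).
- Estimation is in-memory and dense; hundreds of channels at `n_a=6`
  are fine, but the Gram matrix grows as (d_y·n_a + d_x·n_b)².
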