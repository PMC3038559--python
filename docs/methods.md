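# Methods

This note documents the statistical model behind each stage of
`restconn`, the default parameters and why they hold their values, what
the synthetic cohorts do and do not emulate, and the numerical choices
that matter for reproducing results.

## Data model

A cohort is a set of $n$ subjects, each a matrix of $T$ time points by
$R$ named ROIs sampled at a fixed repetition time (TR).  The default
study geometry is $n=29$ subjects, 200 acquired volumes of which the
first 10 are discarded (190 retained) at TR = 2 s, and $R=18$ ROIs —
the left/right pairs of visual, auditory, motor, somatosensory,
olfactory and prefrontal cortex, ACC, PCC and amygdala.

## Temporal preprocessing

Fixed stage order, each switchable: **discard** the first 10 volumes →
**detrend** (per-ROI OLS line against the time index, residual is
mean-zero) → **signal-change ratio** $(x-\mu)/\mu$ with $\mu$ the
per-ROI temporal mean captured *before* detrending (whether the
original chain formed the ratio before or after drift removal is not
determinable; this order is a documented choice, and Pearson
correlation is invariant to it because the ratio is an affine per-column
map) → **band-pass** 0.01–0.08 Hz → **demean**.

The band-pass is a second-order Butterworth applied forward–backward
(zero phase) with Gustafsson initial conditions and the temporal mean
removed first.  Two numerical points: (i) odd-signal padding — the
filtfilt default — reflects the series at its endpoints, which leaks
stop-band energy back in whenever the series is shorter than the
low-cutoff period (a 190-point, 380-s series vs the 100-s period of the
0.01 Hz edge); Gustafsson initial conditions keep the 0.2 Hz amplitude
retention at ~0.013 against a contract of ≤0.1 while passing ≥99% of a
mid-band (0.04 Hz) sinusoid.  (ii) DC sits outside any pass band, and
removing it before filtering prevents the least-squares initial
conditions from smearing a large baseline (raw BOLD units are ~1000)
into the window edges.  Filtered series keep full length; nothing is
trimmed.

A constant ROI column cannot be detrended meaningfully: it returns
zeros with a warning rather than an error, since one dead channel
should not abort a cohort.  A zero-mean ROI makes the signal-change
ratio undefined and is an error naming the ROI.

## Undirected connectivity

Per subject the sample Pearson matrix is computed on the fully
preprocessed series; constant columns are an error (zero variance).
Group analysis Fisher-transforms each off-diagonal entry
($z=\operatorname{arctanh} r$, variance-stabilising) and forms the
Z-matrix $Z = \bar z / s$ (cross-subject mean over sample SD,
denominator $n-1$), with the diagonal set to 1 by convention since its
SD is zero.  Pairs with zero cross-subject spread are flagged with
signed infinity rather than silently patched.

The Z-matrix is the reported effect-size map.  The significance
mechanism linking it to p-values is a one-sample t test of the subject
z-values against zero, $t = Z\sqrt n$ with $n-1$ df — the standard
random-effects choice.  (Treating Z itself as standard normal was the
plausible alternative; it changes per-pair cutoffs but not the
pipeline's structure, and the t test is the defensible default at
$n=29$.)  Bonferroni correction runs over the $R(R-1)/2=153$ unique
pairs at a familywise threshold of .005; surviving edges carry a tier
in {1, 2, 3} for corrected p below .005, .001, .0001 — a line-thickness
ladder for network plots.  Under vectorised null simulation the per-pair
type-I error at α=.05 sits within [0.04, 0.06] and the familywise error
after correction stays at its nominal level (both asserted in the
suite).

## Directed causality

**Pairwise.** For lag order $m$ the restricted model regresses $Y(t)$
on $Y(t-1..m)$, the unrestricted adds $X(t-1..m)$; both are OLS without
an intercept on per-window demeaned data (demeaning plus no intercept
matches regression equations written without a constant; the
denominator df convention $T-2m-1$, with $T$ the number of regression
rows, is then slightly conservative, and the measured null rejection
rate at T=30, m=1 is ~0.05).  The F statistic, its p, and the influence
$\log(\mathrm{RSS}_r/\mathrm{RSS}_{ur})$ are returned per ordered pair.

**Conditional.** The unrestricted model is the full VAR over all $R$
ROIs; the restricted model for $i \to j$ omits the lags of $i$ from
$j$'s equation; df become $(m,\ T-Rm-1)$.  At the default window
(30 points, $R=18$, $m=1$) the unrestricted fit spends 18 of 29
observations on parameters — individually noisy, which is exactly why
group aggregation pools windows (below).  The input contract requires
$T - Rm - 1 \ge m+4$; below that the error message suggests longer
windows or pairwise mode.

**Lag order.** Default $m=1$: at TR = 2 s a lag already spans 2 s, and
30-point windows leave no df budget for more.  Any fixed $m$ can be
passed; the choice is recorded in output metadata.

**Stationarity screening.** Covariance stationarity is a precondition
of VAR estimation, so each 60-s window is screened: per-ROI
Dickey-Fuller unit-root tests (lag 0 — augmenting lags cost most of the
test's power at 30 points) plus a fitted-dynamics stability radius
(full VAR(1) fit when the window has ≥ 2R observations, per-ROI AR(1)
coefficients otherwise).  A window "passes" only if every ROI rejects
the unit root *and* the radius is below 1 — but that joint criterion is
hopeless as an exclusion rule at 30 points, where the Dickey-Fuller
test cannot distinguish persistent stationary dynamics from a unit root
(measured per-ROI rejection ≈ 0.7 on stationary reference data makes
the all-18 joint pass rate ≈ 0.3%).  The default policy therefore
excludes only windows with *explosive* fitted dynamics and logs the
full diagnostics; a strict policy (exclude on any failure) and an off
switch are available.

**Group aggregation.**  Within a subject, each window is fitted
separately (its own coefficients — the piecewise fit is what makes
segmentation protect against slow nonstationarity), and the residual
sums of squares are summed across the subject's $K$ windows:
$\hat I = \log(\sum_w \mathrm{RSS}_{r,w} / \sum_w \mathrm{RSS}_{ur,w})$.
Under the null this pooled ratio is Beta$(Kd/2,\ Km/2)$ with $d$ the
per-window residual df, so its mean, variance and skewness are known
exactly (polygamma functions).  The raw influence is positively biased
under the null — adding regressors never increases in-sample RSS — and
subject influences are recentred by that exact null mean before
testing.

Two cross-subject combiners are provided:

* `pooled` (default): the sum of bias-corrected subject influences
  referred to its exact null distribution via a moment-matched gamma
  (matching the known null variance and third cumulant).  Under the
  null all subjects are exchangeable — in the generator, subject
  variability multiplies coefficients, so absent links stay absent —
  and the test is exactly calibrated while using the *known* null
  spread rather than estimating it from 29 noisy subject values.  At
  30-point windows this is the difference between a usable and an
  unusable test: the per-window influence estimator's null SD (~0.15 at
  $d=10$) swamps the subject-level t statistic, whose threshold after
  Bonferroni (.001 over 306 ordered pairs, one-sided, df 28) no
  stability-bounded effect size can reach.
* `subject-t`: the one-sided one-sample t across subjects on the
  corrected influences — the conservative random-effects alternative,
  robust to between-subject influence heterogeneity under the null,
  with correspondingly less power.

Bonferroni runs over the $R(R-1)=306$ ordered pairs at a familywise
threshold of .001.  On null cohorts the familywise error stays at its
nominal level (asserted over simulation replicates).

The pairwise and conditional paths coincide exactly at $R=2$, and the
causality results are invariant to per-ROI affine rescaling (OLS scale
equivariance) — both are property-tested.

## Synthetic cohorts

The generator draws from $x(t) = \sum_k A_k x(t-k) + e(t)$,
$e \sim N(0, Q)$, with Gaussian innovations (matching the linear
regression framework of the tests), a 100-step burn-in, a per-ROI
baseline of 1000 (arbitrary raw-signal units, so the signal-change
ratio is well defined), and per-subject variability as independent
multiplicative jitter, uniform on $[1-j,\,1+j]$ with $j=0.05$, on each
coefficient (re-drawn until the perturbed model is stationary).
Stationarity (companion spectral radius < 1) and positive-definiteness
of $Q$ are validated at construction with the offending quantity named.
Simulation is bit-for-bit reproducible from a seed.

### The reference network and its calibration

`sensory_pattern_graph()` encodes the two-system architecture: directed
lag-1 edges for the causal skeleton (amygdala ↔ the five sensory
cortices; prefrontal ← olfactory, motor and ↔ visual, auditory,
somatosensory; ACC/PCC linking both streams), expanded to both
hemispheres, each coefficient carrying the sign of its pair's planted
correlation so lag-driven and instantaneous correlation reinforce.

Construction runs a deterministic two-part calibration (~15 s, no
randomness):

1. **Coefficients.** Starting from uniform magnitude, each edge is
   rescaled so its asymptotic conditional influence
   $\log(1 + A_{ji}^2\,\mathrm{varpart}_i / Q_{jj})$ lands in
   [0.13, 0.30] while the companion radius stays ≤ 0.96.  The floor is
   a power requirement: smaller influences are undetectable at the
   group threshold under the study geometry; the cap stops strong edges
   from hoarding the stability budget.  The spectral radius is the hard
   wall — the amygdala's seven bidirectional partners bound what any
   single link can carry.
2. **Innovation covariance.** $Q$ is fitted by PD-constrained projected
   gradient so that the correlation matrix of the *band-passed* series
   (the quantity the correlation analysis estimates; computed exactly
   in the frequency domain from the VAR transfer function and the
   filter's squared response) is polarised around ±0.38 targets, while
   a second penalty holds the *unfiltered* series covariance near
   identity.  The second term is what lets one cohort serve both
   analyses: the causality analysis runs on unfiltered series, and
   near-orthogonal lagged regressors keep its conditional tests
   well conditioned.  Signed target pairs are "protected" — released to
   zero only if truly unachievable — and innovation couplings on listed
   pairs are never allowed to carry the opposite sign (violations are
   zeroed and PD restored by ridge).

**Ground truth is derived, not asserted.**  `correlation_truth()`
computes the model-implied band-limited correlation and declares a pair
*planted* at $|\rho| \ge 0.33$ and *null* at $|\rho| \le 0.03$; pairs
between are claimed by neither side and excluded from recovery scoring.
The 0.33 floor is a power analysis: at 29 subjects, band-limited
190-point series give a between-subject Fisher-z spread of ~0.16
(noise-coupled pairs) to ~0.19 (lag-coupled pairs), and demanding
familywise-significant detection in essentially every run needs
$\operatorname{arctanh}\rho \ge 9.4 \times 0.19/\sqrt{29}$.  The 0.03
ceiling keeps the chance of any familywise false positive across ~36
null pairs negligible.  `directed_edge_mask()` gives the causal truth
(nonzero off-diagonal lag coefficients).

### What the generator does and does not emulate

It reproduces the statistical structure the analyses assume: slow
band-limited fluctuations with a known in-band correlation pattern,
bilateral homologue coupling, a directed causal skeleton, stationary
dynamics, between-subject variability, and a raw-signal baseline.  It
does **not** model hemodynamic convolution, measurement noise with
realistic spectra, motion or physiological artifacts, spatially varying
SNR, or nonstationary arousal effects.  Passing recovery tests
therefore shows the *inference chain* is correct and calibrated at the
study geometry — not that real fMRI data satisfy a VAR, nor that the
reference network's specific couplings are empirically accurate (all
magnitudes are design constants sized for recoverability, not
estimates).  One known fidelity limit: the full listed sign pattern is
mutually frustrated — e.g. the amygdala correlates positively with both
the olfactory and auditory cortices, which are themselves listed as
anticorrelated — so no PD covariance can realise every listed sign at
detectable magnitude simultaneously; roughly half the listed pairs end
planted (always with the listed sign — contradictions are excluded by
construction), the rest land in the unclaimed middle band.

## Degenerate inputs and numerical conventions

* Fisher transform at $|r|\ge 1$ is an error; callers opt into clipping
  explicitly.
* Nested OLS guarantees $\mathrm{RSS}_{ur} \le \mathrm{RSS}_r$; the
  implementation clips tiny negative rounding differences so $F \ge 0$
  and influence $\ge 0$ always; a perfectly predictable target yields
  infinite F with p = 0 rather than overflow.
* Rank-deficient regression designs (constant or collinear series) are
  errors, not warnings.
* Cohort TSVs are written at 17 significant digits (lossless
  round-trip); derived matrices and edge weights at 12 (byte-stable
  across runs).  The run manifest records the seed, all thresholds, and
  per-stage counts; identical config + seed reproduces every output
  byte for byte.

## Problem sizes used in validation

The bundled validation study uses 50 simulated cohorts at the full
study geometry for network recovery, 2,000 replicates for F-test null
calibration, 1,500 replicates for correlation-test calibration, 10,000
random regressions for the nesting invariant, and 150–300 null cohorts
for familywise-error checks — sizes chosen to give binomial error bars
well inside the asserted bands.
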