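# Methods

`isimodels` analyses spontaneous spike trains from hair-cell afferent
neurons (the motivating system is the larval zebrafish lateral line) at the
level of interspike intervals (ISIs).  All times are milliseconds, rates
1/ms.  This note documents the models, the estimators, the numerical
choices, and what the synthetic data do and do not establish.

## Renewal ISI models

Each ISI is modelled as the sum of a refractory period and an excitation
(synaptic-release) waiting time,

    ISI = t_abs + t_rel + t_E,

with `t_abs` a constant absolute refractory period, `t_rel ~ Exp(1/tau_rel)`
the relative refractory period, and `t_E` drawn from one of three
excitation laws:

* **case i** — `f_E(t) = λ_E exp(−λ_E t)`: releases at a constant rate;
* **case ii** — mixture of that exponential (weight `p`) and a gamma with
  shape `n ≥ 1` and the same rate (weight `1−p`).  The gamma component
  represents release under pool depletion: several exponential sub-events
  must accumulate before a release.  `n` is treated as continuous; at
  `n = 1` the model collapses exactly onto case i;
* **case iii** — mixture of two exponentials with rates
  `λ_E1 ≥ λ_E2` (weights `p`, `1−p`): two distinct release sources (or
  modes), fast and slow.  Identifiability is enforced by construction:
  the slow rate is parameterized as `λ_E2 = λ_E1·r` with `r ∈ (0, 1]`.

The ISI density is the convolution of the shifted-exponential refractory
density with the excitation density over the interval support.  For cases
i/iii every term is a two-rate hypoexponential and is evaluated in closed
form; the coincident-rate point `λ_R = λ_E` is a removable singularity
handled by the Erlang-limit branch when the rates agree to a relative
1e−10 (numerical stability near coincidence).  For case ii the gamma
component has no elementary closed form; with the substitution `u = s·v`
the integrand carries an endpoint factor `(1−v)^{n−1}`, which a
Gauss-Jacobi rule with exactly that weight absorbs, leaving an analytic
factor.  A 40-node rule agrees with adaptive quadrature to ~1e−12
relative error (tested), well inside the 1e−8 target for this path; the
case-ii CDF uses a 48-node Gauss-Legendre rule on the same substitution.
`tau_rel = 0` (point-mass refractory) is handled analytically as a pure
shift, never as a narrow numerical kernel.

Sampling is by direct construction — `t_abs + Exp(tau_rel) + excitation
draw`, with the mixture component chosen independently per interval — so
samples are i.i.d. by design (serial structure belongs to the simulators
below).  The relative-refractory and excitation draws are taken
independent, the standard renewal construction.

## Shape metrics

The empirical CDF `F_data` is the usual right-continuous step function.
An exponential is fitted by maximum likelihood (`λ̂ = 1/mean ISI`) and the
squared CDF difference is integrated over each ISI quartile:

    E_k = ∫_{T_{k-1}}^{T_k} (F(t, λ̂) − F_data(t))² dt,   k = 1..4,

with `T_0 = 0`, `T_4 = max ISI`, and `T_1..T_3` the empirical quartiles
under the inverted-CDF (type-1) convention.  Because `F_data` is constant
between order statistics, the integral is computed exactly piecewise
(12-node Gauss-Legendre per piece for the smooth model CDF); there is no
grid-resolution knob.  The L-shape index is `ℓ = E_3/E_1`: distributions
whose dominant misfit is the refractory gap at short ISIs have `ℓ < 1`
("exponential" shape), those with a sharp decay and heavy tail misfit the
third quartile and have `ℓ > 1` ("L-shaped").  Conventions: `ℓ = 1`
classifies as L-shaped (measure-zero tie-break); `E_1 = 0` makes `ℓ`
undefined (NaN) rather than infinite; `ℓ` is invariant under rescaling of
the time unit.  Kurtosis throughout is the raw fourth standardized moment
(population formula), so the exponential benchmark is 9, not the excess
value 6.

## Least-squares fitting and information criteria

Model parameters minimize the integrated squared CDF difference over
`[0, max ISI]` — the same functional as `E_total` — rather than a sum over
data points, for consistency with the shape metrics.  The optimizer is
L-BFGS-B on transformed coordinates (log scale for `tau_rel`, rates, and
the gamma shape; linear for `t_abs`, weights and the rate ratio), with
bounds `t_abs ∈ [0, 0.999·min ISI]` (strictly inside the support so no
observation sits at a zero-density point), `tau_rel ∈ [1e−3, 50]` ms,
rates `∈ [1e−5, 10]` /ms, `p ∈ [0, 1]`, `n ∈ [1, 20]`.  A seeded
Latin-hypercube multi-start (default 10 restarts plus one moment-based
start) guards against local optima; the best restart is returned and the
achieved objective is never worse than any initialization (tested).
During case-ii fitting the convolution CDF is evaluated on a dense
auxiliary grid concentrated quadratically toward the support edge and
interpolated; reported quartile errors and likelihoods are recomputed
exactly at the optimum.

The log-likelihood, AIC (`2k − 2·llf`) and BIC (`k·ln M − 2·llf`, with
`k = 3, 5, 5` free parameters for cases i/ii/iii) are evaluated *at the
least-squares optimum*, not re-maximized; they are therefore conservative
approximations used for ranking, and are flagged as such.  An ISI below
the fitted `t_abs` yields an explicit −inf likelihood rather than a
silent adjustment.  Reported standard errors are quasi-SEs from the
numerical Hessian of the log-likelihood at the least-squares optimum;
they are NaN whenever the Hessian is not positive definite, which is
common when `t_abs` sits against its bound.

## Serial statistics

* **SRC(n)** — the serial correlation coefficient uses the *global*
  sample mean and population variance, averaging the lagged
  cross-products over the `M−n` available pairs, exactly as the
  definition is written; this differs at order `1/M` from the textbook
  autocorrelation that re-centres each lagged subsample.  Significance is
  the Pearson p-value on the lagged pair set under the null SRC(n) = 0.
  The null band used in tests is `|SRC| ≤ 2/√(M−n)`.
* **Recurrence quartile matrix** — `q_ij` is the fraction of the `M−1`
  consecutive pairs whose previous ISI lies in quartile `i` and next in
  quartile `j`; boundaries are the type-1 quartiles, a value exactly on a
  boundary belongs to the lower quartile, and heavy ties that collapse a
  boundary raise an error naming the tie.  Under independence every entry
  is near 1/16.
* **Short/long sequences** — each ISI is classed short (< global mean) or
  long; `μ_short`/`μ_long` are the means of the two classes.  Maximal
  same-class runs of ≥ 2 ISIs are accepted as sequences when the
  within-run mean is ≤ `μ_short` (short) or ≥ `μ_long` (long), greedy
  left-to-right without overlap — an adaptation of burst detection whose
  run-length threshold and acceptance rule are exposed as options, since
  only the acceptance idea, not pseudocode, is fixed by the definition.
* **Fano factor** — variance/mean of spike counts in sliding windows of
  length `dt` advancing by `dt/10` (stride configurable; the definition
  says only "sliding"), windows fully inside the recording, which must
  span ≥ 10·dt.  The homogeneous-Poisson value is 1 at every `dt`; the
  overlapping-window estimator is unbiased to O(dt/T) but has standard
  deviation ≈ √(2·dt/T), which is why benchmark tests average a few
  independent trains at the largest windows.

## Two-state switching simulator

The hair cell alternates between a slow and a fast release mode
(`S_slow ⇌ S_fast` with rates `k_sf`, `k_fs`); the excitation wait is
exponential with mean `tau_slow` or `tau_fast`, and the stationary fast
fraction is `p_fast = k_sf/(k_sf+k_fs)`.  Simulation is exact in
continuous time by competing exponential clocks: during any wait the next
release and the next switch race, and after a switch the release clock is
redrawn at the new mode's rate (memorylessness makes the redraw exact).
No time step is involved, so there is no discretization error to tune.
The mode keeps evolving during the refractory period (the switching
process is a presynaptic hair-cell property, independent of the
afferent's recovery), and the initial mode is drawn from the stationary
distribution unless overridden, avoiding burn-in bias in SRC estimates.

Ignoring serial order, the marginal ISI law corresponds to the case-iii
renewal model under the mapping `λ_E1 = 1/tau_fast`, `λ_E2 = 1/tau_slow`,
`p = p_fast`.  That identity is exact in the per-interval idealization in
which the mode is redrawn independently at each spike
(`simulate_switching_per_interval`, kept as the distributional oracle).
In the continuous-time model the mixture weight observed per *interval*
is spike-count weighted — the fast mode initiates disproportionately many
intervals — so the empirical marginal places more mass on the fast
component than `p_fast`; the mean ISI is correspondingly the inverse of
the time-averaged spike rate, which is what the cohort generator inverts
when calibrating rates.  Slow switching (mode dwell times spanning many
ISIs) produces positive SRC(1) that decays monotonically with lag; fast
switching, equal mode timescales, or occupancy near 0 or 1 all drive
SRC(1) to zero.

## Depletion-replenishment simulator

Each of K independent sources holds a continuous vesicle pool
`n_k(t) ∈ [0, n_max_k]`.  Release from source k occurs with probability
rate `p_depl_k · n_k(t)`; a release decrements the pool by 1 (floored at
0) and triggers a spike only outside the refractory period
(`t_dead + Exp(t_rel)`).  Releases during refractoriness still deplete
the presynaptic pool by default (the pool is presynaptic; only spiking is
blocked) — the alternative is available via
`deplete_during_refractory=False` and changes the reference results only
marginally.  Simulation is a fixed-step Monte Carlo with reference step
0.001 ms; a step making any per-step release probability exceed 0.1 is
rejected.  The inner loop is compiled with numba.

Between releases the pool deficit decays exponentially with timescale
`tau_repl`: per step, `n ← n + (n_max − n)(1 − exp(−dt/tau_repl))`, which
compounds to exact exponential recovery anchored at the post-release pool
size.  An alternative update that re-applies the closed-form recovery
factor with the *total* time since the last release at every step is kept
behind `literal_update=True`: compounded per step it eliminates the
replenishment bottleneck (effective recovery in ~0.06 ms regardless of
`tau_repl`) and with it all depletion phenomenology, so it serves only
for sensitivity analysis.  Pending replenishment is not carried over
across a release; the recovery is re-anchored at the new pool size.

Refractory defaults are `t_dead = t_rel = 0.6` ms, the sub-millisecond
scale of the auditory-nerve depletion model this simulator descends from
(the lateral-line renewal fits use 2 + 2 ms; that longer recovery dilutes
the depletion signature and is not appropriate for the auditory
benchmark).  At the strong-depletion reference point (`tau_repl = 2.5`,
`p_depl = 0.08`, `n_max = 4`, 10,000 ISIs) the simulator yields
SRC(1) ≈ −0.024 ± 0.007 and ℓ ≈ 0.030 ± 0.003 across seeds (computed by
the acceptance script and tests): strong depletion suppresses short ISIs,
concentrating the exponential misfit in the first quartile (ℓ ≪ 1) and
making short ISIs be followed by long ones (negative SRC).  Multiple
identical sources dilute the signature toward zero; strongly
heterogeneous source pairs (release rates differing by ~two orders of
magnitude) can produce weakly positive SRC(1) in a small minority of
parameter combinations.

## Synthetic cohorts

`make_cohort` emulates the study scale: 26 datasets of 2000 spikes each,
half exponential-shaped and half L-shaped by default, with per-dataset
parameters jittered inside the physiological regime anchored at
`t_abs = tau_rel = 2` ms and fast release waits of tens of ms.  Target
mean ISIs are drawn uniformly on 50–120 ms so nominal durations fall in
the one-to-few-hundred-second range; in switching mode the realized
duration fluctuates around that target with mode occupancy.  Shape is
controlled by the fast/slow rate ratio: the L-shaped pool draws ratios of
6–12 (about an order of magnitude); the exponential-shaped pool draws
1.4–1.9, just below the ℓ = 1 crossover, which at this refractory scale
sits near ratio 2 — so ground-truth labels remain well defined while the
two pools bracket the fitted-ratio regimes the classification
distinguishes.  Serial structure comes from the generating mode: `renewal`
(iid), `switching` (slow switching, `k_sf = 1e−4`/ms, giving a majority
of datasets significantly positive SRC(1) — the default, matching the
observed prevalence of positive serial correlation), or `depletion`
(weakly depleting source).  Every parameter and seed is recorded in a
JSON manifest; regeneration from the manifest is bit-identical.

What the synthetic cohorts do *not* emulate: measurement jitter and spike
sorting errors, slow nonstationary drifts in spike rate (a competing
explanation for positive SRC), multi-modal bursting, and the exact
per-recording statistics of any real dataset.  Passing tests on these
cohorts therefore demonstrates correctness and sensitivity of the
estimators under the stated generative mechanisms, not that real
recordings follow those mechanisms.

## Problem sizes in the tests

The test-suite simulation scales are the package's own choices for a
desk-scale regression suite: distribution-level checks use 2·10^4–10^5
draws; parameter-recovery fits use 5000 ISIs with 4 restarts; switching
parameter-trend checks use 8–10 trials of 2000–5000 ISIs per grid point;
depletion scans use 30–40 sampled points of 1000–2000 ISIs (step 0.002 ms
for scans, 0.001 ms wherever a reference value is being reproduced); the
strong-depletion benchmark uses five replicates of 10,000 ISIs at the
reference step.  Larger sweeps scale linearly and are exposed through the
same functions.

## Known limitations

* AIC/BIC at the least-squares optimum (not the MLE) penalize all models
  conservatively; rankings are meaningful, absolute values are not.
* Quasi-standard errors are approximations and frequently NaN at active
  bounds; a bootstrap would be the rigorous alternative.
* The Fano stride and the sequence-detection acceptance rule are
  conventions; both are exposed as options and reported.
* No hidden-state inference (e.g. HMM decoding of the switching mode from
  data) is provided; the simulators are forward models only.
* Renewal fitting assumes exchangeable ISIs; fitting serially correlated
  data yields the marginal fit, which is exactly how the case-iii model
  is meant to summarize switching-type data.
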