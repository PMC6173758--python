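# isimodels

Renewal-process models, serial statistics, and generative simulators for
the spontaneous spiking of hair-cell afferent neurons, analysed at the
level of interspike intervals (ISIs).  The motivating system is the
larval zebrafish lateral line, where hair cells release neurotransmitter
spontaneously and each afferent neuron integrates several synapses; the
same machinery applies to any spike train supplied as timestamps.

The package answers three questions about a spike train:

1. **What shape is the ISI distribution?**  An exponential is fitted by
   maximum likelihood (λ̂ = 1/mean ISI) and the squared CDF misfit is
   integrated per ISI quartile, E₁..E₄.  The L-shape index ℓ = E₃/E₁
   separates exponential-like distributions (ℓ < 1, misfit dominated by
   the refractory gap at short ISIs) from L-shaped ones (ℓ > 1, sharp
   decay with a heavy tail).
2. **Which renewal mechanism explains it?**  Each ISI is modelled as
   t_abs + t_rel + t_E: an absolute plus exponential relative refractory
   period convolved with an excitation wait that is (i) a single
   exponential, (ii) an exponential-gamma mixture (synaptic depletion), or
   (iii) a two-exponential mixture (two release sources/modes,
   λ_E1 > λ_E2).  Models are fitted statsmodels-style by least-squares CDF
   matching with multi-start, and compared by per-quartile errors, AIC and
   BIC.
3. **Are consecutive ISIs dependent?**  Serial correlation SRC(n) with
   Pearson significance, a 4×4 recurrence quartile matrix (1/16 per entry
   under independence), detection of short/long ISI sequences, and the
   sliding-window Fano factor (1 for a homogeneous Poisson process).

Two seeded generative simulators provide mechanistic hypotheses and
ground-truth synthetic data: a **two-state switching model** (hair cell
alternates between fast and slow release modes; slow switching produces
positive SRC(1)) and a **depletion-replenishment model** (vesicle pools
of size n(t) ≤ n_max releasing at rate p_depl·n(t) and refilling with
timescale τ_repl; strong depletion produces negative SRC(1) and ℓ ≪ 1).
A cohort generator emulates the study scale — 26 recordings × 2000 spikes
— with a manifest that makes regeneration bit-identical.

## Worked example

Simulate a slowly switching afferent (fast mode every ~40 ms, slow mode
every ~200 ms, refractory 2 + 2 ms), then analyse it:

```python
from isimodels import (SwitchingParams, simulate_switching, summary_stats,
                       fit_exponential, quartile_errors, classify_shape,
                       serial_correlation, fit_renewal)

params = SwitchingParams.from_p_fast(k_sf=1e-4, p_fast=0.5,
                                     tau_fast=40.0, tau_slow=200.0)
isis = simulate_switching(params, 2000, seed=1).isis

s = summary_stats(isis)
fit = fit_exponential(isis)
q = quartile_errors(isis, fit.cdf)
print(s.mean, s.cv, s.kurtosis, q.ell, classify_shape(q))
print(serial_correlation(isis, 1))
print(fit_renewal(isis, "iii", restarts=4, seed=0).summary())
```

Output (abridged):

```
M = 2000, mean = 75.3 ms, CV = 1.56, kurtosis = 26.52
lambda_hat = 0.01327 /ms, ell = 54.16 -> L-shaped
SRC(1) = 0.315 (p = 3.12e-47)
Renewal ISI model fit (least-squares CDF matching)
====================================================
excitation case:     iii
observations (M):    2000
converged:           True  (restarts used: 5)
CDF error total:     0.00255301 ms
...
parameter       estimate    quasi-se
t_abs             1.9474       0.169
tau_rel           2.4532       0.534
lambda_e1       0.027407     0.00143
p                0.78652      0.0251
rate_ratio       0.18518      0.0129
```

Reading the numbers: CV well above 1 and kurtosis far above the
exponential benchmark of 9 flag an over-dispersed, heavy-tailed ISI
distribution; ℓ ≫ 1 classifies it as L-shaped; SRC(1) ≈ 0.32 shows strong
positive serial dependence (long ISIs follow long, short follow short),
the signature of slow mode switching.  The case-iii fit recovers the
refractory scale (~2 ms each) and a fast rate λ_E1 ≈ 0.027/ms ≈ 1/37 ms
with a fast/slow rate ratio ≈ 5 — the fitted marginal weights the fast
mode above its 50% time share because the fast mode initiates more
intervals (see `docs/methods.md`).

A command-line pipeline wraps the same library for directories of
spike-time files (one ms timestamp per line, or CSV with a `time_ms`
column):

```bash
isimodels make-cohort --out cohort/ --seed 7
isimodels analyze --input cohort/ --out analysis/ --seed 0
isimodels fit --input cohort/ --out fits/ --cases i,ii,iii --seed 0
isimodels report --input analysis/ --out summary.json
```

## Layout

- `src/isimodels/spiketrain.py` — spike/ISI containers, empirical CDF,
  summary moments, text I/O
- `src/isimodels/renewal.py` — the three renewal ISI distributions
  (closed forms + Gauss-Jacobi convolution), sampling
- `src/isimodels/shape.py` — exponential fit, quartile CDF errors, ℓ
- `src/isimodels/fitting.py` — `RenewalISI` model / `RenewalISIResults`
  (least-squares CDF fitting, AIC/BIC, summary, simulate, plot)
- `src/isimodels/serial.py` — SRC(n), recurrence matrix, sequences, Fano
- `src/isimodels/switching.py`, `src/isimodels/depletion.py` — the two
  generative simulators with sweep/scan drivers (numba kernels in
  `_kernels.py`)
- `src/isimodels/cohort.py` — synthetic cohorts with manifests
- `src/isimodels/cli.py` — the `isimodels` command-line pipeline

`docs/methods.md` documents the models, estimator conventions, numerical
choices, and limitations.
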