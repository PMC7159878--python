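# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `stopcascade`.

## The race model and its peripheral chain

Trial outcomes are generated (and analysed) under an independent-race model
with an explicit peripheral chain.  Per trial:

* The go process crosses the response threshold at `G` ms after the Go cue;
  `G` is ex-Gaussian with parameters `(mu_go, sigma_go, tau_go)` (seconds
  internally; the ex-Gaussian mean is `mu + tau` and its variance
  `sigma^2 + tau^2`).
* The keypress registers `electromech_ms` later (default 60 ms), provided it
  beats the 1 s deadline.
* The *commitment point* ("point of no return") lies `ballistic_ms` before
  the threshold crossing (default 0: the crossing itself is the commitment).
* With probability `1 - p_tf` the stop process launches at the Stop signal
  and finishes `S` ms later (ex-Gaussian `(mu_stop, sigma_stop, tau_stop)`);
  its effect reaches the muscle `conduction_ms` (23 ms) after that.  A
  keypress results iff the muscle-level cancellation arrives after the
  commitment point.
* The EMG burst begins a fixed rise-to-threshold interval before `G`
  (solved from the envelope geometry); a successful stop whose cancellation
  lands after that onset leaves a truncated *partial* burst.

Consequences used throughout the tests: the behavioural-minus-EMG SSRT gap
equals `ballistic_ms + electromech_ms` (the rise-to-threshold interval
cancels), and the mean muscle cancellation time is
`mean(S) + conduction_ms` after the Stop signal.

Two independent SSD staircases (one per response direction, +/-50 ms after
each successful/failed stop) hold P(respond|stop) at ~0.5.

## Generator defaults (the simulated study conditions)

| parameter | default | rationale |
|---|---|---|
| `n_trials`, `prop_stop` | 600, 0.25 | session length and stop fraction of a standard manual stop-signal study |
| `ssd_start`, `ssd_step`, `deadline`, `trial_length` | 200, 50, 1000, 2500 ms | task constants |
| go params (s) | mu .34, sigma .05, tau .08 | keypress RT mean ~483 ms, SD ~94 ms after the 60 ms electromechanical delay |
| stop params (s) | mu .105, sigma .02, tau .032 | muscle cancellation ~160 ms post-Stop after 23 ms conduction |
| `p_tf` | 0.04 | typical trigger-failure rate |
| `ballistic_ms`, `electromech_ms` | 0, 60 | behavioural stopping latency ~60 ms beyond the muscle event |
| `emg_rise_ms`, `press_threshold_mv`/`emg_peak_mv` | 110, 0.45/0.5 | tuned once so that ~50% of successful stops carry a partial burst whose amplitude is ~half the keypress-trial amplitude |
| `emg_trunc_decay_ms` | 10 | fast collapse of drive after cancellation (motor-unit derecruitment time-scale); makes the decline readable to ~5 ms at default SNR |
| `noise_sd_mv`, `line_amp_mv` | 0.01, 0.02 | baseline noise and 60 Hz mains contamination |
| `beta_freq`, `beta_lead_ms`, `beta_burst_amp` | 20 Hz, 40 ms, 6x background SD | frontal burst precedes muscle cancellation by ~40 ms; the amplitude gives ~95% detectability, see below |
| MEP: base 0.4 mV lognormal (sd .25), suppression onset 140 ms, factor 0.6, 5% contaminated trials | | global-suppression chronometry |

The EMG envelope is a gamma-like rise `u^2 exp(2(1-u))` over `emg_rise_ms`
followed by exponential decay (40 ms; 10 ms once truncated).  The raw trace
is the envelope times a unit-variance white carrier plus Gaussian noise and
a 60 Hz component, so rectified-RMS processing recovers the envelope with
physiological-looking variability.  Onset-aligned average profiles of full
and truncated bursts therefore coincide early and diverge later.

What the generator does *not* emulate: motor-unit physiology (recruitment,
firing statistics), EMG cross-talk between muscles, multichannel EEG
forward models, non-stationary background spectra, TMS pulse artifacts, or
behavioural non-stationarities (fatigue, strategy drift).  Tests passing on
this generator validate the estimators' arithmetic and calibration under
the stated model, not robustness to every property of real recordings.

## EMG landmark rules

* Threshold: baseline mean + 8 SD, baseline = fixation -> Go cue of the same
  trial; "greater than 8 SD of the mean" is read as `mean + 8*SD` (for a
  near-zero-mean rectified baseline the alternative reading coincides).
  Zero-variance baselines fall back to mean + epsilon with a flag.
* Among multiple supra-threshold excursions the largest-peak one is used
  (robust to baseline blips); all excursions are reported.
* "Five consecutive ms" is `ceil(0.005 * fs)` samples (10 at 2 kHz).
* Decline: earliest post-peak sample followed by 5 ms of strictly
  decreasing RMS; ties break toward the earlier sample.
* The offset landmark mirrors the onset rule forward in time and is
  non-normative (no field-standard rule exists).
* RMS edge handling shrinks the window to the valid range at epoch edges.
* The CancelTime IQR cutoff is computed within the analysed session
  (per participant), after the 50 ms floor; with fewer than 3 partial
  trials only the floor applies (flagged).

## SSRT estimators

`ssrt_integration` uses the n-th ordered go RT with `n = ceil(p*N)` and
replaces go omissions with the maximum RT (consensus practice).  `ssrt_emg`
computes the same quantile per SSD level on correct-go EMG onsets — with
partial-EMG trials recoded as responses P(respond) is far above 0.5, so a
single pooled quantile would be unstable — and averages levels with at
least 5 stop trials (configurable).  Levels with P(respond) of exactly 0 or
1 are skipped.

Per-SSD integration estimates carry a p-dependent bias when the stop
latency is variable (upward at small p, downward at large p).  The
ballistic-stage sweep therefore restricts the per-SSD average to levels
with P(EMG-respond) in [0.25, 0.90] and at least 50 trials: which levels
the staircase populates shifts with the ballistic duration, and the fixed
stable band keeps settings comparable.  With that restriction the predicted
gap tracks the ballistic duration with slope ~1.

The Weibull inhibition function `w(t) = gamma - (gamma-delta)exp(-(t/alpha)^beta)`
is fitted by `scipy.optimize.curve_fit` with per-SSD trial counts as
weights, bounds `gamma, delta in [0,1]`, `alpha, beta > 0`, and data-driven
starting values.

## Race-model likelihood and hierarchical fit

Trial likelihoods are as in the module docstring; the successful-stop
probability integrates the go survival over the stop finish distribution by
64-node Gauss-Legendre quadrature on the interval
`[mu_s - 8 sigma_s, mu_s + 8 sigma_s + 20 tau_s]`.  Centring the interval
on the stop distribution (rather than anchoring at zero) matters: with the
interval anchored at zero, near-degenerate `sigma, tau` are unresolved and
the likelihood of a deterministic stop latency is overestimated, which
rewards a spurious collapsed mode.  The quadrature agrees with brute-force
simulation to < 1e-3 across the parameter range, including degenerate
corners.  The deadline enters as censoring (`min(d + S, T)`), so a
trigger-failure-free deadline miss still counts as a non-response.

The hierarchy places truncated-normal group distributions (mean, SD) over
each of the seven individual parameters, bounded by the uniform prior
boxes `mu: (0,2)`, `sigma, tau: (0,0.5)`, `p_tf: (0,1)`, with flat
hyperpriors.  Sampling is Metropolis-within-Gibbs:

* per-parameter Gaussian random-walk updates for every individual
  parameter and for the group means/SDs, with scales adapted during
  burn-in toward ~30% acceptance;
* adaptive-covariance block updates per participant (full 7-parameter
  block, the stop-side `(mu_stop, sigma_stop, tau_stop, p_tf)` block, and
  the `(mu_stop, sigma_stop, tau_stop)` shape ridge), using running
  empirical covariances in the spirit of the adaptive-Metropolis
  algorithm.  The stop-side blocks run several times per sweep because the
  stop distribution's shape parameters are only weakly identified by
  ~75 failed-stop RTs per participant and mix far more slowly than the go
  side;
* joint *translation* moves that shift every participant's value of a
  stop-side parameter together with its group mean (including the
  sigma/tau and mu/tau trade-off directions).  In a hierarchy the
  population can only crawl along a weakly identified direction if
  individuals and the group move in concert; these moves make that a
  single proposal.

Chains start overdispersed (log-normal jitter around method-of-moments
initials) so the split-chain Gelman-Rubin diagnostic is honest; the fit is
flagged non-converged if any R-hat >= 1.1.  Production defaults follow the
common 5000-samples/thin-5 setting; recovery tests use shorter chains.
The model-based stopping-latency summary is the posterior mean of
`mu_stop + tau_stop` (mean) and of `sqrt(sigma_stop^2 + tau_stop^2)` (SD).
The SSRT-distribution variance is implemented as `sigma^2 + tau^2`, the
ex-Gaussian identity.

Known limitation: with ~150 stop trials per participant the decomposition
of the stop-side variance into `sigma_stop` vs `tau_stop` is close to
unidentified; the identifiable combinations (`mu_stop + tau_stop`,
`sigma_stop^2 + tau_stop^2`) recover well while the individual shape
parameters carry wide, slowly mixing posteriors.

## Beta bursts

The surrogate generator emits the *output* of a right-frontal spatial
filter: unit-SD 1/f background (2-100 Hz) plus, on successfully stopped
trials, one Gaussian-windowed beta burst (FWHM ~3 cycles) whose envelope
peak precedes the muscle cancellation by `beta_lead_ms`.  ICA and dipole
fitting are upstream of this package; only the beta-power selection rule is
implemented (peak 13-30 Hz frequency in the Stop->SSRT window, accepted if
band power exceeds the pre-Go baseline by a 5% relative margin — the margin
absorbs wavelet edge effects that would otherwise accept perfectly
stationary signals).

Burst extraction filters at the peak beta frequency with a frequency-domain
Gaussian (FWHM 5 Hz), takes the analytic envelope (negative frequencies
zeroed, positives doubled, inverse FFT), and thresholds at median + 1.5 SD
(detection) and median + 1 SD (width) of the envelope pooled over the
500-1000 ms post-Stop window (post-mean-SSD on go trials).  "SD" is the
plain standard deviation of that pooled distribution, implementing the
mixed robust/non-robust wording literally.  A burst spanning the
Stop->SSRT window boundary counts if its BurstTime (envelope peak) falls
inside.  Burst % is computed per trial type.  Note the 5 Hz filter makes
the envelope inherently smooth on a ~75 ms scale, so BurstTime precision is
SNR-limited; the generator's default burst amplitude (6x background SD) is
chosen so that injected bursts are recovered within +/-10 ms with >= 90%
recall, the regime the recovery tests certify.

## MEP analysis

Amplitude QC follows the two stated rules; rule (ii)'s `mean +/- 1.5 IQR`
window is applied to raw amplitudes per time-point x trial-type group
(QC before normalisation, following the order of operations), skipped with
a flag for groups under 4 trials.  Normalisation maps the mean QC-passing
ITI amplitude to 100%.  CancelTime-relative binning uses half-open 30 ms
bins labelled by the lower edge over [-90, 60) ms, pooled across
participants after per-participant ITI normalisation, keeping bins with at
least 50 trials.  The conduction-time onset rule (first point above
baseline mean + 3 SD sustained >= 1 ms, minimum over ~10 stimuli) replaces
visual inspection and is non-normative.

## Permutation test

The null redraws one BurstTime per *observed burst* uniformly on
(0, SSRT_Beh) and averages within participant, preserving each
participant's averaging noise (a one-draw-per-participant mode is also
exposed).  p uses the add-one convention `(1 + #{r_perm >= r_obs})/(1 + n)`
so it is never exactly zero.  Under the null the p-distribution is uniform
to within binomial error (calibration test at 500 replicate cohorts).

## Problem sizes used in the test suite

EMG injection-recovery runs on ~1,000 partial trials from a 20,000-trial
session; SSRT consistency on 10,000-trial sessions; race-oracle agreement
on 10^6 simulated races per SSD; hierarchical recovery on 20 participants x
600 trials with 3 chains x (1,000 burn-in + 2,000 kept, thinned by 2);
burst recovery on ~200 injected bursts; permutation calibration on 500
replicate cohorts at 400 iterations each.  The ballistic sweep uses
~10,000 stop trials per duration with common random numbers across the
grid.
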