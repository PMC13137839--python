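# Methods

`ipis` models and analyses communication in a two-region circuit (an upstream
GABAergic nucleus, "BNST", projecting to a downstream striatal target, "NAc")
whose population activity alternates between excitatory (E / UP) and
inhibitory (I / DOWN) network states on the timescale of delta waves.  The
central object is the *inhibitory-period isolated spike* (IPIS): a single or
few-spike event emitted inside an inhibitory period, which the circuit uses as
a high signal-to-noise channel for cross-regional transmission.  This note
documents the generative model, the estimators, the numerical conventions, and
the design choices made where the design was genuinely open.

## The generative model

### Network states

States alternate E/I with gamma-distributed dwell times (shape 2).  Inhibitory
dwells are truncated to [0.1, 0.5] s — the half-cycle range of the 1–5 Hz
delta band — with the scale calibrated numerically so the *truncated* mean
equals the target (default 0.25 s).  Excitatory dwells default to a 0.6 s
mean, giving an I-state duty cycle near 0.3.  Cohort segments with a
prescribed I-state fraction f keep the 0.25 s I mean and set the E mean to
0.25·(1−f)/f.

### LFP

Each region's trace is a sum of:

* a 1/f^χ aperiodic background, with χ switching between states (defaults
  χ_E = 1.0, χ_I = 2.0; flatter in E, the standard E/I-balance reading of the
  aperiodic exponent).  The power law plateaus below 0.5 Hz: state-modulating
  an unbounded 1/f process folds its near-DC power into the 1–5 Hz analysis
  range and biases the fitted exponent, and the plateau lies outside the
  1–100 Hz band every estimator uses.  When χ_E = χ_I a single process is
  generated (no modulation artifacts at all);
* one negative half-sine delta deflection spanning every I interval,
  cross-regionally synchronized (amplitude 4 background SDs, large enough to
  clear the wave detector's 2-SD threshold through the band-pass even for the
  shortest 0.1 s intervals);
* a BNST theta oscillation (7 Hz carrier, amplitude 1.5) and an NAc gamma
  oscillation (80 Hz carrier, amplitude 1.0) whose envelope follows the BNST
  theta phase with depth `pac_strength` and a preferred phase of 330°;
* a weak shared gamma-band component present only during I intervals
  (amplitude 0.15), injected into the NAc with a 3 ms lag.  The lag makes it
  visible to the weighted phase-lag index; a zero-lag copy has identical
  spectra but is wPLI-invisible, which is exactly the contrast the feature
  ablation exploits.

Amplitudes are in units of the background SD and were fixed once so that the
oscillations are resolvable against the in-band 1/f floor, as they visibly are
in real recordings of this kind.

### Spikes

Each unit is an inhomogeneous Poisson process: rate `rate_E` in E states and
`rate_I` times a condition gain in I states.  The default population is
8 BNST + 8 NAc units with 3 partner pairs (about one-third of units, matching
the reported prevalence of IPIS-emitting cells): `rate_E` = 8 Hz, partner
`rate_I` = 2 Hz, all other I-state backgrounds 0.005 Hz.  Partner BNST spikes
falling inside an I interval are relayed to the paired NAc unit
(thinning-and-shift: probability 0.6 × *relay fidelity*, lag 8 ms, 2 ms
Gaussian jitter).

Relay fidelity models the receiving side: transmission needs a silent
inhibitory window, so fidelity defaults to the reciprocal of the interval's
pathological partner gain — 1 when the inhibitory tone is intact, ≈ 1/gain
when hyperactivity floods the window.  This one mechanism produces the
study's phenomenology: stress-susceptible circuits (partner gain 10, other
gain 3) lose both spike isolation and relay fidelity, so IPIS counts and the
partner correlogram collapse; resilient circuits (partner gain 1, other gain
10) keep both.  The gains also make the IPIS count *per se* fall under
stress: the isolation ceiling (k_max = 2 spikes per interval) is non-monotone
in the Poisson mean, and 10× drives both the direct and the relayed counts
past it.

### Cohort segments

Human-like segments are two-region LFP (no spikes) with class-conditional
parameters.  Baselines track the rodent generator — the cross-species premise
is that the windowed features are conserved — and DBS-on steepens the
aperiodic exponent in *every* stimulated subject (a direct local effect),
while theta/gamma bumps, theta→gamma PAC, a high I-state duty cycle (0.745 vs
0.453, the decoded fractions reported for responders vs non-responders), the
lagged I-state gamma coupling, and low severity scores are specific to
responders.  Severity scores are Gaussian around class means (sham 20.5,
cohort-level active mean ≈ 11.1), reproducing the reported ≈ 9.4-point
reduction in expectation.

## Estimators

* **State detection from spikes** — pooled population rate in 10 ms bins,
  Gaussian-smoothed (σ = 20 ms); bins at or below the 20th percentile seed I
  intervals, at or above the 60th percentile seed E intervals.  A core must
  persist for half the minimum duration (default 0.1 s) before its edges are
  extended to the crossing of the mid-level between the two thresholds; the
  extension recovers the boundary the smoothing erodes.  Percentile
  thresholds necessarily place ~5% of stationary data below the low
  threshold, so on state-free input the detector fabricates a small amount of
  I time (bounded, ≪ the true duty cycle) rather than none.
* **IPIS / center spikes** — count-based isolation (1..k_max spikes per unit
  per I interval, k_max = 2 as the smallest non-singleton reading of "single
  or few"); E-center spikes are the spike nearest each E-interval midpoint,
  ties to the earlier spike (with a 1 ns float tolerance).
* **Cross-correlogram** — 5 ms bins over ±200 ms, lag-0 counted in the first
  positive bin.  Monte-Carlo null: every reference time independently
  re-jittered uniformly within ±200 ms per surrogate (default 1000); the
  pointwise band is the [2.5, 97.5] percentile envelope and clusters of
  contiguous supra-band bins are scored by mass against the maximal surrogate
  cluster mass.  Partner cells: pairs with a significant positive cluster
  within ±50 ms using IPIS-restricted references; pairs with fewer than 10
  reference events are not testable and are skipped.
* **Spike SNR** — (partner-spike rate + ε)/(other-spike rate + ε) with
  ε = 0.1 Hz, 25 ms bins over ±0.5 s around events, against a circularly
  time-shifted control.
* **Spectral parameterization** — iterative: robust log-log line (upward
  outliers down-weighted), Gaussian peaks on the residual (≥ 2 residual SDs
  *and* ≥ 0.2 log10 units, guarding against fitting estimator scatter; peaks
  at the fit-range edges are treated as leakage), then an aperiodic refit on
  the peak-subtracted spectrum.  Exponent recovery over χ ∈ {0.5 … 2.5} is
  within ±0.15 on 60 s segments (measured ≤ 0.06).
* **Sample entropy** — Richman–Moorman SampEn, m = 2, r = 0.2 SD, Chebyshev
  distance, self-matches excluded, template pairs counted over the first
  N−m templates; +∞ when no (m+1)-matches exist.  The vectorized
  implementation is tested for exact equality against an O(n²) loop oracle.
* **Sliding features** — 50 ms windows, 25 ms step.  The slope proxy is the
  log-log periodogram slope over 20–100 Hz (a 50 ms window cannot resolve
  lower frequencies; the full-segment exponent uses 1–100 Hz).  Relative
  delta/gamma power comes from a centered 1 s context window so the delta
  band is resolvable.  Delta waves are negative excursions of the 1–5 Hz
  band-passed trace below −2 robust SDs (MAD-based — the waves themselves
  would inflate a plain SD), extended to the zero crossings.
* **wPLI** — |E[Im Sxy]| / E[|Im Sxy|] over Hann-tapered 0.5 s windows with
  50% overlap, averaged over the requested band; plain (non-debiased)
  estimator.
* **PAC** — zero-phase 4th-order Butterworth band-passes, whole-trace Hilbert
  transforms, 18 phase bins of 20°, KL modulation index normalized by ln 18;
  permutation null by circular shifts of the amplitude series.
* **Spectral Granger causality** — bivariate VAR (statsmodels), order by AIC
  up to 20, Geweke's frequency-domain decomposition from the fitted
  coefficients and residual covariance; unstable VAR roots raise.
* **Cluster permutation test** — pointwise t (two-sided p < 0.05 forming
  threshold), same-sign contiguous clusters scored by summed |t|, max-mass
  permutation null; two-group, paired, and one-vs-others (pooled) schemes.
* **IPIS GLM** — logistic regression of windowed IPIS occurrence on the NAc
  gamma power 50 ms earlier, predictor standardized; the exponentiated slope
  per 1 SD is reported with a Wald CI (L2-penalized fallback on separation).

## The E/I decoder

Windows are labeled by the spike-derived state when one state covers ≥ 80% of
the window.  Classifiers: regularized LDA, kNN, RBF-SVM and random forest
(default: 500 trees, `min_samples_leaf` = 1); the positive class is E ("UP").
The train/test split is 70/30 — by whole recording when several are present
(no window leakage), else stratified by label.  Decoding an LFP-only
recording classifies every window, merges contiguous same-class windows and
drops intervals shorter than 50 ms.  Cross-recording recovery of truth
I intervals has median Jaccard ≈ 0.84 (criterion ≥ 0.6); spike-based
detection reaches ≈ 0.85 (criterion ≥ 0.8).

Decoded I-state incidence on cohort segments preserves the class contrast and
ordering (responder DBS-on > non-responder DBS-on > baselines) but
under-recovers the generating duty cycle by several points (≈ 68% vs 0.745,
≈ 43% vs 0.453): the DBS-induced exponent steepening shifts the feature
distribution relative to the training domain and the fixed 0.5 threshold does
not adapt.  The contrast, not the absolute incidence, is the tracked readout.

## Closed-loop DBS model

The causal detector computes the pooled spike count in a trailing 100 ms
window every 10 ms, calibrates 20th/60th percentile thresholds on the leading
30 s, and emits I-/E-onsets at confirmed crossings (2 consecutive bins) with
a 0.3 s refractory period.  Paradigms: pulse (100 ms) at each I-onset
(I_locked), at I-onset + U(0.5, 1.0) s (random_delay), at the next E-onset
(E_locked), or continuous (full_time).

Stimulation acts through three coupled mechanisms:

1. **Somatic suppression** — during pulses BNST rates are multiplied by
   `s_soma` (0.1), applied to the *raw pathological* rate (the relaxed
   between-pulse tone is not suppressed twice).  The suppression outlasts the
   pulse by `carryover_s` (0.2 s) but only through inhibitory time: renewed
   excitatory network drive releases the block.  Without that release,
   onset-locked stimulation would halve E-period rates, contradicting the
   observation that only continuous stimulation reduces them.
2. **Sustained tone restoration** — the pathological I-state gains relax
   toward 1 by `efficacy` (0.9) × the cumulative stimulated-I coverage.
3. **Reception fidelity** — an interval relays at fidelity 1 when a pulse
   *starts* within 0.1 s of its onset and the suppression covers at least
   half of it (phasic, rebound-timed axonal GABA drive), at 0.7 under
   ongoing tonic drive that began earlier (sustained bombardment partially
   occludes the rebound-timed response), and at 1/gain otherwise.

The communication endpoint is the flank-subtracted coincidence excess in the
[0, 20] ms lag window of the IPIS-referenced partner correlogram, per minute
(the ±[20, 40] ms flanks sample the same-interval baseline).  Jitter-band
masses were rejected for this endpoint: the ±200 ms jitter mixes I- and
E-period baselines, so state-locked co-modulation and globally suppressed
backgrounds distort band-relative masses in opposite directions.  Under
these mechanisms the four paradigms reproduce the reported pattern: I-locked
and continuous stimulation restore I-period rates and communication (I-locked
at least as well as continuous), random-delay and E-locked restore neither.

## What the generator does not emulate

Synthetic recordings have Poisson spiking (no refractoriness, bursting or
rate adaptation), stationary state statistics, noiseless electrode pickup,
no volume conduction beyond the deliberately zero-lag shared components, no
movement or stimulation artifacts (an optional 160 Hz tone exists only for
the SNR-ratio check), and idealized pulse effects with no intra-pulse
dynamics.  Passing recovery tests therefore demonstrates estimator
correctness and internal consistency of the pipeline, not performance on
real extracellular data.

## Problem sizes

Tests and the acceptance script run on 20–120 s recordings, cohorts of 6–18
subjects with 30–120 s segments (the container format supports the full
1800 s segments, which remain the `CohortSpec` default), 100–1000 Monte-Carlo
surrogates, and 200-iteration permutation calibrations over 100–200 null
runs; these sizes were chosen as the smallest at which every tested quantity
is statistically stable.
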