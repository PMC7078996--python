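# Methods

This note documents the models, statistical procedures and design choices
behind `iontospike`, in the spirit of a methods appendix: what is assumed,
what is configurable, and what the synthetic benchmarks do and do not show.

## Recording model

A session is 3,600 one-second sweeps (configurable via `SweepStructure`):
a 200 ms tone pip followed by 800 ms of silence. Analyses use two windows
per sweep: *driven* = [0, 0.2) s and *spontaneous* = [0.3, 1.0) s; spikes
in the 100 ms after tone offset belong to neither, allowing post-stimulus
recovery of spontaneous activity. Sweeps are 0-based internally and 1-based
in human-facing conventions (e.g. the PSTH-difference default ranges,
sweeps 301–900 vs 1501–2100); the conversion is centralised in
`iontospike.io`.

## Spike-train generation

Five response classes are generated from a common intensity model
(`intensity_profile`): during the tone an onset peak decaying exponentially
to a steady rate (primary-like, chopper, unclassified; the unclassified
default is flat, peak = steady), a von-Mises-modulated sinusoid-locked rate
(phase-locked), or a stereotyped 1–2 spikes in the first 5 ms over a
near-zero sustained rate (onset); after the tone, the spontaneous rate.

* **Choppers** are gamma-renewal processes with shape `k` (default 25,
  giving ISI CV ≈ 1/√k = 0.2). Unit-mean gamma increments are accumulated
  in operational time and mapped through the inverse cumulative intensity,
  so the local rate follows the gain-scaled adapting profile while
  regularity is preserved. An operational-time offset of `(1 − 1/k)/2`
  cancels the counting deficit of an onset-aligned ordinary renewal
  process, so the realised rate matches the intensity integral (verified to
  within 3 SE over 600 sweeps in the tests).
* **All other classes** are inhomogeneous Poisson processes sampled by
  thinning, followed by greedy enforcement of an absolute refractory period
  (default 1 ms). Poisson intensities are dead-time corrected,
  `λ = r/(1 − r·τ_r)` (capped at a factor 2), which makes the realised rate
  of a non-paralyzable dead-time process equal the configured rate `r`.
  The correction is skipped for phase-locked units, whose intensity
  modulation is faster than the dead time; their calibrated quantity is
  vector strength, not mean rate.

Default class parameters (CF in Hz; rates in spikes/s) are typical of
tone-driven VCN units at 20 dB above threshold: primary-like CF 9k, spont
50, peak 600 → steady 180 (τ 15 ms); chopper CF 6k, spont 20, peak 350 →
steady 200 (τ 20 ms), k = 25; onset CF 12k, 1–2 onset spikes 1–2 ms apart,
sustained 3; phase-locked CF 400, mean driven 150, von Mises κ = 5;
unclassified CF 10k, flat 60. Identical (unit, schedules, effects, seed)
yield bit-identical spike tables.

## Drug-effect model

Iontophoretic effects follow first-order on/off kinetics,
`dx/dt = (x_target − x)/τ`, with the target set by the active ejection
current through a user-supplied map (no Hill fit: observed dose dependence
is sometimes saturating and sometimes not, so the map is left free). The
level acts as:

* a multiplicative gain on the driven and/or spontaneous intensity
  (donors/inhibitor; default donor targets 1.2/1.4/1.6 at 40/80/120 nA,
  inhibitor 1.7 at 80 nA),
* an additive evoked rate (NMDA bursts; default 100 spikes/s at 80 nA with
  fast τ = 15 s), and/or
* a multiplier of *other* drugs' additive evoked rate (`applies_to =
  ("evoked",)`), which is how a modulator enhancing NMDA-evoked excitation
  is expressed (default ×1.5),

optionally with waveform drift: `(amplitude_factor, width_factor)` applied
through the same kinetics. Time constants default to 120 s for donors
(effects build over ~5 min) and 360 s for the inhibitor (build-up and
wash-out over ~20 min). These kinetics are calibration conventions, not
mechanistic claims; the published time courses constrain them only
qualitatively.

## Detection and spike shape

Detection thresholds the absolute deviation of the trace from its median;
events are aligned to the absolute extremum within 1 ms of the rising
crossing, with a greedy 1-ms lockout. "Double the background peak-to-peak"
is operationalised as 2 × (2 × 3.29 robust SD) — the central 99.9% span of
Gaussian noise, estimated by the median absolute deviation, i.e. ≈13.16 σ —
a bounded surrogate for an oscilloscope-eye measure. Which polarity the
original online discriminator used is unknowable, hence the absolute-value
rule. Per-sweep mean waveforms are summarised by peak-to-peak amplitude and
the width of the dominant lobe at half its height above the pre-excerpt
baseline (leading eighth of the excerpt), with linear interpolation between
samples; monotone waveforms yield a missing width. Synthetic templates are
generated in-band, so the optional 0.3–3 kHz band-pass is off by default.
For long-session shape statistics, `simulate_shape_series` emulates the
per-sweep metrics (with 1/√n_spikes measurement noise) without rendering
hours of 25 kHz trace; the full trace → detect → measure path is exercised
on short sessions.

## Classification

The published practice is visual; the classifier is a quantitative
surrogate with every threshold exposed in `ClassifierConfig`. Features are
computed on the first 50 ms of the driven response (0.5 ms PSTH bins): the
onset-window (0–10 ms) and sustained-window (15–50 ms) rates, sustained ISI
CV, chopping peaks (peaks of the lightly smoothed PSTH within 25 ms, with a
prominence floor scaled to the PSTH maximum), and a phase screen (vector
strength + Rayleigh test, required for CF < 5 kHz). The rule order is
phase-locked → onset → chopper → primary-like → unclassified, with defaults
VS ≥ 0.3 and Rayleigh p < 10⁻³; sustained/onset ratio ≤ 0.10; CV < 0.35
with ≥ 2 chopping peaks; adapting PSTH (onset/sustained ≥ 1.3) with
CV ≥ 0.5. "Unclassified" is purely residual, as in the field's practice.
The Rayleigh screen is an implementation convenience for classification
only; it plays no role in the drug decision rules.

## Rank statistics and decision rules

`kruskal_wallis` implements the tie-corrected H with midranks;
`dunn_pairwise` the tie-corrected pairwise z with two-sided normal
p-values, Bonferroni-adjusted over the explicitly tested pairs only (3 for
the donor protocol, 2 for inhibitor/NMDA) — the faithful minimal reading of
an analysis that names only those comparisons. Both also offer
`method="exact"`: full enumeration of the multinomial group assignments
(feasible to N = 16; the second-to-last level is vectorised), giving exact
permutation p-values that the test suite checks against an independent
10⁵-shuffle oracle. The default asymptotic p-values are what the composite
rules use, matching the era's analysis software; at the 10–12 bins per
epoch of the protocols the approximation is adequate for decision-making.

Composite rules (all gated on the omnibus KW at the same α = 0.05):

* **donor** — seven epochs in 10-s bins (final 2 min of baseline, of each
  ejection, and of each recovery); flagged iff (R1, E80) and (R2, E120) are
  significant in the same direction and (E120, R3) is significant in the
  opposite direction. "Return towards baseline" is read as a significant
  E120→R3 reversal, not a test against B.
* **inhibitor** — B/E/R in 60-s bins (final 10 min each); flagged iff
  (B, E) and (E, R) are significant with E extreme on both sides.
* **NMDA** — per period, the six highest 10-s bins of the final three
  applications (ties broken by earliest time) as a percentage of the 180-s
  pre-application baseline; B/E/R compared as for the inhibitor. A zero
  baseline switches to absolute differences and is flagged in the result;
  log₁₀ percent is available for spontaneous windows (rank tests are
  invariant to the transform, so it affects reporting only).

Epoch bins are aligned to block starts; bin phase is otherwise
unconstrained by the protocol definitions.

Calibration, measured by the test suite on the default 200 Hz chopper over
200 seeded hour-long sessions per condition: donor and inhibitor nulls flag
≪ 5%, their injected reversible gains (≥1.4× driven) flag > 80% with the
correct direction in every flagged run. The NMDA enhancement procedure is a
known exception: dividing a period's six bins by a *common* noisy baseline
correlates them, and keeping the six *highest* of 18 bins is an
order-statistic selection; together these lift the composite's type-I rate
to ≈5% (measured 4.8% over 1,000 null sessions) instead of the ≪5% a
conjunction of independent tests would give. Both mechanisms are inherent
to the specified scoring, so the package implements them as defined and
documents the calibration honestly rather than altering the procedure.

## Other procedures

* **K-S test**: D is the exact sup-difference of the empirical CDFs; p uses
  the asymptotic Kolmogorov distribution at √(n_x n_y/(n_x+n_y))·D. On
  circular phase data the cut is fixed at phase 0 (no circular correction,
  matching the analysed convention).
* **Association test**: generalised Fisher exact test for R×C count
  tables — full enumeration of fixed-margin tables for totals ≤ 40, else
  seeded Monte-Carlo (≥10⁵ permuted tables), p = total probability of
  tables no more probable than the observed.
* **Population summaries**: per-unit percent-of-baseline is
  100·rate_E/rate_B, averaged across units (mean of ratios, not ratio of
  means); count percentages round half away from zero to integers; units
  with zero baseline are excluded from percent summaries and counted
  separately.

## Problem sizes

Simulation-based tests use hour-long (3,600-sweep) sessions for the
decision-rule calibration (200 seeds per condition in the acceptance suite,
100 in the acceptance script), 500–600-sweep sessions for rate calibration
and the 250-unit classifier cohort, and 60-sweep sessions for trace-level
detection checks — sizes chosen to give stable Monte-Carlo estimates while
keeping a full run inexpensive on a single CPU.

## What the synthetic benchmarks do and do not show

The generator reproduces the *statistical* structure the analyses consume:
PSTH shapes, ISI regularity, phase locking, slow multiplicative drug
modulation, waveform drift, and Poisson/renewal sampling noise. It does not
model biophysics (no conductances, no NO diffusion), electrode drift or
unit loss, correlated network fluctuations (the slow spontaneous "random
fluctuations" real recordings show), multi-unit contamination, or
stimulus-acoustics artefacts. Passing calibration here therefore
demonstrates that the decision rules are correctly implemented and
well-behaved under the modelled noise — not that their error rates carry
over unchanged to real recordings, where slow non-stationarities would
widen the null distribution of any epoch-comparison test.
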