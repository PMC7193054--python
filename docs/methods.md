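# Methods

This note documents the models, calibrations and numerical choices behind
`zfscreen`. Units throughout: seconds, mm/s for swim velocity, mV for
field potentials, µM for concentrations.

## Synthetic LFP traces

A vehicle (untreated mutant) trace is white Gaussian noise of s.d.
`noise_sigma` (default 0.35 mV, 1 kHz, 600 s) plus injected events:

* **Interictal-like events** are single biphasic transients — one positive
  and one negative half-sine lobe — with nominal durations drawn from
  N(0.47, 0.02²) s truncated positive, peak amplitude
  `interictal_amp_factor × noise_sigma` (default 4×), and random polarity.
  The injected span is widened by `1/(1 − asin(3/a)/π)` (a = amplitude
  factor) so that the *detector's* 3σ-crossing duration, not the raw
  support, recovers the nominal duration. This is a closed-form geometric
  calibration, not a fit.
* **Ictal-like events** are trains of ≥ 3 biphasic spikes at
  `ictal_amp_factor × noise_sigma` (default 6×) spanning a duration drawn
  from N(3.09, 1.01²) s truncated at 0.6 s, with first/last spikes at the
  burst edges and inter-spike gaps ≤ 150 ms.

Vehicle event counts are uniform integers on the configured ranges
(107–453 interictal, 1–10 ictal per 10 min); drug exposure thins each
count binomially with the compound's suppression fraction. Events are
placed non-overlapping with ≥ 0.4 s separation (random slack via a
Dirichlet partition of the free time), which keeps threshold-crossing
regions of neighboring events from merging.

## Synthetic velocity traces

The untreated-mutant swim process is a lognormal baseline (mean 0.8 mm/s,
shape 0.6, i.i.d. at 25 Hz) plus a Poisson train of convulsive bursts
(~90 per 10-min epoch): Gaussian bells of 1 s duration with lognormal
peaks (mean 28 mm/s, CV 0.15), placed without overlap since a fish has one
convulsion at a time. Treatment multiplies the experimental epoch by
`(1 − s)·G`, where `s` is the suppression fraction and `G` a lognormal
session factor. The variance of `G` is derived analytically so that the
percent-change coefficient of variation of vehicle wells equals the
configured `control_pct_change_sd` (17.83 %) once the compound-Poisson
sampling variance of the two epoch means is accounted for; its mean is
bias-corrected so vehicle percent change is centred on zero and treated
wells on −100·s. Toxic wells are immobile (zero velocity) in the
experimental epoch.

The generator emulates summary behavior (epoch means, burst structure,
between-well variability) because only those summaries feed the screen.
It does not emulate habituation dynamics, circadian or clutch effects,
within-epoch drug kinetics, tracking artifacts, or correlated
plate-position effects — so passing tests demonstrate correctness of the
analysis pipeline under the assay's stated statistics, not robustness to
every artifact of real tracking data.

## Noise estimation

`estimate_noise` defaults to the first-difference MAD:
`σ̂ = 1.4826 · MAD(Δx) / √2`. For white noise the first differences have
s.d. σ√2, while smooth event waveforms (≥ 0.2 s lobes) contribute almost
nothing sample-to-sample. The classic full-trace MAD is available as
`method="mad"` but overestimates σ by ~20–30 % at the upper end of the
assay's event loads (up to ~450 × 0.6 s of event support in a 600 s
epoch, i.e. > 40 % occupancy), which is why it is not the default.

## Event detection and classification

1. Deviation from the trace median is boxcar-smoothed (20 ms) so that
   isolated noise samples cannot cross threshold (smoothed noise s.d. is
   ~σ/4.5) while 0.1–0.3 s deflections pass essentially unattenuated.
2. Event bounds are first/last crossings of the 3σ bound level; runs
   separated by < 350 ms merge into one event. 350 ms sits above the
   ~0.32 s lobe-tip spacing of a 0.47 s biphasic event (so one event never
   splits) and below the 0.4 s minimum inter-event spacing.
3. An event is retained only if its peak exceeds `threshold_factor`·σ
   (default 3), making the detected count monotone non-increasing in the
   threshold factor by construction.
4. Spikes are local maxima above the bound, ≥ 20 ms apart, with prominence
   ≥ 1σ (so noise ripples riding a lobe are not counted).
5. Classification: **ictal** iff peak > 5σ and (≥ 3 spikes or duration
   ≥ 1 s); otherwise **interictal**. The 1 s duration split and 3-spike
   rule keep the two published duration scales (0.47 s vs 3.09 s) far from
   the boundary. A long event that fails the ictal rule is classed
   interictal, keeping the classification total and exclusive.

Counts are reported per 10-min epoch (`600/duration` scaling).

## Behavioral staging and hit calling

Stages 0–III are video-scored in the original assay; here they are
proxied from velocity features with config-exposed defaults: stage III =
≥ 3 bursts above 20 mm/s; stage II = mean velocity ≥ 8 mm/s; stage I =
active fraction ≥ 0.05 (samples > 0.5 mm/s); stage 0 otherwise. These are
declared defaults, not published values. Toxicity: a fish is immobile if
it moves < 1 mm total in the experimental epoch; a compound is toxic when
≥ 50 % of fish are immobile. The hit rule is exactly the three-clause
criterion in the README; the −40 % cut is inclusive, and fish with zero
baseline velocity are excluded from the percent-change mean (logged) while
still counting toward toxicity and the stage fraction.

## Dose–response call

A candidate is concentration dependent when, across non-toxic
concentrations in increasing order, mean percent change never *increases*
by more than `dose_monotonicity_tol_pct` (default 5 percentage points) and
at least one concentration is a hit. The tolerance exists because with a
control s.d. of 17.83 % and n = 6, the standard error of a
between-concentration difference reaches ~10 points once the effect
plateaus; a strict non-increasing rule would reject ~30 % of genuine
plateaued suppressors on sampling noise alone. Toxic concentrations are
annotated and skipped in the monotonicity check. The confirmation
concentration for electrophysiology is the highest non-toxic hit
concentration of the panel.

## Confirmation statistics

One-way ANOVA (scipy) followed by Dunnett's two-sided many-to-one
comparisons against vehicle. The adjusted p of comparison *i* is
P(max_j |T_j| ≥ |t_i|) under the joint null of the k−1 pairwise t
statistics, which are equicorrelated through the shared control mean with
correlations set by the (possibly unbalanced) group sizes. That tail is
evaluated by seeded Monte Carlo (default 2×10⁵ draws of group means ~
N(0, 1/n_j) plus a shared pooled-variance χ²), then clipped from below at
the unadjusted pooled-t p so the multiplicity ordering holds despite
Monte-Carlo jitter. Homoscedasticity is assumed (classical Dunnett). A
final hit additionally requires the group mean event frequency to lie
below the vehicle mean, making the test effectively directional for
suppression.

## Reproducibility

Every stochastic component draws from `numpy.random.SeedSequence`
children of a single master seed; a dataset object regenerates any well
or LFP subject bit-identically on demand, and a fixed seed reproduces a
full `ScreenResult` (including Monte-Carlo p-values) exactly.

## Problem sizes

Default study conditions are used throughout: 600 s epochs at 1 kHz
(LFP) and 25 Hz (velocity), 6 fish/drug, 6 controls/plate. The validation
suite uses 18–50 LFP traces and 200 vehicle wells for parameter recovery,
and ten seeded 60-compound screens (25 % suppressors with maximal effects
0.6–0.95, EC50 0.3–1 µM; 20 % toxic; confirmation groups of 10 subjects)
for end-to-end recovery — sizes chosen so each check is a stable estimate
of the quantity it measures.

## Known limitations

* The staging proxy collapses a behavioral scale onto velocity features;
  real stage II "whirlpool" swimming is not distinguishable from fast
  linear swimming by speed alone.
* The detector implements threshold rules only; template matching (as in
  commercial acquisition software) is out of scope.
* Toxicity in the generator is all-or-none at ≥ 10 µM; real toxicity is
  graded and time dependent.
* No pharmacokinetics: suppression is a static function of concentration,
  and false negatives from poor compound absorption cannot be modeled.
* Single-channel LFP only; no seizure-onset localization or multi-channel
  logic.
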