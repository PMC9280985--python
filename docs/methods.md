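# Methods

This note records the models, parameter choices and numerical decisions
behind `neckcore`, in the spirit of a methods appendix: what is computed,
what the synthetic data do and do not emulate, and where the design was
genuinely open.

## Signal model and file formats

A *trial* is a set of synchronously sampled channels (default 2000 Hz)
with metadata: subject, condition, body mass, added head mass, applied
external force, and for graded jumps a nominal effort percentage. Units
are volts (EMG), m·s⁻² (accelerometers, proper acceleration) and newtons
(force plate). Per-channel linear calibration (gain, offset) is applied
at read time, so all processing operates in physical units. Event indices
are 0-based sample indices; time = index / fs.

On disk a trial is a TSV numeric matrix (header row of channel names, one
column per channel, raw uncalibrated values at 10 significant digits)
plus a JSON sidecar `<stem>.meta.json` holding fs, metadata and the
per-channel units/gain/offset. A study is a YAML manifest listing
per-subject trial paths keyed by condition, plus a muscle-availability
map recording which subjects' electrodes were usable. Pull trials carry
the applied horizontal force either as a logged channel or a scalar;
`validate_applied_force` rejects a trial whenever the force leaves the
150–200 N acceptance band.

## EMG processing

1. **Rectification** — pointwise absolute value.
2. **Background** — mean of the 500 smallest rectified samples of a
   relaxed (rest) recording, per muscle and subject. Subtraction clips at
   zero: negative activation is physically meaningless, and the clip is a
   deliberate decision (an unclipped subtraction would let background
   noise integrate to negative areas).
3. **MVC reference** — per MVC trial, the maximum of a centered 250-ms
   moving average of the rectified, background-corrected trace; the
   reference is the mean of per-trial maxima over the available trials
   (nominally four per direction). The smoothing window exists because
   the raw single-sample maximum of a stochastic interference signal is
   an extreme-value statistic dominated by noise. Ventral muscles
   (sternohyoid, sternocleidomastoid, masseter) are referenced to the
   flexion MVC, dorsal muscles to the extension MVC.
4. **Normalization** — a(t) = 100·max(|x| − b, 0)/R in %MVC. The same
   per-subject reference is used for every condition of that subject, so
   manipulation/control ratios are invariant to any multiplicative error
   in R (including the upward bias of a smoothed-maximum estimator).
5. **Cycle segmentation** — half-open strike-to-strike windows from the
   foot-accelerometer events, capped at 20 cycles per trial.
6. **Integration** — trapezoidal, in %MVC·s. The right window edge is
   included as an integration endpoint so a w-sample window integrates
   exactly w/fs seconds (cycles share their boundary sample, an O(dt)
   choice that makes the constant-envelope case exact).
7. **Binning** — windows are split into 100 bins (running) or 200 bins
   (jumps) of near-equal length; when the window length is not a
   multiple of the bin count the leftover samples go one-per-bin to the
   earliest bins. Bin value = mean of its samples.
8. **Ensemble statistics** — hierarchy is cycles → subject mean →
   across-subject mean with a Student-t 95 % CI (the CI method is a
   package choice; with fewer than two units the CI is flagged
   undefined).

The per-jump EMG metrics are the maximum (of a 50-ms moving average, for
the same extreme-value reason as the MVC reference), mean, and integrated
area of a(t) over the countermovement-onset→landing window.

## Accelerometer processing

Traces are smoothed with a centered rolling mean over 10 ms (odd sample
count, 21 samples at 2 kHz; edges shrink the window). Gravity calibration
is two-point: gain = 2g/(V_up − V_down), zero at the midpoint voltage.
Foot strikes are local maxima exceeding median + 6·MAD with a refractory
period of half the hinted stride period — the MAD threshold makes
detection invariant to amplitude scaling. The vertical zero is the mean
of per-stride minima of the *smoothed* trace (the minima lie in the
flight phase, where proper acceleration vanishes; smoothing first avoids
single-sample noise minima, and the remaining noise floor biases a
minimum-based baseline slightly low — visible in tests at high sensor
noise). The fore-aft zero depends on condition: whole-cycle mean
(control, added head mass), mean of per-step peaks (forward pull, where
the applied force eliminates all forward acceleration) or per-step minima
(rearward pull). Steps are strike-to-strike windows, half-steps split at
the temporal midpoint. The cosine tilt correction (factor cos θ,
corrected = measured / cos θ; 0.883 at 28°) is opt-in and not applied by
default, matching a workflow that reports the ≤ 12 % underestimate
rather than correcting it.

## Jump kinetics

Effective weight W is the mean of the quietest standing window (minimum
rolling SD over a 1-s window within the pre-movement segment); any
constant applied downward force is thereby folded into W, which makes
a(t) = (F − W)/m invariant to added gravity, as it must be. Movement
onset is the first sustained (50 ms) drop of force below 90 % of W. The
"drop below 10 % of body weight" phrasing sometimes used for this window
is physically inconsistent with countermovement initiation — force near
10 % of body weight occurs only at takeoff — so the package reads it as a
10 % *drop*; the literal threshold is available via `onset_mode="literal"`.
Takeoff is the first force sample below an absolute 10 N (robust to
plate noise, unlike a %W threshold near zero); landing is the first
subsequent return to 10 % W. Integration is trapezoidal at native fs with
no resampling; net impulse and takeoff velocity are computed from the
same trapezoids, so J = m·v holds to floating-point precision and the
impulse–velocity consistency check in the tests verifies the phase
detection rather than the integrator. Jump height is reported both as
v²/2g and as g·t_f²/8 from the flight time; g = 9.81 m·s⁻² throughout.
Percent impulse change between conditions is reported signed
(100·(mean_control − mean_manip)/mean_control) with the magnitude
alongside, since a small increase and a small decrease both appear in
summaries as "a few percent change".

## Statistics

The paired comparison is the one-tailed Wilcoxon signed-rank test:
differences manipulation − control, zeros dropped (Wilcoxon's original
treatment), tied absolute differences mid-ranked. For n ≤ 25 effective
pairs without ties the exact null distribution is built by dynamic
programming over rank subset sums (a length-n(n+1)/2 convolution, not a
2ⁿ enumeration); otherwise a normal approximation with tie-corrected
variance and a 0.5 continuity correction. The test direction is explicit
per comparison: "greater" for the running manipulations (which predict
activity increases), "less" for added-gravity jumps (where a postural
role would predict a decrease). Familywise error over the eight muscles
is controlled by Holm's step-down adjustment with enforced monotonicity,
mapped back to input order. The EMG–effort relation is fit by
untransformed nonlinear least squares y = a·exp(b·x), initialized from a
log-linear regression on the positive points; log-space regression is
deliberately not used for the final fit because it re-weights residuals.
Non-convergence falls back to the log-linear parameters, flagged.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes;
its defaults are the study conditions (16 subjects, body mass
73.7 ± 7.3 kg, 20 cycles per running trial, 4 jumps per maximal
condition, 4 + 4 + 1 MVC/rest trials, 4.5 kg added head mass, 175 N
applied pull force within the 150–200 N band, ~270 N added gravity,
graded efforts 10/25/50/75/90 % × 4).

**EMG.** A Gaussian white carrier is band-pass filtered to 20–400 Hz
(4th-order Butterworth, zero-phase) and normalized to unit mean rectified
amplitude, then multiplied by a nonnegative activation envelope in %MVC
and by the subject's MVC voltage scale (0.5 mV). Expected mean rectified
amplitude therefore equals the envelope, which is what makes integrated
EMG linear in the envelope and multiplier recovery unbiased. Broadband
instrument noise with a rectified mean of 1 µV (0.2 %MVC-equivalent) is
added; at that level the noise-induced ratio bias is below 1 %. Running
envelopes are a tonic level (0.6–1.2 %MVC) plus wrapped-Gaussian
stride-locked bursts (biphasic for most muscles, amplitudes 1–3.5 %MVC,
phased as described for cervical muscles in running: ventral bursts near
mid-support, dorsal bursts just before foot contact). Jump envelopes are
a tonic level plus a push-off Gaussian locked to the propulsion peak, an
elevated flight level and a landing burst. Condition effects multiply the
whole envelope; the shipped defaults mirror the published group-mean
ratios per muscle and condition, so a default study reproduces those
group means by construction. The default between-subject spread of the
true multiplier is zero: the generator's job in recovery tests is to
measure pipeline fidelity, and a realistic population spread (SDs of
order 1–2 on the ratios) would swamp a 16-subject mean; a
`subject_multiplier_sd` knob restores it when sampling behaviour itself
is under study.

**Running kinematics.** Each stride cycle holds one stance half-sine
(vertical peak 38.5 m·s⁻² ⇒ whole-cycle mean ≈ 9.3 m·s⁻² at duty factor
0.38) followed by a flight segment in which vertical proper acceleration
is zero; sensor offsets (0.3 m·s⁻² vertical, 0.5 m·s⁻² fore-aft) and
0.15 m·s⁻² RMS noise are superimposed, and a sharp Gaussian transient
(50 m·s⁻², σ = 5 ms) marks each foot strike on the foot channel. This is
a deliberate simplification — a real running stride contains *two*
single-support steps, and stride frequency (default 1.4 Hz) and duty
factor are configuration rather than claims — but it exercises exactly
the analysis paths that matter: flight-phase baselining, MAD-threshold
strike detection, per-step statistics and the three fore-aft offset
modes (control braking/propulsion is a zero-mean stance sinusoid; pull
conditions are unidirectional stance half-sines whose flight segments
carry the true zero). Consequently the Table-style fore-aft half-step
summary numbers are qualitative, not calibrated.

**Jump kinetics.** The force curve is piecewise analytic: quiet standing
at W, an unweighting half-sine dip (0.5 W over 0.35 s), a propulsion
half-sine above W (0.40 s) whose amplitude is solved from the impulse
balance so that the net impulse over the push-off equals the configured
target exactly, a cosine release ramp to zero (0.04 s, takeoff), a
ballistic flight of duration 2v/g, a landing half-sine spike (3 W,
0.12 s) and a standing tail; 2 N RMS plate noise. Default targets are
203.7 N·s (control), 159.5 N·s (added gravity) and 210.5 N·s (added head
mass). A zero target degenerates to quiet standing (flat trace, no
flight); a target requiring a propulsion peak above 6 body weights raises
a validation error as unreachable. Submaximal jumps scale the target by
the nominal effort and scale the EMG envelope by exp(b·ΔJ) with
b = 0.012 per N·s, so integrated EMG rises exponentially with impulse as
the effort-graded analysis expects.

All randomness flows from a single `SeedSequence`; per-subject streams
are spawned from it, so studies are bit-reproducible under a fixed seed
and any subset of conditions can be generated without disturbing the
stream of another subject.

## What passing tests do and do not show

The generator's carrier is stationary and Gaussian, channels are
independent (no cross-talk, no motion artifact), envelopes are exactly
phase-locked, and effect multipliers are exact. Recovery of the
configured ratios to within a few tenths of a percent therefore
demonstrates that the pipeline's estimators are unbiased and internally
consistent under the model's assumptions — not that real recordings,
with electrode shifts, crosstalk, non-stationary noise and genuine
between-subject variability, would yield such tight group means. The
null-jump familywise-error sweep shows the exact signed-rank level and
Holm control hold under symmetric nulls; discreteness of the exact test
makes the realized level conservative.

## Problem sizes and numerical notes

Unit tests run on reduced studies (2 subjects, 5 cycles, 1 kHz) as a
problem-size choice; the recovery checks use the full 16-subject designs,
and the familywise-error sweep runs 200 seeded studies at 1 kHz (the
ratio and rank statistics are invariant to sampling rate well above the
EMG band edge). Tolerances in tests reflect Monte-Carlo error of the
carrier, not tuning: a cycle's rectified-mean has a relative SD of a few
percent, subject means average 20 cycles, and group means average 16
subjects. Filter design for the EMG carrier is cached per (band, fs);
`sosfiltfilt` keeps the carrier zero-phase so envelope timing is exact.
Degenerate inputs (all-zero differences, constant fit targets, single
units, empty windows) return flagged results or raise typed errors
(`ValidationError`, `FormatError`, `DetectionError`) rather than
propagating NaNs.

## Known limitations

- The original analog 100-Hz high-pass idiosyncrasy is intentionally not
  reproduced; the digital band is configurable and defaults to the
  surface-EMG band (20–400 Hz).
- No spectral analysis (median frequency, fatigue), no crosstalk
  correction, no orientation estimation or 3-D trajectory reconstruction,
  no drop-jump/landing kinetics beyond landing onset, and no
  motor-unit-level EMG model.
- The manifest format assumes one file per trial; no streaming or
  proprietary acquisition formats (C3D/EDF) are supported.
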