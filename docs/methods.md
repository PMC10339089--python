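# Methods

## Scope and design

The package re-implements, as a testable pipeline, the analysis of
ambulatory continuous-wave NIRS recordings over the tibia and the
gastrocnemius during a timed four-posture protocol, and pairs it with a
forward simulator whose ground truth is set to the published group means.
The guiding principle is *recovery-based verification*: every stage
(spectroscopic conversion, synchronization, filtering, kinetics, statistics)
is validated by generating data with known parameters and checking that the
chain returns them.

## Forward model

Chromophore dynamics are piecewise mono-exponential: within each posture
segment every channel relaxes from its value at the segment boundary toward
`previous plateau + amplitude` with that segment's time constant.  This is
the simplest shape consistent with the two reported estimands — a 1−1/e
time constant and a time-to-95 %-of-nadir, which for an exponential
approach obeys `t95 = τ·ln 20` exactly, making printed nadir times exact
ground truth (tibia PRE: τ = 125.4/ln 20 ≈ 41.9 s).

Two structural rules:

* **tHb is never independent.**  `tHb ≡ O2Hb + HHb` at every sample.  During
  standing, O2Hb and tHb are the exponential primitives (each has its own
  reported time constant, e.g. tibia PRE 44.8 s and 37.5 s) and HHb is the
  difference; elsewhere O2Hb and HHb are primitives.  Consequently the
  walk→stand tHb amplitude is the sum of the O2Hb and HHb amplitudes
  (tibia PRE: 9.2 + 0.6 = 9.8 µM).
* **The recovery segment is baseline-referenced.**  Adjacent-transition
  group means need not telescope across a cohort, so a single deterministic
  trace cannot match both a stand→end-supine delta and a start→end-supine
  delta.  The generator pins the supine-recovery plateau to the baseline
  plateau plus the start-to-end delta, which is the contrast the plateau
  analysis reports.

Rendering to raw signals: the attenuation at wavelength λ and separation ρ
is the MBLL term `DPF·ρ·Σ_c ε_c Δc(t)` plus a zero-mean-in-ρ spatial-slope
term that encodes the absolute absorption implied by the simulated TSI and
total hemoglobin through the SRS relation.  Because the slope term vanishes
at the mean separation — which equals Tx2 in the 30/35/40 mm geometry —
the MBLL inversion at Tx2 and the SRS saturation estimate are *both* exact
on noiseless data (verified to <1e−9 µM and <1e−12 % respectively).  The
separations are not printed by the acquisition software's documentation we
mirror; 30/35/40 mm is the geometry consistent with the stated Tx2
penetration depth of 17.5 mm (= ρ₂/2).

Measurement imperfections: per-sample white noise (default 0.1 µM-equivalent
at 50 Hz), a cadence sinusoid during walking only (default 0.9 Hz — a
1.27 m/s walk with a ~1.4 m stride — amplitude 2 µM-equivalent; the observed
artifact frequency/amplitude are not reported, these are placeholders at a
realistic scale), a slow concentration drift (0.01 µM/min), a constant
clock offset between the two devices, and six event markers at shared true
instants.  µM-equivalents are converted to OD through the MBLL factor of an
equal O2Hb/HHb mixture.  Everything is deterministic given the seed.

Extinction coefficients ship as a versioned table (`data/
extinction_hemoglobin.tsv`, mM⁻¹ cm⁻¹, 750–860 nm, compiled in-vitro
hemoglobin spectra of the Horecker/van Assendelft lineage, linearly
interpolated).  All acceptance quantities are recovery-based and therefore
insensitive to the absolute ε scale; the table's accuracy matters only for
interpreting real device data.

## Processing chain

Order is fixed: synchronize → MBLL/SRS conversion → 0.05 Hz low-pass →
5 s moving average → segmentation.

* **Synchronization**: device b is shifted by the mean of the six per-event
  time differences; residuals are reported and a spread above 0.5 s warns.
* **Low-pass**: 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`).  Zero phase is essential — transition timing is the
  estimand and a causal filter's group delay would bias every kinetic
  metric.  The squared magnitude keeps the passband within 1 % below half
  the cutoff and attenuates the 0.9 Hz cadence by far more than 40 dB.
  Edges use odd-reflection padding.
* **Moving average**: centered, truncated at the edges (the first/last
  minute of each segment is itself an analysis window, so no padding
  values may leak into plateau means).
* **Concentrations are changes** from the first valid sample — the
  continuous-wave limitation; only TSI is absolute.

## Kinetics estimators and their numerical choices

* **t95 of the nadir**: baseline = last-minute mean of the preceding supine
  segment; nadir level = mean of a 15 s window centered on the walk-segment
  minimum; t95 = first crossing of `baseline − 0.95·(baseline − nadir)`.
  Two deliberate deviations from the naive "pointwise minimum of the walk
  segment":
  * the final 20 s of the walk segment (one period of the 0.05 Hz filter,
    capped at 10 % of the segment) are excluded from the nadir search —
    the zero-phase filter is acausal and *rings before the walk→stand
    rise*, producing an undershoot that would masquerade as the nadir
    (on the tibial defaults it shifts t95 by +6.3 s, i.e. +5 %);
  * the nadir *level* is a short plateau average because a pointwise
    minimum of a noisy trace is an extreme-value statistic biased low,
    which lowers the threshold and inflates t95 without bound on shallow
    desaturations.  The nadir *time* remains the argmin.
* **Stand time constants**: fitted over (0, 120] s from the walk→stand
  transition.  "A logarithmic curve's 1−1/e time" is ambiguous, so two
  parameterizations are always reported with method tags: a log-curve fit
  `y = a + b·ln(t + t0)` and a mono-exponential cross-check
  `y = y∞ − A·e^(−t/τ)`.  In the log form **t0 is a fitted parameter**
  (bounded positive): with t0 fixed, the 1−1/e crossing of this family
  over a fixed window is a data-independent constant (≈4.9 s for t0 of
  one sample), i.e. not an estimator at all; with t0 free it tracks a
  true exponential τ of ~20–50 s to within about ±10 %, degrading for
  slower kinetics because the log curve cannot plateau.  The exponential
  cross-check is exact on noiseless exponential input and is the value
  used for quantitative recovery.  Fits whose direction contradicts the
  data's net change are flagged, τ undefined.
* **Plateaus**: last-60 s means per segment; deltas for the three adjacent
  transitions plus start→end supine; baseline-referenced per-segment values
  use subtraction by default (delta units are µM / %), division is exposed
  as an option.

## Statistics

Paired t-tests between adjacent postures at one timepoint with a Bonferroni
family of 4 (the four reported contrasts within a tissue/channel — the
family is not stated explicitly in the reference analysis; per-channel 4 is
the declared choice).  PRE↔POST within-tissue comparisons are plain paired
t-tests.  The tissue × bed-rest two-way repeated-measures ANOVA uses
pingouin; with two 2-level within factors sphericity holds automatically,
so no epsilon correction is applied; Bonferroni pairwise post hocs run only
when the interaction is significant.  Operating characteristics are tested
by simulation: the interaction's type-I error is ≈5 % at α = 0.05 (1000
null cohorts) and the tissue main effect at the reported t95 contrast
(125.4 ± 56.8 vs 55.0 ± 30.1 s, n = 10) is detected in >90 % of
replicates.

## The synthetic cohort and what recovery does (not) show

`reproduce` draws each subject's amplitudes and time constants from normal
distributions with the reported group means and SDs (unreported SDs get
plausible values; sampled time constants are truncated at 5 s, baselines
kept physiological), simulates both devices with default noise and random
clock offsets, runs the full chain and compares per-subject truth with the
per-subject estimate.

Timing metrics are gated by estimability, with thresholds derived from the
chain itself rather than tuned:

* t95 requires a walk desaturation amplitude ≥ 3 % TSI (its 5 %-of-amplitude
  band must resolve above the ~0.15 % processed-trace disturbance floor —
  the low-passed white-noise envelope plus the in-band, unfilterable
  concentration drift) **and** a desaturation τ ≥ 10 s (the zero-phase
  filter's ~8 s rise time plus the 5 s smoothing window set the chain's
  temporal resolution; faster kinetics saturate the estimate near 25–30 s
  for any truth).
* Stand time constants require the transition amplitude to clear 1 µM.

Tolerances for gated parameters: plateau deltas ±0.5 units; stand τ
max(15 %, 3 s); t95 max(15 %, 5 s + 0.95·δ·τ/(0.05·|A|)) — the first-order
propagation of a threshold disturbance δ = 0.15 % through the crossing,
which widens exactly when the crossing is shallow (large τ, small
amplitude).  Under these gates 10-subject PRE+POST cohorts recover all
estimable parameters across seeds.

What the generator does *not* emulate — and hence what passing recovery
does not demonstrate: the mid-walk TSI undershoot-and-partial-recovery seen
in real traces (the simulator's walk nadir is its plateau, so nadir timing
and plateau delta coincide by construction); motion artifacts beyond a pure
cadence sinusoid; physiological drifts with structure (Mayer waves,
thermoregulation); optode coupling changes; partial-volume and
adipose-thickness effects; and any difference between the acquisition
software's proprietary SRS implementation and the canonical
diffusion-approximation estimator used here (recovered TSI is validated
against this package's own forward model, not against the vendor's).

## Known limitations

* Absolute concentrations are not observable by CW-NIRS; simulator
  baselines (tibia 39/21 µM, TSI 65 %; gastrocnemius 42/18 µM, TSI 70 %)
  are plausible values, not measurements.
* The log-curve τ is reported for completeness but is the weaker estimator;
  cross-study comparison should use the exponential value.
* The MBLL/SRS exactness of the forward model relies on Tx2 sitting at the
  mean separation; for other geometries the Tx2 inversion acquires a small
  slope-term contamination.
* Problem sizes used in the shipped verification runs: single recordings
  are 25 min at 50 Hz (75 000 samples × 2 wavelengths × 3 distances);
  cohort runs use 10 subjects × 2 timepoints × 2 tissues; statistical
  operating characteristics use 1000 null and 200 alternative cohorts.
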