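# Methods

This note documents the models, estimators and numerical choices behind
`cardiosense`, and what the synthetic-data generator does and does not
emulate.

## Device model

The IDE cell constant uses the simple-geometry closed form
`K = 2S / (3·W·L·(N−1))`, with finger spacing `S`, width `W`, length
`L` and finger count `N` (all SI metres internally; `K` reported in
cm⁻¹ per ECIS convention). This parse of the formula is the only
grouping that is dimensionally a reciprocal length and yields the
expected sub-1 cm⁻¹ values at the device scale; conformal-mapping
(elliptic-integral) IDE models are deliberately out of scope. The
cantilever is treated as an end-loaded uniform rectangular beam,
`k = E·w·t³/(4L³)`. Young's modulus defaults to 2.0 GPa, the standard
literature value for SU-8, which reproduces the 0.015 N/m stiffness of
a 6 mm × 2 mm × 15 µm beam (computed 0.0156 N/m); a measured spring
constant can override the formula. Composite (polymer + metal) layer
stiffness and Stoney-type surface-stress corrections are ignored.

## Equivalent circuit and fitting

Topology: `Z(ω) = R_s + Z_CPE + R_p/(1 + jωR_pC_p)` — series
solution/electrode resistance, electrode double-layer constant-phase
element `Z_CPE = 1/(Q·(jω)^n)`, and the cell–electrode interface as a
parallel RC. This is the standard two-electrode ECIS lumped model; with
only fitted parameter values available the data cannot discriminate a
series CPE from one parallel to the cell branch, so the standard
topology is adopted. `Q` is used as a bare magnitude in S·sⁿ.

Fitting minimizes `Σᵢ |Z_model(fᵢ) − Z_data(fᵢ)|² / |Z_data(fᵢ)|²`
(modulus weighting, the usual choice for spectra spanning decades;
unit weighting is available). The four positive parameters are
optimized in log space and `n` in logit space, so every iterate is a
valid parameter vector and the Levenberg–Marquardt steps are
unconstrained. Multi-start uses deterministic seeded Gaussian jitter
(0.3–0.7 in the transformed coordinates) around a heuristic initial
guess; ties are broken by lowest weighted residual, then
lexicographically smallest parameter vector. Standard errors come from
the Gauss–Newton covariance at the optimum, mapped through the
transform Jacobian. Convergence tolerances are 1e-15 (xtol/ftol/gtol);
on noiseless model-generated data the generating parameters are
recovered to ~1e-10 relative, far inside the 1e-4 contract.

The initial guess reads `R_s` from the highest-frequency Re(Z), `R_p`
from the low-minus-high-frequency Re(Z) drop (floored at 0.1% of
`R_s`), sets `n = 0.8`, takes `Q` from the mid-band |Z| assuming the
CPE dominates there, and `C_p` from the frequency of the Im(Z)
extremum after removing the estimated CPE reactance. On the reference
parameter set every component lands within a factor ~3 of truth.

ECIS normalizations use impedance **magnitude** at a 5 kHz monitoring
frequency for the cell index (the sensitive band is roughly
0.4–50 kHz) and the **real part** for the adhesion-resistance course;
both choices are configurable.

## Beat analysis

Detection runs on the drift-removed trace (running median, window = 3×
the median beat period from a coarse first pass), low-pass filtered
with a quadratic Savitzky–Golay smoother (~31 ms). Peaks must clear a
prominence of `max(3 × 1.4826·MAD(detrended trace), noise floor)` with
≥ 150 ms separation; the 120 nm default floor is the vibrometer's
resolution limit, and smoothing is what keeps noise extremes (range
≈ 6σ across a valley) from breaching a 3σ-scale threshold. The
multiplier was chosen for a < 1% false-positive rate on the synthetic
suite.

Measurement happens in raw coordinates: the peak value is the raw
sample at the re-centred local maximum (so noise-free amplitudes are
exact and constant offsets cancel), and the per-beat baseline is the
minimum of a running-median-denoised signal between the previous peak
and the current one. At the day-7 scale (10 µm beats) the amplitude
bias under 100 nm readout noise is below 2%; the bias is an absolute
effect of order 100–200 nm (extreme-value selection at peak and
baseline), so relative bias grows for amplitudes approaching 1 µm.

Durations are threshold crossings at `baseline + 0.1 × amplitude`
(linearly interpolated; the fraction is configurable) — a QT-like
width proxy on the mechanical waveform, since no electrophysiological
repolarization signal exists on this device. Beats whose crossing is
cut off by the trace edge report a missing duration. Session
summaries: rate = 1/median(inter-beat interval), irregularity =
sd/mean of intervals, force = k × mean amplitude; a trace with no
detected beats reports zero amplitude/force (quiescent preparation),
and frequency/CV need ≥ 2 beats. The average beat aligns windows
(length = median interval) on the sub-sample parabola vertex of the
smoothed apex and returns the mean-centred pointwise mean; integer
alignment would smear the steep relaxation flank under noise.

## Drug response

Both channels are normalized to the **last pre-dosing measurement**
(t = 0⁻), matching how per-sample relative changes are reported;
percentages may exceed 100 and are never clipped. Recovery profiles
report the grid minimum, its time, and the value at the 24 h horizon
(nearest grid point); "recovered" requires exceeding the minimum by
more than 2 percentage points so noise is not called recovery. The
Hill fit is the inhibitory two-parameter form
`R(d) = 100/(1 + (d/IC50)^h)` in log-parameter space; an IC50 outside
the tested dose range, or a response span under 5 points, flags the
fit unreliable, and non-monotone dose patterns add a warning without
suppressing the fit.

## Synthetic data

The generator encodes the study conditions rather than a mechanistic
model:

- **Spectra**: forward model plus independent proportional Gaussian
  perturbations (sd = noise_rel × |Z|) on both quadratures.
- **Cell coverage**: adhesion and drug effects scale the cell branch
  jointly (`R_p → s·R_p`, `C_p → C_p/s`), making the branch impedance
  exactly linear in the coverage scale `s`; `s = 0` is the cell-free
  pre-seeding baseline. Scaling `R_p` alone cannot reproduce the
  observed 18% resistance rise at the reference `C_p`, because the
  branch's 5 kHz real part saturates once `ωR_pC_p` exceeds 1 — a
  coverage interpretation (more cells ⇒ higher resistance, lower
  capacitance) is also the physically sensible one.
- **Adhesion**: the 5 kHz normalized resistance follows monotone
  piecewise-cubic (PCHIP, no overshoot) interpolation of the keyframes
  {(0 h, 100%), (36 h, 118%), (48 h, 113%), (72 h, 113%)}, sampled
  every 3 h for 72 h; `s(t)` is solved in closed form at each sample.
- **Beating traces**: sums of asymmetric pulses — raised-cosine
  upstroke over the first third of the nominal duration, then a
  slope-continuous exponential-tailed relaxation
  `(1 + Δ/τ)·e^(−Δ/τ)` with `τ = duration/12` — at nominal intervals
  with lognormal jitter (CV = jitter_cv), peaks snapped to the sample
  grid, plus Gaussian readout noise (default 50 nm). Day defaults:
  day 4 (2.5 µm, 3.0 Hz, 0.25 s) → day 7 (10 µm, 1.8 Hz, 0.40 s);
  the amplitude ratios 100 : 166.4 : 243.56 : 400 are the calibrated
  growth landmarks, while the frequencies and durations encode only
  the qualitative trends (rate falls, beats widen) and are synthetic
  stand-ins, not measured values.
- **Drug effects**: per-(drug, dose) keyframe tables
  (`calibration/drug_keyframes.json`) give force and CI percent
  anchors; beat amplitude is scaled by the PCHIP interpolant of the
  force anchors and `s(t)` is solved so the 5 kHz CI tracks the CI
  anchors. E-4031 additionally widens beat duration (peaking at 12 h)
  and inflates interval jitter (rising to 12 h, easing without full
  recovery). Keyframes were chosen over a pharmacodynamic model
  because the available calibration data are trajectory landmarks,
  not kinetics; anchors that are qualitative fill-ins are marked in
  the JSON metadata. Doses between calibrated ones are interpolated
  linearly in log-dose and flagged; timepoints beyond the last
  keyframe raise rather than extrapolate.
- **Seeding**: one global seed fans out to named streams via
  CRC32-keyed `SeedSequence` spawn keys, so adding a stream never
  perturbs existing ones; every generator is a pure function of
  (parameters, seed).

What the generator does **not** emulate: electrode-geometry-resolved
impedance, biological replicate variability, baseline drift/motion
artefacts in the displacement channel, action potentials or calcium
transients, and staining readouts. Passing round-trip tests therefore
demonstrates the analysis chain's correctness and calibration on
idealized single-device data, not robustness to every artefact of real
recordings.

## Problem sizes and determinism

Default spectra use 60 log-spaced points over 100 Hz–2 MHz; traces are
20 s at 1 kHz (≥ 500 Hz is required so 150 ms features are resolved);
Monte-Carlo checks use 50 replicate spectrum fits (1% noise), 100-seed
beat-detection sweeps and 200-replicate IC50 fits — sizes at which the
sampling error of each checked statistic is comfortably below its
tolerance. Landmark round trips (adhesion, growth, drug anchors) run
noise-free and are exact by construction up to analysis error; the
acceptance script's fit-recovery targets are deterministic given the
seed, which only drives the multi-start jitter.

## Known limitations

- The amplitude estimator's noise bias (~0.1–0.2 µm absolute at
  100 nm noise) makes sub-µm beats progressively overestimated.
- The Hill fit on CI suppression that never crosses 50% extrapolates
  IC50 and flags it unreliable (see `examples/05_drug_response.py`).
- Interval CV under heavy E-4031-like jitter is inflated further by
  pulse overlap at widened durations; it remains a valid monotone
  irregularity index but not a calibrated CV of the underlying
  interval distribution.
- The strain-independence of the two channels is architectural (no
  operation reads both channels' inputs) and is verified by an
  end-to-end perturbation test rather than by physics.
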