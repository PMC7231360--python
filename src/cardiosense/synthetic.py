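"""Synthetic-data generators standing in for the physical device.

Everything the analysis pipeline consumes can be generated here with
seeded randomness:

* impedance spectra from the equivalent-circuit forward model
  (100 Hz - 2 MHz by convention), optionally with proportional noise;
* a 72-hour adhesion time course whose 5 kHz normalized resistance
  follows calibrated keyframes (rising to 118% at 36 h, settling near
  113%);
* day 4-7 cardiomyocyte beating traces with growing amplitude and
  falling frequency;
* drug suppression/recovery experiments (Verapamil, E-4031) driven by
  per-(drug, dose) keyframe tables.

Cell growth and detachment are modelled by a single coverage scale s
applied jointly to the cell branch (R_p -> s*R_p, C_p -> C_p/s), which
makes the branch impedance exactly linear in s:

    Z(s, w) = R_s + Z_CPE(w) + s * R_p / (1 + j*w*R_p*C_p)

so s = 0 is the cell-free (pre-seeding) baseline and any target
resistance or magnitude at the monitoring frequency maps to a unique s.

Drug effects are keyframe interpolation (monotone piecewise cubic, no
overshoot), not a mechanistic pharmacodynamic model: the source data
are trajectory landmarks, and keyframes make them exactly reproducible.

Every generator is a pure function of (parameters, seed); a single
global seed fans out to independent per-stream seeds.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.interpolate import PchipInterpolator

from .beat_analysis import DisplacementTrace
from .eis import (
    CircuitParams,
    ImpedanceSpectrum,
    ImpedanceTimeCourse,
    circuit_impedance,
    electrode_impedance,
    reference_params,
)

__all__ = [
    "BeatProfile",
    "DAY_PROFILES",
    "DrugEffectKeyframes",
    "AdhesionCourseParams",
    "DrugExperiment",
    "default_keyframes",
    "default_frequency_grid",
    "stream_rng",
    "simulate_spectrum",
    "scaled_circuit_impedance",
    "simulate_adhesion_course",
    "simulate_beating_trace",
    "apply_drug_model",
    "MONITOR_FREQ_HZ",
    "SEEDING_TIME_H",
]

MONITOR_FREQ_HZ = 5_000.0  # within the sensitive band (~400 Hz - ~50 kHz)
SEEDING_TIME_H = -168.0  # cells seeded one week before dosing (day 0 vs day 7)


def default_frequency_grid(n_points: int = 60) -> np.ndarray:
    """Log-spaced acquisition grid, 100 Hz to 2 MHz."""
    return np.logspace(np.log10(100.0), np.log10(2e6), n_points)


def stream_rng(seed: int, *key) -> np.random.Generator:
    """Independent RNG stream derived from a global seed and a name.

    Streams are keyed by CRC32 of the key parts, so adding a new stream
    never perturbs existing ones.
    """
    spawn = tuple(zlib.crc32(str(k).encode()) for k in key)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=spawn))


# ----------------------------------------------------------------------
# Impedance generators
# ----------------------------------------------------------------------

def simulate_spectrum(
    params: CircuitParams,
    frequencies=None,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> ImpedanceSpectrum:
    """Forward-model spectrum with proportional complex Gaussian noise.

    Independent perturbations with sd = noise_rel * |Z| are added to the
    real and imaginary parts.  noise_rel = 0 returns the exact forward
    model; a fixed seed is bit-reproducible.
    """
    if noise_rel < 0:
        raise ValueError("noise_rel must be >= 0")
    if frequencies is None:
        frequencies = default_frequency_grid()
    spec = circuit_impedance(params, frequencies)
    if noise_rel == 0:
        return spec
    rng = stream_rng(seed, "spectrum")
    sd = noise_rel * np.abs(spec.z)
    z = spec.z + sd * rng.standard_normal(len(spec)) + 1j * sd * rng.standard_normal(len(spec))
    return ImpedanceSpectrum(frequencies=spec.frequencies, z=z)


def _branch(params: CircuitParams, freq: float) -> complex:
    w = 2.0 * np.pi * freq
    return params.r_p / (1.0 + 1j * w * params.r_p * params.c_p)


def scaled_circuit_impedance(
    params: CircuitParams, scale: float, frequencies
) -> ImpedanceSpectrum:
    """Spectrum with the cell branch scaled by coverage factor s >= 0."""
    if scale < 0:
        raise ValueError("coverage scale must be >= 0")
    f = np.asarray(frequencies, dtype=float)
    w = 2.0 * np.pi * f
    z = (
        params.r_s
        + (1.0 / (params.q * w**params.n)) * np.exp(-1j * params.n * np.pi / 2.0)
        + scale * params.r_p / (1.0 + 1j * w * params.r_p * params.c_p)
    )
    return ImpedanceSpectrum(frequencies=f, z=z)


def _scale_for_magnitude(params: CircuitParams, freq: float, target_mag: float) -> float:
    """Coverage scale s such that |Z(s)| at freq equals target_mag."""
    a = complex(electrode_impedance(params, freq))
    b = _branch(params, freq)
    # |a + s b|^2 = m^2 -> |b|^2 s^2 + 2 Re(a conj(b)) s + |a|^2 - m^2 = 0
    A = abs(b) ** 2
    B = 2.0 * (a * b.conjugate()).real
    C = abs(a) ** 2 - target_mag**2
    disc = B * B - 4.0 * A * C
    if disc < 0:
        raise ValueError("target magnitude unreachable for this circuit")
    s = (-B + np.sqrt(disc)) / (2.0 * A)
    return max(float(s), 0.0)


def _scale_for_real(params: CircuitParams, freq: float, target_re: float) -> float:
    a = complex(electrode_impedance(params, freq)).real
    b = _branch(params, freq).real
    return max((target_re - a) / b, 0.0)


def _monotone_interp(keyframes) -> PchipInterpolator:
    kf = np.asarray(keyframes, dtype=float)
    if kf.ndim != 2 or kf.shape[1] != 2 or kf.shape[0] < 2:
        raise ValueError("keyframes must be a list of >= 2 (time, value) pairs")
    if np.any(np.diff(kf[:, 0]) <= 0):
        raise ValueError("keyframe times must be strictly increasing")
    return PchipInterpolator(kf[:, 0], kf[:, 1], extrapolate=False)


DEFAULT_ADHESION_KEYFRAMES = ((0.0, 100.0), (36.0, 118.0), (48.0, 113.0), (72.0, 113.0))


@dataclass(frozen=True)
class AdhesionCourseParams:
    """Configuration of the 72-h adhesion/growth simulation.

    ``resistance_keyframes`` are (time_h, percent-of-baseline) anchors
    for the 5 kHz normalized resistance; the default trajectory rises
    roughly linearly to 118% at 36 h and settles near 113%.
    """

    circuit: CircuitParams = field(default_factory=reference_params)
    resistance_keyframes: tuple = DEFAULT_ADHESION_KEYFRAMES
    sample_interval_h: float = 3.0
    duration_h: float = 72.0
    noise_rel: float = 0.0
    monitor_freq_hz: float = MONITOR_FREQ_HZ

    def __post_init__(self) -> None:
        kf = np.asarray(self.resistance_keyframes, dtype=float)
        if kf[0, 0] != 0.0 or kf[0, 1] != 100.0:
            raise ValueError("resistance trajectory must start at (0 h, 100%)")
        if self.sample_interval_h <= 0:
            raise ValueError("sample_interval_h must be > 0")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")


def simulate_adhesion_course(
    params: AdhesionCourseParams | None = None, seed: int = 0
) -> ImpedanceTimeCourse:
    """Simulate the post-seeding impedance time course.

    The first sample (t = 0) is the cell-free baseline; thereafter the
    cell-branch coverage scale is solved at every sample so the
    monitoring-frequency resistance follows the monotone piecewise-cubic
    interpolation of the keyframes exactly (noise off).
    """
    p = params if params is not None else AdhesionCourseParams()
    interp = _monotone_interp(p.resistance_keyframes)
    times = np.arange(0.0, p.duration_h + 1e-9, p.sample_interval_h)
    frac = interp(times)
    if np.any(np.isnan(frac)):
        raise ValueError("sampling times extend beyond the last keyframe")

    f0 = p.monitor_freq_hz
    a = complex(electrode_impedance(p.circuit, f0))
    b = _branch(p.circuit, f0)
    rng = stream_rng(seed, "adhesion")

    z_mag = np.empty_like(times)
    z_real = np.empty_like(times)
    for i, (t, fr) in enumerate(zip(times, frac)):
        s = _scale_for_real(p.circuit, f0, (fr / 100.0) * a.real)
        z = a + s * b
        if p.noise_rel > 0:
            sd = p.noise_rel * abs(z)
            z = z + sd * rng.standard_normal() + 1j * sd * rng.standard_normal()
        z_mag[i] = abs(z)
        z_real[i] = z.real
    return ImpedanceTimeCourse(times_h=times, z_mag=z_mag, z_real=z_real, frequency_hz=f0)


# ----------------------------------------------------------------------
# Beating traces
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BeatProfile:
    """Nominal beat parameters for one culture day."""

    amplitude: float  # m, peak displacement
    frequency: float  # Hz
    duration: float  # s, nominal contraction width

    def __post_init__(self) -> None:
        if not (self.amplitude > 0 and self.frequency > 0 and self.duration > 0):
            raise ValueError("amplitude, frequency and duration must be > 0")


# Day defaults: amplitudes encode the reported growth ratios
# 100 : 166.4 : 243.56 : 400; frequencies fall and durations widen with
# maturation (trend-level synthetic defaults, not measured values).
DAY_PROFILES: dict[int, BeatProfile] = {
    4: BeatProfile(2.5e-6, 3.0, 0.25),
    5: BeatProfile(4.16e-6, 2.5, 0.30),
    6: BeatProfile(6.089e-6, 2.2, 0.35),
    7: BeatProfile(10.0e-6, 1.8, 0.40),
}


def _add_pulse(samples: np.ndarray, fs: float, peak_idx: int, amp: float, dur: float):
    """Asymmetric beat pulse: raised-cosine upstroke (1/3 of the nominal
    duration) and exponential-tailed relaxation (2/3); the relaxation is
    (1 + dt/tau) * exp(-dt/tau) so the apex is slope-continuous, as in
    measured contraction waveforms; peak exactly on the given sample."""
    t_rise = dur / 3.0
    tau = dur / 12.0
    lo = max(peak_idx - int(np.ceil(t_rise * fs)), 0)
    hi = min(peak_idx + int(np.ceil(2.0 * dur * fs)), samples.size - 1)
    idx = np.arange(lo, hi + 1)
    dt = (idx - peak_idx) / fs
    u = np.clip(dt, 0.0, None) / tau
    pulse = np.where(
        dt <= 0,
        0.5 * amp * (1.0 + np.cos(np.pi * np.clip(-dt, 0.0, t_rise) / t_rise)),
        amp * (1.0 + u) * np.exp(-u),
    )
    pulse[dt < -t_rise] = 0.0
    samples[idx] += pulse


def simulate_beating_trace(
    day: int | None = None,
    amplitude: float | None = None,
    frequency: float | None = None,
    beat_duration: float | None = None,
    length_s: float = 20.0,
    sampling_rate: float = 1000.0,
    noise_sd: float = 50e-9,
    jitter_cv: float = 0.0,
    seed: int = 0,
    start_phase_s: float | None = None,
) -> DisplacementTrace:
    """Synthetic cantilever beating trace.

    Either pass ``day`` (4-7, using :data:`DAY_PROFILES`) or explicit
    (amplitude, frequency, beat_duration).  Inter-beat intervals are the
    nominal period perturbed by lognormal jitter with coefficient of
    variation ``jitter_cv``; Gaussian readout noise of sd ``noise_sd``
    (default 50 nm) is added on top.  Beat peaks are snapped to the
    sample grid so noise-free peak amplitudes are exact.
    """
    if day is not None:
        prof = DAY_PROFILES[day]
        amplitude, frequency, beat_duration = prof.amplitude, prof.frequency, prof.duration
    if amplitude is None or frequency is None or beat_duration is None:
        raise ValueError("pass day= or all of amplitude/frequency/beat_duration")
    if amplitude <= 0 or frequency <= 0 or beat_duration <= 0:
        raise ValueError("amplitude, frequency and beat_duration must be > 0")
    if sampling_rate < 500.0:
        raise ValueError("sampling_rate must be >= 500 Hz to resolve 150 ms features")
    if length_s < 3.0 / frequency:
        raise ValueError("trace must span at least 3 beat periods")
    if jitter_cv < 0 or noise_sd < 0:
        raise ValueError("jitter_cv and noise_sd must be >= 0")

    n = int(round(length_s * sampling_rate))
    samples = np.zeros(n)
    rng = stream_rng(seed, "beats")

    period = 1.0 / frequency
    t = start_phase_s if start_phase_s is not None else 0.6 * period
    while t < length_s - beat_duration:
        peak_idx = int(round(t * sampling_rate))
        _add_pulse(samples, sampling_rate, peak_idx, amplitude, beat_duration)
        if jitter_cv > 0:
            sigma2 = np.log1p(jitter_cv**2)
            step = period * rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2))
        else:
            step = period
        t += step
    if noise_sd > 0:
        samples = samples + noise_sd * rng.standard_normal(n)
    return DisplacementTrace(sampling_rate=sampling_rate, samples=samples)


# ----------------------------------------------------------------------
# Drug model
# ----------------------------------------------------------------------

def _validate_anchor_table(table: dict, start_value: float, what: str) -> None:
    for dose, kf in table.items():
        kf = np.asarray(kf, dtype=float)
        if kf[0, 0] != 0.0 or kf[0, 1] != start_value:
            raise ValueError(f"{what} keyframes for dose {dose} must start at (0, {start_value})")
        if np.any(np.diff(kf[:, 0]) <= 0):
            raise ValueError(f"{what} keyframe times for dose {dose} must be strictly increasing")
        if np.any(kf[:, 1] < 0):
            raise ValueError(f"{what} keyframe values for dose {dose} must be >= 0")


@dataclass(frozen=True)
class DrugEffectKeyframes:
    """Per-(drug, dose) anchor tables for the drug-effect generator.

    ``force`` and ``ci`` map dose (nmol/L) to (time_h, percent) anchor
    lists; ``duration_factor`` and ``jitter_factor`` map dose to
    (time_h, multiplicative factor) profiles (may be empty).
    """

    drug: str
    force: dict
    ci: dict
    duration_factor: dict = field(default_factory=dict)
    jitter_factor: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate_anchor_table(self.force, 100.0, "force")
        _validate_anchor_table(self.ci, 100.0, "ci")
        _validate_anchor_table(self.duration_factor, 1.0, "duration_factor")
        _validate_anchor_table(self.jitter_factor, 1.0, "jitter_factor")

    @property
    def doses(self) -> list[float]:
        return sorted(self.force)


def default_keyframes(drug: str) -> DrugEffectKeyframes:
    """Load the packaged calibration keyframes for ``verapamil`` or ``e4031``."""
    text = resources.files("cardiosense.calibration").joinpath("drug_keyframes.json").read_text()
    data = json.loads(text)
    key = drug.lower().replace("-", "")
    if key not in data or key.startswith("_"):
        raise KeyError(f"no calibration for drug {drug!r}")
    block = data[key]

    def _num(d):
        return {float(k): [tuple(p) for p in v] for k, v in d.items()}

    return DrugEffectKeyframes(
        drug=key,
        force=_num(block["force"]),
        ci=_num(block["ci"]),
        duration_factor=_num(block.get("duration_factor", {})),
        jitter_factor=_num(block.get("jitter_factor", {})),
    )


def _interp_dose(table: dict, dose: float):
    """Anchor list for a dose, interpolating channel curves linearly in
    log-dose between the bracketing calibrated doses when needed.
    Returns (anchors, interpolated_flag)."""
    if not table:
        return None, False
    if dose in table:
        return table[dose], False
    doses = sorted(table)
    if dose < doses[0] or dose > doses[-1]:
        raise ValueError(f"dose {dose} outside calibrated range {doses[0]}-{doses[-1]}")
    hi = min(d for d in doses if d > dose)
    lo = max(d for d in doses if d < dose)
    w = (np.log(dose) - np.log(lo)) / (np.log(hi) - np.log(lo))
    t_union = sorted({t for t, _ in table[lo]} | {t for t, _ in table[hi]})
    f_lo = _monotone_interp(table[lo])
    f_hi = _monotone_interp(table[hi])
    t_max = min(max(t for t, _ in table[lo]), max(t for t, _ in table[hi]))
    anchors = [
        (t, float((1 - w) * f_lo(t) + w * f_hi(t))) for t in t_union if t <= t_max
    ]
    return anchors, True


@dataclass(frozen=True)
class DrugExperiment:
    """Generated dual-channel drug experiment.

    ``traces`` maps time (h, relative to dosing; 0.0 is pre-drug) to a
    displacement trace; ``spectra`` maps the same keys to full impedance
    spectra.  ``course`` is the monitoring-frequency impedance course
    whose first entry is the pre-seeding baseline (at SEEDING_TIME_H).
    """

    drug: str
    dose_nmol_l: float
    traces: dict
    spectra: dict
    course: ImpedanceTimeCourse
    predrug_profile: BeatProfile
    interpolated_dose: bool = False


def apply_drug_model(
    drug: str,
    dose_nmol_l: float,
    timepoints_h,
    keyframes: DrugEffectKeyframes | None = None,
    predrug_profile: BeatProfile | None = None,
    circuit: CircuitParams | None = None,
    length_s: float = 20.0,
    sampling_rate: float = 1000.0,
    noise_sd: float = 0.0,
    jitter_cv: float = 0.02,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> DrugExperiment:
    """Generate per-timepoint beating traces and impedance for one dose.

    Beat amplitude is scaled by the monotone piecewise-cubic
    interpolation of the force keyframes; the cell-branch coverage scale
    is solved at each timepoint so the 5 kHz cell index follows the CI
    keyframes; duration-widening and jitter-inflation profiles (E-4031)
    are applied when present.  Timepoints beyond the last keyframe
    raise (no extrapolation).
    """
    kf = keyframes if keyframes is not None else default_keyframes(drug)
    prof = predrug_profile if predrug_profile is not None else DAY_PROFILES[7]
    params = circuit if circuit is not None else reference_params()
    timepoints = [float(t) for t in timepoints_h]
    if any(t <= 0 for t in timepoints):
        raise ValueError("timepoints must be > 0 (0 h is the implicit pre-drug point)")

    force_kf, interp_f = _interp_dose(kf.force, dose_nmol_l)
    ci_kf, interp_c = _interp_dose(kf.ci, dose_nmol_l)
    dur_kf, _ = _interp_dose(kf.duration_factor, dose_nmol_l) if dose_nmol_l in kf.duration_factor else (None, False)
    jit_kf, _ = _interp_dose(kf.jitter_factor, dose_nmol_l) if dose_nmol_l in kf.jitter_factor else (None, False)

    f_force = _monotone_interp(force_kf)
    f_ci = _monotone_interp(ci_kf)
    f_dur = _monotone_interp(dur_kf) if dur_kf else None
    f_jit = _monotone_interp(jit_kf) if jit_kf else None

    last_t = min(force_kf[-1][0], ci_kf[-1][0])
    if any(t > last_t + 1e-9 for t in timepoints):
        raise ValueError(f"timepoint beyond last keyframe ({last_t} h); no extrapolation")

    f0 = MONITOR_FREQ_HZ
    grid = default_frequency_grid()
    a = complex(electrode_impedance(params, f0))
    b = _branch(params, f0)
    z0_mag = abs(a)
    ci_pre = (abs(a + b) - z0_mag) / z0_mag  # coverage scale 1 pre-drug

    times = [0.0] + timepoints
    traces: dict[float, DisplacementTrace] = {}
    spectra: dict[float, ImpedanceSpectrum] = {}
    course_t = [SEEDING_TIME_H]
    course_mag = [z0_mag]
    course_re = [a.real]

    for t in times:
        frac_force = float(f_force(t)) / 100.0
        dur_factor = float(f_dur(t)) if f_dur is not None else 1.0
        jit_factor = float(f_jit(t)) if f_jit is not None else 1.0
        amp = prof.amplitude * frac_force
        if amp > 0:
            trace = simulate_beating_trace(
                amplitude=amp,
                frequency=prof.frequency,
                beat_duration=prof.duration * dur_factor,
                length_s=length_s,
                sampling_rate=sampling_rate,
                noise_sd=noise_sd,
                jitter_cv=jitter_cv * jit_factor,
                seed=int(stream_rng(seed, "drug-trace", drug, dose_nmol_l, t).integers(2**31)),
            )
        else:  # contraction fully suppressed: flat trace (plus readout noise)
            n = int(round(length_s * sampling_rate))
            rng = stream_rng(seed, "drug-trace", drug, dose_nmol_l, t)
            flat = noise_sd * rng.standard_normal(n) if noise_sd > 0 else np.zeros(n)
            trace = DisplacementTrace(sampling_rate=sampling_rate, samples=flat)
        traces[t] = trace

        target_ci = ci_pre * float(f_ci(t)) / 100.0
        s = _scale_for_magnitude(params, f0, z0_mag * (1.0 + target_ci))
        z_mon = a + s * b
        if noise_rel > 0:
            rng = stream_rng(seed, "drug-z", drug, dose_nmol_l, t)
            sd = noise_rel * abs(z_mon)
            z_mon = z_mon + sd * rng.standard_normal() + 1j * sd * rng.standard_normal()
        course_t.append(t)
        course_mag.append(abs(z_mon))
        course_re.append(z_mon.real)
        spectra[t] = scaled_circuit_impedance(params, s, grid)

    course = ImpedanceTimeCourse(
        times_h=np.array(course_t),
        z_mag=np.array(course_mag),
        z_real=np.array(course_re),
        frequency_hz=f0,
    )
    return DrugExperiment(
        drug=kf.drug,
        dose_nmol_l=dose_nmol_l,
        traces=traces,
        spectra=spectra,
        course=course,
        predrug_profile=prof,
        interpolated_dose=interp_f or interp_c,
    )
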