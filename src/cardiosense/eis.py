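"""Equivalent-circuit impedance model, complex nonlinear least-squares
fitting, and ECIS normalizations.

The lumped two-electrode model is

    Z(w) = R_s + 1 / (Q * (j*w)**n) + R_p / (1 + j*w*R_p*C_p)

with R_s the series (solution + electrode + connector) resistance, a
constant-phase element (CPE, magnitude Q, exponent n) for the electrode
double layer, and a parallel R_p/C_p branch for the cell-electrode
interface.  Fitting minimizes the modulus-weighted complex residual

    sum_i |Z_model(f_i) - Z_data(f_i)|**2 / |Z_data(f_i)|**2

with the positive parameters optimized in log space and the CPE exponent
in logit space, from a heuristic initial guess with deterministic
multi-start jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "CircuitParams",
    "ImpedanceSpectrum",
    "FitResult",
    "ImpedanceTimeCourse",
    "cpe_impedance",
    "circuit_impedance",
    "electrode_impedance",
    "fit_circuit",
    "initial_guess",
    "cell_index",
    "normalized_resistance_course",
    "normalized_ci_course",
]

# Reported day-4-7 mean fit values for the assembled reference device;
# used as the canonical parameter set throughout the package.
REFERENCE_PARAMS_KW = dict(r_s=5.177e3, q=5.01e-8, n=0.705, r_p=40.52e3, c_p=3.29e-9)


@dataclass(frozen=True)
class CircuitParams:
    """Equivalent-circuit parameter vector.

    r_s : series resistance (ohm)
    q   : CPE magnitude (S * s**n)
    n   : CPE exponent, in (0, 1]
    r_p : cell-electrode resistance (ohm)
    c_p : cell-electrode capacitance (F)
    """

    r_s: float
    q: float
    n: float
    r_p: float
    c_p: float

    def __post_init__(self) -> None:
        for name in ("r_s", "q", "r_p", "c_p"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not (0.0 < self.n <= 1.0):
            raise ValueError(f"n must be in (0, 1], got {self.n}")

    def as_array(self) -> np.ndarray:
        return np.array([self.r_s, self.q, self.n, self.r_p, self.c_p])


def reference_params() -> CircuitParams:
    """Canonical day-4-7 mean circuit parameters of the assembled device."""
    return CircuitParams(**REFERENCE_PARAMS_KW)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """One impedance acquisition: frequency grid and complex impedance."""

    frequencies: np.ndarray  # Hz, strictly ascending
    z: np.ndarray  # complex ohm

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        z = np.asarray(self.z, dtype=complex)
        if f.shape != z.shape or f.ndim != 1:
            raise ValueError("frequencies and z must be 1-D arrays of equal length")
        if f.size == 0:
            raise ValueError("spectrum is empty")
        if not np.all(f > 0):
            raise ValueError("frequencies must be positive")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly ascending")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "z", z)

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.z)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a circuit fit."""

    params: CircuitParams
    stderr: dict[str, float]
    residual_norm: float  # sqrt of the weighted sum of squares
    converged: bool
    n_starts_used: int
    message: str = ""


@dataclass(frozen=True)
class ImpedanceTimeCourse:
    """Impedance magnitude and resistance at a monitoring frequency over time.

    The first entry is the pre-seeding baseline Z_0 (the cell-free
    electrode + medium impedance); times are hours and non-decreasing.
    """

    times_h: np.ndarray
    z_mag: np.ndarray  # |Z| at the monitoring frequency (ohm)
    z_real: np.ndarray  # Re(Z) at the monitoring frequency (ohm)
    frequency_hz: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        m = np.asarray(self.z_mag, dtype=float)
        r = np.asarray(self.z_real, dtype=float)
        if not (t.shape == m.shape == r.shape) or t.ndim != 1 or t.size < 1:
            raise ValueError("times, z_mag and z_real must be equal-length 1-D arrays")
        if np.any(np.diff(t) < 0):
            raise ValueError("times must be non-decreasing")
        if self.frequency_hz <= 0:
            raise ValueError("monitoring frequency must be positive")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "z_mag", m)
        object.__setattr__(self, "z_real", r)


# ----------------------------------------------------------------------
# Forward model
# ----------------------------------------------------------------------

def cpe_impedance(q: float, n: float, freq) -> np.ndarray | complex:
    """Constant-phase-element impedance Z = 1 / (Q * (j*w)**n).

    |Z| = 1 / (Q * w**n), phase = -n*pi/2.  n = 1 is an ideal capacitor.
    """
    if not (q > 0):
        raise ValueError(f"Q must be > 0, got {q}")
    if not (0.0 < n <= 1.0):
        raise ValueError(f"n must be in (0, 1], got {n}")
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    w = 2.0 * np.pi * f
    z = (1.0 / (q * w**n)) * np.exp(-1j * n * np.pi / 2.0)
    return complex(z) if z.ndim == 0 else z


def electrode_impedance(params: CircuitParams, freq) -> np.ndarray | complex:
    """Cell-free impedance R_s + Z_CPE (the pre-seeding baseline)."""
    return params.r_s + cpe_impedance(params.q, params.n, freq)


def _circuit_z(r_s, q, n, r_p, c_p, f):
    w = 2.0 * np.pi * np.asarray(f, dtype=float)
    z_cpe = (1.0 / (q * w**n)) * np.exp(-1j * n * np.pi / 2.0)
    z_cell = r_p / (1.0 + 1j * w * r_p * c_p)
    return r_s + z_cpe + z_cell


def circuit_impedance(params: CircuitParams, frequencies) -> ImpedanceSpectrum:
    """Evaluate the full equivalent circuit on a frequency grid."""
    f = np.asarray(frequencies, dtype=float)
    if f.size == 0:
        raise ValueError("frequency list is empty")
    z = _circuit_z(params.r_s, params.q, params.n, params.r_p, params.c_p, f)
    return ImpedanceSpectrum(frequencies=f, z=z)


# ----------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------

_N_LO, _N_HI = 1e-4, 1.0 - 1e-9  # open interval for the logit transform


def _to_internal(p: CircuitParams) -> np.ndarray:
    n = min(max(p.n, _N_LO), _N_HI)
    return np.array(
        [
            math.log(p.r_s),
            math.log(p.q),
            math.log(n / (1.0 - n)),
            math.log(p.r_p),
            math.log(p.c_p),
        ]
    )


def _from_internal(x: np.ndarray) -> CircuitParams:
    n = 1.0 / (1.0 + math.exp(-x[2]))
    return CircuitParams(
        r_s=math.exp(x[0]), q=math.exp(x[1]), n=n, r_p=math.exp(x[3]), c_p=math.exp(x[4])
    )


def initial_guess(spectrum: ImpedanceSpectrum) -> CircuitParams:
    """Heuristic starting point for :func:`fit_circuit`.

    R_s from the highest-frequency Re(Z); R_p from the low-minus-high
    frequency Re(Z) drop (floored); n = 0.8; Q from the mid-band |Z|
    assuming the CPE dominates there; C_p from the frequency of the
    Im(Z) extremum once the estimated CPE contribution is removed.
    Always returns a valid parameter vector.
    """
    f = spectrum.frequencies
    z = spectrum.z
    re = z.real
    r_s = max(float(re[-1]), 1e-3)
    r_p = max(float(re[0] - re[-1]), 1e-3 * r_s)

    n0 = 0.8
    i_mid = len(f) // 2
    w_mid = 2.0 * np.pi * f[i_mid]
    z_cpe_mag = max(float(np.abs(z[i_mid])) - r_s, 0.1 * float(np.abs(z[i_mid])))
    q = 1.0 / (z_cpe_mag * w_mid**n0)
    q = max(q, 1e-15)

    # remove the estimated CPE reactance, then locate the cell-branch
    # Im extremum:  |Im| of R_p || C_p peaks at w = 1/(R_p C_p)
    im_cpe = -np.sin(n0 * np.pi / 2.0) / (q * (2.0 * np.pi * f) ** n0)
    im_resid = z.imag - im_cpe
    i_ext = int(np.argmin(im_resid))
    f_ext = float(f[i_ext])
    c_p = 1.0 / (2.0 * np.pi * f_ext * r_p)
    c_p = max(c_p, 1e-15)

    return CircuitParams(r_s=r_s, q=q, n=n0, r_p=r_p, c_p=c_p)


def _residuals(x: np.ndarray, f: np.ndarray, z: np.ndarray, w: np.ndarray) -> np.ndarray:
    n = 1.0 / (1.0 + np.exp(-x[2]))
    zm = _circuit_z(np.exp(x[0]), np.exp(x[1]), n, np.exp(x[3]), np.exp(x[4]), f)
    d = (zm - z) * w
    return np.concatenate([d.real, d.imag])


def fit_circuit(
    spectrum: ImpedanceSpectrum,
    init: CircuitParams | None = None,
    n_starts: int = 8,
    weighting: str = "modulus",
    seed: int = 0,
) -> FitResult:
    """Complex nonlinear least-squares fit of the equivalent circuit.

    Parameters are optimized unconstrained in log space (logit space for
    the CPE exponent), guaranteeing validity of the returned vector.
    ``n_starts`` deterministic jittered restarts around the initial
    guess guard against local minima; ties are broken by lowest weighted
    residual, then by lexicographically smallest parameter vector.

    Standard errors come from the Gauss-Newton covariance at the
    optimum, propagated through the parameter transform.
    """
    f = spectrum.frequencies
    z = spectrum.z
    if len(spectrum) < 10 or f[-1] / f[0] < 100.0:
        raise ValueError("need >= 10 frequency points spanning >= 2 decades")
    if weighting == "modulus":
        w = 1.0 / np.abs(z)
    elif weighting == "unit":
        w = np.ones_like(f)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    x0 = _to_internal(init if init is not None else initial_guess(spectrum))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    jitter_scale = np.array([0.3, 0.7, 0.5, 0.5, 0.7])

    best = None
    n_used = 0
    for k in range(max(int(n_starts), 1)):
        xk = x0 if k == 0 else x0 + jitter_scale * rng.standard_normal(5)
        try:
            sol = optimize.least_squares(
                _residuals,
                xk,
                args=(f, z, w),
                method="lm",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=20000,
            )
        except Exception:
            continue
        n_used = k + 1
        ok = sol.status > 0 and np.all(np.isfinite(sol.x))
        if not ok:
            continue
        key = (sol.cost, tuple(_from_internal(sol.x).as_array()))
        if best is None or key < best[0]:
            best = (key, sol)

    if best is None:
        fallback = _from_internal(x0)
        return FitResult(
            params=fallback,
            stderr={k: float("nan") for k in ("r_s", "q", "n", "r_p", "c_p")},
            residual_norm=float("nan"),
            converged=False,
            n_starts_used=n_used,
            message="no start converged",
        )

    sol = best[1]
    params = _from_internal(sol.x)
    resid_norm = float(np.sqrt(2.0 * sol.cost))

    # covariance in transformed space, chain rule back to natural units
    m, p = sol.fun.size, sol.x.size
    stderr = {}
    names = ("r_s", "q", "n", "r_p", "c_p")
    try:
        jtj = sol.jac.T @ sol.jac
        s2 = 2.0 * sol.cost / max(m - p, 1)
        cov = np.linalg.pinv(jtj) * s2
        se_t = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        nat = params.as_array()
        deriv = np.array(
            [nat[0], nat[1], nat[2] * (1.0 - nat[2]), nat[3], nat[4]]
        )
        se_nat = se_t * np.abs(deriv)
        stderr = dict(zip(names, (float(s) for s in se_nat)))
    except np.linalg.LinAlgError:
        stderr = {k: float("nan") for k in names}

    return FitResult(
        params=params,
        stderr=stderr,
        residual_norm=resid_norm,
        converged=True,
        n_starts_used=n_used,
        message=sol.message,
    )


# ----------------------------------------------------------------------
# ECIS normalizations
# ----------------------------------------------------------------------

def cell_index(z_t, z_0: float):
    """Cell index CI = (Z_t - Z_0) / Z_0 from impedance magnitudes.

    Z_0 is the pre-seeding baseline; CI reflects cell number, morphology
    and attachment and is invariant under common rescaling of both
    magnitudes.
    """
    if not (z_0 > 0):
        raise ValueError(f"baseline Z_0 must be > 0, got {z_0}")
    z_t = np.asarray(z_t, dtype=float)
    out = (z_t - z_0) / z_0
    return float(out) if out.ndim == 0 else out


def normalized_resistance_course(course: ImpedanceTimeCourse) -> np.ndarray:
    """Resistance time course as percent of the t = 0 baseline.

    Returns an array of (time_h, percent) rows; the baseline row is
    exactly 100.
    """
    if course.times_h[0] != 0.0:
        raise ValueError("course must start with a baseline entry at t = 0")
    r0 = course.z_real[0]
    if not (r0 > 0):
        raise ValueError("baseline resistance must be positive")
    pct = 100.0 * course.z_real / r0
    return np.column_stack([course.times_h, pct])


def normalized_ci_course(
    course: ImpedanceTimeCourse, predrug_time: float
) -> np.ndarray:
    """Cell-index time course as percent of its pre-drug value.

    The course's first entry is the pre-seeding baseline Z_0 used to
    form CI; ``predrug_time`` selects the last pre-dosing measurement
    that defines 100%.  Returns (time relative to predrug_time, percent)
    rows for all entries at or after the pre-drug timepoint.
    """
    t = course.times_h
    idx = np.flatnonzero(np.isclose(t, predrug_time, rtol=0, atol=1e-9))
    if idx.size == 0:
        raise ValueError(f"predrug_time {predrug_time} not found in course")
    i0 = int(idx[0])
    z0 = course.z_mag[0]
    ci = cell_index(course.z_mag, z0)
    ci_pre = ci[i0]
    if ci_pre == 0:
        raise ValueError("pre-drug cell index is zero (no cells)")
    sel = slice(i0, None)
    pct = 100.0 * ci[sel] / ci_pre
    return np.column_stack([t[sel] - predrug_time, pct])
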