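"""Dose-response and recovery quantification for the two readout channels.

Contraction force (cantilever) and cell index (impedance) are
normalized to the last pre-dosing measurement, yielding percent-of-
baseline curves over the observation window (24 h by default).  A
recovery profile reports the minimum, its time, and whether the channel
recovered by the horizon; an optional Hill fit summarizes fixed-time
dose responses with an IC50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .beat_analysis import BeatSummary

__all__ = [
    "DoseResponseCurve",
    "RecoveryProfile",
    "HillFit",
    "build_curve",
    "recovery_profile",
    "hill_fit",
]

RECOVERY_TOLERANCE_PCT = 2.0  # points above the minimum required to call recovery
DEFAULT_HORIZON_H = 24.0


@dataclass(frozen=True)
class DoseResponseCurve:
    """Force and cell-index channels as percent of pre-drug baseline.

    The time grid starts at 0 (dosing) where both channels are exactly
    100%.  Percentages may exceed 100 (hypercontractility); never
    clipped.
    """

    drug: str
    dose_mol_l: float
    times_h: np.ndarray
    force_pct: np.ndarray
    ci_pct: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        f = np.asarray(self.force_pct, dtype=float)
        c = np.asarray(self.ci_pct, dtype=float)
        if not (t.shape == f.shape == c.shape) or t.ndim != 1:
            raise ValueError("times, force and ci must be equal-length 1-D arrays")
        if t[0] != 0.0 or f[0] != 100.0 or c[0] != 100.0:
            raise ValueError("curve must start at t=0 with both channels at 100%")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(f < 0) or np.any(c < 0):
            raise ValueError("percentages must be >= 0")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "force_pct", f)
        object.__setattr__(self, "ci_pct", c)

    def channel(self, name: str) -> np.ndarray:
        if name == "force":
            return self.force_pct
        if name == "ci":
            return self.ci_pct
        raise KeyError(f"unknown channel {name!r}")


@dataclass(frozen=True)
class RecoveryProfile:
    """Minimum / horizon summary of one normalized channel."""

    minimum_pct: float
    time_of_minimum_h: float
    value_at_horizon_pct: float
    recovered: bool


def build_curve(
    drug: str,
    dose_mol_l: float,
    predrug: tuple[BeatSummary, float],
    timepoints: list[tuple[float, BeatSummary, float]],
) -> DoseResponseCurve:
    """Assemble a dose-response curve from analyzed timepoints.

    ``predrug`` is (BeatSummary, cell index) at the last pre-dosing
    measurement; ``timepoints`` are (time_h, BeatSummary, cell index)
    after dosing.  Both channels are expressed as percent of the
    pre-drug values ("of its current value"); a t = 0 row at 100% is
    inserted.  A timepoint with no detected beats contributes 0% force
    (contraction fully suppressed).
    """
    pre_summary, pre_ci = predrug
    if not (pre_summary.mean_force > 0):
        raise ValueError("pre-drug mean force must be > 0")
    if pre_ci == 0:
        raise ValueError("pre-drug cell index must be nonzero")

    times = [0.0]
    force = [100.0]
    ci = [100.0]
    for t, summary, ci_t in sorted(timepoints, key=lambda x: x[0]):
        times.append(float(t))
        force.append(100.0 * summary.mean_force / pre_summary.mean_force)
        ci.append(100.0 * ci_t / pre_ci)
    return DoseResponseCurve(
        drug=drug,
        dose_mol_l=dose_mol_l,
        times_h=np.array(times),
        force_pct=np.array(force),
        ci_pct=np.array(ci),
    )


def recovery_profile(
    times_h,
    percent,
    horizon_h: float = DEFAULT_HORIZON_H,
    tolerance_pct: float = RECOVERY_TOLERANCE_PCT,
) -> RecoveryProfile:
    """Minimum and horizon value of a normalized channel.

    The horizon value is read at the nearest grid point; ``recovered``
    is set when it exceeds the minimum by more than ``tolerance_pct``
    (2 points by default, so noise is not called recovery).
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(percent, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 timepoints for a recovery profile")
    if horizon_h < t[0]:
        raise ValueError("horizon before first timepoint")
    i_min = int(np.argmin(y))
    i_hor = int(np.argmin(np.abs(t - horizon_h)))
    minimum = float(y[i_min])
    at_horizon = float(y[i_hor])
    return RecoveryProfile(
        minimum_pct=minimum,
        time_of_minimum_h=float(t[i_min]),
        value_at_horizon_pct=at_horizon,
        recovered=bool(at_horizon > minimum + tolerance_pct),
    )


@dataclass(frozen=True)
class HillFit:
    """Inhibitory Hill-curve fit R(d) = 100 / (1 + (d / IC50)^h)."""

    ic50: float  # mol/L
    hill: float
    residual_norm: float
    reliable: bool  # IC50 inside the tested dose range
    warnings: tuple = ()


def _hill(d, log_ic50, log_h):
    return 100.0 / (1.0 + (d / np.exp(log_ic50)) ** np.exp(log_h))


def hill_fit(doses, responses_pct) -> HillFit:
    """Least-squares inhibitory Hill fit of a fixed-time dose response.

    Requires >= 4 distinct doses.  An IC50 outside the tested dose
    range is flagged unreliable (extrapolated); a non-monotone response
    pattern adds a warning to the diagnostics but the fit is still
    returned.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses_pct, dtype=float)
    if d.shape != r.shape or d.ndim != 1:
        raise ValueError("doses and responses must be equal-length 1-D arrays")
    if np.unique(d).size < 4:
        raise ValueError("need >= 4 distinct doses")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")

    warns = []
    order = np.argsort(d)
    resid_span = float(np.ptp(r))
    if np.any(np.diff(r[order]) > max(0.05 * resid_span, 2.0)):
        warns.append("responses are non-monotone in dose beyond noise")

    x0 = (np.log(np.exp(np.mean(np.log(d)))), 0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _hill, d, r, p0=x0, maxfev=20000, xtol=1e-14, ftol=1e-14
            )
        ic50 = float(np.exp(popt[0]))
        h = float(np.exp(popt[1]))
        resid = float(np.linalg.norm(_hill(d, *popt) - r))
    except Exception:
        ic50, h, resid = float("nan"), float("nan"), float("nan")
        warns.append("fit did not converge")

    reliable = bool(
        np.isfinite(ic50) and d.min() <= ic50 <= d.max() and resid_span > 5.0
    )
    if resid_span <= 5.0:
        warns.append("response span too small to constrain IC50")
    return HillFit(
        ic50=ic50, hill=h, residual_norm=resid, reliable=reliable, warnings=tuple(warns)
    )
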