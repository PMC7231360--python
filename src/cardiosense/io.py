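"""File formats: CSV schemas for spectra, time courses and traces;
JSON fit reports; validated run configuration.

CSV conventions: UTF-8, '.' decimal, header required.  Complex
impedance is stored as separate signed real/imaginary columns
(capacitive Im(Z) < 0).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .beat_analysis import DisplacementTrace
from .eis import CircuitParams, FitResult, ImpedanceSpectrum, ImpedanceTimeCourse

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "fit_report_to_json",
    "fit_report_from_json",
    "RunConfig",
    "load_config",
]

SPECTRUM_COLUMNS = ["freq_hz", "z_real_ohm", "z_imag_ohm"]
TRACE_COLUMNS = ["time_s", "displacement_m"]
TIMECOURSE_COLUMNS = ["time_h", "freq_hz", "z_real_ohm", "z_imag_ohm"]


class SchemaError(ValueError):
    """Malformed input file (carries row/column context in the message)."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    for col in required:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric value in column {col!r} at row {bad[0] + 2}")


def read_spectrum_csv(path) -> ImpedanceSpectrum:
    df = pd.read_csv(path)
    _check_columns(df, SPECTRUM_COLUMNS, path)
    try:
        return ImpedanceSpectrum(
            frequencies=df["freq_hz"].to_numpy(float),
            z=df["z_real_ohm"].to_numpy(float) + 1j * df["z_imag_ohm"].to_numpy(float),
        )
    except ValueError as e:
        raise SchemaError(f"{path}: {e}") from e


def write_spectrum_csv(spectrum: ImpedanceSpectrum, path) -> None:
    pd.DataFrame(
        {
            "freq_hz": spectrum.frequencies,
            "z_real_ohm": spectrum.z.real,
            "z_imag_ohm": spectrum.z.imag,
        }
    ).to_csv(path, index=False)


def read_trace_csv(path, noise_floor: Optional[float] = None) -> DisplacementTrace:
    df = pd.read_csv(path)
    _check_columns(df, TRACE_COLUMNS, path)
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise SchemaError(f"{path}: need >= 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SchemaError(f"{path}: time_s must be strictly increasing")
    # uniform grid enforced to 1 ppm
    if np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
        raise SchemaError(f"{path}: non-uniform sampling grid (tolerance 1 ppm)")
    kwargs = {} if noise_floor is None else {"noise_floor": noise_floor}
    return DisplacementTrace(
        sampling_rate=1.0 / float(dt[0]),
        samples=df["displacement_m"].to_numpy(float),
        start_time=float(t[0]),
        **kwargs,
    )


def write_trace_csv(trace: DisplacementTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "displacement_m": trace.samples}).to_csv(
        path, index=False
    )


def read_timecourse_csv(path) -> ImpedanceTimeCourse:
    df = pd.read_csv(path)
    _check_columns(df, TIMECOURSE_COLUMNS, path)
    freqs = df["freq_hz"].unique()
    if freqs.size != 1:
        raise SchemaError(f"{path}: expected a single monitoring frequency, found {freqs}")
    z = df["z_real_ohm"].to_numpy(float) + 1j * df["z_imag_ohm"].to_numpy(float)
    try:
        return ImpedanceTimeCourse(
            times_h=df["time_h"].to_numpy(float),
            z_mag=np.abs(z),
            z_real=z.real,
            frequency_hz=float(freqs[0]),
        )
    except ValueError as e:
        raise SchemaError(f"{path}: {e}") from e


def write_timecourse_csv(course: ImpedanceTimeCourse, path) -> None:
    # real part is stored; the imaginary part is reconstructed from
    # magnitude with the capacitive sign convention
    im = -np.sqrt(np.maximum(course.z_mag**2 - course.z_real**2, 0.0))
    pd.DataFrame(
        {
            "time_h": course.times_h,
            "freq_hz": course.frequency_hz,
            "z_real_ohm": course.z_real,
            "z_imag_ohm": im,
        }
    ).to_csv(path, index=False)


# ----------------------------------------------------------------------
# Fit reports
# ----------------------------------------------------------------------

def fit_report_to_json(result: FitResult, settings: dict | None = None) -> str:
    payload = {
        "params": {
            "r_s_ohm": result.params.r_s,
            "q_s_sn": result.params.q,
            "n": result.params.n,
            "r_p_ohm": result.params.r_p,
            "c_p_f": result.params.c_p,
        },
        "stderr": result.stderr,
        "residual_norm": result.residual_norm,
        "converged": result.converged,
        "n_starts_used": result.n_starts_used,
        "message": result.message,
        "settings": settings or {},
    }
    return json.dumps(payload, indent=2)


def fit_report_from_json(text: str) -> FitResult:
    d = json.loads(text)
    p = d["params"]
    return FitResult(
        params=CircuitParams(
            r_s=p["r_s_ohm"], q=p["q_s_sn"], n=p["n"], r_p=p["r_p_ohm"], c_p=p["c_p_f"]
        ),
        stderr=d["stderr"],
        residual_norm=d["residual_norm"],
        converged=d["converged"],
        n_starts_used=d["n_starts_used"],
        message=d.get("message", ""),
    )


# ----------------------------------------------------------------------
# Run configuration
# ----------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class IDEConfig(_Strict):
    W_um: float = Field(gt=0)
    S_um: float = Field(gt=0)
    L_mm: float = Field(gt=0)
    N: int = Field(ge=2)


class CantileverConfig(_Strict):
    L_mm: float = Field(gt=0)
    w_mm: float = Field(gt=0)
    t_um: float = Field(gt=0)
    E_GPa: float = Field(default=2.0, gt=0)
    k_N_per_m: Optional[float] = Field(default=None, gt=0)


class CircuitConfig(_Strict):
    r_s_ohm: float = Field(gt=0)
    q_s_sn: float = Field(gt=0)
    n: float = Field(gt=0, le=1)
    r_p_ohm: float = Field(gt=0)
    c_p_f: float = Field(gt=0)

    def to_params(self) -> CircuitParams:
        return CircuitParams(
            r_s=self.r_s_ohm, q=self.q_s_sn, n=self.n, r_p=self.r_p_ohm, c_p=self.c_p_f
        )


class AdhesionConfig(_Strict):
    sample_interval_h: float = Field(default=3.0, gt=0)
    duration_h: float = Field(default=72.0, gt=0)
    noise_rel: float = Field(default=0.0, ge=0)


class BeatingConfig(_Strict):
    days: list[int] = Field(default=[4, 5, 6, 7])
    length_s: float = Field(default=20.0, gt=0)
    sampling_rate: float = Field(default=1000.0, ge=500.0)
    noise_sd: float = Field(default=50e-9, ge=0)
    jitter_cv: float = Field(default=0.0, ge=0)


class DrugConfig(_Strict):
    drug: str
    dose_nmol_L: float = Field(gt=0)
    timepoints_h: list[float] = Field(default=[4, 8, 12, 16, 20, 24])
    noise_sd: float = Field(default=0.0, ge=0)
    jitter_cv: float = Field(default=0.02, ge=0)


class AnalysisConfig(_Strict):
    monitor_freq_hz: float = Field(default=5000.0, gt=0)
    duration_threshold_fraction: float = Field(default=0.1, gt=0, lt=1)


class RunConfig(_Strict):
    """Validated run configuration; unknown keys are rejected.

    The resolved (fully defaulted) form is written beside every run's
    outputs so a run directory is self-describing.
    """

    seed: int
    ide: Optional[IDEConfig] = None
    cantilever: Optional[CantileverConfig] = None
    circuit: Optional[CircuitConfig] = None
    adhesion: Optional[AdhesionConfig] = None
    beating: Optional[BeatingConfig] = None
    drug: Optional[DrugConfig] = None
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)


def load_config(path) -> RunConfig:
    return RunConfig.model_validate_json(Path(path).read_text())
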