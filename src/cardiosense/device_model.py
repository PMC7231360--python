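"""Geometry-to-physics conversions for the cantilever/IDE sensing device.

Two transducers live on the same chip: an interdigitated electrode array
(IDE) whose geometry sets the cell constant of the impedance measurement,
and an end-loaded rectangular polymer cantilever whose spring constant
converts tip displacement into contraction force.

All lengths are SI metres internally; the cell constant is reported in
cm**-1 at the API boundary, following ECIS convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "IDEGeometry",
    "CantileverSpec",
    "InvalidGeometryError",
    "cell_constant",
    "spring_constant",
    "force_from_displacement",
    "displacement_from_force",
]

ArrayLike = Union[float, np.ndarray]


class InvalidGeometryError(ValueError):
    """Raised when device geometry violates its physical constraints."""


@dataclass(frozen=True)
class IDEGeometry:
    """Interdigitated electrode array geometry.

    Parameters
    ----------
    finger_width : float
        Electrode finger width W (m).
    finger_spacing : float
        Gap S between adjacent fingers (m).
    finger_length : float
        Finger length L (m).
    n_fingers : int
        Total number of fingers N (both combs); must be >= 2.
    """

    finger_width: float
    finger_spacing: float
    finger_length: float
    n_fingers: int

    def __post_init__(self) -> None:
        for name in ("finger_width", "finger_spacing", "finger_length"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidGeometryError(f"{name} must be finite and > 0, got {v}")
        if int(self.n_fingers) != self.n_fingers or self.n_fingers < 2:
            raise InvalidGeometryError(
                f"n_fingers must be an integer >= 2, got {self.n_fingers}"
            )


@dataclass(frozen=True)
class CantileverSpec:
    """End-loaded rectangular cantilever.

    The spring constant defaults to the thin-beam closed form
    k = E * w * t**3 / (4 * L**3); an explicit ``spring_constant_override``
    (e.g. from an experimental calibration) takes precedence.
    """

    length: float  # L_c (m)
    width: float  # w_c (m)
    thickness: float  # t_c (m)
    youngs_modulus: float = 2.0e9  # E (Pa); SU-8 literature value
    spring_constant_override: float | None = None  # k (N/m)

    def __post_init__(self) -> None:
        for name in ("length", "width", "thickness", "youngs_modulus"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidGeometryError(f"{name} must be finite and > 0, got {v}")
        if self.spring_constant_override is not None and not (
            np.isfinite(self.spring_constant_override)
            and self.spring_constant_override > 0
        ):
            raise InvalidGeometryError("spring_constant_override must be > 0")


def cell_constant(geom: IDEGeometry) -> float:
    """Theoretical IDE cell constant K in cm**-1.

    K = 2 S / (3 W L (N - 1)).  A low cell constant (< 1 cm**-1 for
    typical devices) gives high sensitivity to cell-induced impedance
    changes.  Strictly increasing in S; strictly decreasing in W, L, N.
    """
    k_per_m = (2.0 * geom.finger_spacing) / (
        3.0 * geom.finger_width * geom.finger_length * (geom.n_fingers - 1)
    )
    return k_per_m / 100.0  # m**-1 -> cm**-1


def spring_constant(spec: CantileverSpec) -> float:
    """Cantilever spring constant k (N/m).

    Uses the override when supplied, otherwise the end-loaded
    rectangular-beam formula k = E w t^3 / (4 L^3).
    """
    if spec.spring_constant_override is not None:
        return spec.spring_constant_override
    return (
        spec.youngs_modulus * spec.width * spec.thickness**3 / (4.0 * spec.length**3)
    )


def _check_k(k: float) -> None:
    if not (np.isfinite(k) and k > 0):
        raise ValueError(f"spring constant must be finite and > 0, got {k}")


def force_from_displacement(k: float, delta: ArrayLike) -> ArrayLike:
    """Tip force F = k * delta (N) for tip displacement delta (m).

    Negative displacement is allowed (direction); NaN is rejected.
    """
    _check_k(k)
    delta = np.asarray(delta, dtype=float)
    if np.any(np.isnan(delta)):
        raise ValueError("displacement contains NaN")
    out = k * delta
    return float(out) if out.ndim == 0 else out


def displacement_from_force(k: float, force: ArrayLike) -> ArrayLike:
    """Inverse of :func:`force_from_displacement`: delta = F / k (m)."""
    _check_k(k)
    force = np.asarray(force, dtype=float)
    if np.any(np.isnan(force)):
        raise ValueError("force contains NaN")
    out = force / k
    return float(out) if out.ndim == 0 else out
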