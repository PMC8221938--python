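"""Closed-form paraxial model of non-telecentric remote-focus distortion.

A remote focus unit (acousto-optic lens, electrically tunable lens, SLM, ...)
placed one objective focal length ``f`` from the objective (conjugate to the
back aperture) is *telecentric*: the axial focus shift is proportional to the
commanded wavefront curvature ``kappa`` and the lateral magnification of the
field of view is depth-independent.  Real systems miss that plane.  The
misalignment is summarised by three parameters:

``Z_ERROR``
    axial misalignment (mm) of the unit output from the telecentric plane;
    produces a depth-dependent lateral magnification ``M(z)`` and non-uniform
    z-plane spacing for equal curvature steps.
``X_ERROR``, ``Y_ERROR``
    lateral misalignments (mm); each produces a skew of the imaging volume
    (the field drifts laterally as the focus moves in z).

With immersion refractive index ``n``, commanded curvature ``kappa`` (1/mm)
and semi-scan angles ``theta_x``, ``theta_y`` (rad), the actual focus is

    z_RF = -n f^2 kappa / (kappa Z_ERROR + 1)
    x_RF = f (theta_x - kappa X_ERROR) / (kappa Z_ERROR + 1)

(y analogous with ``Y_ERROR``/``theta_y``), and the depth-dependent lateral
magnification is

    M(z_RF) = (n f^2 + z_RF Z_ERROR) / (n f^2)  =  1 / (kappa Z_ERROR + 1).

The model is exactly invertible: driving the unit with

    kappa_COMP   = -z_CORR / (z_CORR Z_ERROR + n f^2)
    theta_x_COMP = kappa_COMP X_ERROR + x_CORR (kappa_COMP Z_ERROR + 1) / f

lands the focus exactly on the desired target (x_CORR, y_CORR, z_CORR) —
the *precompensation* at the heart of this package.

Units and signs
---------------
Optical lengths (``f``, misalignments) are millimetres, curvature 1/mm,
angles radians; focus coordinates in the sample volume are micrometres.
``z_RF`` is measured from the natural focal plane (the focus for a planar,
``kappa = 0`` input) and is negative below it; with all misalignments zero,
``z_RF = -n f^2 kappa``, so positive curvature focuses below the natural
plane under this convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import SingularDriveError, SingularTargetError, ValidationError

__all__ = [
    "OpticalSystem",
    "Drive",
    "FocusPoint",
    "TargetPoint",
    "remote_focus",
    "precompensate",
    "magnification",
    "skew_angle",
    "focus_error",
    "apparent_position",
    "drive_schedule",
    "SINGULARITY_TOL",
]

#: Below this tolerance the conjugate-plane denominators are treated as
#: singular (dimensionless for |kappa Z + 1|, mm^2 for |z Z + n f^2|).
SINGULARITY_TOL = 1e-9

_UM_PER_MM = 1e3


def _require_finite(**values: float) -> None:
    for name, value in values.items():
        if not math.isfinite(value):
            raise ValidationError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class OpticalSystem:
    """Objective plus remote-focus-unit misalignment parameters.

    Parameters
    ----------
    f : float
        Objective focal length, mm (> 0).
    n : float
        Immersion refractive index (>= 1).
    x_error, y_error : float
        Lateral misalignments of the remote-focus-unit output, mm.
    z_error : float
        Axial misalignment of the remote-focus-unit output, mm (signed).
    """

    f: float
    n: float
    x_error: float = 0.0
    y_error: float = 0.0
    z_error: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(f=self.f, n=self.n, x_error=self.x_error,
                        y_error=self.y_error, z_error=self.z_error)
        if self.f <= 0:
            raise ValidationError(f"focal length must be > 0, got {self.f}")
        if self.n < 1:
            raise ValidationError(f"refractive index must be >= 1, got {self.n}")

    @property
    def nf2(self) -> float:
        """n * f**2 in mm^2 — the telecentric curvature-to-focus scale."""
        return self.n * self.f * self.f

    def lateral_error(self, axis: Literal["x", "y"]) -> float:
        if axis == "x":
            return self.x_error
        if axis == "y":
            return self.y_error
        raise ValidationError(f"axis must be 'x' or 'y', got {axis!r}")


@dataclass(frozen=True)
class Drive:
    """Remote-focus-unit output state: curvature and semi-scan angles.

    kappa : wavefront curvature at the unit output, 1/mm (signed).
    theta_x, theta_y : semi-scan angles, rad.
    """

    kappa: float
    theta_x: float = 0.0
    theta_y: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(kappa=self.kappa, theta_x=self.theta_x,
                        theta_y=self.theta_y)


@dataclass(frozen=True)
class FocusPoint:
    """Actual 3-D focus in the sample volume, µm.

    ``z_rf`` is relative to the natural focal plane (negative below it).
    """

    x_rf: float
    y_rf: float
    z_rf: float

    def __post_init__(self) -> None:
        _require_finite(x_rf=self.x_rf, y_rf=self.y_rf, z_rf=self.z_rf)


@dataclass(frozen=True)
class TargetPoint:
    """Desired 3-D focus in the sample volume, µm."""

    x_corr: float = 0.0
    y_corr: float = 0.0
    z_corr: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(x_corr=self.x_corr, y_corr=self.y_corr,
                        z_corr=self.z_corr)


def _drive_denominator(system: OpticalSystem, kappa: float) -> float:
    den = kappa * system.z_error + 1.0
    if abs(den) < SINGULARITY_TOL:
        raise SingularDriveError(
            f"kappa * Z_ERROR + 1 = {den:.3e} is singular "
            f"(kappa={kappa}, Z_ERROR={system.z_error})")
    return den


def remote_focus(system: OpticalSystem, drive: Drive) -> FocusPoint:
    """Forward model: where does a given drive actually focus?

    Evaluates the closed-form distortion model (see module docstring) and
    returns the focus in µm.

    Raises
    ------
    SingularDriveError
        If ``|kappa Z_ERROR + 1| < 1e-9`` (focus at infinity).
    """
    den = _drive_denominator(system, drive.kappa)
    z_rf = -system.nf2 * drive.kappa / den
    x_rf = system.f * (drive.theta_x - drive.kappa * system.x_error) / den
    y_rf = system.f * (drive.theta_y - drive.kappa * system.y_error) / den
    return FocusPoint(x_rf * _UM_PER_MM, y_rf * _UM_PER_MM, z_rf * _UM_PER_MM)


def precompensate(system: OpticalSystem, target: TargetPoint) -> Drive:
    """Exact inverse of :func:`remote_focus`.

    Returns the drive whose actual focus is ``target``; the round trip
    ``remote_focus(system, precompensate(system, target))`` reproduces the
    target to floating-point accuracy.

    Raises
    ------
    SingularTargetError
        If ``|z_corr Z_ERROR + n f^2| < 1e-9`` mm² (target conjugate to
        the unit output; unreachable).
    """
    z_corr = target.z_corr / _UM_PER_MM
    x_corr = target.x_corr / _UM_PER_MM
    y_corr = target.y_corr / _UM_PER_MM
    den = z_corr * system.z_error + system.nf2
    if abs(den) < SINGULARITY_TOL:
        raise SingularTargetError(
            f"z_corr * Z_ERROR + n f^2 = {den:.3e} mm^2 is singular "
            f"(z_corr={target.z_corr} um, Z_ERROR={system.z_error} mm)")
    kappa = -z_corr / den
    scale = kappa * system.z_error + 1.0
    theta_x = kappa * system.x_error + x_corr * scale / system.f
    theta_y = kappa * system.y_error + y_corr * scale / system.f
    return Drive(kappa, theta_x, theta_y)


def magnification(system: OpticalSystem, z_rf: float) -> float:
    """Depth-dependent lateral magnification ``M(z_RF)``.

    Parameters
    ----------
    z_rf : float
        Axial focus relative to the natural plane, µm.

    Notes
    -----
    ``M = (n f^2 + z_RF Z_ERROR) / (n f^2)``; equals ``1`` at the natural
    plane and identically 1 for a telecentric system, and coincides with
    ``1 / (kappa Z_ERROR + 1)`` for the curvature producing ``z_rf``.
    """
    _require_finite(z_rf=z_rf)
    return (system.nf2 + (z_rf / _UM_PER_MM) * system.z_error) / system.nf2


def skew_angle(system: OpticalSystem, axis: Literal["x", "y"] = "x") -> float:
    """Skew of the imaging volume caused by a lateral misalignment, degrees.

    The locus of the central ray (``theta = 0``) in the (x, z) plane is a
    straight line through the origin with slope ``X_ERROR / (n f)``; the skew
    angle is its arctangent (y axis analogous).
    """
    err = system.lateral_error(axis)
    return math.degrees(math.atan(err / (system.n * system.f)))


def focus_error(system: OpticalSystem, z_cmd: float,
                compensated: bool = False) -> float:
    """Axial focus error ``z_RF - z_cmd`` (µm) when commanding ``z_cmd``.

    Uncompensated drives assume the telecentric proportionality
    ``kappa = -z_cmd / (n f^2)``, so any axial misalignment makes the
    realised focus miss the commanded plane; precompensated drives are
    exact and the error is zero (to rounding).
    """
    _require_finite(z_cmd=z_cmd)
    if compensated:
        drive = precompensate(system, TargetPoint(z_corr=z_cmd))
    else:
        drive = Drive(kappa=-(z_cmd / _UM_PER_MM) / system.nf2)
    return remote_focus(system, drive).z_rf - z_cmd


def apparent_position(system: OpticalSystem, bead: tuple[float, float],
                      kappa: float) -> tuple[float, float]:
    """Apparent lateral position (µm) of a fixed bead imaged at curvature
    ``kappa``.

    In a calibration z-stack the scan-angle-to-image mapping is calibrated at
    the natural plane (``theta = x_image / f``).  Inverting the lateral focus
    equation for the scan angle that lands on a bead at ``(x_b, y_b)`` gives
    the image-space position

        x_app = x_b (kappa Z_ERROR + 1) + f kappa X_ERROR   (y analogous)

    so ``x_app = x_b`` at ``kappa = 0`` and misalignments reveal themselves
    as depth-dependent bead displacements.
    """
    x_b, y_b = bead
    _require_finite(x_b=x_b, y_b=y_b, kappa=kappa)
    scale = _drive_denominator(system, kappa)
    x_app = x_b * scale + system.f * kappa * system.x_error * _UM_PER_MM
    y_app = y_b * scale + system.f * kappa * system.y_error * _UM_PER_MM
    return (x_app, y_app)


def apparent_positions(system: OpticalSystem, beads: np.ndarray, kappa: float,
                       assumed: OpticalSystem | None = None) -> np.ndarray:
    """Vectorised :func:`apparent_position` for an (n, 2) array of beads (µm).

    ``assumed`` models acquisition whose scan mapping already precompensates
    for an *assumed* set of misalignments (e.g. a fitted system): the image
    pixel targeting sample position ``x_t`` uses the assumed system's
    compensated scan angle, so a bead appears at

        x_app = [x_b (kappa Z + 1) + f kappa (X - X_a)] / (kappa Z_a + 1)

    where unsubscripted parameters are the true system and ``_a`` the
    assumed one.  ``assumed=None`` means a naive natural-plane mapping
    (assumed errors zero), reproducing :func:`apparent_position`; a correct
    assumption (``assumed == system``) makes every bead appear at its
    reference position — the signature of a well-compensated stack.
    """
    beads = np.asarray(beads, dtype=float)
    if beads.ndim != 2 or beads.shape[1] != 2:
        raise ValidationError(f"beads must have shape (n, 2), got {beads.shape}")
    if not np.all(np.isfinite(beads)):
        raise ValidationError("bead positions must be finite")
    scale = _drive_denominator(system, kappa)
    err = np.array([system.x_error, system.y_error])
    if assumed is None:
        offset = err * system.f * kappa * _UM_PER_MM
        return beads * scale + offset
    scale_a = _drive_denominator(assumed, kappa)
    err_a = np.array([assumed.x_error, assumed.y_error])
    offset = (err - err_a) * system.f * kappa * _UM_PER_MM
    return (beads * scale + offset) / scale_a


def drive_schedule(system: OpticalSystem, z_planes: Sequence[float] | Iterable[float],
                   compensated: bool = False) -> list[Drive]:
    """One drive per commanded z plane (µm), on-axis (``theta = 0`` targets).

    Uncompensated drives use the naive telecentric mapping
    ``kappa = -z / (n f^2)``; compensated drives come from
    :func:`precompensate` and land exactly on each plane.

    Raises the underlying singularity error annotated with the offending
    plane index.
    """
    drives: list[Drive] = []
    for i, z in enumerate(z_planes):
        _require_finite(**{f"z_planes[{i}]": float(z)})
        try:
            if compensated:
                drives.append(precompensate(system, TargetPoint(z_corr=float(z))))
            else:
                kappa = -(float(z) / _UM_PER_MM) / system.nf2
                _drive_denominator(system, kappa)
                drives.append(Drive(kappa=kappa))
        except (SingularDriveError, SingularTargetError) as exc:
            raise type(exc)(f"plane {i} (z={z} um): {exc}") from exc
    return drives
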