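"""Independent paraxial ABCD ray-trace of a remote-focus path.

This module is deliberately redundant with :mod:`refocal.model`: it knows
nothing about the closed-form distortion equations and instead propagates a
fan of paraxial rays through an explicit sequence of optical elements
(free-space gaps, thin lenses with lateral offsets, a remote-focus output,
and a refractive interface into the immersion medium).  Because both
descriptions are exact in the paraxial regime they must agree to rounding,
which makes this module a numerical oracle for the closed forms — and a way
to reduce a *relayed* system (remote-focus unit, relay lenses, objective)
to the single-objective misalignment parameters the closed forms use.

Per transverse axis a ray is ``(h, u)``: lateral offset (mm) from the
optical axis and paraxial slope (rad).  Elements act affinely:

* free space ``d``:       ``h' = h + d u``
* thin lens ``f`` offset ``o``:  ``u' = u - (h - o) / f``
* interface ``n_ratio``:  ``u' = u / n_ratio``
* remote-focus output:    launches the fan, ``u = theta - kappa * t`` at
  local aperture height ``t`` (so ``h = offset + t``).

Sign convention: the closed-form model's ``X_ERROR`` equals *minus* the
ray-space lateral offset of the unit output (the printed lateral-focus
equation fixes the sign; :func:`sequence_for_system` encodes the mapping).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import NoFocusError, ValidationError
from .model import Drive, FocusPoint, OpticalSystem

__all__ = [
    "FreeSpace",
    "ThinLens",
    "RfOutput",
    "Interface",
    "ElementSequence",
    "sequence_for_system",
    "trace_fan",
    "trace_to_focus",
    "EffectiveModel",
    "effective_misalignment",
]

_UM_PER_MM = 1e3


@dataclass(frozen=True)
class FreeSpace:
    """Homogeneous propagation over a signed distance ``d`` (mm)."""
    d: float


@dataclass(frozen=True)
class ThinLens:
    """Thin lens of focal length ``f`` (mm), laterally offset per axis (mm)."""
    f: float
    offset_x: float = 0.0
    offset_y: float = 0.0

    def __post_init__(self) -> None:
        if self.f == 0 or not math.isfinite(self.f):
            raise ValidationError(f"lens focal length must be finite and nonzero, got {self.f}")

    def offset(self, axis: Literal["x", "y"]) -> float:
        return self.offset_x if axis == "x" else self.offset_y


@dataclass(frozen=True)
class RfOutput:
    """Remote-focus-unit output plane; the fan is launched here.

    The drive (curvature, semi-scan angles) is supplied at trace time so one
    sequence can be swept over a drive grid.
    """
    offset_x: float = 0.0
    offset_y: float = 0.0

    def offset(self, axis: Literal["x", "y"]) -> float:
        return self.offset_x if axis == "x" else self.offset_y


@dataclass(frozen=True)
class Interface:
    """Flat refractive interface; paraxial slopes scale by ``1 / n_ratio``."""
    n_ratio: float

    def __post_init__(self) -> None:
        if self.n_ratio <= 0 or not math.isfinite(self.n_ratio):
            raise ValidationError(f"n_ratio must be finite and > 0, got {self.n_ratio}")


Element = FreeSpace | ThinLens | RfOutput | Interface


@dataclass(frozen=True)
class ElementSequence:
    """Ordered optical path: one RfOutput, then gaps/lenses, ending with the
    objective (last thin lens) immediately followed by the immersion
    interface."""

    elements: tuple[Element, ...]

    def __init__(self, elements) -> None:
        object.__setattr__(self, "elements", tuple(elements))
        self._validate()

    def _validate(self) -> None:
        els = self.elements
        n_rf = sum(isinstance(e, RfOutput) for e in els)
        if n_rf != 1:
            raise ValidationError(f"sequence needs exactly one RfOutput, found {n_rf}")
        if not isinstance(els[0], RfOutput):
            raise ValidationError("RfOutput must be the first element")
        if len(els) < 3 or not isinstance(els[-1], Interface):
            raise ValidationError("sequence must end with the immersion Interface")
        if not isinstance(els[-2], ThinLens):
            raise ValidationError("the objective ThinLens must immediately precede the Interface")
        if any(isinstance(e, Interface) for e in els[:-1]):
            raise ValidationError("only the final immersion Interface is supported")

    @property
    def rf_output(self) -> RfOutput:
        return self.elements[0]  # type: ignore[return-value]

    @property
    def objective(self) -> ThinLens:
        return self.elements[-2]  # type: ignore[return-value]

    @property
    def immersion_index(self) -> float:
        return self.elements[-1].n_ratio  # type: ignore[union-attr]


def sequence_for_system(system: OpticalSystem) -> ElementSequence:
    """Canonical two-element path equivalent to a closed-form system.

    The unit output sits ``f - Z_ERROR`` before the objective (telecentric
    when ``Z_ERROR = 0``) with ray-space lateral offsets ``-X_ERROR``,
    ``-Y_ERROR`` (see module docstring for the sign convention).
    """
    return ElementSequence([
        RfOutput(offset_x=-system.x_error, offset_y=-system.y_error),
        FreeSpace(system.f - system.z_error),
        ThinLens(system.f),
        Interface(system.n),
    ])


def trace_fan(seq: ElementSequence, drive: Drive, axis: Literal["x", "y"],
              fan_size: int = 5, aperture: float = 1.0) -> np.ndarray:
    """Propagate a fan through every element; returns (fan_size, 2) array of
    ``(h, u)`` in image space at the objective plane."""
    if fan_size < 2:
        raise ValidationError(f"fan_size must be >= 2, got {fan_size}")
    rf = seq.rf_output
    theta = drive.theta_x if axis == "x" else drive.theta_y
    t = np.linspace(-aperture, aperture, fan_size)
    h = rf.offset(axis) + t
    u = theta - drive.kappa * t
    for el in seq.elements[1:]:
        if isinstance(el, FreeSpace):
            h = h + el.d * u
        elif isinstance(el, ThinLens):
            u = u - (h - el.offset(axis)) / el.f
        elif isinstance(el, Interface):
            u = u / el.n_ratio
        else:  # pragma: no cover - validated out
            raise ValidationError(f"unexpected element {el!r}")
    return np.column_stack([h, u])


def _intersect(rays: np.ndarray) -> tuple[float, float]:
    """Common intersection (z from reference plane, lateral height) of a
    paraxial fan; uses the extreme rays, exact for affine optics."""
    (h1, u1), (h2, u2) = rays[0], rays[-1]
    du = u1 - u2
    if abs(du) < 1e-12:
        raise NoFocusError("ray fan is collimated in image space (no finite focus)")
    z = (h2 - h1) / du
    return z, h1 + z * u1


def trace_to_focus(seq: ElementSequence, drive: Drive,
                   fan_size: int = 5) -> FocusPoint:
    """Focus of the traced fan, µm, relative to the natural focal plane.

    The natural plane of any sequence is one immersion-scaled focal length
    (``n f``) beyond the objective — the focus of a planar (``kappa = 0``)
    input — so the returned ``z_rf`` is directly comparable with
    :func:`refocal.model.remote_focus`.

    Raises
    ------
    NoFocusError
        If the fan leaves the objective collimated.
    """
    natural = seq.immersion_index * seq.objective.f
    zx, x = _intersect(trace_fan(seq, drive, "x", fan_size))
    zy, y = _intersect(trace_fan(seq, drive, "y", fan_size))
    if abs(zx - zy) > 1e-6 * max(1.0, abs(zx)):
        raise ValidationError(
            f"astigmatic trace: x and y foci differ ({zx} vs {zy} mm)")
    z = 0.5 * (zx + zy)
    return FocusPoint(x * _UM_PER_MM, y * _UM_PER_MM, (z - natural) * _UM_PER_MM)


@dataclass(frozen=True)
class EffectiveModel:
    """Single-objective reduction of a relayed remote-focus path.

    ``system`` carries the effective misalignments (mm) of the unit-output
    conjugate plane: lateral offsets scale with the relay's transverse
    magnification ``m``, axial offsets with ``m**2``.  For a non-unit relay
    the commanded drive transforms too (curvature by ``1/m**2`` plus any
    residual relay power, angles by ``1/m``); :meth:`map_drive` applies the
    transform, which is the identity for a unit-magnification tilt-free
    relay.

    ``theta_offset`` is a residual constant beam tilt (rad) at the conjugate
    plane.  A constant tilt shifts the whole field independently of depth and
    is absorbed by the natural-plane reference image during calibration;
    what a calibration *measures* is :attr:`registered_system`, whose lateral
    error folds the tilt in as ``X + Z * tilt``.
    """

    system: OpticalSystem
    magnification: float
    kappa_offset: float = 0.0
    theta_offset: tuple[float, float] = (0.0, 0.0)

    def map_drive(self, drive: Drive) -> Drive:
        m = self.magnification
        return Drive(
            kappa=drive.kappa / m ** 2 + self.kappa_offset,
            theta_x=drive.theta_x / m + self.theta_offset[0],
            theta_y=drive.theta_y / m + self.theta_offset[1],
        )

    @property
    def registered_system(self) -> OpticalSystem:
        """Misalignments as seen by a natural-plane-referenced calibration."""
        s = self.system
        ux, uy = self.theta_offset
        return OpticalSystem(
            f=s.f, n=s.n,
            x_error=s.x_error + s.z_error * ux,
            y_error=s.y_error + s.z_error * uy,
            z_error=s.z_error,
        )


def effective_misalignment(seq: ElementSequence) -> EffectiveModel:
    """Reduce a relayed path to single-objective misalignment parameters.

    The relay between the unit output and the objective images the output
    plane to a conjugate plane; the effective system places the unit there.
    Works for any imaging relay (afocal or not); raises
    :class:`ValidationError` when the relay images the unit output to
    infinity (``D``-term of the relay matrix ~ 0), in which case no
    finite-conjugate reduction exists.
    """
    objective = seq.objective
    n = seq.immersion_index

    results = {}
    for axis in ("x", "y"):
        # affine map (M, e) from the unit output plane to the objective input
        M = np.eye(2)
        e = np.zeros(2)
        for el in seq.elements[1:-2]:
            if isinstance(el, FreeSpace):
                T = np.array([[1.0, el.d], [0.0, 1.0]])
                M = T @ M
                e = T @ e
            elif isinstance(el, ThinLens):
                T = np.array([[1.0, 0.0], [-1.0 / el.f, 1.0]])
                M = T @ M
                e = T @ e + np.array([0.0, el.offset(axis) / el.f])
            else:  # pragma: no cover - validated out
                raise ValidationError(f"unexpected relay element {el!r}")
        A, B = M[0]
        C, D = M[1]
        if abs(D) < 1e-12:
            raise ValidationError("relay images the unit output to infinity; "
                                  "no finite effective misalignment exists")
        m = 1.0 / D          # transverse magnification at the conjugate plane
        w = B / D            # conjugate plane sits w (mm) before the objective
        base = M @ np.array([seq.rf_output.offset(axis), 0.0]) + e
        h_c = base[0] - w * base[1]
        u_c = base[1]
        results[axis] = (m, w, C, h_c, u_c)

    (mx, wx, Cx, h_cx, u_cx) = results["x"]
    (my, wy, Cy, h_cy, u_cy) = results["y"]
    if not (math.isclose(mx, my, rel_tol=1e-9, abs_tol=1e-12)
            and math.isclose(wx, wy, rel_tol=1e-9, abs_tol=1e-9)):
        raise ValidationError("astigmatic relay: x/y reductions disagree")

    system = OpticalSystem(
        f=objective.f, n=n,
        x_error=-h_cx, y_error=-h_cy,
        z_error=objective.f - wx,
    )
    return EffectiveModel(
        system=system,
        magnification=mx,
        kappa_offset=-Cx / mx,
        theta_offset=(u_cx, u_cy),
    )
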