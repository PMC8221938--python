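"""Synthetic calibration z-stacks of fluorescent beads.

Emulates the bead-slide calibration experiment: a thin layer of ~5 µm
fluorescent beads is imaged at a series of commanded remote foci (typically
±200 µm in 5 µm steps) while the objective is mechanically counter-displaced
by the same amount, so every plane stays in focus.  In a telecentric system
the bead images superimpose across the whole stack; misalignments reveal
themselves as depth-dependent lateral bead displacements, which is exactly
what :func:`refocal.model.apparent_position` predicts.

Because each plane is in focus by construction, beads are rendered as 2-D
Gaussian spots (no axial PSF); the calibration only measures lateral
displacements.  Noise is Poisson shot noise on the signal plus additive
Gaussian read noise, both optional.  An optional per-plane, per-bead position
jitter emulates residual localization error of a real tracking step; it is
specified as the RMS 2-D localization error in µm (per-axis sigma is that
value over sqrt(2)).

Conventions (recorded in the stack metadata): page order follows the
commanded-plane list; array axes are (plane, row, column) = (Z, Y, X);
sample coordinate (0, 0) µm maps to the image centre ``(size - 1) / 2`` px;
+x sample maps to +column, +y to +row.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile

from . import model
from .errors import PlacementError, ValidationError
from .model import Drive, OpticalSystem

__all__ = [
    "BeadField",
    "StackSpec",
    "SyntheticStack",
    "generate_bead_field",
    "render_stack",
    "save_stack",
    "load_stack",
]


@dataclass(frozen=True)
class BeadField:
    """Lateral bead positions (µm, shape (n, 2)) with per-bead brightness."""

    positions: np.ndarray
    brightness: np.ndarray
    diameter_um: float = 5.0

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, 2)
        if pos.ndim != 2 or pos.shape[1] != 2 or not np.all(np.isfinite(pos)):
            raise ValidationError("positions must be a finite (n, 2) array in um")
        bri = np.asarray(self.brightness, dtype=float).reshape(-1)
        if bri.shape[0] != pos.shape[0] or np.any(bri < 0):
            raise ValidationError("brightness must be one non-negative value per bead")
        if self.diameter_um <= 0:
            raise ValidationError("bead diameter must be > 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "brightness", bri)

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class StackSpec:
    """Acquisition recipe for a synthetic calibration stack.

    z_planes_um : commanded remote foci, µm (>= 2 planes).
    image_size_px : square image side, px.
    pixel_size_um : sample-space pixel pitch at the natural plane, µm/px.
    psf_sigma_px : Gaussian spot sigma, px.
    amplitude / background : peak signal counts per unit brightness and
        uniform background counts.
    read_noise : additive Gaussian sigma, counts (0 disables).
    shot_noise : apply Poisson noise to signal + background.
    localization_jitter_um : RMS 2-D position jitter per bead per plane, µm
        (0 disables).
    scale_spot_with_magnification : if True the spot sigma scales with the
        inverse depth-dependent magnification, emulating the apparent bead
        size change; off by default.
    seed : recorded in the output metadata and the only randomness source.
    """

    z_planes_um: tuple[float, ...]
    image_size_px: int = 384
    pixel_size_um: float = 1.0
    psf_sigma_px: float = 1.5
    amplitude: float = 1000.0
    background: float = 10.0
    read_noise: float = 2.0
    shot_noise: bool = True
    localization_jitter_um: float = 0.0
    scale_spot_with_magnification: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        z = tuple(float(v) for v in self.z_planes_um)
        if len(z) < 2 or not all(np.isfinite(z)):
            raise ValidationError("need >= 2 finite commanded z planes")
        object.__setattr__(self, "z_planes_um", z)
        if self.pixel_size_um <= 0 or self.image_size_px < 8:
            raise ValidationError("pixel size must be > 0 and image size >= 8 px")
        if self.psf_sigma_px <= 0:
            raise ValidationError("psf_sigma_px must be > 0")

    @property
    def center_px(self) -> float:
        return (self.image_size_px - 1) / 2.0


def default_z_planes(z_range_um: float = 200.0, step_um: float = 5.0) -> tuple[float, ...]:
    """The standard calibration schedule: ±z_range in step increments."""
    n = int(round(2 * z_range_um / step_um)) + 1
    return tuple(np.linspace(-z_range_um, z_range_um, n))


def generate_bead_field(n_beads: int, fov_um: float = 260.0,
                        min_separation_um: float = 20.0, seed: int = 0,
                        diameter_um: float = 5.0,
                        brightness_range: tuple[float, float] = (0.8, 1.2),
                        max_attempts: int = 10_000) -> BeadField:
    """Uniform random bead layer with a minimum pairwise separation.

    Rejection-samples positions in the square ``[-fov/2, fov/2]^2``;
    raises :class:`PlacementError` once ``max_attempts`` draws fail to
    place the next bead.  Deterministic for a fixed seed.
    """
    if n_beads < 0:
        raise ValidationError("n_beads must be >= 0")
    rng = np.random.default_rng(seed)
    positions: list[np.ndarray] = []
    attempts = 0
    half = fov_um / 2.0
    while len(positions) < n_beads:
        cand = rng.uniform(-half, half, size=2)
        if all(np.hypot(*(cand - p)) >= min_separation_um for p in positions):
            positions.append(cand)
        else:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(
                    f"placed {len(positions)}/{n_beads} beads after "
                    f"{max_attempts} rejected draws (fov={fov_um} um, "
                    f"min_separation={min_separation_um} um)")
    pos = np.array(positions).reshape(len(positions), 2)
    bri = rng.uniform(*brightness_range, size=len(positions))
    return BeadField(pos, bri, diameter_um=diameter_um)


@dataclass
class SyntheticStack:
    """Rendered stack plus everything needed to interpret it."""

    images: np.ndarray              # (planes, rows, cols), float32 counts
    spec: StackSpec
    system: OpticalSystem
    drives: list[Drive]
    compensated: bool
    true_positions_um: np.ndarray   # (planes, n_beads, 2): jittered apparent xy

    @property
    def metadata(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "system": asdict(self.system),
            "drives": [asdict(d) for d in self.drives],
            "compensated": self.compensated,
            "seed": self.spec.seed,
            "axis_order": "ZYX",
            "coordinates": "sample (0,0) um at image centre; +x -> +column, "
                           "+y -> +row; pixel indices 0-based",
        }


def _paint_spot(image: np.ndarray, row: float, col: float, sigma: float,
                amplitude: float) -> None:
    """Add one 2-D Gaussian spot, evaluated on a +-4 sigma window."""
    size = image.shape[0]
    r = int(np.ceil(4 * sigma))
    r0, r1 = int(np.floor(row)) - r, int(np.floor(row)) + r + 1
    c0, c1 = int(np.floor(col)) - r, int(np.floor(col)) + r + 1
    r0, r1 = max(r0, 0), min(r1, size)
    c0, c1 = max(c0, 0), min(c1, size)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    image[r0:r1, c0:c1] += amplitude * np.exp(
        -((rows - row) ** 2 + (cols - col) ** 2) / (2.0 * sigma ** 2))


def render_stack(field: BeadField, spec: StackSpec, system: OpticalSystem,
                 compensated: bool = False,
                 control_system: OpticalSystem | None = None) -> SyntheticStack:
    """Render the calibration stack for a bead field under a distortion field.

    Each plane uses the drive from :func:`refocal.model.drive_schedule`
    (uncompensated: naive telecentric curvature; compensated: exact inverse)
    and places every bead at its model-predicted apparent position, plus
    optional localization jitter, then applies the noise model.

    ``control_system`` is the system the *acquisition software believes in*
    when computing compensated drives and scan mappings — pass a fitted
    system to emulate re-acquisition after calibration, while ``system``
    stays the physical truth.  Defaults to ``system`` (perfect knowledge).
    """
    control = control_system if control_system is not None else system
    drives = model.drive_schedule(control, spec.z_planes_um, compensated=compensated)
    assumed = control if compensated else None
    rng = np.random.default_rng(spec.seed)
    n_planes = len(spec.z_planes_um)
    images = np.empty((n_planes, spec.image_size_px, spec.image_size_px),
                      dtype=np.float32)
    truth = np.zeros((n_planes, len(field), 2))
    jitter_axis_sigma = spec.localization_jitter_um / np.sqrt(2.0)

    for k, drive in enumerate(drives):
        frame = np.full((spec.image_size_px, spec.image_size_px),
                        spec.background, dtype=float)
        if len(field):
            apparent = model.apparent_positions(system, field.positions,
                                                drive.kappa, assumed=assumed)
            if jitter_axis_sigma > 0:
                apparent = apparent + rng.normal(
                    0.0, jitter_axis_sigma, size=apparent.shape)
            truth[k] = apparent
            sigma = spec.psf_sigma_px
            if spec.scale_spot_with_magnification:
                sigma = sigma * (drive.kappa * system.z_error + 1.0)
            for (x_um, y_um), bri in zip(apparent, field.brightness):
                col = spec.center_px + x_um / spec.pixel_size_um
                row = spec.center_px + y_um / spec.pixel_size_um
                _paint_spot(frame, row, col, sigma, spec.amplitude * bri)
        if spec.shot_noise:
            frame = rng.poisson(np.clip(frame, 0, None)).astype(float)
        if spec.read_noise > 0:
            frame = frame + rng.normal(0.0, spec.read_noise, size=frame.shape)
        images[k] = frame.astype(np.float32)

    return SyntheticStack(images=images, spec=spec, system=system,
                          drives=drives, compensated=compensated,
                          true_positions_um=truth)


def save_stack(stack: SyntheticStack, tiff_path: str | Path) -> Path:
    """Write a multi-page TIFF plus a JSON sidecar with the full metadata."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.images, photometric="minisblack")
    sidecar = tiff_path.with_suffix(tiff_path.suffix + ".json")
    sidecar.write_text(json.dumps(stack.metadata, indent=2))
    return sidecar


def load_stack(tiff_path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a stack TIFF and its JSON sidecar; returns (images, metadata)."""
    tiff_path = Path(tiff_path)
    images = tifffile.imread(tiff_path)
    sidecar = tiff_path.with_suffix(tiff_path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return np.asarray(images), meta
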