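"""Bead detection and trajectory linking for calibration z-stacks.

Plays the role a generic particle tracker (e.g. TrackMate) plays in the
bead-slide calibration: detect sub-pixel bead centroids in every plane of a
calibration stack, then link them across planes into per-bead trajectories.
Calibration stacks are sparse and bead drift between adjacent planes is
smooth, so linking is greedy nearest-neighbour with a distance gate and
optional gap closing; a brute-force assignment oracle in the test suite
pins its correctness on well-separated fields.

Detection is difference-of-Gaussians band-pass filtering followed by local
maxima and sub-pixel refinement (intensity-weighted centroid by default, or
a 2-D Gaussian fit).  A candidate peak must exceed both a relative threshold
(fraction of the brightest band-passed peak) and a 5x robust-noise floor, so
a noise-only frame yields no detections.

Pixel-to-micrometre conversion uses the natural-plane (kappa = 0) image
frame: the scan-angle-to-image mapping is calibrated at the natural focus,
so one uniform pixel pitch applies to every plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

from .errors import AmbiguityWarning, ValidationError

__all__ = [
    "Detection",
    "Trajectory",
    "detect_beads",
    "link_trajectories",
    "track_stack",
    "trajectories_to_dataframe",
    "trajectories_from_dataframe",
]


@dataclass(frozen=True)
class Detection:
    """One sub-pixel bead detection in one plane (pixel coordinates)."""

    plane_index: int
    row: float
    col: float
    intensity: float
    residual: float = 0.0


@dataclass
class Trajectory:
    """Per-bead apparent position across the commanded planes of a stack.

    ``points`` rows are (plane_index, z_cmd_um, x_um, y_um); ``gap_flags``
    marks points that follow one or more skipped (gap-closed) planes.
    """

    bead_id: int
    plane_indices: np.ndarray
    z_cmd_um: np.ndarray
    xy_um: np.ndarray
    gap_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.plane_indices = np.asarray(self.plane_indices, dtype=int)
        self.z_cmd_um = np.asarray(self.z_cmd_um, dtype=float)
        self.xy_um = np.asarray(self.xy_um, dtype=float).reshape(-1, 2)
        if self.gap_flags is None:
            self.gap_flags = np.zeros(len(self.plane_indices), dtype=bool)
        self.gap_flags = np.asarray(self.gap_flags, dtype=bool)
        if np.any(np.diff(self.plane_indices) <= 0):
            raise ValidationError("plane indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.plane_indices)

    def position_at_plane(self, plane_index: int) -> np.ndarray | None:
        hit = np.nonzero(self.plane_indices == plane_index)[0]
        return self.xy_um[hit[0]] if hit.size else None


def _gaussian_refine(window: np.ndarray, row0: float, col0: float,
                     sigma0: float) -> tuple[float, float, float]:
    """2-D Gaussian fit in a window; returns (row, col, rms residual)."""
    rows, cols = np.indices(window.shape)
    flat = window.ravel()

    def resid(p):
        amp, r, c, sig, bg = p
        m = bg + amp * np.exp(-((rows - r) ** 2 + (cols - c) ** 2) / (2 * sig ** 2))
        return m.ravel() - flat

    p0 = [window.max() - np.median(window), row0, col0, sigma0, np.median(window)]
    sol = optimize.least_squares(resid, p0, max_nfev=200)
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return float(sol.x[1]), float(sol.x[2]), rms


def detect_beads(image: np.ndarray, min_sigma: float = 1.0,
                 max_sigma: float = 3.0, threshold: float = 0.3,
                 refine: str = "centroid",
                 plane_index: int = 0) -> list[Detection]:
    """Detect bead spots in one frame; returns detections sorted by
    decreasing intensity.

    Parameters
    ----------
    threshold : float
        Relative threshold in (0, 1]: fraction of the brightest band-passed
        peak a candidate must reach (a 5x robust-noise floor applies on top).
    refine : {"centroid", "gaussian"}
        Sub-pixel refinement: intensity-weighted centroid in a window, or a
        2-D Gaussian least-squares fit (slower, reports fit residual).
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValidationError("image must be finite")
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    if refine not in ("centroid", "gaussian"):
        raise ValidationError(f"unknown refinement {refine!r}")

    bandpass = (ndimage.gaussian_filter(image, min_sigma)
                - ndimage.gaussian_filter(image, max_sigma))
    noise = 1.4826 * np.median(np.abs(bandpass - np.median(bandpass)))
    floor = max(threshold * bandpass.max(), 5.0 * noise)
    peaks = peak_local_max(bandpass, min_distance=max(1, int(np.ceil(2 * min_sigma))),
                           threshold_abs=floor, exclude_border=False)

    background = float(np.median(image))
    win = max(2, int(np.ceil(3.0 * max_sigma)))
    size = image.shape
    detections: list[Detection] = []
    for r0, c0 in peaks:
        rlo, rhi = max(r0 - win, 0), min(r0 + win + 1, size[0])
        clo, chi = max(c0 - win, 0), min(c0 + win + 1, size[1])
        window = image[rlo:rhi, clo:chi] - background
        intensity = float(np.clip(window, 0, None).sum())
        if refine == "gaussian":
            row, col, rms = _gaussian_refine(image[rlo:rhi, clo:chi],
                                             r0 - rlo, c0 - clo, min_sigma)
            row, col = row + rlo, col + clo
        else:
            # iterative Gaussian-weighted centroid: weighting by a kernel
            # matched to the spot suppresses background-noise lever arms of
            # distant pixels; re-centering the kernel removes its shrinkage
            # bias at the fixed point
            row, col = float(r0), float(c0)
            sigma_w = 1.5 * min_sigma
            ok = True
            for _ in range(6):
                rows, cols = np.indices(window.shape)
                wgt = np.exp(-(((rows + rlo) - row) ** 2
                               + ((cols + clo) - col) ** 2) / (2 * sigma_w ** 2))
                w = np.clip(window, 0, None) * wgt
                total = w.sum()
                if total <= 0:
                    ok = False
                    break
                row = float((w * rows).sum() / total) + rlo
                col = float((w * cols).sum() / total) + clo
            if not ok:
                continue
            rms = 0.0
        if not (0 <= row < size[0] and 0 <= col < size[1]):
            continue
        detections.append(Detection(plane_index, row, col, intensity, rms))
    detections.sort(key=lambda d: -d.intensity)
    return detections


def link_trajectories(detections_per_plane: list[list[Detection]],
                      gate_radius: float = 10.0, max_gap: int = 1,
                      z_cmd_um: list[float] | None = None,
                      pixel_size_um: float = 1.0,
                      center_px: float | tuple[float, float] | None = None,
                      min_length: int = 2) -> list[Trajectory]:
    """Greedy nearest-neighbour linking of per-plane detections.

    Candidate (track, detection) pairs within ``gate_radius`` px are linked
    in order of increasing distance (ties broken by lower detection index,
    with an :class:`AmbiguityWarning`); unmatched detections start new
    tracks; a track missing from up to ``max_gap`` consecutive planes may
    still be extended, the resuming point being gap-flagged.

    Positions are converted to µm about ``center_px`` (image centre by
    default) using ``pixel_size_um``; tracks shorter than ``min_length``
    are dropped.
    """
    n_planes = len(detections_per_plane)
    if z_cmd_um is not None and len(z_cmd_um) != n_planes:
        raise ValidationError("z_cmd_um must have one entry per plane")

    # active track state: list of dicts with last (row, col), last plane, points
    tracks: list[dict] = []
    for k, dets in enumerate(detections_per_plane):
        candidates = []
        active = [t for t in tracks if k - t["last_plane"] <= max_gap + 1]
        for ti, t in enumerate(active):
            for di, d in enumerate(dets):
                dist = float(np.hypot(d.row - t["last_pos"][0],
                                      d.col - t["last_pos"][1]))
                if dist <= gate_radius:
                    candidates.append((dist, di, ti))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        for a, b in zip(candidates, candidates[1:]):
            if abs(a[0] - b[0]) < 1e-9 and (a[1] == b[1] or a[2] == b[2]):
                warnings.warn(
                    f"plane {k}: tie within tolerance at distance {a[0]:.6g} px; "
                    "broken by smaller distance then lower detection index",
                    AmbiguityWarning, stacklevel=2)
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, di, ti in candidates:
            if ti in used_tracks or di in used_dets:
                continue
            t = active[ti]
            d = dets[di]
            t["points"].append((k, d.row, d.col, k - t["last_plane"] > 1))
            t["last_pos"] = (d.row, d.col)
            t["last_plane"] = k
            used_tracks.add(ti)
            used_dets.add(di)
        for di, d in enumerate(dets):
            if di not in used_dets:
                tracks.append({"points": [(k, d.row, d.col, False)],
                               "last_pos": (d.row, d.col), "last_plane": k})

    if center_px is None:
        center = (0.0, 0.0)
    elif np.isscalar(center_px):
        center = (float(center_px), float(center_px))
    else:
        center = (float(center_px[0]), float(center_px[1]))

    out: list[Trajectory] = []
    for t in tracks:
        if len(t["points"]) < min_length:
            continue
        planes = [p[0] for p in t["points"]]
        xy = np.array([[(p[2] - center[1]) * pixel_size_um,
                        (p[1] - center[0]) * pixel_size_um] for p in t["points"]])
        gaps = np.array([p[3] for p in t["points"]], dtype=bool)
        z = (np.array([z_cmd_um[p] for p in planes], dtype=float)
             if z_cmd_um is not None else np.full(len(planes), np.nan))
        out.append(Trajectory(len(out), np.array(planes), z, xy, gaps))
    return out


def track_stack(images: np.ndarray, z_cmd_um: list[float],
                pixel_size_um: float = 1.0,
                center_px: float | None = None,
                min_sigma: float = 1.0, max_sigma: float = 3.0,
                threshold: float = 0.3, refine: str = "centroid",
                gate_radius_px: float = 10.0, max_gap: int = 1,
                min_length: int = 2) -> list[Trajectory]:
    """Detect-and-link convenience over a whole (planes, rows, cols) stack."""
    images = np.asarray(images)
    if images.ndim != 3 or images.shape[0] != len(z_cmd_um):
        raise ValidationError("images must be (n_planes, rows, cols) matching z_cmd_um")
    if center_px is None:
        center_px = (images.shape[1] - 1) / 2.0
    per_plane = [detect_beads(images[k], min_sigma, max_sigma, threshold,
                              refine, plane_index=k)
                 for k in range(images.shape[0])]
    return link_trajectories(per_plane, gate_radius=gate_radius_px,
                             max_gap=max_gap, z_cmd_um=list(z_cmd_um),
                             pixel_size_um=pixel_size_um, center_px=center_px,
                             min_length=min_length)


def trajectories_to_dataframe(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Long-format table: bead_id, plane_index, z_cmd_um, x_app_um,
    y_app_um, gap_flag."""
    rows = []
    for t in trajectories:
        for i in range(len(t)):
            rows.append({
                "bead_id": t.bead_id,
                "plane_index": int(t.plane_indices[i]),
                "z_cmd_um": float(t.z_cmd_um[i]),
                "x_app_um": float(t.xy_um[i, 0]),
                "y_app_um": float(t.xy_um[i, 1]),
                "gap_flag": bool(t.gap_flags[i]),
            })
    return pd.DataFrame(rows, columns=["bead_id", "plane_index", "z_cmd_um",
                                       "x_app_um", "y_app_um", "gap_flag"])


def trajectories_from_dataframe(df: pd.DataFrame) -> list[Trajectory]:
    """Inverse of :func:`trajectories_to_dataframe`."""
    out = []
    for bead_id, grp in df.groupby("bead_id", sort=True):
        grp = grp.sort_values("plane_index")
        out.append(Trajectory(
            int(bead_id),
            grp["plane_index"].to_numpy(),
            grp["z_cmd_um"].to_numpy(),
            grp[["x_app_um", "y_app_um"]].to_numpy(),
            grp["gap_flag"].to_numpy() if "gap_flag" in grp else None,
        ))
    return out
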