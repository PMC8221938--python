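"""Estimate remote-focus misalignments from tracked bead trajectories.

The calibration inverts the apparent-position observation model: a bead at
natural-plane position ``(x_b, y_b)`` imaged with curvature ``kappa`` appears
at

    x_app = x_b (kappa Z_ERROR + 1) + f kappa X_ERROR        (y analogous),

so across the planes of a calibration stack each bead traces a line whose
slope against ``kappa`` mixes a magnification term (``x_b Z_ERROR``, common
scaling of the field) and a skew term (``f X_ERROR``, uniform drift).  The
objective focal length ``f`` and immersion index ``n`` are treated as known
system configuration; the bead natural-plane positions are nuisance
parameters eliminated by reading them off the ``kappa = 0`` (natural-plane)
reference image, mirroring the reference-image protocol of the bead-slide
experiment.

The fit is two-stage: a closed-form initialization (per-plane linear
regression of apparent vs reference position, then regressing the per-plane
slopes and intercepts on ``kappa``), followed by a joint least-squares
refinement over every observation with standard errors from the Jacobian.
Trajectories whose residual RMS exceeds 5x the median are excluded once and
the model refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from . import model
from .errors import DegenerateDesignError, NonConvergenceError, ValidationError
from .model import Drive, OpticalSystem
from .tracking import Trajectory

__all__ = ["DistortionFit", "fit_misalignment", "verify_compensation"]

_UM_PER_MM = 1e3


@dataclass
class DistortionFit:
    """Estimated misalignments (mm) with uncertainty and diagnostics."""

    x_error: float
    y_error: float
    z_error: float
    stderr: dict[str, float]
    f: float
    n: float
    nf2: float | None = None            # fitted only in the extended mode
    residual_rms_um: float = np.nan
    per_plane_rms_um: dict[int, float] = field(default_factory=dict)
    converged: bool = True
    n_obs: int = 0
    excluded_beads: list[int] = field(default_factory=list)
    init_estimates: tuple[float, float, float] = (np.nan, np.nan, np.nan)

    @property
    def system(self) -> OpticalSystem:
        """The fitted misalignments as an optical system (for
        precompensation or re-simulation)."""
        return OpticalSystem(f=self.f, n=self.n, x_error=self.x_error,
                             y_error=self.y_error, z_error=self.z_error)

    def as_dict(self) -> dict:
        return {
            "x_error_mm": self.x_error,
            "y_error_mm": self.y_error,
            "z_error_mm": self.z_error,
            "stderr_mm": self.stderr,
            "f_mm": self.f,
            "n": self.n,
            "nf2_mm2": self.nf2,
            "residual_rms_um": self.residual_rms_um,
            "per_plane_rms_um": {str(k): v for k, v in self.per_plane_rms_um.items()},
            "converged": self.converged,
            "n_obs": self.n_obs,
            "excluded_beads": self.excluded_beads,
            "init_estimates_mm": list(self.init_estimates),
        }


def _kappas_from_drives(drives: Sequence[Drive] | Sequence[float] | np.ndarray) -> np.ndarray:
    kappas = np.array([d.kappa if isinstance(d, Drive) else float(d)
                       for d in drives])
    if not np.all(np.isfinite(kappas)):
        raise ValidationError("per-plane curvatures must be finite")
    return kappas


def _collect_observations(trajectories: Sequence[Trajectory],
                          kappas: np.ndarray):
    """Flatten trajectories into (bead, plane, kappa, ref_xy, obs_xy) arrays.

    The reference position of each bead is its detection in the plane of
    smallest |kappa| it appears in (the natural plane when present).
    """
    ref_order = np.argsort(np.abs(kappas), kind="stable")
    rank = np.empty_like(ref_order)
    rank[ref_order] = np.arange(len(kappas))

    bead_ids, plane_idx, obs = [], [], []
    refs = []
    for t in trajectories:
        if len(t) < 2:
            continue
        valid = t.plane_indices < len(kappas)
        if not np.all(valid):
            raise ValidationError("trajectory references a plane without a drive")
        best = np.argmin(rank[t.plane_indices])
        refs.append(t.xy_um[best])
        for i in range(len(t)):
            bead_ids.append(len(refs) - 1)
            plane_idx.append(int(t.plane_indices[i]))
            obs.append(t.xy_um[i])
    if not refs:
        raise DegenerateDesignError("no usable trajectories (need length >= 2)")
    return (np.array(bead_ids), np.array(plane_idx), np.array(obs),
            np.array(refs))


def _initialize(plane_idx: np.ndarray, kappas: np.ndarray, ref: np.ndarray,
                obs: np.ndarray, f: float) -> tuple[float, float, float]:
    """Closed-form start: per-plane regressions, then regress slope-1 and
    intercept on kappa."""
    slopes, intercepts, ks = [], [], []
    for k in np.unique(plane_idx):
        sel = plane_idx == k
        if sel.sum() < 2:
            continue
        for axis in (0, 1):
            x = ref[sel, axis]
            y = obs[sel, axis]
            if np.ptp(x) < 1e-9:
                continue
            a, b = np.polyfit(x, y, 1)
            slopes.append((kappas[k], a))
            intercepts.append((axis, kappas[k], b))
        ks.append(kappas[k])
    if not slopes:
        # single-bead stacks: no per-plane regression; start from zero
        return 0.0, 0.0, 0.0
    sk = np.array([s[0] for s in slopes])
    sa = np.array([s[1] for s in slopes])
    z0 = float(sk @ (sa - 1.0) / (sk @ sk)) if sk @ sk > 0 else 0.0
    lat = [0.0, 0.0]
    for axis in (0, 1):
        pts = [(k, b) for a, k, b in intercepts if a == axis]
        if pts:
            kk = np.array([p[0] for p in pts]) * f * _UM_PER_MM
            bb = np.array([p[1] for p in pts])
            if kk @ kk > 0:
                lat[axis] = float(kk @ bb / (kk @ kk))
    return lat[0], lat[1], z0


def fit_misalignment(trajectories: Sequence[Trajectory],
                     drives: Sequence[Drive] | Sequence[float],
                     system_prior: OpticalSystem,
                     loss: str = "linear",
                     f_scale: float = 1.0,
                     exclude_outliers: bool = True,
                     max_nfev: int = 200) -> DistortionFit:
    """Fit (X_ERROR, Y_ERROR, Z_ERROR) to tracked bead trajectories.

    Parameters
    ----------
    trajectories : tracked bead trajectories (µm, natural-plane frame).
    drives : per-plane drives (or curvatures, 1/mm), indexed by plane.
    system_prior : supplies the known ``f`` and ``n``; its misalignment
        fields are ignored.
    loss : "linear" (default) or any robust loss accepted by
        :func:`scipy.optimize.least_squares` (e.g. "soft_l1").

    Raises
    ------
    DegenerateDesignError
        If fewer than two distinct curvatures, no usable trajectories, or
        all bead reference positions coincide.
    """
    kappas = _kappas_from_drives(drives)
    if np.ptp(kappas) < 1e-15:
        raise DegenerateDesignError("all planes share one curvature; "
                                    "misalignments are not identifiable")
    bead_ids, plane_idx, obs, refs = _collect_observations(trajectories, kappas)
    if len(refs) >= 2 and np.ptp(refs, axis=0).max() < 1e-9:
        raise DegenerateDesignError("all beads coincide; Z_ERROR is not "
                                    "identifiable")

    f, n = system_prior.f, system_prior.n
    kap = kappas[plane_idx]
    ref_b = refs[bead_ids]

    def residuals(p: np.ndarray) -> np.ndarray:
        X, Y, Z = p
        scale = kap * Z + 1.0
        rx = obs[:, 0] - (ref_b[:, 0] * scale + f * kap * X * _UM_PER_MM)
        ry = obs[:, 1] - (ref_b[:, 1] * scale + f * kap * Y * _UM_PER_MM)
        return np.concatenate([rx, ry])

    def jacobian(p: np.ndarray) -> np.ndarray:
        m = len(kap)
        J = np.zeros((2 * m, 3))
        J[:m, 0] = -f * kap * _UM_PER_MM
        J[m:, 1] = -f * kap * _UM_PER_MM
        J[:m, 2] = -ref_b[:, 0] * kap
        J[m:, 2] = -ref_b[:, 1] * kap
        return J

    p0 = np.array(_initialize(plane_idx, kappas, ref_b, obs, f))
    init = tuple(float(v) for v in p0)

    def solve(mask: np.ndarray):
        sol = optimize.least_squares(
            lambda p: residuals(p)[np.tile(mask, 2)], p0,
            jac=(lambda p: jacobian(p)[np.tile(mask, 2)]) if loss == "linear" else "2-point",
            loss=loss, f_scale=f_scale, max_nfev=max_nfev)
        return sol

    mask = np.ones(len(kap), dtype=bool)
    sol = solve(mask)
    excluded: list[int] = []
    if exclude_outliers and len(np.unique(bead_ids)) > 2:
        r = residuals(sol.x).reshape(2, -1)
        per_bead = np.array([np.sqrt(np.mean(r[:, bead_ids == b] ** 2))
                             for b in np.unique(bead_ids)])
        med = np.median(per_bead)
        bad = np.unique(bead_ids)[per_bead > 5 * med] if med > 0 else []
        if len(bad):
            excluded = [int(b) for b in bad]
            mask = ~np.isin(bead_ids, bad)
            sol = solve(mask)

    if not sol.success or not np.all(np.isfinite(sol.x)):
        fit_x = p0 if not np.all(np.isfinite(sol.x)) else sol.x
        converged = False
        x_err, y_err, z_err = (float(v) for v in fit_x)
        stderr = {"x_error": np.nan, "y_error": np.nan, "z_error": np.nan}
        res = residuals(np.array([x_err, y_err, z_err]))[np.tile(mask, 2)]
    else:
        converged = True
        x_err, y_err, z_err = (float(v) for v in sol.x)
        res = sol.fun
        dof = max(res.size - 3, 1)
        sigma2 = float(res @ res) / dof
        J = jacobian(sol.x)[np.tile(mask, 2)]
        try:
            cov = sigma2 * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(3, np.nan)
        stderr = {"x_error": float(se[0]), "y_error": float(se[1]),
                  "z_error": float(se[2])}

    rms = float(np.sqrt(np.mean(res ** 2))) if res.size else np.nan
    per_plane: dict[int, float] = {}
    r_full = residuals(np.array([x_err, y_err, z_err])).reshape(2, -1)
    for k in np.unique(plane_idx):
        sel = (plane_idx == k) & mask
        if sel.any():
            per_plane[int(k)] = float(np.sqrt(np.mean(r_full[:, sel] ** 2)))

    return DistortionFit(
        x_error=x_err, y_error=y_err, z_error=z_err, stderr=stderr,
        f=f, n=n, residual_rms_um=rms, per_plane_rms_um=per_plane,
        converged=converged, n_obs=int(2 * mask.sum()),
        excluded_beads=excluded, init_estimates=init)


def verify_compensation(trajectories: Sequence[Trajectory],
                        system: OpticalSystem | None = None,
                        drives: Sequence[Drive] | None = None) -> dict:
    """Quality report for a (precompensated) calibration stack.

    For every tracked bead, measures its displacement from its position in
    the natural-plane reference (the plane with z_cmd closest to 0), and the
    skew angle of the most central bead's trajectory (arctan of the fitted
    x-vs-z and y-vs-z slopes).  If the fitted ``system`` and per-plane
    ``drives`` are supplied, also reports the uniformity of the realised
    z-plane spacing predicted by the model.

    Returns a JSON-serialisable dict with keys ``max_displacement_um``,
    ``mean_max_displacement_um``, ``std_max_displacement_um``,
    ``skew_x_deg``, ``skew_y_deg``, ``z_spacing_cv`` and per-bead details.
    """
    per_bead_max: list[float] = []
    details = []
    central = None
    central_dist = np.inf
    for t in trajectories:
        if len(t) < 2:
            continue
        ref_i = int(np.argmin(np.abs(t.z_cmd_um)))
        disp = np.hypot(*(t.xy_um - t.xy_um[ref_i]).T)
        per_bead_max.append(float(disp.max()))
        details.append({"bead_id": int(t.bead_id),
                        "max_displacement_um": float(disp.max())})
        r = float(np.hypot(*t.xy_um[ref_i]))
        if r < central_dist:
            central_dist, central = r, t

    skew_x = skew_y = np.nan
    if central is not None and np.ptp(central.z_cmd_um) > 0:
        sx = np.polyfit(central.z_cmd_um, central.xy_um[:, 0], 1)[0]
        sy = np.polyfit(central.z_cmd_um, central.xy_um[:, 1], 1)[0]
        skew_x = float(np.degrees(np.arctan(sx)))
        skew_y = float(np.degrees(np.arctan(sy)))

    z_cv = np.nan
    if system is not None and drives is not None and len(drives) >= 3:
        z_rf = np.array([model.remote_focus(system, d).z_rf for d in drives])
        spacing = np.diff(np.sort(z_rf))
        if spacing.mean() != 0:
            z_cv = float(spacing.std() / abs(spacing.mean()))

    return {
        "n_beads": len(per_bead_max),
        "max_displacement_um": float(np.max(per_bead_max)) if per_bead_max else np.nan,
        "mean_max_displacement_um": float(np.mean(per_bead_max)) if per_bead_max else np.nan,
        "std_max_displacement_um": float(np.std(per_bead_max)) if per_bead_max else np.nan,
        "skew_x_deg": skew_x,
        "skew_y_deg": skew_y,
        "z_spacing_cv": z_cv,
        "per_bead": details,
    }
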