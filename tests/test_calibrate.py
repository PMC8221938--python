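"""Misalignment fitting and compensation verification."""

import numpy as np
import pytest

from conftest import synthetic_trajectories
from refocal.calibrate import fit_misalignment, verify_compensation
from refocal.errors import DegenerateDesignError
from refocal.model import OpticalSystem, skew_angle
from refocal.simulate import default_z_planes

Z81 = np.array(default_z_planes(200.0, 5.0))


def kappas_for(system, z_um=Z81):
    return -np.asarray(z_um) / 1e3 / system.nf2


def bead_grid(n_side=5, half=130.0):
    g = np.linspace(-half, half, n_side)
    return np.array([[x, y] for x in g for y in g])


class TestFitMisalignment:
    def test_noiseless_recovery_to_1e6_relative(self, aol_system):
        kappas = kappas_for(aol_system)
        trajs = synthetic_trajectories(aol_system, kappas, bead_grid())
        fit = fit_misalignment(trajs, kappas, OpticalSystem(f=12.5, n=1.33))
        assert fit.converged
        assert fit.x_error == pytest.approx(2.3, rel=1e-6)
        assert fit.y_error == pytest.approx(1.3, rel=1e-6)
        assert fit.z_error == pytest.approx(-69.0, rel=1e-6)
        assert fit.residual_rms_um < 1e-9

    def test_noisy_recovery_within_bounds_over_20_seeds(self, aol_system):
        kappas = kappas_for(aol_system)
        beads = bead_grid()
        dx, dy, dz = [], [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            trajs = synthetic_trajectories(aol_system, kappas, beads,
                                           noise_um=0.1, rng=rng)
            fit = fit_misalignment(trajs, kappas,
                                   OpticalSystem(f=12.5, n=1.33))
            dx.append(fit.x_error - 2.3)
            dy.append(fit.y_error - 1.3)
            dz.append(fit.z_error + 69.0)
        assert np.max(np.abs(dx)) <= 0.05
        assert np.max(np.abs(dy)) <= 0.05
        assert np.max(np.abs(dz)) <= 2.0

    def test_bias_below_standard_error_across_replicates(self, aol_system):
        """Parameter recovery is unbiased at the stated noise level."""
        kappas = kappas_for(aol_system)
        beads = bead_grid()
        errs, ses = [], []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            trajs = synthetic_trajectories(aol_system, kappas, beads,
                                           noise_um=0.1, rng=rng)
            fit = fit_misalignment(trajs, kappas,
                                   OpticalSystem(f=12.5, n=1.33))
            errs.append([fit.x_error - 2.3, fit.y_error - 1.3,
                         fit.z_error + 69.0])
            ses.append([fit.stderr["x_error"], fit.stderr["y_error"],
                        fit.stderr["z_error"]])
        bias = np.abs(np.mean(errs, axis=0))
        se = np.mean(ses, axis=0)
        assert np.all(bias <= se)

    def test_undistorted_system_fits_to_zero(self):
        clean = OpticalSystem(f=12.5, n=1.33)
        kappas = kappas_for(clean)
        rng = np.random.default_rng(1)
        trajs = synthetic_trajectories(clean, kappas, bead_grid(),
                                       noise_um=0.1, rng=rng)
        fit = fit_misalignment(trajs, kappas, clean)
        assert abs(fit.x_error) < 3 * max(fit.stderr["x_error"], 1e-3)
        assert abs(fit.y_error) < 3 * max(fit.stderr["y_error"], 1e-3)
        assert abs(fit.z_error) < 3 * max(fit.stderr["z_error"], 0.1)

    def test_refinement_never_degrades_initialization(self, aol_system):
        kappas = kappas_for(aol_system)

        def rms_at(params, trajs):
            X, Y, Z = params
            probe = OpticalSystem(f=12.5, n=1.33, x_error=X, y_error=Y,
                                  z_error=Z)
            resid = []
            for t, tt in zip(trajs, synthetic_trajectories(probe, kappas,
                                                           ref_positions(trajs, kappas))):
                resid.append(t.xy_um - tt.xy_um)
            return float(np.sqrt(np.mean(np.square(np.concatenate(resid)))))

        def ref_positions(trajs, kappas):
            k0 = int(np.argmin(np.abs(kappas)))
            return np.array([t.xy_um[k0] for t in trajs])

        for seed in (0, 5, 9):
            rng = np.random.default_rng(seed)
            trajs = synthetic_trajectories(aol_system, kappas, bead_grid(),
                                           noise_um=0.3, rng=rng)
            fit = fit_misalignment(trajs, kappas,
                                   OpticalSystem(f=12.5, n=1.33))
            assert rms_at((fit.x_error, fit.y_error, fit.z_error), trajs) <= \
                rms_at(fit.init_estimates, trajs) + 1e-12

    def test_self_consistency_refit_of_fitted_system(self, aol_system):
        """Rendering trajectories from the fitted system and re-fitting
        reproduces the estimates (noiseless)."""
        kappas = kappas_for(aol_system)
        rng = np.random.default_rng(2)
        trajs = synthetic_trajectories(aol_system, kappas, bead_grid(),
                                       noise_um=0.1, rng=rng)
        fit1 = fit_misalignment(trajs, kappas, OpticalSystem(f=12.5, n=1.33))
        trajs2 = synthetic_trajectories(fit1.system, kappas, bead_grid())
        fit2 = fit_misalignment(trajs2, kappas, OpticalSystem(f=12.5, n=1.33))
        assert fit2.x_error == pytest.approx(fit1.x_error, rel=1e-3)
        assert fit2.y_error == pytest.approx(fit1.y_error, rel=1e-3)
        assert fit2.z_error == pytest.approx(fit1.z_error, rel=1e-3)

    def test_outlier_trajectory_excluded_once(self, aol_system):
        kappas = kappas_for(aol_system)
        rng = np.random.default_rng(4)
        trajs = synthetic_trajectories(aol_system, kappas, bead_grid(),
                                       noise_um=0.05, rng=rng)
        # corrupt one bead with a large drift unrelated to the model
        trajs[7].xy_um = trajs[7].xy_um + np.linspace(0, 40, len(Z81))[:, None]
        fit = fit_misalignment(trajs, kappas, OpticalSystem(f=12.5, n=1.33))
        assert fit.excluded_beads == [7]
        assert fit.x_error == pytest.approx(2.3, abs=0.05)
        assert fit.z_error == pytest.approx(-69.0, abs=1.0)

    def test_degenerate_designs_raise(self, aol_system):
        trajs = synthetic_trajectories(aol_system, kappas_for(aol_system),
                                       bead_grid())
        with pytest.raises(DegenerateDesignError):
            fit_misalignment(trajs, np.zeros(len(Z81)),
                             OpticalSystem(f=12.5, n=1.33))
        coincident = synthetic_trajectories(
            aol_system, kappas_for(aol_system),
            np.array([[10.0, 10.0], [10.0, 10.0]]))
        with pytest.raises(DegenerateDesignError):
            fit_misalignment(coincident, kappas_for(aol_system),
                             OpticalSystem(f=12.5, n=1.33))
        with pytest.raises(DegenerateDesignError):
            fit_misalignment([], kappas_for(aol_system),
                             OpticalSystem(f=12.5, n=1.33))


class TestVerifyCompensation:
    def test_perfectly_compensated_stack_reports_zero(self):
        # a distortion-free system leaves every bead at its reference
        # position over the whole schedule
        clean = OpticalSystem(f=12.5, n=1.33)
        beads = bead_grid(3, 100.0)
        trajs = synthetic_trajectories(clean, kappas_for(clean), beads)
        report = verify_compensation(trajs)
        assert report["max_displacement_um"] == pytest.approx(0.0, abs=1e-12)
        assert report["skew_x_deg"] == pytest.approx(0.0, abs=1e-12)

    def test_uncompensated_skew_matches_closed_form(self):
        """A -5.9 mm lateral (y) misalignment produces a 19.5 degree yz
        skew of the central bead trajectory."""
        sys_ = OpticalSystem(f=12.5, n=1.33, y_error=-5.9)
        kappas = kappas_for(sys_)
        beads = np.array([[0.0, 0.0], [80.0, 50.0], [-60.0, -90.0]])
        trajs = synthetic_trajectories(sys_, kappas, beads)
        report = verify_compensation(trajs)
        assert abs(report["skew_y_deg"]) == pytest.approx(19.54, abs=0.2)
        assert abs(report["skew_y_deg"]) == pytest.approx(
            abs(skew_angle(sys_, "y")), abs=0.2)

    def test_noisy_compensated_displacement_below_half_micron(self):
        # residual displacement of a well-compensated stack is set by the
        # 0.1 um localization noise alone
        clean = OpticalSystem(f=12.5, n=1.33)
        rng = np.random.default_rng(11)
        trajs = synthetic_trajectories(clean, kappas_for(clean), bead_grid(),
                                       noise_um=0.1, rng=rng)
        report = verify_compensation(trajs)
        assert report["max_displacement_um"] < 0.5

    def test_z_spacing_uniformity_flags_uncompensated_schedule(self, aol_system):
        from refocal.model import drive_schedule
        trajs = synthetic_trajectories(aol_system, kappas_for(aol_system),
                                       bead_grid(3, 100.0))
        uncomp = drive_schedule(aol_system, Z81, compensated=False)
        comp = drive_schedule(aol_system, Z81, compensated=True)
        r_un = verify_compensation(trajs, system=aol_system, drives=uncomp)
        r_co = verify_compensation(trajs, system=aol_system, drives=comp)
        assert r_co["z_spacing_cv"] < 1e-12
        assert r_un["z_spacing_cv"] > 1e-3
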