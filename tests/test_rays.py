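"""ABCD ray oracle: agreement with the closed forms and relay reduction."""

import numpy as np
import pytest

from refocal.errors import NoFocusError, ValidationError
from refocal.model import Drive, OpticalSystem, remote_focus
from refocal.rays import (ElementSequence, FreeSpace, Interface, RfOutput,
                          ThinLens, effective_misalignment,
                          sequence_for_system, trace_fan, trace_to_focus)


def random_system(rng) -> OpticalSystem:
    return OpticalSystem(
        f=rng.uniform(2.0, 25.0), n=rng.uniform(1.0, 1.6),
        x_error=rng.uniform(-6.0, 6.0), y_error=rng.uniform(-6.0, 6.0),
        z_error=rng.uniform(-80.0, 80.0))


def random_drive(rng, system) -> Drive:
    while True:
        kappa = rng.uniform(-0.008, 0.008)
        if abs(kappa * system.z_error + 1) > 0.05:
            return Drive(kappa, rng.uniform(-0.04, 0.04), rng.uniform(-0.04, 0.04))


def assert_same_focus(a, b, rel=1e-9, abs_=1e-6):
    assert a.x_rf == pytest.approx(b.x_rf, rel=rel, abs=abs_)
    assert a.y_rf == pytest.approx(b.y_rf, rel=rel, abs=abs_)
    assert a.z_rf == pytest.approx(b.z_rf, rel=rel, abs=abs_)


class TestTraceToFocus:
    def test_aligned_planar_input_focuses_on_axis_at_natural_plane(self):
        seq = sequence_for_system(OpticalSystem(f=10.0, n=1.33))
        fp = trace_to_focus(seq, Drive(0.0))
        assert fp.x_rf == pytest.approx(0.0, abs=1e-12)
        assert fp.z_rf == pytest.approx(0.0, abs=1e-9)

    def test_etl_worked_example_matches_closed_form(self, etl_system):
        drive = Drive(kappa=-0.0119981, theta_x=0.036)
        assert_same_focus(trace_to_focus(sequence_for_system(etl_system), drive),
                          remote_focus(etl_system, drive))

    def test_all_ray_pairs_intersect_at_one_point(self, aol_system):
        fan = trace_fan(sequence_for_system(aol_system),
                        Drive(-0.003, theta_x=0.02), "x", fan_size=7)
        # pairwise intersection points of a paraxial fan coincide
        zs, xs = [], []
        for i in range(len(fan)):
            for j in range(i + 1, len(fan)):
                (h1, u1), (h2, u2) = fan[i], fan[j]
                z = (h2 - h1) / (u1 - u2)
                zs.append(z)
                xs.append(h1 + z * u1)
        assert np.ptp(zs) < 1e-12 * max(1, abs(np.mean(zs)))
        assert np.ptp(xs) < 1e-12

    def test_collimated_output_raises(self):
        # device sitting on the objective (Z_ERROR = f) driven with
        # kappa = -1/f: the objective exactly cancels the curvature and the
        # output is collimated (kappa Z + 1 = 0 in the closed form)
        sys_ = OpticalSystem(f=10.0, n=1.0, z_error=10.0)
        with pytest.raises(NoFocusError):
            trace_to_focus(sequence_for_system(sys_), Drive(-0.1))

    def test_oracle_equivalence_over_random_grid(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            sys_ = random_system(rng)
            drive = random_drive(rng, sys_)
            assert_same_focus(trace_to_focus(sequence_for_system(sys_), drive),
                              remote_focus(sys_, drive))

    def test_sequence_validation(self):
        with pytest.raises(ValidationError):
            ElementSequence([FreeSpace(10), ThinLens(5), Interface(1.33)])
        with pytest.raises(ValidationError):
            ElementSequence([RfOutput(), ThinLens(5)])
        with pytest.raises(ValidationError):
            trace_fan(sequence_for_system(OpticalSystem(f=4, n=1.33)),
                      Drive(0.0), "x", fan_size=1)


def relay(f1, f2, dev_gap=None, obj_gap=20.0, offsets=((0, 0), (0, 0))):
    """Elements of a two-lens afocal relay (magnification -f2/f1)."""
    dev_gap = f1 if dev_gap is None else dev_gap
    (o1x, o1y), (o2x, o2y) = offsets
    return [FreeSpace(dev_gap), ThinLens(f1, o1x, o1y), FreeSpace(f1 + f2),
            ThinLens(f2, o2x, o2y), FreeSpace(obj_gap)]


class TestEffectiveMisalignment:
    def test_unit_relay_without_offsets_preserves_device_errors(self):
        # two cascaded 4f relays: overall magnification +1
        els = ([RfOutput(offset_x=-1.2, offset_y=0.7)]
               + relay(10, 10, dev_gap=10, obj_gap=10)
               + relay(15, 15, dev_gap=0, obj_gap=12.0)[1:]
               + [ThinLens(12.5), Interface(1.33)])
        eff = effective_misalignment(ElementSequence(els))
        assert eff.magnification == pytest.approx(1.0)
        assert eff.system.x_error == pytest.approx(1.2, abs=1e-9)
        assert eff.system.y_error == pytest.approx(-0.7, abs=1e-9)

    def test_magnification_scales_lateral_and_axial_offsets(self):
        """Lateral device offsets scale by m, axial by m^2."""
        def z_eff(extra_axial, lateral):
            els = ([RfOutput(offset_x=lateral)]
                   + relay(10, 20, dev_gap=10 - extra_axial, obj_gap=15)
                   + [ThinLens(12.5), Interface(1.33)])
            return effective_misalignment(ElementSequence(els))

        base = z_eff(0.0, 0.0)
        assert abs(base.magnification) == pytest.approx(2.0)
        moved = z_eff(5.0, 1.0)
        # moving the device 5 mm axially moves the conjugate plane m^2 * 5
        assert abs(moved.system.z_error - base.system.z_error) == \
            pytest.approx(4 * 5.0, abs=1e-9)
        # a 1 mm lateral device offset appears as |m| * 1 = 2 mm
        assert abs(moved.system.x_error - base.system.x_error) == \
            pytest.approx(2.0, abs=1e-9)

    def test_reduced_model_reproduces_trace_over_drive_grid(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            f1, f2 = rng.uniform(5, 40, 2)
            els = ([RfOutput(offset_x=rng.normal(0, 1), offset_y=rng.normal(0, 1))]
                   + relay(f1, f2, dev_gap=rng.uniform(2, 30),
                           obj_gap=rng.uniform(5, 30),
                           offsets=((rng.normal(0, .5), rng.normal(0, .5)),
                                    (rng.normal(0, .5), rng.normal(0, .5))))
                   + [ThinLens(rng.uniform(3, 15)), Interface(rng.uniform(1.0, 1.6))])
            seq = ElementSequence(els)
            eff = effective_misalignment(seq)
            drive = random_drive(rng, eff.system)
            traced = trace_to_focus(seq, drive)
            closed = remote_focus(eff.system, eff.map_drive(drive))
            assert_same_focus(traced, closed)

    def test_inserting_aligned_unit_relay_leaves_focus_unchanged(self, aol_system):
        drive = Drive(-0.002, theta_x=0.015, theta_y=-0.01)
        base = remote_focus(aol_system, drive)
        els = ([RfOutput(offset_x=-aol_system.x_error, offset_y=-aol_system.y_error)]
               + relay(10, 10, dev_gap=10, obj_gap=10)
               + relay(10, 10, dev_gap=0,
                       obj_gap=aol_system.f - aol_system.z_error + 20.0)[1:]
               + [ThinLens(aol_system.f), Interface(aol_system.n)])
        fp = trace_to_focus(ElementSequence(els), drive)
        assert_same_focus(fp, base, rel=1e-12, abs_=1e-9)

    def test_single_4f_pair_inverts_the_field(self):
        sys_ = OpticalSystem(f=12.5, n=1.33)
        drive = Drive(-0.002, theta_x=0.015)
        # conjugate of the device lands 10 mm after the second lens; leave
        # exactly f more to the objective so the effective Z_ERROR is zero
        els = ([RfOutput()] + relay(10, 10, dev_gap=10, obj_gap=10 + sys_.f)
               + [ThinLens(sys_.f), Interface(sys_.n)])
        fp = trace_to_focus(ElementSequence(els), drive)
        base = remote_focus(sys_, drive)
        assert fp.z_rf == pytest.approx(base.z_rf, rel=1e-9, abs=1e-9)
        assert fp.x_rf == pytest.approx(-base.x_rf, rel=1e-9, abs=1e-9)

    def test_pre_relay_tilt_maps_to_pure_lateral_misalignment(self):
        """A Risley-style beam tilt adds lateral error but no axial error."""
        def seq_with_tilt(tilt):
            # emulate a tilt by a tiny wedge: offset lens of huge focal length
            # placed right after the device (deflects by offset/f)
            return ElementSequence(
                [RfOutput(), FreeSpace(0.0),
                 ThinLens(1e6, offset_x=tilt * 1e6)]
                + relay(10, 10, dev_gap=10, obj_gap=10)
                + relay(10, 10, dev_gap=0, obj_gap=30.0)[1:]
                + [ThinLens(12.5), Interface(1.33)])

        base = effective_misalignment(seq_with_tilt(0.0))
        tilted = effective_misalignment(seq_with_tilt(0.002))
        assert tilted.system.z_error == pytest.approx(base.system.z_error,
                                                      abs=1e-6)
        reg = tilted.registered_system
        # registered lateral error grows by tilt * Z_ERROR over the baseline
        assert reg.x_error - base.registered_system.x_error == pytest.approx(
            0.002 * base.system.z_error, rel=1e-6)

    def test_non_imaging_relay_rejected(self):
        # single-lens relay with the device at its front focal plane:
        # the device plane is imaged to infinity
        els = [RfOutput(), FreeSpace(10.0), ThinLens(10.0), FreeSpace(25.0),
               ThinLens(8.0), Interface(1.33)]
        with pytest.raises(ValidationError):
            effective_misalignment(ElementSequence(els))
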