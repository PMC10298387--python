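"""Enforced rotation and N-terminal restraint."""

import numpy as np
import pytest

from spinfold.geometry import rotation_about_axis
from spinfold.steering import (
    RestraintSpec,
    RotationProtocol,
    reference_angle,
    restraint_energy_force,
    rotation_energy_force,
    schedule_active,
)


def make_proto(**kwargs):
    defaults = dict(
        group=np.array([0, 1, 2]),
        reference_positions=np.array(
            [[0.0, 0.1, 0.0], [0.0, 0.0, 0.1], [0.1, 0.0, 0.0]]
        ),
        duration=100.0,
    )
    defaults.update(kwargs)
    return RotationProtocol(**defaults)


class TestRotationPotential:
    def test_zero_at_exact_tracking(self):
        proto = make_proto()
        t = 37.0
        theta = np.radians(reference_angle(t, proto))
        rot = rotation_about_axis(proto.axis, theta)
        tracked = (proto.reference_positions - proto.pivot) @ rot.T + proto.pivot
        e, f = rotation_energy_force(tracked, t, proto)
        assert e == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_zero_at_t0_identity(self):
        proto = make_proto()
        e, _ = rotation_energy_force(proto.reference_positions, 0.0, proto)
        assert e == pytest.approx(0.0, abs=1e-18)

    def test_harmonic_closed_form(self):
        # one bead displaced 0.01 nm from its rotated reference at
        # k = 10,000 gives E = 0.5 * 10000 * 1e-4 = 0.5 kJ/mol
        proto = RotationProtocol(
            group=np.array([0]),
            reference_positions=np.array([[0.0, 0.2, 0.0]]),
            duration=100.0,
            pivot=np.zeros(3),
        )
        t = 10.0
        theta = np.radians(reference_angle(t, proto))
        rot = rotation_about_axis(proto.axis, theta)
        ref = (proto.reference_positions - proto.pivot) @ rot.T + proto.pivot
        perp = np.cross(proto.axis, ref[0] - proto.pivot)
        perp /= np.linalg.norm(perp)
        displaced = ref + 0.01 * perp
        e, f = rotation_energy_force(displaced, t, proto)
        assert e == pytest.approx(0.5, rel=1e-9)
        np.testing.assert_allclose(f[0], -10_000 * 0.01 * perp, atol=1e-6)

    def test_inactive_after_duration(self):
        proto = make_proto(duration=50.0)
        pos = proto.reference_positions + 0.3
        e, f = rotation_energy_force(pos, 50.0, proto)
        assert e == 0.0
        np.testing.assert_array_equal(f, 0.0)

    def test_accumulated_angle_one_rotation_per_ns(self):
        proto = make_proto(duration=2000.0)
        assert abs(reference_angle(1000.0, proto)) == pytest.approx(360.0, abs=1e-12)

    def test_force_is_negative_gradient(self, rng):
        proto = make_proto()
        pos = proto.reference_positions + 0.05 * rng.standard_normal((3, 3))
        t = 21.0
        e, f = rotation_energy_force(pos, t, proto)
        h = 1e-7
        for i in range(3):
            for c in range(3):
                p1 = pos.copy()
                p1[i, c] += h
                p2 = pos.copy()
                p2[i, c] -= h
                fd = -(
                    rotation_energy_force(p1, t, proto)[0]
                    - rotation_energy_force(p2, t, proto)[0]
                ) / (2 * h)
                assert abs(fd - f[i, c]) / max(abs(fd), 1.0) < 1e-4


class TestAxialFreeVariant:
    def test_axial_displacement_unpenalised(self):
        proto = make_proto(axial_free=True, duration=100.0)
        slid = proto.reference_positions + np.array([0.7, 0.0, 0.0])  # +x = axis
        e, f = rotation_energy_force(slid, 0.0, proto)
        assert e == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_perpendicular_displacement_same_as_pinned(self):
        pinned = make_proto(duration=100.0)
        free = make_proto(axial_free=True, duration=100.0)
        pos = pinned.reference_positions + np.array([0.0, 0.05, -0.02])
        e1, f1 = rotation_energy_force(pos, 5.0, pinned)
        e2, f2 = rotation_energy_force(pos, 5.0, free)
        assert e1 == pytest.approx(e2, rel=1e-12)
        np.testing.assert_allclose(f1, f2, atol=1e-9)

    def test_force_is_negative_gradient(self, rng):
        proto = make_proto(axial_free=True, duration=100.0)
        pos = proto.reference_positions + 0.1 * rng.standard_normal((3, 3))
        t = 13.0
        _, f = rotation_energy_force(pos, t, proto)
        h = 1e-7
        for i in range(3):
            for c in range(3):
                p1 = pos.copy()
                p1[i, c] += h
                p2 = pos.copy()
                p2[i, c] -= h
                fd = -(
                    rotation_energy_force(p1, t, proto)[0]
                    - rotation_energy_force(p2, t, proto)[0]
                ) / (2 * h)
                assert abs(fd - f[i, c]) <= 1e-4 * max(abs(fd), 1.0)


class TestRestraint:
    def test_zero_at_reference(self):
        spec = RestraintSpec(
            group=np.array([0, 1]), reference_positions=np.zeros((2, 3))
        )
        e, f = restraint_energy_force(np.zeros((2, 3)), spec)
        assert e == 0.0
        np.testing.assert_array_equal(f, 0.0)

    def test_harmonic_closed_form(self):
        # 0.1 nm displacement at k = 1000 -> E = 5 kJ/mol
        spec = RestraintSpec(
            group=np.array([0]), reference_positions=np.zeros((1, 3))
        )
        pos = np.array([[0.1, 0.0, 0.0]])
        e, f = restraint_energy_force(pos, spec)
        assert e == pytest.approx(5.0, rel=1e-12)
        np.testing.assert_allclose(f, [[-100.0, 0.0, 0.0]], atol=1e-9)

    def test_finite_difference(self, rng):
        spec = RestraintSpec(
            group=np.arange(4),
            reference_positions=rng.standard_normal((4, 3)),
            force_constant=321.0,
        )
        pos = spec.reference_positions + 0.2 * rng.standard_normal((4, 3))
        _, f = restraint_energy_force(pos, spec)
        h = 1e-7
        for i in range(4):
            for c in range(3):
                p1 = pos.copy()
                p1[i, c] += h
                p2 = pos.copy()
                p2[i, c] -= h
                fd = -(
                    restraint_energy_force(p1, spec)[0]
                    - restraint_energy_force(p2, spec)[0]
                ) / (2 * h)
                assert abs(fd - f[i, c]) / max(abs(fd), 1.0) < 1e-4


class TestSchedule:
    def test_steered_at_zero(self):
        assert schedule_active(0.0, make_proto(duration=10.0)) == "steered"

    def test_free_at_duration_boundary(self):
        # half-open [0, duration)
        assert schedule_active(10.0, make_proto(duration=10.0)) == "free"

    def test_zero_duration_always_free(self):
        proto = make_proto(duration=0.0)
        for t in [0.0, 1.0, 1e6]:
            assert schedule_active(t, proto) == "free"

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            schedule_active(-1.0, make_proto())


class TestValidation:
    def test_axis_normalised(self):
        proto = make_proto(axis=np.array([2.0, 0.0, 0.0]))
        assert np.linalg.norm(proto.axis) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            RotationProtocol(
                group=np.array([], dtype=int),
                reference_positions=np.zeros((0, 3)),
                duration=1.0,
            )

    def test_bad_sense_rejected(self):
        with pytest.raises(ValueError):
            make_proto(sense=0)

    def test_default_pivot_is_group_centroid(self):
        proto = make_proto()
        np.testing.assert_allclose(
            proto.pivot, proto.reference_positions.mean(axis=0)
        )


class TestTrackingLag:
    def test_free_group_tracks_reference(self):
        # overdamped Langevin on one bead pulled by the rotating reference:
        # steady-state lag angle stays below 5 degrees at the default rate
        proto = RotationProtocol(
            group=np.array([0]),
            reference_positions=np.array([[0.0, 0.2, 0.0]]),
            duration=3000.0,
            pivot=np.zeros(3),
        )
        rng = np.random.default_rng(3)
        kbt = 0.008314462618 * 300.0
        gamma, mass, dt = 5.0, 40.0, 0.005
        x = proto.reference_positions.copy()
        v = np.zeros_like(x)
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(1 - c1 * c1) * np.sqrt(kbt / mass)
        lags = []
        t = 0.0
        for i in range(40_000):
            _, f = rotation_energy_force(x, t, proto)
            v += 0.5 * dt * f / mass
            x += 0.5 * dt * v
            v = c1 * v + c2 * rng.standard_normal(x.shape)
            x += 0.5 * dt * v
            t += dt
            _, f = rotation_energy_force(x, t, proto)
            v += 0.5 * dt * f / mass
            if i > 20_000:
                # signed angular lag about the rotation axis (+ = behind);
                # thermal jitter averages out, the systematic lag must not
                theta_ref = np.radians(reference_angle(t, proto))
                theta_bead = np.arctan2(x[0, 2], x[0, 1]) * proto.sense
                lag = np.degrees(
                    np.angle(np.exp(1j * (abs(theta_ref) - theta_bead)))
                )
                lags.append(lag)
        assert abs(np.mean(lags)) < 5.0
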