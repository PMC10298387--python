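"""Trajectory readouts: RMSD, contacts/Q, secondary structure, kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinfold.analysis import (
    ContactDefinition,
    FoldingEvent,
    acceleration_summary,
    contact_map,
    first_passage,
    kabsch_rmsd,
    kabsch_superpose,
    native_contact_state,
    secondary_labels,
)
from spinfold.chain import Conformation, build_extended
from spinfold.geometry import rotation_about_axis
from spinfold.targets import make_helix_target


def native_conf(ref):
    return Conformation(positions=ref.bead_positions.copy())


class TestKabsch:
    def test_identity(self, helix20):
        assert kabsch_rmsd(native_conf(helix20), helix20) < 1e-9

    def test_rigid_motion_invariance(self, helix20, rng):
        rot = rotation_about_axis(rng.standard_normal(3), 1.23)
        moved = helix20.bead_positions @ rot.T + np.array([3.0, -1.0, 2.0])
        assert kabsch_rmsd(Conformation(positions=moved), helix20) < 1e-6

    def test_against_rotation_grid_oracle(self, rng):
        # brute force: scan rotations (Fibonacci axes x angles), refine
        target = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0], [0.0, 0.4, 0.1]])
        mobile = target.copy()
        mobile[2] += np.array([0.08, -0.05, 0.1])
        rot = rotation_about_axis(np.array([0.2, 1.0, -0.3]), 0.9)
        mobile = mobile @ rot.T + 1.5

        _, analytic = kabsch_superpose(mobile, target)

        pc = mobile - mobile.mean(axis=0)
        qc = target - target.mean(axis=0)

        def rmsd_of(ax, ang):
            R = rotation_about_axis(ax, ang)
            d = pc @ R.T - qc
            return np.sqrt(np.mean(np.sum(d**2, axis=1)))

        def grid_min(axes, angles):
            best = (np.inf, None, None)
            for ax in axes:
                for ang in angles:
                    v = rmsd_of(ax, ang)
                    if v < best[0]:
                        best = (v, ax, ang)
            return best

        golden = np.pi * (3 - np.sqrt(5))
        k = np.arange(300)
        z = 1 - 2 * (k + 0.5) / 300
        r = np.sqrt(1 - z * z)
        axes = np.column_stack([r * np.cos(golden * k), r * np.sin(golden * k), z])
        best, best_ax, best_ang = grid_min(
            axes, np.linspace(0, 2 * np.pi, 180, endpoint=False)
        )
        # local refinement in shrinking neighbourhoods
        grid_rng = np.random.default_rng(0)
        for eps in (0.2, 0.05, 0.01, 0.002):
            cand_axes = best_ax + eps * grid_rng.standard_normal((40, 3))
            cand_axes /= np.linalg.norm(cand_axes, axis=1)[:, None]
            cand_axes = np.vstack([best_ax, cand_axes])
            angles = best_ang + np.linspace(-5 * eps, 5 * eps, 41)
            best, best_ax, best_ang = grid_min(cand_axes, angles)
        assert analytic <= best + 1e-12
        assert abs(best - analytic) < 1e-4

    def test_symmetric(self, helix20, rng):
        a = helix20.ca_positions + 0.1 * rng.standard_normal((20, 3))
        b = helix20.ca_positions
        _, r1 = kabsch_superpose(a, b)
        _, r2 = kabsch_superpose(b, a)
        assert abs(r1 - r2) < 1e-9

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)

    def test_too_few_points_rejected(self):
        pts = np.zeros((2, 3))
        with pytest.raises(ValueError):
            kabsch_superpose(pts, pts)


class TestContacts:
    def test_native_q_is_one(self, helix20, cdef):
        s = native_contact_state(native_conf(helix20), helix20, cdef)
        assert s.q == 1.0
        assert s.per_residue_formed.all()

    def test_extended_chain_q_below_015(self, helix20, cdef):
        conf = build_extended(20)
        s = native_contact_state(conf, helix20, cdef)
        assert s.q < 0.15
        has_contacts = np.bincount(s.pair_indices.ravel(), minlength=20) > 0
        assert not s.per_residue_formed[has_contacts].any()

    def test_q_arithmetic(self):
        # Q = N / N_all from the printed formula: 7/10 = 0.7
        s_dummy = FoldingEvent  # noqa: F841 - keep import used
        from spinfold.analysis import ContactSummary

        s = ContactSummary(
            7, 10, np.zeros((10, 2), int), np.zeros(10, bool), np.zeros(3, bool)
        )
        assert s.q == pytest.approx(0.7)

    def test_brute_force_equivalence(self, helix20, cdef, rng):
        # oracle: O(n^2) distance scan per frame
        for _ in range(5):
            pos = helix20.bead_positions + 0.15 * rng.standard_normal(
                helix20.bead_positions.shape
            )
            conf = Conformation(positions=pos)
            s = native_contact_state(conf, helix20, cdef)
            ca = conf.ca_positions
            ref_ca = helix20.ca_positions
            n = 20
            for a, (i, j) in enumerate(s.pair_indices):
                ref_d = np.linalg.norm(ref_ca[i] - ref_ca[j])
                assert ref_d <= cdef.cutoff and j - i >= 3
                d = np.linalg.norm(ca[i] - ca[j])
                assert s.pair_formed[a] == (d <= cdef.cutoff)
            # completeness: no native pair missing from the list
            listed = set(map(tuple, s.pair_indices))
            for i in range(n):
                for j in range(i + 3, n):
                    if np.linalg.norm(ref_ca[i] - ref_ca[j]) <= cdef.cutoff:
                        assert (i, j) in listed

    def test_q_monotone_under_contact_addition(self, helix20, cdef):
        # forming one more native pair never decreases Q
        pairs, _ = contact_map(helix20.ca_positions, cdef)
        ext = build_extended(20)
        s0 = native_contact_state(ext, helix20, cdef)
        pos = ext.positions.copy()
        i, j = pairs[0]
        # drag residue j's CA next to residue i's
        pos[3 * j + 1] = pos[3 * i + 1] + np.array([0.3, 0.0, 0.0])
        s1 = native_contact_state(Conformation(positions=pos), helix20, cdef)
        assert s1.q >= s0.q

    def test_strict_rule_residue_formed_implies_all_pairs(self, helix20, cdef, rng):
        pos = helix20.bead_positions + 0.1 * rng.standard_normal(
            helix20.bead_positions.shape
        )
        s = native_contact_state(Conformation(positions=pos), helix20, cdef)
        for res in np.where(s.per_residue_formed)[0]:
            involved = (s.pair_indices == res).any(axis=1)
            assert s.pair_formed[involved].all()

    def test_mismatched_counts_rejected(self, helix20):
        with pytest.raises(ValueError):
            native_contact_state(build_extended(10), helix20)

    def test_per_residue_variants(self, helix20):
        ext = build_extended(20)
        any_rule = ContactDefinition(per_residue_rule="any")
        s = native_contact_state(ext, helix20, any_rule)
        assert not s.per_residue_formed[5]


class TestSecondaryStructure:
    def test_ideal_helix_mostly_helix(self, helix20):
        labels = secondary_labels(helix20.ca_positions)
        interior = labels[1:-2]
        assert (interior == "H").mean() >= 0.8

    def test_extended_chain_no_helix(self):
        conf = build_extended(20)
        labels = secondary_labels(conf.ca_positions)
        assert not (labels == "H").any()
        assert not (labels == "G").any()
        interior = labels[1:-2]
        assert set(interior) <= {"E", "C"}

    def test_extended_chain_strand_dominates(self):
        conf = build_extended(20)
        labels = secondary_labels(conf.ca_positions)
        assert (labels[1:-2] == "E").mean() > 0.5

    def test_three_residue_chain_all_coil(self):
        labels = secondary_labels(np.random.default_rng(0).standard_normal((3, 3)))
        assert (labels == "C").all()

    def test_termini_coil(self, helix20):
        labels = secondary_labels(helix20.ca_positions)
        assert labels[0] == "C" and labels[-1] == "C" and labels[-2] == "C"


class TestFirstPassage:
    def test_constant_one_hits_first_snapshot(self):
        times = np.arange(20.0)
        ev = first_passage(times, np.ones(20), 0.85, dwell=5.0)
        assert not ev.censored
        assert ev.first_passage_time == 0.0

    def test_constant_low_censored(self):
        times = np.arange(20.0)
        ev = first_passage(times, np.full(20, 0.2), 0.85, dwell=5.0)
        assert ev.censored
        assert ev.first_passage_time is None
        assert ev.budget == 19.0

    def test_dwell_example(self):
        q = np.array([0.2, 0.9, 0.3, 0.9, 0.9, 0.9])
        ev = first_passage(np.arange(6.0), q, 0.85, dwell=2.0)
        assert ev.first_passage_time == 3.0

    @settings(max_examples=200, deadline=None)
    @given(
        q=st.lists(st.floats(0, 1), min_size=1, max_size=40),
        threshold=st.floats(0.1, 0.99),
        dwell_steps=st.integers(0, 12),
    )
    def test_matches_exhaustive_window_scan(self, q, threshold, dwell_steps):
        q = np.asarray(q)
        times = np.arange(len(q), dtype=float)
        dwell = float(dwell_steps)
        ev = first_passage(times, q, threshold, dwell)

        # oracle: brute-force scan over all candidate windows
        expected = None
        for i in range(len(q)):
            t_end = times[i] + dwell
            if t_end > times[-1]:
                break
            idx = [j for j in range(len(q)) if times[i] <= times[j] <= t_end]
            if all(q[j] >= threshold for j in idx):
                expected = times[i]
                break
        if expected is None:
            assert ev.censored
        else:
            assert not ev.censored
            assert ev.first_passage_time == expected


class TestAccelerationSummary:
    @staticmethod
    def ev(t=None, budget=100.0):
        return FoldingEvent(t, t is None, 0.85, 10.0, budget)

    def test_basic_ratio(self):
        s = acceleration_summary(
            [self.ev(1.0)] * 3, [self.ev(10.0)] * 3
        )
        assert s.ratio == pytest.approx(10.0)
        assert not s.is_lower_bound

    def test_equal_arms_ratio_one(self):
        s = acceleration_summary([self.ev(5.0)] * 3, [self.ev(5.0)] * 3)
        assert s.ratio == pytest.approx(1.0)

    def test_all_controls_censored_lower_bound(self):
        s = acceleration_summary(
            [self.ev(4.0)] * 3, [self.ev(None, budget=100.0)] * 3
        )
        assert s.is_lower_bound
        assert s.ratio == pytest.approx(100.0 / 4.0)

    def test_all_assisted_censored_flagged(self):
        s = acceleration_summary(
            [self.ev(None)] * 3, [self.ev(10.0)] * 3
        )
        assert s.ratio is None

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            acceleration_summary([], [self.ev(1.0)])
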