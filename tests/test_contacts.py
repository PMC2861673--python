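"""Contact counting, H-bond geometry, axis projections and RMSD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from dimerswitch import (SelectionSpec, contact_timeseries, count_contacts,
                         detect_hbonds, rmsd_vs_start, z_projection)
from dimerswitch.contacts import BRUTE_FORCE_PAIR_LIMIT
from dimerswitch.model import Trajectory
from dimerswitch.synthetic import generate_trajectory, symmetric_schedule

from conftest import make_frame


def brute_contact_count(coords, gi, gj, cutoff=4.0):
    """Independent O(n^2) oracle: explicit loop over all pairs."""
    n = 0
    for a in gi:
        for b in gj:
            if math.dist(coords[a], coords[b]) < cutoff:
                n += 1
    return n


class TestCountContacts:
    def test_beyond_and_within_cutoff(self, two_atom_frame_factory):
        assert count_contacts(two_atom_frame_factory(5.0), [0], [1]) == 0
        assert count_contacts(two_atom_frame_factory(3.9), [0], [1]) == 1

    def test_exactly_at_cutoff_is_not_a_contact(self, two_atom_frame_factory):
        assert count_contacts(two_atom_frame_factory(4.0), [0], [1]) == 0

    def test_constructed_groups_match_exhaustive_enumeration(self):
        coords = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0],   # group i
                           [1, 1, 0], [10, 0, 0]])            # group j
        fr = make_frame(coords)
        gi, gj = [0, 1, 2], [3, 4]
        assert count_contacts(fr, gi, gj) == brute_contact_count(coords, gi, gj)

    @pytest.mark.parametrize("seed", range(8))
    def test_randomized_frames_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 12, size=(40, 3))
        fr = make_frame(coords)
        gi = list(range(18))
        gj = list(range(18, 40))
        expected = brute_contact_count(coords, gi, gj)
        assert count_contacts(fr, gi, gj) == expected
        assert count_contacts(fr, gj, gi) == expected  # symmetric

    def test_tree_path_agrees_with_brute_force(self):
        rng = np.random.default_rng(99)
        n = int(math.isqrt(BRUTE_FORCE_PAIR_LIMIT)) + 30  # force the tree path
        coords = rng.uniform(0, 30, size=(2 * n, 3))
        fr = make_frame(coords, resnums=list(range(1, 2 * n + 1)))
        gi, gj = list(range(n)), list(range(n, 2 * n))
        assert count_contacts(fr, gi, gj) == brute_contact_count(coords, gi, gj)

    def test_overlapping_groups_error(self, two_atom_frame_factory):
        with pytest.raises(ValueError, match="overlap"):
            count_contacts(two_atom_frame_factory(3.0), [0, 1], [1])

    def test_heavy_only_drops_hydrogens(self):
        fr = make_frame([[0, 0, 0], [1, 0, 0]], elements=["C", "H"])
        assert count_contacts(fr, [0], [1]) == 1
        assert count_contacts(fr, [0], [1], heavy_only=True) == 0

    @given(cutoffs=st.lists(st.floats(0.5, 20), min_size=2, max_size=4),
           seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_cutoff(self, cutoffs, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 10, size=(12, 3))
        fr = make_frame(coords)
        counts = [count_contacts(fr, list(range(6)), list(range(6, 12)), c)
                  for c in sorted(cutoffs)]
        assert counts == sorted(counts)


class TestContactTimeseries:
    def test_stride_equals_interval(self, dimer):
        traj = generate_trajectory(dimer, symmetric_schedule(2.0), 2.0)
        mm = dimer.motif_map
        ts = contact_timeseries(traj, mm.spec("ligand", "A"),
                                mm.spec("Q_loop_Q", "A"), stride_ps=50.0)
        assert len(ts) == traj.n_frames

    def test_decimation(self, dimer):
        traj = generate_trajectory(dimer, symmetric_schedule(2.0), 2.0)
        mm = dimer.motif_map
        full = contact_timeseries(traj, mm.spec("ligand", "A"),
                                  mm.spec("Q_loop_Q", "A"), stride_ps=50.0)
        half = contact_timeseries(traj, mm.spec("ligand", "A"),
                                  mm.spec("Q_loop_Q", "A"), stride_ps=100.0)
        assert len(half) == (len(full) + 1) // 2
        assert np.array_equal(half.times_ps, full.times_ps[::2])

    def test_planted_constant_count(self, dimer):
        sched = symmetric_schedule(1.0)
        sched.segments[("MgATP-Q422", "NBS_A")] = [(0.0, 1.0, 7)]
        traj = generate_trajectory(dimer, sched, 1.0)
        mm = dimer.motif_map
        ts = contact_timeseries(traj, mm.spec("ligand", "A"),
                                mm.spec("Q_loop_Q", "A"),
                                pair_label="MgATP-Q422")
        assert np.all(ts.counts == 7)

    def test_stride_below_interval_errors(self, dimer, symmetric_traj):
        mm = dimer.motif_map
        with pytest.raises(ValueError, match="stride"):
            contact_timeseries(symmetric_traj, mm.spec("ligand", "A"),
                               mm.spec("Q_loop_Q", "A"), stride_ps=10.0)


def _hbond_frame(points):
    return make_frame(points, elements=["N", "H", "O"][:len(points)] +
                      ["O"] * max(0, len(points) - 3))


class TestHBonds:
    def test_ideal_collinear_geometry(self):
        fr = make_frame([[0, 0, 0], [1, 0, 0], [3, 0, 0]],
                        elements=["N", "H", "O"])
        hb = detect_hbonds(fr, [(0, 1)], [2])
        assert len(hb) == 1
        assert hb[0].distance == pytest.approx(3.0)
        assert hb[0].angle_deg == pytest.approx(0.0)

    def test_distance_threshold(self):
        fr = make_frame([[0, 0, 0], [1, 0, 0], [3.6, 0, 0]],
                        elements=["N", "H", "O"])
        assert detect_hbonds(fr, [(0, 1)], [2]) == []
        fr2 = make_frame([[0, 0, 0], [1, 0, 0], [3.5, 0, 0]],
                         elements=["N", "H", "O"])
        assert len(detect_hbonds(fr2, [(0, 1)], [2])) == 1  # inclusive

    def test_angle_threshold(self):
        # acceptor at 35 deg from the D->H direction, within distance
        ang = math.radians(35)
        fr = make_frame([[0, 0, 0], [1, 0, 0],
                         [3 * math.cos(ang), 3 * math.sin(ang), 0]],
                        elements=["N", "H", "O"])
        assert detect_hbonds(fr, [(0, 1)], [2]) == []

    def test_exhaustive_over_all_triples(self):
        rng = np.random.default_rng(3)
        donors_xyz = rng.uniform(0, 6, size=(4, 3))
        hydro_xyz = donors_xyz + rng.normal(0, 0.4, size=(4, 3))
        acc_xyz = rng.uniform(0, 6, size=(3, 3))
        coords = np.vstack([donors_xyz, hydro_xyz, acc_xyz])
        fr = make_frame(coords, elements=["N"] * 4 + ["H"] * 4 + ["O"] * 3)
        donors = [(i, i + 4) for i in range(4)]
        acceptors = [8, 9, 10]
        got = {(h.donor, h.hydrogen, h.acceptor)
               for h in detect_hbonds(fr, donors, acceptors)}
        expect = set()
        for d, h in donors:
            for a in acceptors:
                da = coords[a] - coords[d]
                dh = coords[h] - coords[d]
                dist = np.linalg.norm(da)
                cosang = np.dot(da, dh) / (dist * np.linalg.norm(dh))
                angle = math.degrees(math.acos(np.clip(cosang, -1, 1)))
                if dist <= 3.5 and angle <= 30.0:
                    expect.add((d, h, a))
        assert got == expect

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 6, size=(9, 3))
        fr = make_frame(coords, elements=["N", "H", "O"] * 3)
        donors = [(0, 1), (3, 4), (6, 7)]
        acceptors = [2, 5, 8]
        ref = detect_hbonds(fr, donors, acceptors)
        rot = Rotation.from_euler("xyz", [40, -70, 15], degrees=True)
        moved = make_frame(rot.apply(coords) + np.array([5.0, -3.0, 11.0]),
                           elements=["N", "H", "O"] * 3)
        got = detect_hbonds(moved, donors, acceptors)
        assert [(h.donor, h.hydrogen, h.acceptor) for h in got] == \
               [(h.donor, h.hydrogen, h.acceptor) for h in ref]
        for a, b in zip(got, ref):
            assert a.distance == pytest.approx(b.distance, abs=1e-9)
            assert a.angle_deg == pytest.approx(b.angle_deg, abs=1e-7)

    def test_missing_hydrogen_names_donor(self):
        fr = make_frame([[0, 0, 0], [1, 0, 0], [3, 0, 0]],
                        elements=["N", "H", "O"])
        with pytest.raises(IndexError, match="donor 0"):
            detect_hbonds(fr, [(0, 99)], [2])


def _tiny_traj(coord_frames, names=None, resnames="ALA"):
    frames = [make_frame(c, names=names, resname=resnames, time_ps=50.0 * i)
              for i, c in enumerate(coord_frames)]
    return Trajectory.from_frames(frames)


class TestZProjection:
    def test_static_atom(self):
        traj = _tiny_traj([[[0, 0, 12.5]], [[0, 0, 12.5]]])
        _, z = z_projection(traj, SelectionSpec("A", frozenset({1})),
                            mode="all")
        assert np.allclose(z, 12.5)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 5, size=(4, 3))
        traj = _tiny_traj([base, base + np.array([0, 0, 3.0])])
        _, z = z_projection(traj, SelectionSpec("A", frozenset({1, 2, 3, 4})),
                            mode="all")
        assert z[1] - z[0] == pytest.approx(3.0)

    def test_terminal_atom_subset_and_crossing(self, dimer):
        """Planted stacking swap is visible as a z-order crossing."""
        from dimerswitch.synthetic import symmetric_schedule
        sched = symmetric_schedule(2.0)
        sched.segments[("R474_stacking", "axis")] = [
            (0.0, 1.0, "A"), (1.0, 2.0, "B")]
        traj = generate_trajectory(dimer, sched, 2.0)
        mm = dimer.motif_map
        t, za = z_projection(traj, mm.spec("xloop_R", "A"))
        _, zb = z_projection(traj, mm.spec("xloop_R", "B"))
        dz = za - zb
        crossings = np.nonzero(np.diff(np.sign(dz)))[0]
        assert len(crossings) == 1
        assert t[crossings[0] + 1] == pytest.approx(1000.0)

    def test_bad_axis(self):
        traj = _tiny_traj([[[0, 0, 1.0]]])
        with pytest.raises(ValueError, match="norm"):
            z_projection(traj, SelectionSpec("A", frozenset({1})),
                         axis=np.zeros(3), mode="all")
        with pytest.raises(ValueError, match="unit"):
            z_projection(traj, SelectionSpec("A", frozenset({1})),
                         axis=np.array([0, 0, 2.0]), mode="all")


def kabsch_rmsd(ref, mob):
    """Independent closed-form oracle: Kabsch superposition via SVD."""
    ref = ref - ref.mean(axis=0)
    mob = mob - mob.mean(axis=0)
    U, S, Vt = np.linalg.svd(mob.T @ ref)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = (U @ D @ Vt).T
    moved = mob @ R.T
    return float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))


class TestRmsd:
    SPEC = SelectionSpec("A", frozenset({1, 2, 3, 4}))

    def _traj(self, frames):
        frs = [make_frame(c, names=["CA"] * 4, time_ps=50.0 * i)
               for i, c in enumerate(frames)]
        return Trajectory.from_frames(frs)

    BASE = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0.5, 0.5, 3]], float)

    def test_identity_and_reference_zero(self):
        rs = rmsd_vs_start(self._traj([self.BASE, self.BASE]), self.SPEC)
        assert rs.rmsd[0] == pytest.approx(0.0, abs=1e-12)
        assert rs.rmsd[1] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rot = Rotation.from_euler("z", 90, degrees=True)
        moved = rot.apply(self.BASE) + np.array([2.0, -1.0, 7.0])
        rs = rmsd_vs_start(self._traj([self.BASE, moved]), self.SPEC)
        assert rs.rmsd[1] == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_matches_oracle(self):
        moved = self.BASE.copy()
        moved[3] += np.array([1.0, -0.5, 0.8])
        rs = rmsd_vs_start(self._traj([self.BASE, moved]), self.SPEC)
        assert rs.rmsd[1] == pytest.approx(kabsch_rmsd(self.BASE, moved),
                                           abs=1e-9)

    def test_matches_mdanalysis_on_random_frames(self):
        mda_rms = pytest.importorskip("MDAnalysis.analysis.rms")
        rng = np.random.default_rng(5)
        frames = [self.BASE] + [self.BASE + rng.normal(0, 0.7, (4, 3))
                                for _ in range(3)]
        rs = rmsd_vs_start(self._traj(frames), self.SPEC)
        for i, fr in enumerate(frames):
            expect = mda_rms.rmsd(fr, self.BASE, center=True,
                                  superposition=True)
            assert rs.rmsd[i] == pytest.approx(expect, abs=1e-7)

    def test_too_few_or_collinear_atoms_error(self):
        spec2 = SelectionSpec("A", frozenset({1, 2}))
        with pytest.raises(ValueError, match="at least 3"):
            rmsd_vs_start(self._traj([self.BASE, self.BASE]), spec2)
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear"):
            rmsd_vs_start(self._traj([line, line]), self.SPEC)
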