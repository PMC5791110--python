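"""Per-frame observables against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hydrosieve.core import ArgumentError
from hydrosieve.trajectory import (
    Topology,
    TopologyError,
    TrajectoryFrame,
    analyze_trajectory,
    capture_fraction,
    fibonacci_sphere,
    hbond_count,
    rgyr,
    sasa,
    water_shell_count,
)

O_R = 1.52   # Bondi oxygen radius
PROBE = 1.4


def frame_of(elements, roles, coords, mol_ids=None, bonds=(), box=None):
    if mol_ids is None:
        mol_ids = list(range(len(elements)))
    top = Topology(elements=list(elements), roles=list(roles),
                   mol_ids=np.array(mol_ids), bonds=list(bonds))
    return TrajectoryFrame(np.asarray(coords, float), top,
                           box=None if box is None else np.asarray(box, float))


class TestSASA:
    def test_isolated_sphere_closed_form(self):
        fr = frame_of(["O"], ["hydrogel"], [[0, 0, 0]])
        exact = 4 * math.pi * (O_R + PROBE) ** 2
        assert sasa(fr, [0]) == pytest.approx(exact, rel=0.01)

    def test_disjoint_spheres_additive(self):
        fr = frame_of(["O", "O"], ["hydrogel"] * 2, [[0, 0, 0], [50, 0, 0]],
                      mol_ids=[0, 1])
        single = 4 * math.pi * (O_R + PROBE) ** 2
        assert sasa(fr, [0, 1]) == pytest.approx(2 * single, rel=0.01)

    @pytest.mark.parametrize("d", [1.0, 2.0, 3.0, 4.5])
    def test_overlapping_pair_matches_dense_oracle(self, d):
        fr = frame_of(["O", "O"], ["hydrogel"] * 2, [[0, 0, 0], [d, 0, 0]],
                      mol_ids=[0, 1])
        fast = sasa(fr, [0, 1], n_points=960)
        dense = sasa(fr, [0, 1], n_points=10_000)
        assert fast == pytest.approx(dense, rel=0.02)

    def test_overlapping_pair_matches_spherical_cap_formula(self):
        # two equal probe-expanded spheres of radius R at distance d:
        # exposed area each = 4πR² - 2πR·h with cap height h = R - d/2
        d = 3.0
        R = O_R + PROBE
        fr = frame_of(["O", "O"], ["hydrogel"] * 2, [[0, 0, 0], [d, 0, 0]],
                      mol_ids=[0, 1])
        h = R - d / 2
        exact = 2 * (4 * math.pi * R**2 - 2 * math.pi * R * h)
        assert sasa(fr, [0, 1], n_points=5000) == pytest.approx(exact, rel=0.01)

    def test_empty_selection_rejected(self):
        fr = frame_of(["O"], ["hydrogel"], [[0, 0, 0]])
        with pytest.raises(ArgumentError):
            sasa(fr, [])

    def test_fibonacci_points_unit_norm(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.abs(pts.mean(axis=0)).max() < 0.01


class TestRGYR:
    def test_single_atom_zero(self):
        fr = frame_of(["C"], ["hydrogel"], [[3, 4, 5]])
        assert rgyr(fr, [0]) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_masses(self):
        fr = frame_of(["C", "C"], ["hydrogel"] * 2, [[0, 0, 0], [10, 0, 0]])
        assert rgyr(fr, [0, 1]) == pytest.approx(5.0, abs=1e-12)

    def test_matches_direct_summation_random_cloud(self, rng):
        els = list(np.array(["C", "O", "H", "N"])[rng.integers(0, 4, 100)])
        coords = rng.normal(scale=8.0, size=(100, 3))
        fr = frame_of(els, ["hydrogel"] * 100, coords)
        m = fr.topology.masses
        com = (m[:, None] * coords).sum(0) / m.sum()
        expected = math.sqrt((m * ((coords - com) ** 2).sum(1)).sum() / m.sum())
        assert rgyr(fr, np.arange(100)) == pytest.approx(expected, abs=1e-10)


class TestWaterShell:
    def _frame(self, waters, box=None):
        els = ["C"] + ["O", "H", "H"] * len(waters)
        roles = ["hydrogel"] + ["water"] * (3 * len(waters))
        mids = [0] + [1 + k for k in range(len(waters)) for _ in range(3)]
        coords = [[0, 0, 0]]
        bonds = []
        for k, w in enumerate(waters):
            i = 1 + 3 * k
            coords += [list(w), [w[0] + 0.95, w[1], w[2]], [w[0], w[1] + 0.95, w[2]]]
            bonds += [(i, i + 1), (i, i + 2)]
        return frame_of(els, roles, coords, mids, bonds, box)

    def test_no_waters(self):
        fr = frame_of(["C"], ["hydrogel"], [[0, 0, 0]])
        assert water_shell_count(fr, com_radius=10.0) == 0

    def test_planted_counts(self):
        inside = [(2.0, 0, 0), (0, 8.0, 0)]        # near backbone / in sphere
        outside = [(40.0, 0, 0)]
        fr = self._frame(inside + outside, box=[100.0] * 3)
        assert water_shell_count(fr, 3.0, com_radius=10.0) == 2

    def test_matches_brute_force_random_frame(self, rng):
        waters = rng.uniform(0, 30, size=(40, 3))
        fr = self._frame([tuple(w) for w in waters], box=[30.0] * 3)
        got = water_shell_count(fr, 3.0, com_radius=9.0)
        box = np.array([30.0] * 3)
        count = 0
        for w in waters:
            dr = w - np.zeros(3)
            dr = dr - box * np.round(dr / box)
            near = np.linalg.norm(dr) <= 3.0
            inside = np.linalg.norm(dr) <= 9.0
            count += int(near or inside)
        assert got == count

    def test_bad_radius_rejected(self):
        fr = self._frame([(2.0, 0, 0)])
        with pytest.raises(ArgumentError):
            water_shell_count(fr, 3.0, com_radius=-1.0)


class TestCapture:
    def _frame(self, dmt_positions, box=None):
        els = ["C"] + ["C"] * len(dmt_positions)
        roles = ["hydrogel"] + ["DMT"] * len(dmt_positions)
        mids = [0] + [1 + k for k in range(len(dmt_positions))]
        return frame_of(els, roles, [[0, 0, 0]] + [list(p) for p in dmt_positions],
                        mids, box=box)

    def test_all_far_gives_zero(self):
        fr = self._frame([(60, 0, 0), (0, 70, 0)], box=[200.0] * 3)
        assert capture_fraction(fr) == 0.0

    def test_planted_60_percent(self):
        near = [(3.0, 0, 0)] * 3
        far = [(50.0, 0, 0)] * 2
        fr = self._frame(near + far, box=[200.0] * 3)
        assert capture_fraction(fr) == pytest.approx(60.0)

    def test_monotone_in_cutoff(self, rng):
        pos = rng.uniform(-30, 30, size=(20, 3))
        fr = self._frame([tuple(p) for p in pos])
        vals = [capture_fraction(fr, c) for c in (2.0, 4.5, 8.0, 20.0, 60.0)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_matches_brute_force(self, rng):
        pos = rng.uniform(0, 25, size=(15, 3))
        fr = self._frame([tuple(p) for p in pos], box=[25.0] * 3)
        box = np.array([25.0] * 3)
        expected = 0
        for p in pos:
            dr = p - box * np.round(p / box)
            expected += int(np.linalg.norm(dr) <= 4.5)
        assert capture_fraction(fr) == pytest.approx(100.0 * expected / 15)

    def test_no_guests_rejected(self):
        fr = frame_of(["C"], ["hydrogel"], [[0, 0, 0]])
        with pytest.raises(ArgumentError):
            capture_fraction(fr)


class TestHbonds:
    def _triple(self, a_pos, a_el="O"):
        return frame_of(["O", "H", a_el],
                        ["hydrogel", "hydrogel", "DMT"],
                        [[0, 0, 0], [0.96, 0, 0], list(a_pos)],
                        mol_ids=[0, 0, 1], bonds=[(0, 1)])

    def test_textbook_geometry_counts(self):
        assert hbond_count(self._triple((2.8, 0, 0))) == 1

    def test_distance_gate(self):
        assert hbond_count(self._triple((4.0, 0, 0))) == 0

    def test_sulfur_gets_longer_cutoff(self):
        assert hbond_count(self._triple((3.3, 0, 0), "S")) == 1
        assert hbond_count(self._triple((3.3, 0, 0), "O")) == 0

    def test_angle_gate_45_degrees(self):
        ang = math.radians(45)
        a = (0.96 + 1.9 * math.cos(ang), 1.9 * math.sin(ang), 0.0)
        fr = self._triple(a)
        assert np.linalg.norm(a) <= 3.0       # distance passes, angle fails
        assert hbond_count(fr) == 0

    @pytest.mark.parametrize("deviation,expected", [(0, 1), (15, 1), (29, 1),
                                                    (31, 0), (60, 0)])
    def test_planted_angle_sweep_matches_rule(self, deviation, expected):
        # place A at D-A distance 2.9 with controlled D-H...A deviation
        dev = math.radians(deviation)
        d_da = 2.9
        # A on the cone around the D->H axis through H
        # solve position: from H, direction making angle dev with (H-D) axis
        hx = 0.96
        # distance H->A from law of cosines in triangle D-H-A
        # |DA|² = |DH|² + |HA|² - 2|DH||HA|cos(pi - dev)
        a = 1.0
        b = 2 * hx * math.cos(dev)
        c = hx**2 - d_da**2
        ha = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
        apos = (hx + ha * math.cos(dev), ha * math.sin(dev), 0.0)
        fr = self._triple(apos)
        assert np.linalg.norm(apos) == pytest.approx(d_da, abs=1e-9)
        assert hbond_count(fr) == expected

    def test_missing_bonds_raise_topology_error(self):
        fr = frame_of(["O", "H", "O"], ["hydrogel", "hydrogel", "DMT"],
                      [[0, 0, 0], [0.96, 0, 0], [2.8, 0, 0]],
                      mol_ids=[0, 0, 1], bonds=[])
        with pytest.raises(TopologyError):
            hbond_count(fr)


class TestRigidMotionInvariance:
    def test_observables_invariant_under_rotation_translation(self, rng):
        n = 30
        els = ["C", "O", "H"] * 10
        roles = (["hydrogel"] * 15 + ["DMT"] * 15)
        mids = [0] * 15 + [1 + k // 3 for k in range(15)]
        coords = rng.normal(scale=5.0, size=(n, 3))
        bonds = [(i, i + 2) for i in range(0, n - 2, 3)]
        top = Topology(elements=els, roles=roles, mol_ids=np.array(mids),
                       bonds=bonds)
        f1 = TrajectoryFrame(coords, top)
        R = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        f2 = TrajectoryFrame(coords @ R.T + np.array([5.0, -3.0, 8.0]), top)
        gel = top.select("hydrogel")
        # the deterministic lattice is lab-fixed, so SASA is invariant only
        # up to its own quadrature resolution
        assert sasa(f1, gel) == pytest.approx(sasa(f2, gel), rel=5e-3)
        assert rgyr(f1, gel) == pytest.approx(rgyr(f2, gel), abs=1e-9)
        assert capture_fraction(f1) == capture_fraction(f2)
        assert hbond_count(f1) == hbond_count(f2)


class TestAnalyzeTrajectory:
    def test_single_frame_equals_individual_ops(self):
        fr = frame_of(["C", "C"], ["hydrogel", "DMT"], [[0, 0, 0], [3.0, 0, 0]],
                      mol_ids=[0, 1], box=[50.0] * 3)
        df = analyze_trajectory([fr], observables=("rgyr", "capture"))
        assert df["capture_pct"].iloc[0] == capture_fraction(fr)
        assert df["rgyr_A"].iloc[0] == rgyr(fr, fr.topology.select("hydrogel"))

    def test_first_crossing_time_of_full_capture(self):
        frames = []
        for t, x in enumerate([20.0, 10.0, 3.0, 3.0]):
            fr = frame_of(["C", "C"], ["hydrogel", "DMT"],
                          [[0, 0, 0], [x, 0, 0]], mol_ids=[0, 1], box=[50.0] * 3)
            fr.time = float(t)
            frames.append(fr)
        df = analyze_trajectory(frames, observables=("capture",))
        assert df.attrs["first_full_capture_ns"] == 2.0

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ArgumentError):
            analyze_trajectory([])
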