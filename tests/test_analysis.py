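"""Analysis stack: clusters, axes, metrics, classification, maps, KDE.

The classifier tests use synthetic trajectories built from a real relaxed
membrane rigidly moved along prescribed tracks with rods pinned at the kink
(or scattered, for the unclustered archetype), so every label has a known
ground truth.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

import kinkvesicle as kv
from kinkvesicle.analysis import (ClassifierThresholds, DEFAULT_CLUSTER_CUTOFF,
                                  _axis_series)
from kinkvesicle.errors import InsufficientDataError, NoKinkAxisError


# ---------------------------------------------------------------------------
# synthetic trajectory builder
# ---------------------------------------------------------------------------

def _rot(v, ang):
    c, s = math.cos(ang), math.sin(ang)
    return np.einsum("ij,...j->...i", np.array([[c, -s], [s, c]]), v)


def make_rigid_trajectory(membrane_state, vesicle, rod_spec,
                          path, headings, times, rods_at_kink=True,
                          scatter_rng=None):
    """Move the whole configuration rigidly: centroid follows ``path``,
    the kink axis follows ``headings``. Rods are pinned near the kink
    (clustered) or scattered (never clustered)."""
    mem0 = membrane_state.membrane_unwrapped()
    c0 = mem0.mean(axis=0)
    v0, axis0 = kv.kink_frame(membrane_state, vesicle)
    ang0 = math.atan2(axis0[1], axis0[0])
    if rods_at_kink:
        seq = kv.StackingSequence((kv.Slot("left", 0, "parallel"),
                                   kv.Slot("right", 0, "parallel"),
                                   kv.Slot("left", 1, "parallel")))
        st = kv.build_frozen_stacking(seq, membrane_state, rod_spec, vesicle)
        rods_rel = st.rod_centers_unwrapped() - c0
        rodw = st.rod_orientations.copy()
    else:
        rng = scatter_rng or np.random.default_rng(0)
        n = 6
        ang = rng.uniform(0, 2 * math.pi, n)
        rad = rng.uniform(3.0, 12.0, n)
        rods_rel = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
        rodw = rng.uniform(0, 2 * math.pi, n)

    F = len(times)
    mem = np.empty((F, len(mem0), 2))
    cen = np.empty((F, len(rods_rel), 2))
    wor = np.empty((F, len(rods_rel)))
    for f in range(F):
        dang = headings[f] - ang0
        mem[f] = path[f] + _rot(mem0 - c0, dang)
        cen[f] = path[f] + _rot(rods_rel, dang)
        wor[f] = rodw + dang
    return kv.Trajectory(
        times=np.asarray(times, float),
        membrane=mem, rod_centers=cen, rod_orientations=wor,
        rod_active=np.ones((F, len(rods_rel)), bool),
        kink_angle=np.full(F, vesicle.kink_angle),
        energies=np.zeros((F, 3)),
        box_length=membrane_state.box_length,
        kink_index=vesicle.kink_index,
        rod_n_disks=rod_spec.n_disks)


@pytest.fixture(scope="module")
def archetypes(wide_membrane, wide_kink_vesicle, trimer):
    """The four directed-motion archetype tracks plus controls."""
    times = np.linspace(0, 100, 101)
    out = {}
    v = 0.05
    # linear forward: straight line, axis along the motion
    path = np.stack([60 + v * times, np.full_like(times, 60.0)], axis=1)
    out["linear_forward"] = make_rigid_trajectory(
        wide_membrane, wide_kink_vesicle, trimer, path,
        np.zeros_like(times), times)
    # linear backward: axis opposite the motion
    out["linear_backward"] = make_rigid_trajectory(
        wide_membrane, wide_kink_vesicle, trimer, path,
        np.full_like(times, math.pi), times)
    # circular forward: circle of radius 40, axis tangent along motion
    R = 40.0
    phi = v * times / R
    circ = np.stack([60 + R * np.sin(phi), 60 + R * (1 - np.cos(phi))], axis=1)
    out["circular_forward"] = make_rigid_trajectory(
        wide_membrane, wide_kink_vesicle, trimer, circ, phi, times)
    out["circular_backward"] = make_rigid_trajectory(
        wide_membrane, wide_kink_vesicle, trimer, circ, phi + math.pi, times)
    return out


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

class TestDetectClusters:
    def test_two_distant_rods_are_singletons(self, trimer):
        st = kv.SystemState(np.empty((0, 2)),
                            np.array([[10.0, 10.0], [20.0, 10.0]]),
                            np.zeros(2), 125.0)
        ca = kv.detect_clusters(st, trimer)
        assert ca.n_clusters == 2
        assert list(ca.sizes) == [1, 1]

    def test_chain_transitivity(self, trimer):
        # A-B in contact, B-C in contact, A-C distant -> one 3-cluster
        st = kv.SystemState(np.empty((0, 2)),
                            np.array([[10.0, 10.0], [10.0, 11.1], [10.0, 12.2]]),
                            np.zeros(3), 125.0)
        ca = kv.detect_clusters(st, trimer)
        assert ca.n_clusters == 1
        assert ca.sizes[0] == 3

    def test_matches_bruteforce_components(self, trimer, rng):
        """50 random rods: partition equals a double-loop union-find oracle."""
        n = 50
        cen = 30 + rng.random((n, 2)) * 25
        w = rng.uniform(0, 2 * math.pi, n)
        st = kv.SystemState(np.empty((0, 2)), cen, w, 125.0)
        ca = kv.detect_clusters(st, trimer)
        # brute force oracle
        disks = st.rod_disk_positions(trimer)
        m = trimer.n_disks
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a in range(n * m):
            for b in range(a + 1, n * m):
                if a // m != b // m and (np.linalg.norm(disks[a] - disks[b])
                                         < DEFAULT_CLUSTER_CUTOFF):
                    ra, rb = find(a // m), find(b // m)
                    parent[ra] = rb
        oracle = [find(i) for i in range(n)]
        # same partition up to relabelling
        mapping = {}
        for mine, theirs in zip(ca.labels, oracle):
            assert mapping.setdefault(mine, theirs) == theirs
        assert len(set(mapping.values())) == len(mapping)

    def test_invariant_under_rod_relabelling(self, trimer, rng):
        cen = 30 + rng.random((12, 2)) * 10
        w = rng.uniform(0, 2 * math.pi, 12)
        st = kv.SystemState(np.empty((0, 2)), cen, w, 125.0)
        ca = kv.detect_clusters(st, trimer)
        perm = rng.permutation(12)
        st2 = kv.SystemState(np.empty((0, 2)), cen[perm], w[perm], 125.0)
        ca2 = kv.detect_clusters(st2, trimer)
        # partitions agree: rods in the same cluster before stay together
        for i in range(12):
            for j in range(12):
                same1 = ca.labels[i] == ca.labels[j]
                same2 = ca2.labels[np.argwhere(perm == i)[0, 0]] \
                    == ca2.labels[np.argwhere(perm == j)[0, 0]]
                assert same1 == same2


# ---------------------------------------------------------------------------
# kink axis and alignment angles
# ---------------------------------------------------------------------------

class TestKinkAxis:
    def test_teardrop_axis_points_to_vertex(self, wide_membrane,
                                            wide_kink_vesicle):
        axis = kv.kink_axis(wide_membrane, wide_kink_vesicle)
        mem = wide_membrane.membrane_unwrapped()
        expect = mem[0] - mem.mean(axis=0)
        expect /= np.linalg.norm(expect)
        assert np.allclose(axis, expect, atol=1e-12)

    def test_rotation_equivariance(self, wide_membrane, wide_kink_vesicle):
        phi = 0.83
        mem = wide_membrane.membrane_unwrapped()
        c = mem.mean(axis=0)
        rotated = kv.SystemState(c + _rot(mem - c, phi), np.empty((0, 2)),
                                 np.empty(0), wide_membrane.box_length)
        a0 = kv.kink_axis(wide_membrane, wide_kink_vesicle)
        a1 = kv.kink_axis(rotated, wide_kink_vesicle)
        assert np.allclose(a1, _rot(a0, phi), atol=1e-9)

    def test_no_kink_raises(self, params):
        ves = kv.VesicleSpec(kink_angle=math.pi)
        st = kv.build_vesicle(ves, params)
        with pytest.raises(NoKinkAxisError):
            kv.kink_axis(st, ves)


class TestAlignmentAngles:
    def test_parallel_stacking_near_zero(self, wide_membrane,
                                         wide_kink_vesicle, trimer):
        seq = kv.StackingSequence((kv.Slot("left", 0, "parallel"),
                                   kv.Slot("right", 0, "parallel")))
        st = kv.build_frozen_stacking(seq, wide_membrane, trimer,
                                      wide_kink_vesicle)
        ca = kv.detect_clusters(st, trimer)
        ang = kv.alignment_angles(st, ca, wide_kink_vesicle)
        assert len(ang) == 2
        assert np.all(ang < 0.1)

    def test_wall_aligned_at_half_kink_angle(self, params, dimer):
        ves = kv.VesicleSpec(kink_angle=math.pi / 2)
        mem = kv.build_vesicle(ves, params)
        seq = kv.StackingSequence.from_partition(2, 1, mode="wall")
        st = kv.build_frozen_stacking(seq, mem, dimer, ves)
        ca = kv.detect_clusters(st, dimer, cutoff=3.0)  # one loose cluster
        ang = kv.alignment_angles(st, ca, ves)
        assert np.allclose(ang, math.pi / 4, atol=1e-9)

    def test_perpendicular_rod(self, wide_membrane, wide_kink_vesicle, trimer):
        axis = kv.kink_axis(wide_membrane, wide_kink_vesicle)
        w = math.atan2(axis[1], axis[0]) + math.pi / 2
        c = wide_membrane.membrane_unwrapped().mean(axis=0)
        st = kv.SystemState(wide_membrane.membrane_positions.copy(),
                            np.array([c, c + [0.0, 1.05]]),
                            np.array([w, w]), wide_membrane.box_length,
                            membrane_images=wide_membrane.membrane_images.copy())
        ca = kv.detect_clusters(st, trimer)
        ang = kv.alignment_angles(st, ca, wide_kink_vesicle)
        assert np.allclose(ang, math.pi / 2, atol=1e-9)

    def test_no_qualifying_cluster_empty(self, wide_membrane,
                                         wide_kink_vesicle, trimer):
        st = kv.SystemState(wide_membrane.membrane_positions.copy(),
                            np.array([[50.0, 50.0]]), np.zeros(1),
                            wide_membrane.box_length,
                            membrane_images=wide_membrane.membrane_images.copy())
        ca = kv.detect_clusters(st, trimer)
        assert len(kv.alignment_angles(st, ca, wide_kink_vesicle)) == 0


# ---------------------------------------------------------------------------
# motion metrics and circle fit
# ---------------------------------------------------------------------------

class TestMotionMetrics:
    def test_stationary(self, wide_membrane, wide_kink_vesicle, trimer):
        times = np.linspace(0, 10, 21)
        path = np.tile([60.0, 60.0], (21, 1))
        traj = make_rigid_trajectory(wide_membrane, wide_kink_vesicle, trimer,
                                     path, np.zeros(21), times)
        speeds, omegas, _ = kv.motion_metrics(traj)
        assert np.allclose(speeds, 0.0, atol=1e-12)
        assert np.allclose(omegas, 0.0, atol=1e-12)

    def test_rigid_translation(self, wide_membrane, wide_kink_vesicle, trimer):
        u = np.array([0.03, -0.04])
        times = np.linspace(0, 10, 21)
        path = 60.0 + times[:, None] * u
        traj = make_rigid_trajectory(wide_membrane, wide_kink_vesicle, trimer,
                                     path, np.zeros(21), times)
        speeds, omegas, _ = kv.motion_metrics(traj)
        assert np.allclose(speeds, 0.05, atol=1e-9)
        assert np.allclose(omegas, 0.0, atol=1e-9)

    def test_rigid_rotation_about_centroid(self, wide_membrane,
                                           wide_kink_vesicle, trimer):
        Omega = 0.02
        times = np.linspace(0, 100, 51)
        path = np.tile([60.0, 60.0], (51, 1))
        traj = make_rigid_trajectory(wide_membrane, wide_kink_vesicle, trimer,
                                     path, Omega * times, times)
        speeds, omegas, _ = kv.motion_metrics(traj)
        assert np.allclose(omegas, Omega, atol=1e-9)
        assert np.allclose(speeds, 0.0, atol=1e-9)

    def test_too_short_raises(self, wide_membrane, wide_kink_vesicle, trimer):
        times = np.linspace(0, 1, 5)
        path = np.tile([60.0, 60.0], (5, 1))
        traj = make_rigid_trajectory(wide_membrane, wide_kink_vesicle, trimer,
                                     path, np.zeros(5), times)
        with pytest.raises(InsufficientDataError):
            kv.motion_metrics(traj, window=1.0)


class TestFitCircle:
    def test_exact_circle(self, rng):
        phi = np.sort(rng.uniform(0, 2, 60))
        pts = 30.0 * np.stack([np.cos(phi), np.sin(phi)], axis=1) + [5.0, -3.0]
        assert kv.fit_circle(pts) == pytest.approx(30.0, abs=0.1)

    def test_collinear_returns_infinity(self):
        t = np.linspace(0, 10, 30)
        pts = np.stack([t, 2 * t + 1], axis=1)
        assert kv.fit_circle(pts) == math.inf

    def test_noisy_large_circle(self, rng):
        phi = np.sort(rng.uniform(0, 2 * math.pi, 200))
        pts = 100.0 * np.stack([np.cos(phi), np.sin(phi)], axis=1) \
            + rng.normal(scale=0.5, size=(200, 2))
        assert kv.fit_circle(pts) == pytest.approx(100.0, rel=0.05)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassifyMotion:
    @pytest.mark.parametrize("label", ["linear_forward", "linear_backward",
                                       "circular_forward", "circular_backward"])
    def test_four_archetypes(self, archetypes, label, wide_kink_vesicle,
                             trimer, params):
        mc = kv.classify_motion(archetypes[label], wide_kink_vesicle, trimer,
                                params)
        assert mc.regime == label

    def test_no_kink_is_unbiased(self, params, trimer):
        ves = kv.VesicleSpec(kink_angle=math.pi)
        mem = kv.build_vesicle(ves, params)
        times = np.linspace(0, 50, 51)
        path = np.stack([60 + 0.05 * times, np.full_like(times, 60.0)], axis=1)
        # rods scattered; kink_index nominal
        traj = make_rigid_trajectory(mem, ves.with_(kink_angle=2.0), trimer,
                                     path, np.zeros(51), times,
                                     rods_at_kink=False)
        traj.kink_angle[:] = math.pi
        mc = kv.classify_motion(traj, ves, trimer, params)
        assert mc.regime == "unbiased"

    def test_scattered_rods_unclustered(self, wide_membrane, wide_kink_vesicle,
                                        trimer, params, rng):
        times = np.linspace(0, 50, 51)
        path = np.stack([60 + 0.05 * times, np.full_like(times, 60.0)], axis=1)
        traj = make_rigid_trajectory(wide_membrane, wide_kink_vesicle, trimer,
                                     path, np.zeros(51), times,
                                     rods_at_kink=False, scatter_rng=rng)
        mc = kv.classify_motion(traj, wide_kink_vesicle, trimer, params)
        assert mc.regime == "unclustered"

    def test_translation_invariance(self, archetypes, wide_kink_vesicle,
                                    trimer, params):
        traj = archetypes["circular_forward"]
        shifted = kv.Trajectory(
            times=traj.times, membrane=traj.membrane + 37.0,
            rod_centers=traj.rod_centers + 37.0,
            rod_orientations=traj.rod_orientations,
            rod_active=traj.rod_active, kink_angle=traj.kink_angle,
            energies=traj.energies, box_length=traj.box_length,
            kink_index=traj.kink_index, rod_n_disks=traj.rod_n_disks)
        mc = kv.classify_motion(shifted, wide_kink_vesicle, trimer, params)
        assert mc.regime == "circular_forward"

    def test_dominance_aggregation(self, archetypes, wide_kink_vesicle, trimer,
                                   params):
        mcs = [kv.classify_motion(archetypes["linear_forward"],
                                  wide_kink_vesicle, trimer, params)] * 3 \
            + [kv.classify_motion(archetypes["circular_backward"],
                                  wide_kink_vesicle, trimer, params)]
        modal, dom = kv.regime_dominance(mcs)
        assert modal == "linear_forward"
        assert dom == pytest.approx(0.75)


# ---------------------------------------------------------------------------
# spatial maps, cluster curves, KDE
# ---------------------------------------------------------------------------

class TestSpatialDistribution:
    def test_single_rod_at_vertex_mass_forward(self, wide_membrane,
                                               wide_kink_vesicle, trimer):
        seq = kv.StackingSequence((kv.Slot("left", 0, "parallel"),))
        st = kv.build_frozen_stacking(seq, wide_membrane, trimer,
                                      wide_kink_vesicle)
        times = np.array([0.0, 1.0])
        traj = make_rigid_trajectory(wide_membrane, wide_kink_vesicle, trimer,
                                     np.tile(st.membrane_unwrapped().mean(0),
                                             (2, 1)),
                                     np.zeros(2), times)
        H, xe, ye = kv.spatial_distribution(traj, trimer, bins=20)
        area = (xe[1] - xe[0]) * (ye[1] - ye[0])
        assert H.sum() * area == pytest.approx(1.0, abs=1e-9)
        xc = 0.5 * (xe[:-1] + xe[1:])
        mass_forward = H[xc > 0, :].sum()
        assert mass_forward > 0.99 * H.sum()

    def test_rotation_invariance(self, wide_membrane, wide_kink_vesicle,
                                 trimer):
        times = np.linspace(0, 10, 11)
        path = np.tile([60.0, 60.0], (11, 1))
        t1 = make_rigid_trajectory(wide_membrane, wide_kink_vesicle, trimer,
                                   path, np.zeros(11), times)
        t2 = make_rigid_trajectory(wide_membrane, wide_kink_vesicle, trimer,
                                   path, np.full(11, 1.234), times)
        H1, *_ = kv.spatial_distribution(t1, trimer, bins=16, extent=20.0)
        H2, *_ = kv.spatial_distribution(t2, trimer, bins=16, extent=20.0)
        assert np.allclose(H1, H2, atol=1e-9)


class TestClusterCountCurve:
    def _traj_with_rods(self, wide_membrane, wide_kink_vesicle, trimer,
                        centers):
        st = kv.SystemState(wide_membrane.membrane_positions.copy(),
                            np.asarray(centers, float),
                            np.zeros(len(centers)), wide_membrane.box_length,
                            membrane_images=wide_membrane.membrane_images.copy())
        times = np.linspace(0, 20, 21)
        return self._manual(st, times, wide_membrane, wide_kink_vesicle,
                            trimer)

    def _manual(self, st, times, wide_membrane, wide_kink_vesicle, trimer):
        F = len(times)
        return kv.Trajectory(
            times=times,
            membrane=np.tile(st.membrane_unwrapped(), (F, 1, 1)),
            rod_centers=np.tile(st.rod_centers_unwrapped(), (F, 1, 1)),
            rod_orientations=np.tile(st.rod_orientations, (F, 1)),
            rod_active=np.ones((F, st.n_rods), bool),
            kink_angle=np.full(F, wide_kink_vesicle.kink_angle),
            energies=np.zeros((F, 3)), box_length=st.box_length,
            kink_index=0, rod_n_disks=trimer.n_disks)

    def test_singletons_and_single_cluster(self, wide_membrane,
                                           wide_kink_vesicle, trimer):
        c = wide_membrane.membrane_unwrapped().mean(axis=0)
        # 5 well separated rods
        far = [c + [dx, dy] for dx, dy in
               [(-8, -8), (-8, 8), (8, -8), (8, 8), (0, 0)]]
        t_far = self._traj_with_rods(wide_membrane, wide_kink_vesicle, trimer,
                                     far)
        # 5 rods side by side (one cluster)
        near = [c + [0, 1.05 * k - 2.1] for k in range(5)]
        t_near = self._traj_with_rods(wide_membrane, wide_kink_vesicle, trimer,
                                      near)
        df = kv.cluster_count_curve(
            {(0.05, 5 * math.pi / 6): [t_far, t_far],
             (0.05, math.pi / 2): [t_near, t_near]}, trimer)
        row_far = df[df.theta_kink == 5 * math.pi / 6].iloc[0]
        row_near = df[df.theta_kink == math.pi / 2].iloc[0]
        assert row_far.mean_clusters == pytest.approx(5.0)
        assert row_near.mean_clusters == pytest.approx(1.0)
        assert row_far.sd == 0.0


class TestKDE:
    def test_narrow_peak_for_degenerate_sample(self):
        grid, dens = kv.kde(np.full(50, 3.0))
        assert grid[np.argmax(dens)] == pytest.approx(3.0, abs=0.01)

    def test_matches_normal_pdf(self, rng):
        x = rng.normal(size=10_000)
        grid, dens = kv.kde(x, grid=np.linspace(-4, 4, 200))
        from scipy.stats import norm
        assert np.abs(dens - norm.pdf(grid)).max() < 0.05

    def test_integrates_to_one(self, rng):
        x = rng.normal(size=2000)
        grid, dens = kv.kde(x, grid=np.linspace(-8, 8, 2000))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_bimodal_recovers_two_modes(self, rng):
        x = np.concatenate([rng.normal(-3, 0.5, 3000),
                            rng.normal(3, 0.5, 3000)])
        grid, dens = kv.kde(x, grid=np.linspace(-6, 6, 400))
        from scipy.signal import argrelmax
        peaks = grid[argrelmax(dens, order=20)[0]]
        assert len(peaks) == 2
        assert np.allclose(sorted(peaks), [-3, 3], atol=0.5)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            kv.kde([1.0, 2.0, 3.0])
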