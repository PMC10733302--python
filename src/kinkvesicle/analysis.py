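"""Trajectory descriptors and motion-regime classification.

Implements the full descriptor stack for the vesicle superstructure:

* rod cluster detection (distance-cutoff connected components),
* the kink (symmetry) axis and per-rod alignment angles,
* centroid speed and angular velocity of the superstructure,
* circle fits of the centroid track (Kasa algebraic fit),
* the four-regime motion classification (linear/circular x forward/backward)
  with replica dominance,
* body-frame spatial probability maps and Gaussian KDE curves.

All descriptors are invariant under global translation/rotation of the
trajectory and under rod relabelling; "forward" always means along the unit
vector from the membrane centroid to the kink vertex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .errors import InsufficientDataError, NoKinkAxisError
from .params import RodSpec, SIGMA, SimulationParams, VesicleSpec
from .state import SystemState, Trajectory

__all__ = ["ClusterAssignment", "MotionClassification", "ClassifierThresholds",
           "detect_clusters", "kink_axis", "alignment_angles", "motion_metrics",
           "fit_circle", "classify_motion", "spatial_distribution",
           "cluster_count_curve", "kde", "regime_dominance"]

#: default cluster cutoff: just above the WCA cutoff 2^(1/6) sigma
DEFAULT_CLUSTER_CUTOFF = 1.2 * SIGMA
#: circle radii at or above this value are perceived as linear motion
LINEAR_RADIUS_THRESHOLD = 500.0 * SIGMA


@dataclass
class ClusterAssignment:
    """Partition of the rods into distance-cutoff connected components."""

    labels: np.ndarray          # (N_a,) cluster label per rod
    cutoff: float
    centroids: np.ndarray | None = None   # (n_clusters, 2), body frame if available

    @property
    def n_clusters(self) -> int:
        return 0 if self.labels.size == 0 else int(self.labels.max()) + 1

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    def largest_fraction(self) -> float:
        if self.labels.size == 0:
            return 0.0
        return float(self.sizes.max() / self.labels.size)


@dataclass
class MotionClassification:
    """Regime label plus the quantitative motion descriptors behind it."""

    regime: str                  # unbiased | linear_forward | linear_backward |
                                 # circular_forward | circular_backward | unclustered
    mean_speed: float            # sigma / tau
    normalized_speed: float      # v / v_a
    mean_angular_velocity: float  # rad / tau, signed
    circle_radius: float         # sigma (inf = line)
    clustered_fraction: float    # fraction of window frames passing the cluster rule
    dominance: float = 1.0       # fraction of replicas sharing the modal regime


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds of the four-regime classifier."""

    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF
    min_cluster_fraction: float = 0.5    # largest cluster must hold >= this
    min_frame_fraction: float = 0.5      # ... for at least this share of frames
    linear_radius: float = LINEAR_RADIUS_THRESHOLD
    window: float = 0.5                  # steady-state window (latter fraction)
    cluster_stride: int = 1              # evaluate clusters every n-th frame


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def detect_clusters(state: SystemState, rod_spec: RodSpec,
                    cutoff: float = DEFAULT_CLUSTER_CUTOFF) -> ClusterAssignment:
    """Connected components of the rod contact graph.

    Two rods are connected when any pair of their constituent disks is
    closer than ``cutoff``; clusters are the transitive closure. The result
    is independent of rod ordering (labels are renumbered by first
    occurrence).
    """
    na = state.n_rods
    if na == 0:
        return ClusterAssignment(np.empty(0, dtype=int), cutoff)
    m = rod_spec.n_disks
    disks = state.rod_disk_positions(rod_spec)
    tree = cKDTree(disks)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    ri = pairs[:, 0] // m
    rj = pairs[:, 1] // m
    keep = ri != rj
    graph = sparse.coo_matrix(
        (np.ones(keep.sum()), (ri[keep], rj[keep])), shape=(na, na))
    _, labels = sparse.csgraph.connected_components(graph, directed=False)
    # renumber by first occurrence so labels are permutation-stable
    order = {}
    out = np.empty(na, dtype=int)
    for i, lab in enumerate(labels):
        out[i] = order.setdefault(lab, len(order))
    cen = state.rod_centers_unwrapped()
    centroids = np.array([cen[out == k].mean(axis=0) for k in range(len(order))])
    return ClusterAssignment(out, cutoff, centroids)


# ---------------------------------------------------------------------------
# kink axis and alignment
# ---------------------------------------------------------------------------

def kink_axis(state: SystemState, vesicle: VesicleSpec) -> np.ndarray:
    """Unit vector from the membrane centroid to the kink vertex disk."""
    if not vesicle.has_kink:
        raise NoKinkAxisError(
            "theta_kink = pi: the vesicle has no kink axis")
    mem = state.membrane_unwrapped()
    v = mem[vesicle.kink_index] - mem.mean(axis=0)
    n = np.linalg.norm(v)
    if n == 0:
        raise NoKinkAxisError("kink vertex coincides with the centroid")
    return v / n


def _axis_series(traj: Trajectory, kink_index: int | None = None) -> np.ndarray:
    k = traj.kink_index if kink_index is None else kink_index
    v = traj.membrane[:, k, :] - traj.centroids()
    return v / np.linalg.norm(v, axis=1)[:, None]


def alignment_angles(state: SystemState, clusters: ClusterAssignment,
                     vesicle: VesicleSpec, min_cluster_size: int = 2) -> np.ndarray:
    """Acute angle between each clustered rod's axis and the kink axis.

    Rod axes are head-tail symmetric, so angles live in [0, pi/2]: 0 means
    parallel stacking along the symmetry axis, theta_kink/2 is the signature
    of wall-aligned (angled) stacking.
    """
    axis = kink_axis(state, vesicle)
    sizes = clusters.sizes
    qualifying = np.flatnonzero(sizes[clusters.labels] >= min_cluster_size)
    if qualifying.size == 0:
        return np.empty(0)
    e = state.rod_unit_vectors[qualifying]
    dots = np.abs(e @ axis)
    return np.arccos(np.clip(dots, -1.0, 1.0))


# ---------------------------------------------------------------------------
# motion metrics
# ---------------------------------------------------------------------------

def motion_metrics(traj: Trajectory, window: float = 0.5):
    """Per-frame-pair centroid speeds and kink-axis angular velocities.

    Speeds come from finite differences of the unwrapped membrane centroid;
    the angular velocity is the frame-to-frame increment of the
    (angle-unwrapped) kink-axis orientation. Returns (speeds, omegas, times)
    over the steady-state window.
    """
    sl = traj.window_slice(window)
    if sl.stop - sl.start < 10:
        raise InsufficientDataError(
            f"need >= 10 frames in the window, got {sl.stop - sl.start}")
    c = traj.centroids()[sl]
    t = traj.times[sl]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InsufficientDataError("non-increasing frame times")
    v = np.diff(c, axis=0) / dt[:, None]
    speeds = np.linalg.norm(v, axis=1)
    ax = _axis_series(traj)[sl]
    ang = np.unwrap(np.arctan2(ax[:, 1], ax[:, 0]))
    omegas = np.diff(ang) / dt
    return speeds, omegas, t[:-1]


def fit_circle(traj_or_points, window: float = 0.5) -> float:
    """Kasa algebraic circle fit of the centroid track; radius in sigma.

    Returns ``inf`` when a straight line explains the points at least as
    well as the best circle (collinear tracks have no finite radius).
    """
    if isinstance(traj_or_points, Trajectory):
        pts = traj_or_points.centroids()[traj_or_points.window_slice(window)]
    else:
        pts = np.asarray(traj_or_points, dtype=float)
    if len(pts) < 10:
        raise InsufficientDataError("need >= 10 centroid points")
    x, y = pts[:, 0] - pts[:, 0].mean(), pts[:, 1] - pts[:, 1].mean()
    # line fit (total least squares) residual
    cov = np.cov(np.stack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    line_rms = math.sqrt(max(evals[0], 0.0))
    # Kasa: minimize ||x^2+y^2 - 2ax - 2by - c||
    A = np.stack([2 * x, 2 * y, np.ones_like(x)], axis=1)
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    a, bb, c = sol
    r2 = c + a * a + bb * bb
    if r2 <= 0:
        return math.inf
    radius = math.sqrt(r2)
    circ_rms = float(np.sqrt(np.mean(
        (np.hypot(x - a, y - bb) - radius) ** 2)))
    if line_rms <= circ_rms:
        return math.inf
    return radius


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_motion(traj: Trajectory, vesicle: VesicleSpec, rod_spec: RodSpec,
                    params: SimulationParams,
                    thresholds: ClassifierThresholds | None = None
                    ) -> MotionClassification:
    """Assign one of the six regime labels to a single trajectory.

    Rules, evaluated over the steady-state window: a vesicle without a kink
    is ``unbiased``; a run whose largest rod cluster holds < 50% of the rods
    for more than 50% of the frames is ``unclustered``; otherwise the track
    is ``linear`` when the fitted circle radius is >= 500 sigma and
    ``circular`` below, and ``forward``/``backward`` by the sign of the
    window-mean centroid velocity projected on the kink axis.
    """
    th = thresholds or ClassifierThresholds()
    speeds, omegas, _ = motion_metrics(traj, th.window)
    v_a = rod_spec.with_(active=True).active_speed(
        params.temperature, params.gamma_t)
    mean_speed = float(speeds.mean())
    mean_omega = float(omegas.mean())

    sl = traj.window_slice(th.window)
    frames = range(sl.start, sl.stop, th.cluster_stride)
    clustered = []
    for f in frames:
        ca = detect_clusters(traj.state_at(f), rod_spec, th.cluster_cutoff)
        clustered.append(ca.largest_fraction() >= th.min_cluster_fraction)
    clustered_fraction = float(np.mean(clustered)) if clustered else 0.0

    if not vesicle.has_kink:
        radius = fit_circle(traj, th.window)
        return MotionClassification("unbiased", mean_speed,
                                    mean_speed / v_a if v_a else math.nan,
                                    mean_omega, radius, clustered_fraction)
    if clustered_fraction < th.min_frame_fraction:
        radius = fit_circle(traj, th.window)
        return MotionClassification("unclustered", mean_speed,
                                    mean_speed / v_a if v_a else math.nan,
                                    mean_omega, radius, clustered_fraction)

    radius = fit_circle(traj, th.window)
    c = traj.centroids()
    ax = _axis_series(traj)
    disp = c[sl.stop - 1] - c[sl.start]
    t_span = traj.times[sl.stop - 1] - traj.times[sl.start]
    mean_axis = ax[sl].mean(axis=0)
    forward = float(disp @ mean_axis) / t_span >= 0.0
    kind = "linear" if radius >= th.linear_radius else "circular"
    regime = f"{kind}_{'forward' if forward else 'backward'}"
    return MotionClassification(regime, mean_speed,
                                mean_speed / v_a if v_a else math.nan,
                                mean_omega, radius, clustered_fraction)


def regime_dominance(classifications: Sequence[MotionClassification]
                     ) -> tuple[str, float]:
    """Modal regime across replicas and the fraction sharing it."""
    if not classifications:
        raise InsufficientDataError("no classifications")
    labels = [c.regime for c in classifications]
    modal = max(set(labels), key=labels.count)
    return modal, labels.count(modal) / len(labels)


# ---------------------------------------------------------------------------
# spatial maps, aggregated curves, KDE
# ---------------------------------------------------------------------------

def spatial_distribution(traj: Trajectory, rod_spec: RodSpec, bins: int = 40,
                         extent: float | None = None, window: float = 1.0):
    """Body-frame 2D probability density of the rod constituent disks.

    Every frame is mapped into the frame with the membrane centroid at the
    origin and the kink axis along +x, so the map is invariant under global
    rotation/translation of the trajectory. Normalized so that
    sum(density) * bin_area = 1. Returns (density, xedges, yedges).
    """
    sl = traj.window_slice(window)
    c = traj.centroids()
    ax = _axis_series(traj)
    if extent is None:
        rel = traj.membrane[sl] - c[sl, None, :]
        extent = float(np.abs(rel).max()) * 1.05
    pts = []
    offs = rod_spec.disk_offsets()
    for f in range(sl.start, sl.stop):
        e = np.stack([np.cos(traj.rod_orientations[f]),
                      np.sin(traj.rod_orientations[f])], axis=1)
        disks = (traj.rod_centers[f][:, None, :]
                 + offs[None, :, None] * e[:, None, :]).reshape(-1, 2)
        rel = disks - c[f]
        u, w = ax[f], np.array([-ax[f, 1], ax[f, 0]])
        pts.append(np.stack([rel @ u, rel @ w], axis=1))
    pts = np.concatenate(pts)
    H, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins,
                               range=[[-extent, extent], [-extent, extent]])
    area = (xe[1] - xe[0]) * (ye[1] - ye[0])
    total = H.sum()
    if total > 0:
        H = H / (total * area)
    return H, xe, ye


def cluster_count_curve(ensembles: Mapping[tuple, Iterable[Trajectory]],
                        rod_spec: RodSpec,
                        cutoff: float = DEFAULT_CLUSTER_CUTOFF,
                        window: float = 0.5, stride: int = 1) -> pd.DataFrame:
    """Window-averaged cluster counts per (rho, theta_kink) parameter cell.

    ``ensembles`` maps (rho, theta_kink) -> iterable of replica trajectories.
    Returns a DataFrame with columns rho, theta_kink, mean_clusters, sd,
    n_replicas.
    """
    rows = []
    for (rho, theta), trajs in ensembles.items():
        per_rep = []
        for traj in trajs:
            sl = traj.window_slice(window)
            counts = [detect_clusters(traj.state_at(f), rod_spec, cutoff).n_clusters
                      for f in range(sl.start, sl.stop, stride)]
            per_rep.append(np.mean(counts))
        if len(per_rep) < 2:
            raise InsufficientDataError(
                f"cell (rho={rho}, theta={theta}) needs >= 2 replicas")
        rows.append({"rho": rho, "theta_kink": theta,
                     "mean_clusters": float(np.mean(per_rep)),
                     "sd": float(np.std(per_rep, ddof=1)),
                     "n_replicas": len(per_rep)})
    return pd.DataFrame(rows)


def kde(values: Sequence[float], bandwidth: str | float = "scott",
        grid: np.ndarray | None = None, n_grid: int = 256):
    """Gaussian kernel density estimate (Scott's rule by default).

    Returns (grid, density); the density integrates to ~1 over the support.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 5:
        raise InsufficientDataError("KDE needs at least 5 values")
    spread = values.std()
    if spread == 0:
        # degenerate sample: represent as a narrow peak at the value
        spread = max(1e-3, abs(values[0]) * 1e-3)
        est = gaussian_kde(values + np.linspace(-spread, spread, values.size) * 1e-3)
    else:
        est = gaussian_kde(values, bw_method=bandwidth)
    if grid is None:
        pad = 3.0 * spread + 1e-6
        grid = np.linspace(values.min() - pad, values.max() + pad, n_grid)
    return grid, est(grid)
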