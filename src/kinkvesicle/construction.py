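"""Initial-configuration builders.

The kinked vesicle is constructed as an "ice-cream cone" curve: two straight
arms meeting at the kink vertex with interior angle theta_kink, tangent to a
circular back arc. For a target perimeter P = N_v * b (b = realized bond
length from the WCA/FENE balance) the arc radius follows from

    P = 2 R / tan(theta_kink / 2) + R (pi + theta_kink),

which degenerates to the circle of circumference P at theta_kink = pi.
N_v disks are placed at equal arclength along this curve and relaxed to
mechanical equilibrium with a short zero-noise descent; the relaxed shape is
the elongated teardrop whose long axis runs from centroid to kink vertex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from .dynamics import relax
from .errors import ConstructionError, GeometryError, PackingInfeasibleError
from .params import RodSpec, SIGMA, SimulationParams, VesicleSpec, WCA_CUTOFF
from .state import SystemState

__all__ = ["StackingSequence", "Slot", "realized_bond_length", "build_vesicle",
           "place_rods", "build_frozen_stacking"]


def realized_bond_length(vesicle: VesicleSpec, params: SimulationParams) -> float:
    """Bond length at which the FENE pull balances the WCA push.

    Bonded membrane neighbours are not excluded from WCA, so the realized
    spacing sits between sigma and the WCA cutoff (about 1.1 sigma for the
    default parameters), not at the FENE divergence length r0.
    """
    s = vesicle.disk_diameter
    eps = params.epsilon_wca
    kb = vesicle.bond_strength
    r0 = vesicle.fene_r0
    rc = WCA_CUTOFF * s

    def f(r):
        wca = 24.0 * eps * (2.0 * (s / r) ** 13 - (s / r) ** 7) / s if r < rc else 0.0
        fene = kb * r / (1.0 - (r / r0) ** 2)
        return fene - wca

    lo = 0.9 * s
    hi = min(rc, 0.999 * r0)
    if f(hi) <= 0:
        return hi
    return float(brentq(f, lo, hi))


def _teardrop_points(n: int, b: float, theta_kink: float) -> np.ndarray:
    """n points at equal arclength b along the tangent-arm teardrop curve,
    point 0 at the kink vertex, axis along +x, traversed counterclockwise."""
    P = n * b
    if abs(theta_kink - math.pi) < 1e-9:
        R = P / (2.0 * math.pi)
        ang = 2.0 * math.pi * np.arange(n) / n
        # vertex of the 'no kink' ring sits at +x like the kinked case
        return np.stack([R * np.cos(ang), R * np.sin(ang)], axis=1)
    half = 0.5 * theta_kink
    R = P / (2.0 / math.tan(half) + math.pi + theta_kink)
    D = R / math.sin(half)
    L_arm = R / math.tan(half)
    arc = R * (math.pi + theta_kink)
    V = np.array([D, 0.0])
    dir_up = np.array([math.cos(math.pi - half), math.sin(math.pi - half)])
    T_up = V + L_arm * dir_up
    phi0 = math.atan2(T_up[1], T_up[0])
    pts = np.empty((n, 2))
    for k in range(n):
        sarc = k * b
        if sarc <= L_arm:
            pts[k] = V + sarc * dir_up
        elif sarc <= L_arm + arc:
            phi = phi0 + (sarc - L_arm) / R
            pts[k] = [R * math.cos(phi), R * math.sin(phi)]
        else:
            srem = sarc - L_arm - arc
            dir_dn = np.array([math.cos(math.pi - half), -math.sin(math.pi - half)])
            T_dn = V + L_arm * dir_dn
            pts[k] = T_dn - srem * dir_dn  # walk from T_dn back toward V
    return pts


def membrane_angles(positions: np.ndarray) -> np.ndarray:
    """Interior angle at every disk of a closed ring (unwrapped coords)."""
    prev = np.roll(positions, 1, axis=0)
    nxt = np.roll(positions, -1, axis=0)
    a = prev - positions
    bv = nxt - positions
    cosq = np.einsum("ij,ij->i", a, bv) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(bv, axis=1))
    return np.arccos(np.clip(cosq, -1.0, 1.0))


def build_vesicle(vesicle: VesicleSpec, params: SimulationParams,
                  relax_time: float = 20.0,
                  angle_tolerance: float = 0.01) -> SystemState:
    """Build and relax the membrane ring; returns a membrane-only state.

    The kink vertex points along +x from the vesicle centroid; the ring is
    centred in the box. Raises :class:`ConstructionError` when the relaxed
    kink angle misses ``kink_angle`` by more than ``angle_tolerance`` rad or
    a bond leaves (0, r0).
    """
    if vesicle.kink_angle <= 0:
        raise ConstructionError("kink angle too small to close the ring")
    b = realized_bond_length(vesicle, params)
    pts = _teardrop_points(vesicle.n_disks, b, vesicle.kink_angle)
    pts = np.roll(pts, vesicle.kink_index, axis=0)
    pts = pts - pts.mean(axis=0) + params.box_length / 2.0
    state = SystemState(pts, np.empty((0, 2)), np.empty(0), params.box_length)
    n_steps = int(round(relax_time / params.timestep))
    state = relax(state, vesicle, [], params, n_steps)
    state.time = 0.0

    mem = state.membrane_unwrapped()
    angles = membrane_angles(mem)
    kang = angles[vesicle.kink_index]
    if vesicle.has_kink and abs(kang - vesicle.kink_angle) > angle_tolerance:
        raise ConstructionError(
            f"relaxed kink angle {kang:.4f} misses target "
            f"{vesicle.kink_angle:.4f} by more than {angle_tolerance}")
    bonds = np.linalg.norm(np.roll(mem, -1, axis=0) - mem, axis=1)
    if np.any(bonds <= 0) or np.any(bonds >= vesicle.fene_r0):
        raise ConstructionError("relaxed membrane has an invalid bond length")
    return state


# ---------------------------------------------------------------------------
# rod placement
# ---------------------------------------------------------------------------

def place_rods(membrane_state: SystemState, rod_spec: RodSpec, density: float,
               rng: np.random.Generator | int | None = None,
               max_rejects: int = 100_000) -> SystemState:
    """Place N_a = round(rho * N_v * sigma) rods uniformly inside the membrane.

    Rejection sampling: uniform centre in the membrane polygon, uniform
    orientation; a candidate is rejected whenever any constituent disk comes
    within sigma of a membrane disk or an already placed rod disk, or leaves
    the polygon. Deterministic for a given seed/generator.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    nv = membrane_state.n_membrane
    sigma = SIGMA
    n_rods = int(round(density * nv * sigma))
    if n_rods == 0:
        return membrane_state.copy()
    mem = membrane_state.membrane_unwrapped()
    poly = Polygon(mem).buffer(-1.0 * sigma)
    tree = cKDTree(mem)
    lo = mem.min(axis=0)
    hi = mem.max(axis=0)
    offsets = rod_spec.disk_offsets()
    centers, orients, placed_disks = [], [], []
    rejects = 0
    while len(centers) < n_rods:
        if rejects > max_rejects:
            raise PackingInfeasibleError(
                f"placed {len(centers)}/{n_rods} rods after {rejects} rejects")
        c = lo + rng.random(2) * (hi - lo)
        w = rng.random() * 2.0 * math.pi
        e = np.array([math.cos(w), math.sin(w)])
        disks = c + np.outer(offsets, e)
        ok = all(poly.contains(Point(*d)) for d in disks)
        if ok and np.min(tree.query(disks)[0]) < sigma:
            ok = False
        if ok and placed_disks:
            prev = np.concatenate(placed_disks)
            d2 = np.sum((prev[:, None, :] - disks[None, :, :]) ** 2, axis=2)
            if d2.min() < sigma * sigma:
                ok = False
        if not ok:
            rejects += 1
            continue
        centers.append(c)
        orients.append(w)
        placed_disks.append(disks)
    return SystemState(
        membrane_state.membrane_positions.copy(), np.array(centers),
        np.array(orients), membrane_state.box_length, membrane_state.time,
        membrane_images=membrane_state.membrane_images.copy())


# ---------------------------------------------------------------------------
# frozen stackings
# ---------------------------------------------------------------------------

Side = Literal["left", "right"]
Mode = Literal["wall", "parallel"]


@dataclass(frozen=True)
class Slot:
    side: Side
    index: int          # distance rank from the kink vertex / wall
    mode: Mode = "wall"


@dataclass(frozen=True)
class StackingSequence:
    """An ordered arrangement of rod slots at the kink.

    A sequence and its mirror image are the same equivalence class; the
    canonical form has at least as many slots on the left arm as on the
    right. Asymmetric wall-aligned partitions cause net rotation.
    """

    slots: tuple = ()

    @classmethod
    def from_partition(cls, n_left: int, n_right: int,
                       mode: Mode = "wall") -> "StackingSequence":
        if n_left < n_right:
            n_left, n_right = n_right, n_left
        slots = [Slot("left", j, mode) for j in range(n_left)]
        slots += [Slot("right", j, mode) for j in range(n_right)]
        return cls(tuple(slots))

    @property
    def n_left(self) -> int:
        return sum(1 for s in self.slots if s.side == "left")

    @property
    def n_right(self) -> int:
        return sum(1 for s in self.slots if s.side == "right")

    @property
    def n_rods(self) -> int:
        return len(self.slots)

    @property
    def rotating(self) -> bool:
        """Mirror-asymmetric partitions predict a net rotation."""
        return self.n_left != self.n_right

    @property
    def partition(self) -> tuple[int, int]:
        return (self.n_left, self.n_right)


def kink_frame(membrane_state: SystemState, vesicle: VesicleSpec):
    """(vertex, unit axis centroid->vertex) of the kinked membrane."""
    mem = membrane_state.membrane_unwrapped()
    v = mem[vesicle.kink_index]
    c = mem.mean(axis=0)
    axis = v - c
    n = np.linalg.norm(axis)
    if n == 0:
        raise GeometryError("kink vertex coincides with the centroid")
    return v, axis / n


def build_frozen_stacking(seq: StackingSequence, membrane_state: SystemState,
                          rod_spec: RodSpec, vesicle: VesicleSpec,
                          lateral_spacing: float = 1.0,
                          wall_gap: float = 0.05) -> SystemState:
    """Deterministically place rods in their stacking slots at the kink.

    Wall-aligned slots lie against the (ideal) kink arms at +-theta_kink/2
    from the symmetry axis, self-propulsion pointing into the vertex; stack
    index j offsets a rod one lateral spacing further from its wall, with a
    half-disk stagger along the arm. Parallel slots align with the symmetry
    axis on alternating lateral offsets near the tip. The construction is
    exactly mirror-symmetric for mirror-symmetric sequences. ``wall_gap`` is
    the surface gap between the first rod layer and the wall line (< 0.1
    sigma: the rods touch the membrane).
    """
    if not vesicle.has_kink:
        raise GeometryError("frozen stackings require a kinked vesicle")
    v, axis = kink_frame(membrane_state, vesicle)
    half = 0.5 * vesicle.kink_angle
    m = rod_spec.n_disks
    sigma = SIGMA

    def rot(vec, ang):
        c, s = math.cos(ang), math.sin(ang)
        return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])

    arm = {"left": rot(-axis, -half), "right": rot(-axis, +half)}
    # inward normal of each arm (pointing toward the symmetry axis)
    normal = {"left": rot(arm["left"], +math.pi / 2),
              "right": rot(arm["right"], -math.pi / 2)}
    lat0 = sigma + wall_gap

    centers, orients = [], []
    sin_k = max(math.sin(vesicle.kink_angle), 0.2)
    sin_h = max(math.sin(half), 0.1)
    cos_h = math.cos(half)
    for slot in seq.slots:
        if slot.mode == "wall":
            a = arm[slot.side]
            nrm = normal[slot.side]
            d_lat = lat0 + lateral_spacing * sigma * slot.index
            # deeper layers sit further down the arm so the stack stays
            # inside the wedge (the staircase of the angled stacking) and
            # clears the mirror stack on the opposite arm
            d_long = max(0.5 * m * sigma + 0.7 * sigma,
                         (d_lat + 1.0 * sigma) / sin_k,
                         (0.55 * sigma + d_lat * cos_h) / sin_h
                         + 0.5 * (m - 1) * sigma
                         ) + 0.3 * sigma * slot.index
            c = v + a * d_long + nrm * d_lat
            w = math.atan2(-a[1], -a[0])    # propulsion toward the vertex
        else:
            sign = 1.0 if slot.side == "left" else -1.0
            lat = sign * (0.55 + lateral_spacing * slot.index) * sigma
            nrm = rot(axis, math.pi / 2)
            c = v - axis * (0.5 * m * sigma + 0.9 * sigma
                            + 0.35 * sigma * slot.index) + nrm * lat
            w = math.atan2(axis[1], axis[0])
        centers.append(c)
        orients.append(w)

    centers = np.array(centers).reshape(-1, 2)
    orients = np.array(orients)
    # realizability: all rod disks strictly inside the membrane polygon
    mem = membrane_state.membrane_unwrapped()
    poly = Polygon(mem).buffer(-0.8 * sigma)
    offsets = rod_spec.disk_offsets()
    for c, w in zip(centers, orients):
        e = np.array([math.cos(w), math.sin(w)])
        for d in c + np.outer(offsets, e):
            if not poly.contains(Point(*d)):
                raise GeometryError(
                    f"stacking {seq.partition} unrealizable: rod disk at "
                    f"{d} leaves the membrane interior")
    # no rod-rod overlap
    disks = np.concatenate([
        c + np.outer(offsets, np.array([math.cos(w), math.sin(w)]))
        for c, w in zip(centers, orients)]) if len(centers) else np.empty((0, 2))
    if len(disks) > 1:
        d2 = np.sum((disks[:, None] - disks[None, :]) ** 2, axis=2)
        np.fill_diagonal(d2, np.inf)
        same = np.repeat(np.arange(len(centers)), m)
        d2[same[:, None] == same[None, :]] = np.inf
        if d2.min() < (0.95 * sigma) ** 2:
            raise GeometryError(f"stacking {seq.partition} unrealizable: "
                                "rod footprints overlap")
    return SystemState(
        membrane_state.membrane_positions.copy(), centers, orients,
        membrane_state.box_length, membrane_state.time,
        membrane_images=membrane_state.membrane_images.copy())
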