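"""Interaction force field: WCA, FENE, harmonic angle, active force.

Pair conventions: ``separation`` is always the minimum-image vector from
disk j to disk i, and the returned force is the force ON i (the force on j
is its negative). Scalar helpers (:func:`wca_pair`, :func:`fene_bond`,
:func:`angle_term`) operate on single interactions; :func:`evaluate_forces`
evaluates the whole system with an all-pairs O(N^2) sweep and reduces rod
constituent forces to per-rod net forces and torques. The time-stepping
kernel in :mod:`kinkvesicle._kernel` uses a neighbour list but must agree
with this reference implementation to floating-point roundoff.

Potentials (energies in simulation units):

* WCA: U = 4 eps [(sigma/r)^12 - (sigma/r)^6] + eps for r < rc = 2^(1/6) sigma,
  0 beyond; purely repulsive and continuous at rc.
* FENE: U = -1/2 kappa_b r0^2 ln(1 - (r/r0)^2); attractive, diverges at r0.
* Angle: U = 1/2 kappa_a (theta - theta0)^2 on each consecutive membrane
  triplet, theta measured at the middle disk.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .errors import BondOverstretchError, DegenerateContactError, GeometryError
from .params import RodSpec, SIGMA, SimulationParams, VesicleSpec, WCA_CUTOFF
from .state import ForceTorqueSet, SystemState

__all__ = ["wca_pair", "fene_bond", "angle_term", "active_force",
           "evaluate_forces"]


def wca_pair(separation, epsilon: float, sigma: float = SIGMA):
    """WCA force on i and pair energy for a given j->i separation vector."""
    d = np.asarray(separation, dtype=float)
    r2 = float(d @ d)
    if r2 == 0.0:
        raise DegenerateContactError("exact disk overlap: contact direction undefined")
    rc2 = (WCA_CUTOFF * sigma) ** 2
    if r2 >= rc2:
        return np.zeros(2), 0.0
    s2 = sigma * sigma / r2
    s6 = s2 * s2 * s2
    energy = 4.0 * epsilon * (s6 * s6 - s6) + epsilon
    fmag_over_r = 24.0 * epsilon * (2.0 * s6 * s6 - s6) / r2
    return fmag_over_r * d, energy


def fene_bond(separation, kappa_b: float, r0: float):
    """FENE force on i (attractive, toward j) and bond energy."""
    d = np.asarray(separation, dtype=float)
    r = float(np.hypot(d[0], d[1]))
    if r >= r0:
        raise BondOverstretchError(-1, -1, r, r0)
    x2 = (r / r0) ** 2
    energy = -0.5 * kappa_b * r0 * r0 * math.log1p(-x2)
    # force on i = -dU/dr * rhat, dU/dr = kappa_b r / (1 - x2) > 0
    return (-kappa_b / (1.0 - x2)) * d, energy


def angle_term(p_i, p_k, p_l, kappa_a: float, theta0: float):
    """Harmonic angle forces on a bonded triplet (i, k, l), centred at k.

    Returns (f_i, f_k, f_l, energy). The forces are the exact negative
    gradient of 1/2 kappa (theta - theta0)^2: they sum to zero and exert zero
    net torque about any point. The limit theta -> pi (straight triplet) is
    handled analytically.
    """
    a = np.asarray(p_i, float) - np.asarray(p_k, float)
    b = np.asarray(p_l, float) - np.asarray(p_k, float)
    ra = math.hypot(a[0], a[1])
    rb = math.hypot(b[0], b[1])
    if ra == 0.0 or rb == 0.0:
        raise GeometryError("zero-length angle arm")
    cosq = float(a @ b) / (ra * rb)
    cosq = max(-1.0, min(1.0, cosq))
    theta = math.acos(cosq)
    energy = 0.5 * kappa_a * (theta - theta0) ** 2
    sinq = math.sqrt(max(0.0, 1.0 - cosq * cosq))
    # force prefactor +kappa (theta - theta0)/sin(theta); the straight-chain
    # limit theta -> theta0 = pi is removable: (theta-pi)/sin(theta) -> -1
    if sinq >= 1.0e-8:
        coeff = kappa_a * (theta - theta0) / sinq
    elif abs(theta - theta0) < 1.0e-6:
        coeff = -kappa_a if cosq < 0.0 else kappa_a
    else:
        # exact collinearity away from the rest angle: cusp of the energy;
        # clamp the prefactor (direction below is ~0 length anyway)
        coeff = kappa_a * (theta - theta0) / 1.0e-8
    ahat = a / ra
    bhat = b / rb
    f_i = coeff * (bhat - cosq * ahat) / ra
    f_l = coeff * (ahat - cosq * bhat) / rb
    f_k = -(f_i + f_l)
    return f_i, f_k, f_l, energy


def active_force(rod: RodSpec, orientation: float, temperature: float) -> np.ndarray:
    """Self-propulsion force F_A (cos w, sin w); zero for inactive rods."""
    fa = rod.active_force(temperature)
    return np.array([fa * math.cos(orientation), fa * math.sin(orientation)])


# ---------------------------------------------------------------------------
# full-system reference evaluation
# ---------------------------------------------------------------------------

def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def _all_disks(state: SystemState, rods: Sequence[RodSpec]):
    """Concatenate membrane + rod constituent disks; return (pos, body ids)."""
    nv = state.n_membrane
    mem = state.membrane_positions
    if state.n_rods:
        rod_disks = state.rod_disk_positions(rods, wrapped=False)
        pos = np.concatenate([mem, rod_disks % state.box_length], axis=0)
        body = np.concatenate([
            np.arange(nv),
            nv + np.repeat(np.arange(state.n_rods),
                           [r.n_disks for r in rods])])
    else:
        pos = mem.copy()
        body = np.arange(nv)
    return pos, body


def evaluate_forces(state: SystemState, vesicle: VesicleSpec,
                    rods: Sequence[RodSpec] | RodSpec,
                    params: SimulationParams) -> ForceTorqueSet:
    """Evaluate every force-field term for ``state`` (all-pairs reference).

    WCA acts between every disk pair except pairs within the same rigid body
    (rod-internal pairs and, in rigid-kink mode, kink-triplet-internal pairs).
    FENE-bonded membrane neighbours are NOT excluded from WCA; their realized
    bond length emerges from the WCA/FENE balance. FENE and angle terms act on
    the membrane ring; the active force acts at each rod centre along its axis
    and contributes no torque.
    """
    if isinstance(rods, RodSpec):
        rods = [rods] * state.n_rods
    rods = list(rods)
    if len(rods) != state.n_rods:
        raise ValueError("need one RodSpec per rod")
    nv, na = state.n_membrane, state.n_rods
    box = state.box_length
    eps, sigma = params.epsilon_wca, vesicle.disk_diameter

    pos, body = _all_disks(state, rods)
    nd = len(pos)
    if vesicle.rigid_kink and vesicle.has_kink:
        k = vesicle.kink_index
        trip = [(k - 1) % nv, k, (k + 1) % nv]
        body = body.copy()
        body[trip] = body[trip[1]]  # one rigid body for WCA exclusion

    forces = np.zeros((nd, 2))
    # -- WCA, all pairs ---------------------------------------------------
    d = _min_image(pos[:, None, :] - pos[None, :, :], box)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    iu, ju = np.triu_indices(nd, k=1)
    mask = (r2[iu, ju] < (WCA_CUTOFF * sigma) ** 2) & (body[iu] != body[ju])
    pi, pj = iu[mask], ju[mask]
    r2p = r2[pi, pj]
    if np.any(r2p == 0.0):
        bad = int(np.argmin(r2p))
        raise DegenerateContactError(
            f"exact overlap of disks {pi[bad]} and {pj[bad]}")
    s2 = sigma * sigma / r2p
    s6 = s2 ** 3
    e_wca = float(np.sum(4.0 * eps * (s6 * s6 - s6) + eps))
    fmag = (24.0 * eps * (2.0 * s6 * s6 - s6) / r2p)[:, None] * d[pi, pj]
    np.add.at(forces, pi, fmag)
    np.add.at(forces, pj, -fmag)

    # -- FENE ring bonds ---------------------------------------------------
    if nv and nv != vesicle.n_disks:
        raise ValueError("state/membrane disk count mismatch")
    e_fene = 0.0
    e_angle = 0.0
    if nv == 0:
        membrane_forces = forces[:0]
        return _reduce_rods(state, rods, params, forces, nv, na,
                            membrane_forces, e_wca, e_fene, e_angle)
    nxt = (np.arange(nv) + 1) % nv
    db = _min_image(pos[:nv] - pos[nxt], box)   # vector j+1 -> j? (i - j)
    rb = np.hypot(db[:, 0], db[:, 1])
    if np.any(rb >= vesicle.fene_r0):
        j = int(np.argmax(rb))
        raise BondOverstretchError(j, int(nxt[j]), float(rb[j]), vesicle.fene_r0)
    x2 = (rb / vesicle.fene_r0) ** 2
    e_fene = float(np.sum(-0.5 * vesicle.bond_strength * vesicle.fene_r0 ** 2
                          * np.log1p(-x2)))
    fb = (-vesicle.bond_strength / (1.0 - x2))[:, None] * db
    np.add.at(forces, np.arange(nv), fb)
    np.add.at(forces, nxt, -fb)

    # -- angle terms -------------------------------------------------------
    trips = vesicle.triplets()
    rest = vesicle.angle_rest_angles()
    kap = vesicle.angle_stiffnesses()
    keep = np.ones(nv, dtype=bool)
    if vesicle.rigid_kink and vesicle.has_kink:
        keep[vesicle.kink_index] = False   # fixed triplet carries no angle term
    e_angle = 0.0
    for t, th0, ka, use in zip(trips, rest, kap, keep):
        if not use:
            continue
        i, k, l = (int(x) for x in t)
        a = _min_image(pos[i] - pos[k], box)
        b = _min_image(pos[l] - pos[k], box)
        f_i, f_k, f_l, en = angle_term(a, (0.0, 0.0), b, ka, th0)
        forces[i] += f_i
        forces[k] += f_k
        forces[l] += f_l
        e_angle += en

    # -- reduce to bodies --------------------------------------------------
    membrane_forces = forces[:nv]
    return _reduce_rods(state, rods, params, forces, nv, na, membrane_forces,
                        e_wca, e_fene, e_angle)


def _reduce_rods(state, rods, params, forces, nv, na, membrane_forces,
                 e_wca, e_fene, e_angle):
    rod_forces = np.zeros((na, 2))
    rod_torques = np.zeros(na)
    active_vecs = np.zeros((na, 2))
    ptr = nv
    cen_un = state.rod_centers_unwrapped()
    e_hat = state.rod_unit_vectors
    for i, spec in enumerate(rods):
        m = spec.n_disks
        f = forces[ptr:ptr + m]
        offs = np.outer(spec.disk_offsets(), e_hat[i])   # exact body-frame offsets
        rod_forces[i] = f.sum(axis=0)
        rod_torques[i] = float(np.sum(offs[:, 0] * f[:, 1] - offs[:, 1] * f[:, 0]))
        fa = active_force(spec, state.rod_orientations[i], params.temperature)
        active_vecs[i] = fa
        rod_forces[i] += fa
        ptr += m

    active_power = float(np.sum(np.einsum("ij,ij->i", active_vecs,
                                          rod_forces) / params.gamma_t)) if na else 0.0
    energies = {"wca": e_wca, "fene": e_fene, "angle": e_angle,
                "active_power": active_power, "_active_vectors": active_vecs}
    return ForceTorqueSet(membrane_forces, rod_forces, rod_torques, energies)
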