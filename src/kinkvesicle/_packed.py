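"""Packed array representation driving the numba kernel.

`PackedSystem` owns the flat body/disk arrays for one replica and advances
them chunk-wise through :func:`kinkvesicle._kernel.run_chunk`. One instance
corresponds to one (state, vesicle, rods, params) combination; protocol
events mutate it in place between chunks.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from . import _kernel
from .errors import BondOverstretchError, DegenerateContactError, IntegrationError
from .params import RodSpec, SimulationParams, VesicleSpec
from .state import SystemState

_MAX_CHUNK = 20_000          # steps per kernel call (bounds the noise buffer)
_PAIR_CAPACITY_PER_DISK = 24


def _min_image(d, box):
    return d - box * np.round(d / box)


class PackedSystem:
    def __init__(self, state: SystemState, vesicle: VesicleSpec,
                 rods: Sequence[RodSpec], params: SimulationParams):
        if isinstance(rods, RodSpec):
            rods = [rods] * state.n_rods
        rods = list(rods)
        if len(rods) != state.n_rods:
            raise ValueError("need one RodSpec per rod")
        self.vesicle = vesicle
        self.rods = rods
        self.params = params
        self.box = float(state.box_length)
        self.time = float(state.time)

        nv, na = state.n_membrane, state.n_rods
        self.nv, self.na = nv, na
        rigid_kink = vesicle.rigid_kink and vesicle.has_kink and nv > 0
        self.rigid_kink = rigid_kink
        kidx = vesicle.kink_index
        ktrip = [(kidx - 1) % nv, kidx, (kidx + 1) % nv] if nv else []
        self._ktrip = ktrip

        # ---- disks -------------------------------------------------------
        nd = nv + sum(r.n_disks for r in rods)
        self.nd = nd
        disk_body = np.empty(nd, dtype=np.int64)
        loc = np.zeros((nd, 2))

        # ---- bodies ------------------------------------------------------
        # membrane free disks keep body index == disk index except that in
        # rigid-kink mode the triplet collapses onto one body.
        mem_un = state.membrane_unwrapped()
        bodies_cen: list[np.ndarray] = []
        bodies_theta: list[float] = []
        bodies_img: list[np.ndarray] = []
        gam_t: list[float] = []
        gam_r: list[float] = []
        rotates: list[int] = []
        f_act: list[float] = []

        self._kink_body = -1
        mem_body_of_disk = {}
        if rigid_kink:
            # kink triplet as one rigid body, unit-mass per-disk drags summed
            rel = _min_image(mem_un[ktrip] - mem_un[kidx], self.box) + mem_un[kidx]
            cen = rel.mean(axis=0)
            b = len(bodies_cen)
            self._kink_body = b
            for d, p in zip(ktrip, rel):
                mem_body_of_disk[d] = b
                loc[d] = p - cen
            bodies_cen.append(cen % self.box)
            bodies_img.append(np.floor(cen / self.box).astype(np.int64))
            bodies_theta.append(0.0)
            gam_t.append(3.0 * params.gamma_t)
            gam_r.append(params.gamma_t * float(np.sum(np.sum((rel - cen) ** 2, axis=1))))
            rotates.append(1)
            f_act.append(0.0)
        for d in range(nv):
            if d in mem_body_of_disk:
                disk_body[d] = mem_body_of_disk[d]
                continue
            b = len(bodies_cen)
            disk_body[d] = b
            bodies_cen.append(state.membrane_positions[d].copy())
            bodies_img.append(state.membrane_images[d].copy())
            bodies_theta.append(0.0)
            gam_t.append(params.gamma_t)
            gam_r.append(params.gamma_r)
            rotates.append(0)
            f_act.append(0.0)
        for d in ktrip:
            if rigid_kink:
                disk_body[d] = mem_body_of_disk[d]

        self._rod_body = np.empty(na, dtype=np.int64)
        ptr = nv
        for i, spec in enumerate(rods):
            b = len(bodies_cen)
            self._rod_body[i] = b
            m = spec.n_disks
            disk_body[ptr:ptr + m] = b
            loc[ptr:ptr + m, 0] = spec.disk_offsets()
            ptr += m
            bodies_cen.append(state.rod_centers[i].copy())
            bodies_img.append(state.rod_images[i].copy())
            bodies_theta.append(float(state.rod_orientations[i]))
            gam_t.append(params.gamma_t)
            gam_r.append(params.gamma_r)
            rotates.append(1)
            f_act.append(spec.active_force(params.temperature))

        self.cen = np.array(bodies_cen, dtype=float).reshape(-1, 2)
        self.theta = np.array(bodies_theta, dtype=float)
        self.img = np.array(bodies_img, dtype=np.int64).reshape(-1, 2)
        self.gam_t = np.array(gam_t, dtype=float)
        self.gam_r = np.array(gam_r, dtype=float)
        self.rotates = np.array(rotates, dtype=np.int64)
        self.f_act = np.array(f_act, dtype=float)
        self.disk_body = disk_body
        self.loc = loc
        self.rot_body = np.flatnonzero(self.rotates).astype(np.int64)
        self.nb = len(self.cen)

        # ---- bonded lists -------------------------------------------------
        if nv == 0:
            # free bodies only (validation runs without a membrane)
            self.bond_i = np.empty(0, dtype=np.int64)
            self.bond_j = np.empty(0, dtype=np.int64)
            self.ang_i = np.empty(0, dtype=np.int64)
            self.ang_k = np.empty(0, dtype=np.int64)
            self.ang_l = np.empty(0, dtype=np.int64)
            self.ang_theta0 = np.empty(0)
            self.ang_kappa = np.empty(0)
            self.kink_aidx = -1
        else:
            if nv != vesicle.n_disks:
                raise ValueError("state/membrane disk count mismatch")
            idx = np.arange(nv)
            self.bond_i = idx.astype(np.int64)
            self.bond_j = ((idx + 1) % nv).astype(np.int64)
            trips = vesicle.triplets()
            rest = vesicle.angle_rest_angles()
            kap = vesicle.angle_stiffnesses()
            keep = np.ones(nv, dtype=bool)
            if rigid_kink:
                keep[kidx] = False
            self.ang_i = trips[keep, 0].astype(np.int64)
            self.ang_k = trips[keep, 1].astype(np.int64)
            self.ang_l = trips[keep, 2].astype(np.int64)
            self.ang_theta0 = rest[keep].astype(float)
            self.ang_kappa = kap[keep].astype(float)
            if rigid_kink:
                self.kink_aidx = -1
            else:
                self.kink_aidx = int(np.flatnonzero(trips[keep, 1] == kidx)[0])

        # ---- workspaces ---------------------------------------------------
        self.pos = np.zeros((nd, 2))
        self.pos_ref = np.full((nd, 2), np.inf)
        self.forces = np.zeros((nd, 2))
        cap = _PAIR_CAPACITY_PER_DISK * nd
        self.pair_i = np.zeros(cap, dtype=np.int64)
        self.pair_j = np.zeros(cap, dtype=np.int64)
        self.last_energies = (np.nan, np.nan, np.nan)
        #: count of displacement-cap events (numerical spike guard)
        self.n_capped = 0

    # ------------------------------------------------------------------
    @property
    def nnoise(self) -> int:
        return 2 * self.nb + len(self.rot_body)

    def kink_rest_angle(self) -> float:
        if self.kink_aidx >= 0:
            return float(self.ang_theta0[self.kink_aidx])
        if self.rigid_kink:
            return self._rigid_kink_angle
        return self.vesicle.kink_angle

    def set_active(self, species: str, active: bool) -> int:
        """Toggle the activity flag of all rods of ``species``; returns count."""
        n = 0
        for i, spec in enumerate(self.rods):
            if spec.species == species:
                self.rods[i] = spec.with_(active=active)
                self.f_act[self._rod_body[i]] = self.rods[i].active_force(
                    self.params.temperature)
                n += 1
        return n

    def set_kink_angle(self, theta: float) -> None:
        if self.kink_aidx >= 0:
            self.ang_theta0[self.kink_aidx] = theta
        else:
            self._set_rigid_kink_angle(theta)
        self.vesicle = self.vesicle.with_(kink_angle=theta)

    @property
    def _rigid_kink_angle(self) -> float:
        a = self.loc[self._ktrip[0]] - self.loc[self._ktrip[1]]
        b = self.loc[self._ktrip[2]] - self.loc[self._ktrip[1]]
        c = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        return math.acos(max(-1.0, min(1.0, c)))

    def _set_rigid_kink_angle(self, theta: float) -> None:
        """Re-pose the rigid kink triplet: rotate both arms symmetrically
        about the vertex disk, keeping bond lengths and the vertex position."""
        i0, k0, l0 = self._ktrip
        a = self.loc[i0] - self.loc[k0]
        b = self.loc[l0] - self.loc[k0]
        cur = self._rigid_kink_angle
        d = 0.5 * (theta - cur)
        sign = 1.0 if (a[0] * b[1] - a[1] * b[0]) >= 0 else -1.0
        rot = lambda v, ang: np.array([
            v[0] * math.cos(ang) - v[1] * math.sin(ang),
            v[0] * math.sin(ang) + v[1] * math.cos(ang)])
        vertex = self.loc[k0].copy()
        self.loc[i0] = vertex + rot(a, -sign * d)
        self.loc[l0] = vertex + rot(b, sign * d)
        # recentre the body frame so the centre stays the disks' centroid
        shift = (self.loc[self._ktrip]).mean(axis=0)
        for dd in self._ktrip:
            self.loc[dd] -= shift
        bdy = self._kink_body
        c, s = math.cos(self.theta[bdy]), math.sin(self.theta[bdy])
        self.cen[bdy] += np.array([c * shift[0] - s * shift[1],
                                   s * shift[0] + c * shift[1]])
        self.pos_ref[:] = np.inf  # force neighbour-list rebuild

    # ------------------------------------------------------------------
    def advance(self, nsteps: int, rng: np.random.Generator | None,
                dtheta_step: float = 0.0,
                temperature: float | None = None) -> None:
        """Run ``nsteps`` integrator steps (chunked), updating in place."""
        p = self.params
        kT = p.temperature if temperature is None else temperature
        done = 0
        while done < nsteps:
            n = min(_MAX_CHUNK, nsteps - done)
            if kT > 0.0:
                if rng is None:
                    raise ValueError("temperature > 0 requires an rng")
                # float32 draws: noise amplitudes are ~1e-3 sigma, so single
                # precision is far below the physical scale; generation is
                # ~1.5x faster than float64
                noise = rng.standard_normal((n, self.nnoise), dtype=np.float32)
            else:
                noise = np.zeros((1, 1), dtype=np.float32)
            err, eidx, npairs, ew, ef, ea, ncap = _kernel.run_chunk(
                self.cen, self.theta, self.img, self.gam_t, self.gam_r,
                self.rotates, self.f_act,
                self.disk_body, self.loc, self.pos, self.pos_ref,
                self.bond_i, self.bond_j,
                float(self.vesicle.bond_strength), float(self.vesicle.fene_r0),
                self.ang_i, self.ang_k, self.ang_l,
                self.ang_theta0, self.ang_kappa,
                self.kink_aidx, dtheta_step,
                float(p.epsilon_wca), float(self.vesicle.disk_diameter),
                self.box, float(p.timestep), float(kT),
                noise, self.rot_body,
                self.pair_i, self.pair_j, self.forces,
                n,
            )
            if err == _kernel.ERR_OVERSTRETCH:
                i = int(self.bond_i[eidx])
                raise BondOverstretchError(i, int(self.bond_j[eidx]),
                                           float("nan"), self.vesicle.fene_r0)
            if err == _kernel.ERR_OVERLAP:
                raise DegenerateContactError(f"exact disk overlap at disk {eidx}")
            if err != _kernel.ERR_OK:
                raise IntegrationError(
                    f"non-finite force/displacement at body {eidx}, "
                    f"t = {self.time:.6g} tau")
            done += n
            self.time += n * p.timestep
            self.last_energies = (ew, ef, ea)
            self.n_capped += int(ncap)

    # ------------------------------------------------------------------
    def to_state(self) -> SystemState:
        nv, na = self.nv, self.na
        mem = np.empty((nv, 2))
        mem_img = np.empty((nv, 2), dtype=np.int64)
        for d in range(nv):
            b = self.disk_body[d]
            if self.rotates[b] == 1:    # rigid kink body
                c, s = math.cos(self.theta[b]), math.sin(self.theta[b])
                off = np.array([c * self.loc[d, 0] - s * self.loc[d, 1],
                                s * self.loc[d, 0] + c * self.loc[d, 1]])
                x = self.cen[b] + off
                mem[d] = x % self.box
                mem_img[d] = self.img[b] + np.floor(x / self.box).astype(np.int64)
            else:
                mem[d] = self.cen[b]
                mem_img[d] = self.img[b]
        rb = self._rod_body
        return SystemState(
            mem, self.cen[rb].copy() if na else np.empty((0, 2)),
            self.theta[rb].copy() if na else np.empty(0),
            self.box, self.time,
            membrane_images=mem_img,
            rod_images=self.img[rb].copy() if na else np.empty((0, 2), dtype=np.int64),
        )
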