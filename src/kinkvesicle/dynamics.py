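"""Overdamped Brownian dynamics and time-dependent protocols.

The equations of motion are first-order (Euler-Maruyama): for every body
(membrane disk or rigid rod)

    dr = (F_net / gamma) dt + sqrt(2 (k_BT/gamma) dt) xi,
    dw = (T_net / gamma_r) dt + sqrt(2 (k_BT/gamma_r) dt) zeta,

with independent standard normals xi, zeta per step. :func:`brownian_step`
applies a single step to an explicit :class:`ForceTorqueSet` (useful for
validation against external potentials); :func:`run` is the production path
that iterates force evaluation + stepping inside the compiled kernel and
records frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._packed import PackedSystem
from .errors import ConfigError, IntegrationError, KinkVesicleError
from .forcefield import evaluate_forces
from .params import RodSpec, SimulationParams, VesicleSpec
from .state import ForceTorqueSet, SystemState, Trajectory

__all__ = ["NoiseModel", "Protocol", "ActivationEvent", "KinkRampEvent",
           "brownian_step", "run", "relax", "apply_protocol_event",
           "switchable_loop_protocol"]


@dataclass
class NoiseModel:
    """Seeded Gaussian white-noise stream for one replica.

    Translational displacement noise has per-component standard deviation
    sqrt(2 (k_BT/gamma) dt); rotational noise sqrt(2 (k_BT/gamma_r) dt).
    Distinct seeds give independent streams; the same seed reproduces the
    trajectory bit for bit.
    """

    seed: int = 0
    _rng: np.random.Generator | None = field(default=None, repr=False)

    @property
    def rng(self) -> np.random.Generator:
        if self._rng is None:
            self._rng = np.random.Generator(np.random.SFC64(self.seed))
        return self._rng

    @staticmethod
    def translational_sigma(params: SimulationParams) -> float:
        return math.sqrt(2.0 * params.temperature / params.gamma_t
                         * params.timestep)

    @staticmethod
    def rotational_sigma(params: SimulationParams) -> float:
        return math.sqrt(2.0 * params.temperature / params.gamma_r
                         * params.timestep)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivationEvent:
    """Switch the activity of all rods of one species on or off at ``time``."""
    time: float
    species: str
    active: bool


@dataclass(frozen=True)
class KinkRampEvent:
    """Linearly ramp the kink rest angle over [time, time_end]."""
    time: float
    time_end: float
    theta_start: float
    theta_end: float

    def angle_at(self, t: float) -> float:
        if t <= self.time:
            return self.theta_start
        if t >= self.time_end:
            return self.theta_end
        f = (t - self.time) / (self.time_end - self.time)
        return self.theta_start + f * (self.theta_end - self.theta_start)


@dataclass
class Protocol:
    """Ordered schedule of activation toggles and kink-angle ramps."""

    events: list = field(default_factory=list)

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.time)
        ramps = self.ramps()
        for a, b in zip(ramps, ramps[1:]):
            if b.time < a.time_end - 1e-12:
                raise ConfigError("overlapping kink ramps are not allowed")
        for r in ramps:
            if r.time_end <= r.time:
                raise ConfigError("ramp must have time_end > time")

    def activations(self) -> list[ActivationEvent]:
        return [e for e in self.events if isinstance(e, ActivationEvent)]

    def ramps(self) -> list[KinkRampEvent]:
        return [e for e in self.events if isinstance(e, KinkRampEvent)]

    def active_ramp(self, t: float) -> KinkRampEvent | None:
        for r in self.ramps():
            if r.time - 1e-12 <= t < r.time_end - 1e-12:
                return r
        return None


def switchable_loop_protocol(t0: float, dwell: float, ramp_time: float,
                             species: str = "B",
                             theta_wide: float = 5 * math.pi / 6,
                             theta_narrow: float = math.pi / 2) -> Protocol:
    """The four-phase switching loop: activate a second rod species, narrow
    the kink, deactivate the species again, widen the kink back."""
    return Protocol([
        ActivationEvent(t0, species, True),
        KinkRampEvent(t0 + dwell, t0 + dwell + ramp_time,
                      theta_wide, theta_narrow),
        ActivationEvent(t0 + 2 * dwell + ramp_time, species, False),
        KinkRampEvent(t0 + 3 * dwell + ramp_time, t0 + 3 * dwell + 2 * ramp_time,
                      theta_narrow, theta_wide),
    ])


def apply_protocol_event(vesicle: VesicleSpec, rods: Sequence[RodSpec],
                         event, time: float | None = None):
    """Apply one protocol event to the specs; returns (vesicle, rods).

    Activation toggles flip the ``active`` flag of every rod of the species;
    a ramp event evaluated at ``time`` sets the kink rest angle to the
    linearly interpolated value. Never moves any particle.
    """
    rods = list(rods)
    if isinstance(event, ActivationEvent):
        if not any(r.species == event.species for r in rods):
            raise ConfigError(f"unknown rod species {event.species!r}")
        rods = [r.with_(active=event.active) if r.species == event.species else r
                for r in rods]
        return vesicle, rods
    if isinstance(event, KinkRampEvent):
        t = event.time if time is None else time
        return vesicle.with_(kink_angle=event.angle_at(t)), rods
    raise ConfigError(f"unknown protocol event {event!r}")


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def brownian_step(state: SystemState, forces: ForceTorqueSet,
                  params: SimulationParams,
                  noise: NoiseModel | None = None) -> SystemState:
    """One Euler-Maruyama step from explicitly supplied forces and torques."""
    dt = params.timestep
    new = state.copy()
    disp_m = forces.membrane_forces / params.gamma_t * dt
    if state.n_rods:
        disp_r = forces.rod_forces / params.gamma_t * dt
        drot = forces.rod_torques / params.gamma_r * dt
    else:
        disp_r = np.empty((0, 2))
        drot = np.empty(0)
    if params.temperature > 0.0:
        if noise is None:
            raise ValueError("temperature > 0 requires a NoiseModel")
        st = NoiseModel.translational_sigma(params)
        sr = NoiseModel.rotational_sigma(params)
        disp_m = disp_m + st * noise.rng.standard_normal(disp_m.shape)
        if state.n_rods:
            disp_r = disp_r + st * noise.rng.standard_normal(disp_r.shape)
            drot = drot + sr * noise.rng.standard_normal(drot.shape)
    if not (np.all(np.isfinite(disp_m)) and np.all(np.isfinite(disp_r))):
        raise IntegrationError("non-finite displacement", frame_index=None)
    box = state.box_length
    mem = state.membrane_positions + disp_m
    shift = np.floor(mem / box).astype(np.int64)
    new.membrane_positions = mem - shift * box
    new.membrane_images = state.membrane_images + shift
    if state.n_rods:
        cen = state.rod_centers + disp_r
        shift = np.floor(cen / box).astype(np.int64)
        new.rod_centers = cen - shift * box
        new.rod_images = state.rod_images + shift
        new.rod_orientations = state.rod_orientations + drot
    new.time = state.time + dt
    return new


def _record(frames: dict, packed: PackedSystem, energies=None):
    st = packed.to_state()
    frames["times"].append(packed.time)
    frames["membrane"].append(st.membrane_unwrapped())
    frames["rod_centers"].append(st.rod_centers_unwrapped())
    frames["rod_orientations"].append(st.rod_orientations.copy())
    frames["rod_active"].append(np.array([r.active for r in packed.rods], bool))
    frames["kink_angle"].append(packed.kink_rest_angle())
    frames["energies"].append(
        packed.last_energies if energies is None else energies)


def _make_traj(frames: dict, packed: PackedSystem, metadata: dict,
               complete: bool) -> Trajectory:
    return Trajectory(
        times=np.array(frames["times"]),
        membrane=np.array(frames["membrane"]),
        rod_centers=np.array(frames["rod_centers"]),
        rod_orientations=np.array(frames["rod_orientations"]),
        rod_active=np.array(frames["rod_active"]),
        kink_angle=np.array(frames["kink_angle"]),
        energies=np.array(frames["energies"], dtype=float),
        box_length=packed.box,
        kink_index=packed.vesicle.kink_index,
        rod_n_disks=packed.rods[0].n_disks if packed.rods else 0,
        metadata=metadata,
        complete=complete,
    )


def run(initial: SystemState, vesicle: VesicleSpec,
        rods: Sequence[RodSpec] | RodSpec, params: SimulationParams,
        protocol: Protocol | None = None, output_stride: int = 10_000,
        noise: NoiseModel | None = None) -> Trajectory:
    """Integrate for ``params.duration`` tau, recording every ``output_stride``
    steps (the initial state is always frame 0).

    Protocol events are applied at their scheduled times: activation toggles
    change the active force between steps, kink ramps move the kink rest
    angle every step. On an integration failure the partial trajectory is
    attached to the raised :class:`IntegrationError` and flagged incomplete.
    """
    if output_stride < 1:
        raise ValueError("output_stride must be >= 1")
    protocol = protocol or Protocol()
    packed = PackedSystem(initial, vesicle, rods, params)
    noise = noise or NoiseModel(params.seed)
    dt = params.timestep
    t0 = packed.time
    n_total = int(round(params.duration / dt))

    # apply any events scheduled at or before t0
    for ev in protocol.activations():
        if ev.time <= t0 + 1e-12:
            packed.set_active(ev.species, ev.active)

    e0 = evaluate_forces(packed.to_state(), packed.vesicle, packed.rods, params)
    frames = {k: [] for k in ("times", "membrane", "rod_centers",
                              "rod_orientations", "rod_active", "kink_angle",
                              "energies")}
    metadata = {"seed": noise.seed, "output_stride": output_stride,
                "params": params, "vesicle": vesicle, "rods": list(packed.rods),
                "protocol": protocol}
    _record(frames, packed,
            energies=(e0.energies["wca"], e0.energies["fene"], e0.energies["angle"]))

    # segment boundaries (step indices): frames + protocol event edges
    bounds = set(range(output_stride, n_total + 1, output_stride))
    bounds.add(n_total)
    bounds.discard(0)          # the initial frame is already recorded
    for ev in protocol.activations():
        s = int(round((ev.time - t0) / dt))
        if 0 < s <= n_total:
            bounds.add(s)
    for r in protocol.ramps():
        for tt in (r.time, r.time_end):
            s = int(round((tt - t0) / dt))
            if 0 < s <= n_total:
                bounds.add(s)
    bounds = sorted(bounds)

    s_cur = 0
    try:
        for s_next in bounds:
            nsteps = s_next - s_cur
            if nsteps > 0:
                t_now = t0 + s_cur * dt
                ramp = protocol.active_ramp(t_now)
                dth = 0.0
                if ramp is not None:
                    packed.set_kink_angle(ramp.angle_at(t_now))
                    if packed.kink_aidx >= 0:
                        dth = (ramp.theta_end - ramp.theta_start) \
                            / ((ramp.time_end - ramp.time) / dt)
                packed.advance(nsteps, noise.rng, dtheta_step=dth)
                if ramp is not None and packed.kink_aidx < 0:
                    # rigid kink: re-pose at segment boundaries
                    packed.set_kink_angle(ramp.angle_at(packed.time))
            s_cur = s_next
            t_now = t0 + s_cur * dt
            for ev in protocol.activations():
                if abs(ev.time - t_now) < 0.5 * dt:
                    packed.set_active(ev.species, ev.active)
            ramp = protocol.active_ramp(t_now)
            if ramp is None:
                for r in protocol.ramps():
                    if abs(r.time_end - t_now) < 0.5 * dt:
                        packed.set_kink_angle(r.theta_end)
            if s_cur % output_stride == 0 or s_cur == n_total:
                _record(frames, packed)
    except KinkVesicleError as exc:
        metadata["n_capped"] = packed.n_capped
        traj = _make_traj(frames, packed, metadata, complete=False)
        raise IntegrationError(
            f"integration failed at t = {packed.time:.6g} tau: {exc}",
            frame_index=len(frames["times"]) - 1,
            partial_trajectory=traj) from exc

    metadata["n_capped"] = packed.n_capped
    return _make_traj(frames, packed, metadata, complete=True)


def relax(state: SystemState, vesicle: VesicleSpec,
          rods: Sequence[RodSpec] | RodSpec, params: SimulationParams,
          n_steps: int) -> SystemState:
    """Zero-noise, zero-activity overdamped descent to a nearby minimum.

    Total potential energy is non-increasing along the run (up to roundoff)
    because the step is pure gradient descent with the physical mobilities.
    """
    if isinstance(rods, RodSpec):
        rods = [rods] * state.n_rods
    quiet = [r.with_(active=False) for r in rods]
    packed = PackedSystem(state, vesicle, quiet, params)
    packed.advance(int(n_steps), rng=None, temperature=0.0)
    out = packed.to_state()
    return out
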