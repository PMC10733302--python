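"""Trajectory and state serialization.

Trajectories are stored as HDF5 containers (one stacked dataset per frame
quantity, an explicit ``n_frames`` attribute for truncation detection, and
the run configuration echoed as a JSON attribute), plus an extended-XYZ
text export for visualization. A single-frame trajectory doubles as a state
file for the ``build`` CLI subcommand.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .errors import TrajectoryFormatError
from .params import RodSpec, SimulationParams, VesicleSpec
from .state import SystemState, Trajectory

__all__ = ["write_trajectory", "read_trajectory", "write_xyz",
           "write_sidecar", "trajectory_from_state", "state_from_trajectory"]

_FRAME_KEYS = ("times", "membrane", "rod_centers", "rod_orientations",
               "rod_active", "kink_angle", "energies")


def _specs_to_json(metadata: dict) -> str:
    out = {}
    for key, val in metadata.items():
        if dataclasses.is_dataclass(val) and not isinstance(val, type):
            out[key] = dataclasses.asdict(val)
        elif key == "rods":
            out[key] = [dataclasses.asdict(r) for r in val]
        elif key == "protocol":
            out[key] = [dict(type=type(e).__name__, **dataclasses.asdict(e))
                        for e in getattr(val, "events", [])]
        else:
            try:
                json.dumps(val)
                out[key] = val
            except TypeError:
                out[key] = repr(val)
    return json.dumps(out)


def write_trajectory(path, traj: Trajectory) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "kinkvesicle-trajectory-1"
        f.attrs["n_frames"] = traj.n_frames
        f.attrs["box_length"] = traj.box_length
        f.attrs["kink_index"] = traj.kink_index
        f.attrs["rod_n_disks"] = traj.rod_n_disks
        f.attrs["complete"] = traj.complete
        f.attrs["metadata"] = _specs_to_json(traj.metadata)
        g = f.create_group("frames")
        for key in _FRAME_KEYS:
            g.create_dataset(key, data=getattr(traj, key))


def read_trajectory(path) -> Trajectory:
    """Read a trajectory container; raises :class:`TrajectoryFormatError`
    (naming the last complete frame when determinable) on corruption."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise TrajectoryFormatError(
            f"{path} is not a readable trajectory container (truncated or "
            f"corrupted file): {exc}") from exc
    with f:
        if f.attrs.get("format") != "kinkvesicle-trajectory-1":
            raise TrajectoryFormatError(f"{path}: unknown container format")
        data = {}
        n_expected = int(f.attrs["n_frames"])
        for key in _FRAME_KEYS:
            if f"frames/{key}" not in f:
                raise TrajectoryFormatError(
                    f"{path}: missing dataset {key}", last_complete_frame=-1)
            data[key] = np.asarray(f["frames"][key])
        n_actual = min(len(data[k]) for k in _FRAME_KEYS)
        if n_actual < n_expected:
            raise TrajectoryFormatError(
                f"{path}: expected {n_expected} frames but only "
                f"{n_actual} are complete (last complete frame "
                f"{n_actual - 1})", last_complete_frame=n_actual - 1)
        meta = json.loads(f.attrs.get("metadata", "{}"))
        return Trajectory(
            **data,
            box_length=float(f.attrs["box_length"]),
            kink_index=int(f.attrs["kink_index"]),
            rod_n_disks=int(f.attrs["rod_n_disks"]),
            metadata=meta,
            complete=bool(f.attrs["complete"]),
        )


def trajectory_from_state(state: SystemState, vesicle: VesicleSpec,
                          rods: Sequence[RodSpec], params: SimulationParams,
                          metadata: dict | None = None) -> Trajectory:
    """Wrap a single state as a one-frame trajectory (state-file format)."""
    na = state.n_rods
    return Trajectory(
        times=np.array([state.time]),
        membrane=state.membrane_unwrapped()[None],
        rod_centers=state.rod_centers_unwrapped()[None],
        rod_orientations=state.rod_orientations[None].copy(),
        rod_active=np.array([[r.active for r in rods]], dtype=bool)
        if na else np.zeros((1, 0), dtype=bool),
        kink_angle=np.array([vesicle.kink_angle]),
        energies=np.full((1, 3), np.nan),
        box_length=state.box_length,
        kink_index=vesicle.kink_index,
        rod_n_disks=rods[0].n_disks if rods else 0,
        metadata=dict(metadata or {}, params=params, vesicle=vesicle,
                      rods=list(rods)),
    )


def state_from_trajectory(traj: Trajectory, frame: int = -1) -> SystemState:
    if frame < 0:
        frame += traj.n_frames
    return traj.state_at(frame)


def write_xyz(path, traj: Trajectory, frames: Sequence[int] | None = None,
              species_labels: tuple[str, str, str] = ("M", "K", "R")) -> None:
    """Extended-XYZ export: one record per disk with a species column.

    Membrane disks are labelled M (the kink vertex K); rod constituent
    disks R<species_index>. Lengths in sigma, z = 0.
    """
    path = Path(path)
    if frames is None:
        frames = range(traj.n_frames)
    m = traj.rod_n_disks
    offs = (np.arange(m) - (m - 1) / 2.0) if m else np.empty(0)
    with open(path, "w") as fh:
        for fidx in frames:
            mem = traj.membrane[fidx]
            e = np.stack([np.cos(traj.rod_orientations[fidx]),
                          np.sin(traj.rod_orientations[fidx])], axis=1)
            rods = (traj.rod_centers[fidx][:, None, :]
                    + offs[None, :, None] * e[:, None, :]).reshape(-1, 2) \
                if traj.n_rods else np.empty((0, 2))
            n = len(mem) + len(rods)
            fh.write(f"{n}\n")
            L = traj.box_length
            fh.write(
                f'Lattice="{L} 0 0 0 {L} 0 0 0 1" '
                f'Properties=species:S:1:pos:R:3 Time={traj.times[fidx]}\n')
            for i, p in enumerate(mem):
                lab = species_labels[1] if i == traj.kink_index else species_labels[0]
                fh.write(f"{lab} {p[0]:.8f} {p[1]:.8f} 0.0\n")
            for i, p in enumerate(rods):
                fh.write(f"{species_labels[2]} {p[0]:.8f} {p[1]:.8f} 0.0\n")


def write_sidecar(path, traj: Trajectory) -> None:
    """JSON sidecar with the full provenance of a run (config + seed)."""
    payload = json.loads(_specs_to_json(traj.metadata))
    payload["n_frames"] = traj.n_frames
    payload["complete"] = traj.complete
    payload["box_length"] = traj.box_length
    Path(path).write_text(json.dumps(payload, indent=2))


def write_energy_ledger(path, traj: Trajectory) -> None:
    """Per-frame potential-energy terms as CSV."""
    with open(path, "w") as fh:
        fh.write("# per-frame potential energies, simulation units\n")
        fh.write("time,wca,fene,angle\n")
        for t, (ew, ef, ea) in zip(traj.times, traj.energies):
            fh.write(f"{t},{ew},{ef},{ea}\n")
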