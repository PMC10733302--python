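"""System state and trajectory containers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .params import RodSpec, SIGMA

__all__ = ["SystemState", "ForceTorqueSet", "Trajectory"]


def _wrap(x: np.ndarray, box: float) -> tuple[np.ndarray, np.ndarray]:
    """Wrap coordinates into [0, box); return (wrapped, image shifts)."""
    img = np.floor(x / box).astype(np.int64)
    return x - img * box, img


@dataclass
class SystemState:
    """Instantaneous configuration: membrane disks plus rigid rods.

    Positions are wrapped into the primary box; ``*_images`` carry the
    periodic image counts so unwrapped coordinates are recoverable for
    analysis. Rod orientations are angles w_i with unit vectors
    e_i = (cos w_i, sin w_i).
    """

    membrane_positions: np.ndarray          # (N_v, 2), wrapped
    rod_centers: np.ndarray                 # (N_a, 2), wrapped
    rod_orientations: np.ndarray            # (N_a,)
    box_length: float
    time: float = 0.0
    membrane_images: np.ndarray | None = None   # (N_v, 2) int
    rod_images: np.ndarray | None = None        # (N_a, 2) int

    def __post_init__(self):
        self.membrane_positions = np.asarray(self.membrane_positions, dtype=float)
        self.rod_centers = np.asarray(self.rod_centers, dtype=float).reshape(-1, 2)
        self.rod_orientations = np.asarray(self.rod_orientations, dtype=float).ravel()
        if self.rod_centers.shape[0] != self.rod_orientations.shape[0]:
            raise ValueError("rod_centers and rod_orientations length mismatch")
        if self.membrane_images is None:
            self.membrane_positions, self.membrane_images = _wrap(
                self.membrane_positions, self.box_length)
        if self.rod_images is None:
            self.rod_centers, self.rod_images = _wrap(self.rod_centers, self.box_length)

    # -- basic sizes ------------------------------------------------------
    @property
    def n_membrane(self) -> int:
        return self.membrane_positions.shape[0]

    @property
    def n_rods(self) -> int:
        return self.rod_centers.shape[0]

    def density(self, sigma: float = SIGMA) -> float:
        """Rod line density rho = N_a / (N_v * sigma)."""
        return self.n_rods / (self.n_membrane * sigma)

    # -- derived coordinates ---------------------------------------------
    @property
    def rod_unit_vectors(self) -> np.ndarray:
        w = self.rod_orientations
        return np.stack([np.cos(w), np.sin(w)], axis=1)

    def membrane_unwrapped(self) -> np.ndarray:
        return self.membrane_positions + self.membrane_images * self.box_length

    def rod_centers_unwrapped(self) -> np.ndarray:
        return self.rod_centers + self.rod_images * self.box_length

    def rod_disk_positions(self, rods: Sequence[RodSpec] | RodSpec,
                           wrapped: bool = False) -> np.ndarray:
        """Constituent disk centres of every rod, stacked (sum m_i, 2)."""
        if isinstance(rods, RodSpec):
            rods = [rods] * self.n_rods
        cen = self.rod_centers if wrapped else self.rod_centers_unwrapped()
        e = self.rod_unit_vectors
        out = []
        for i, spec in enumerate(rods):
            out.append(cen[i] + np.outer(spec.disk_offsets(), e[i]))
        return np.concatenate(out, axis=0) if out else np.empty((0, 2))

    def copy(self) -> "SystemState":
        return SystemState(
            self.membrane_positions.copy(), self.rod_centers.copy(),
            self.rod_orientations.copy(), self.box_length, self.time,
            self.membrane_images.copy(), self.rod_images.copy())


@dataclass
class ForceTorqueSet:
    """Forces and torques of one state, with a per-term energy ledger.

    ``rod_torques`` are scalars (2D) about the rod centres; the active force
    acts at the centre and contributes zero torque. The sum of all internal
    (WCA + FENE + angle) forces over all bodies vanishes.
    """

    membrane_forces: np.ndarray     # (N_v, 2)
    rod_forces: np.ndarray          # (N_a, 2)
    rod_torques: np.ndarray         # (N_a,)
    energies: dict = field(default_factory=dict)  # wca/fene/angle/active_power

    def total_internal_force(self) -> np.ndarray:
        """Sum of non-active forces over all bodies (Newton's third law -> 0)."""
        active = self.energies.get("_active_vectors")
        rod = self.rod_forces
        if active is not None and len(active):
            rod = rod - active
        return self.membrane_forces.sum(axis=0) + (
            rod.sum(axis=0) if len(rod) else np.zeros(2))

    def potential_energy(self) -> float:
        return sum(v for k, v in self.energies.items()
                   if k in ("wca", "fene", "angle"))


@dataclass
class Trajectory:
    """Time series of states in unwrapped coordinates plus per-frame metadata.

    Frames store unwrapped membrane and rod-centre positions (analysis is done
    in unwrapped coordinates; the superstructure stays compact), rod
    orientations and activity flags, the instantaneous kink rest angle, and a
    per-term potential-energy ledger.
    """

    times: np.ndarray                # (F,)
    membrane: np.ndarray             # (F, N_v, 2) unwrapped
    rod_centers: np.ndarray          # (F, N_a, 2) unwrapped
    rod_orientations: np.ndarray     # (F, N_a)
    rod_active: np.ndarray           # (F, N_a) bool
    kink_angle: np.ndarray           # (F,)
    energies: np.ndarray             # (F, 3): wca, fene, angle
    box_length: float
    kink_index: int = 0
    rod_n_disks: int = 3
    metadata: dict[str, Any] = field(default_factory=dict)
    complete: bool = True

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_rods(self) -> int:
        return self.rod_centers.shape[1]

    def centroids(self) -> np.ndarray:
        """Membrane centroid per frame (unwrapped), (F, 2)."""
        return self.membrane.mean(axis=1)

    def window_slice(self, window: float = 0.5) -> slice:
        """Index slice selecting the last ``window`` fraction of frames."""
        if not 0 < window <= 1:
            raise ValueError("window must be in (0, 1]")
        start = int(np.floor(self.n_frames * (1.0 - window)))
        return slice(start, self.n_frames)

    def state_at(self, frame: int) -> SystemState:
        return SystemState(
            self.membrane[frame] % self.box_length,
            self.rod_centers[frame] % self.box_length,
            self.rod_orientations[frame],
            self.box_length,
            time=float(self.times[frame]),
            membrane_images=np.floor(self.membrane[frame] / self.box_length).astype(np.int64),
            rod_images=np.floor(self.rod_centers[frame] / self.box_length).astype(np.int64),
        )
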