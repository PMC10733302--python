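"""Physical parameter sets for the vesicle/rod model.

Units: lengths in the disk diameter sigma, energies in the simulation energy
unit (epsilon = 1 corresponds to 100 k_BT at the default temperature
k_BT = 0.01), times in the unit time tau. Drag gamma = 1 energy*tau/sigma^2,
so k_BT/gamma is a diffusivity in sigma^2/tau and Pe*k_BT/gamma an active
speed in sigma/tau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SimulationParams", "VesicleSpec", "RodSpec"]

SIGMA = 1.0
#: WCA cutoff 2^(1/6) sigma
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class SimulationParams:
    """Global physical and numerical constants.

    Defaults reproduce the reference model: a square periodic box of side
    L_b = 125 sigma, temperature k_BT = 0.01, translational drag gamma = 1,
    rotational drag gamma_r = sigma^3 gamma / 3 (Stokes-Einstein), timestep
    1e-4 tau and duration 2e4 tau.
    """

    box_length: float = 125.0
    timestep: float = 1.0e-4
    temperature: float = 0.01
    gamma_t: float = 1.0
    gamma_r: float | None = None
    # WCA energy scale. 10 simulation energy units = 1000 k_BT at the
    # default temperature, matching the bending energy scale: this keeps the
    # membrane impenetrable to the emergent rod stacks (at 100 k_BT the
    # stack pressure can pry stretched bonds apart and rupture the ring).
    epsilon_wca: float = 10.0
    seed: int = 0
    duration: float = 2.0e4

    def __post_init__(self):
        if self.gamma_r is None:
            object.__setattr__(self, "gamma_r", SIGMA ** 3 * self.gamma_t / 3.0)
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.box_length <= 0:
            raise ValueError("box_length must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")

    @property
    def unit_time(self) -> float:
        """Conventional unit time sqrt(m sigma^2 / k_BT) with unit mass.

        Pure metadata: the overdamped dynamics never involve a mass, and all
        times in this package are measured directly in tau.
        """
        return math.sqrt(SIGMA ** 2 / self.temperature) if self.temperature > 0 else math.inf

    @property
    def translational_diffusivity(self) -> float:
        """D_t = k_BT / gamma, sigma^2 per tau."""
        return self.temperature / self.gamma_t

    @property
    def rotational_diffusivity(self) -> float:
        """D_r = k_BT / gamma_r, rad^2 per tau."""
        return self.temperature / self.gamma_r

    def with_(self, **kw) -> "SimulationParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class VesicleSpec:
    """Membrane ring topology and bonded force-field parameters.

    The membrane is a single closed ring of ``n_disks`` disks. Neighbours are
    FENE-bonded; every consecutive triplet carries a harmonic angle term with
    rest angle pi, except the one triplet centred on ``kink_index`` whose rest
    angle is ``kink_angle`` and whose stiffness is multiplied by
    ``kink_stiffness_multiplier`` (the kink is effectively fixed relative to
    its neighbours). ``kink_angle = pi`` means "no kink".

    ``bond_strength`` and ``bend_coeff`` are absolute energies: the defaults
    1.0 (energy/sigma^2) and 10.0 (energy) equal 100 k_BT sigma^-2 and
    1000 k_BT at k_BT = 0.01.
    """

    n_disks: int = 100
    disk_diameter: float = 1.0
    bond_strength: float = 1.0
    fene_r0: float = 2.0
    bend_coeff: float = 10.0
    rest_angle: float = math.pi
    kink_index: int = 0
    kink_angle: float = math.pi
    kink_stiffness_multiplier: float = 10.0
    # Default kink: a harmonic angle term with rest angle theta_kink and
    # 10x stiffness, holding the triplet within ~5 mrad of the target while
    # letting the vertex comply elastically. The strict rigid-triplet mode
    # (rigid_kink=True) integrates the triplet as one rigid body; its
    # junction bonds then concentrate the stack pressure and can be pried
    # open by rod tips in long runs, so it is not the default.
    rigid_kink: bool = False

    def __post_init__(self):
        if self.n_disks < 3:
            raise ValueError("a ring needs at least 3 disks")
        if not (0.0 < self.kink_angle <= math.pi + 1e-12):
            raise ValueError("kink_angle must lie in (0, pi]")
        if not (0 <= self.kink_index < self.n_disks):
            raise ValueError("kink_index out of range")
        if self.fene_r0 <= 0 or self.bond_strength < 0 or self.bend_coeff < 0:
            raise ValueError("bad bonded parameters")

    @property
    def has_kink(self) -> bool:
        return self.kink_angle < math.pi - 1e-9

    def triplets(self) -> np.ndarray:
        """(n_disks, 3) consecutive triplets (i-1, i, i+1) around the ring."""
        n = self.n_disks
        idx = np.arange(n)
        return np.stack([(idx - 1) % n, idx, (idx + 1) % n], axis=1)

    def angle_rest_angles(self) -> np.ndarray:
        rest = np.full(self.n_disks, self.rest_angle)
        rest[self.kink_index] = self.kink_angle
        return rest

    def angle_stiffnesses(self) -> np.ndarray:
        kap = np.full(self.n_disks, self.bend_coeff)
        if self.has_kink:
            kap[self.kink_index] = (self.bend_coeff
                                    * self.kink_stiffness_multiplier)
        return kap

    def with_(self, **kw) -> "VesicleSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class RodSpec:
    """A rigid self-propelled rod of ``n_disks`` tangent disks.

    Constituent disk centres lie on the rod axis at spacing sigma (end to
    end), so the rod length is m*sigma and the aspect ratio alpha = m.
    The active force F_A = Pe*k_BT acts at the rod centre along the symmetry
    axis e = (cos w, sin w) and contributes no torque.
    """

    n_disks: int = 3
    peclet: float = 75.0
    species: str = "A"
    active: bool = True

    def __post_init__(self):
        if self.n_disks < 1:
            raise ValueError("a rod needs at least one disk")
        if self.peclet < 0:
            raise ValueError("peclet must be >= 0")

    @property
    def aspect_ratio(self) -> float:
        return float(self.n_disks)

    def disk_offsets(self) -> np.ndarray:
        """Axial offsets of the constituent disk centres from the rod centre."""
        m = self.n_disks
        return (np.arange(m) - (m - 1) / 2.0) * SIGMA

    def active_force(self, temperature: float) -> float:
        """F_A = Pe * k_BT when active, 0 otherwise."""
        return self.peclet * temperature if self.active else 0.0

    def active_speed(self, temperature: float, gamma_t: float = 1.0) -> float:
        """v_a = F_A / gamma, sigma per tau."""
        return self.active_force(temperature) / gamma_t

    def with_(self, **kw) -> "RodSpec":
        return replace(self, **kw)
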