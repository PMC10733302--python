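"""Exception hierarchy for kinkvesicle."""


class KinkVesicleError(Exception):
    """Base class for all package errors."""


class DegenerateContactError(KinkVesicleError):
    """Two disks sit at exactly zero separation; the contact direction is undefined."""


class BondOverstretchError(KinkVesicleError):
    """A FENE bond reached or exceeded its divergence length r0."""

    def __init__(self, i: int, j: int, length: float, r0: float):
        self.pair = (i, j)
        self.length = length
        super().__init__(
            f"FENE bond ({i}, {j}) overstretched: r = {length:.6g} >= r0 = {r0:.6g}"
        )


class GeometryError(KinkVesicleError):
    """Degenerate geometry (zero-length angle arm, unrealizable stacking, ...)."""


class ConstructionError(KinkVesicleError):
    """An initial configuration could not be built."""


class PackingInfeasibleError(ConstructionError):
    """Rejection sampling failed to place rods without overlap."""


class IntegrationError(KinkVesicleError):
    """Non-finite force or displacement during time stepping.

    ``partial_trajectory`` holds the frames written before the failure (flagged
    incomplete) when the failure happened inside :func:`kinkvesicle.dynamics.run`.
    """

    def __init__(self, message: str, frame_index: int | None = None,
                 partial_trajectory=None):
        self.frame_index = frame_index
        self.partial_trajectory = partial_trajectory
        super().__init__(message)


class ConfigError(KinkVesicleError):
    """Invalid run configuration (unknown key, unknown species, bad value)."""


class NoKinkAxisError(KinkVesicleError):
    """Requested the kink axis of a vesicle with theta_kink = pi (no kink)."""


class InsufficientDataError(KinkVesicleError):
    """Not enough frames/samples for the requested statistic."""


class TrajectoryFormatError(KinkVesicleError):
    """Corrupted or truncated trajectory file."""

    def __init__(self, message: str, last_complete_frame: int | None = None):
        self.last_complete_frame = last_complete_frame
        super().__init__(message)
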