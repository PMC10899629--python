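"""Exception types shared across the package."""


class NerveRingError(Exception):
    """Base class for package errors."""


class ValidationError(NerveRingError, ValueError):
    """Malformed or inconsistent input values."""


class UnknownNeuronError(NerveRingError, KeyError):
    """A neuron name that is not part of the roster."""


class UnknownStageError(NerveRingError, KeyError):
    """A stage label that is not part of the ensemble."""


class DegenerateScaleError(NerveRingError, ValueError):
    """Normalisation divisor is zero (fewer than two distinct weights)."""


class EmptyInputError(NerveRingError, ValueError):
    """An operation that requires data received none."""


class GeometryError(NerveRingError, ValueError):
    """Impossible volume geometry (overlap, no release site, ...)."""


class ResidualVoxelError(NerveRingError, RuntimeError):
    """Background-mask voxels unreachable from any segment."""

    def __init__(self, count: int):
        self.count = count
        super().__init__(f"{count} mask voxel(s) unreachable from any segment")
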