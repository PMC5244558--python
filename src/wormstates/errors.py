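"""Exception hierarchy for wormstates.

Every error raised deliberately by the package derives from
:class:`WormstatesError`, so callers can catch the package's own failures
without swallowing programming errors.
"""


class WormstatesError(Exception):
    """Base class for all wormstates errors."""


class FormatError(WormstatesError):
    """A dataset file violates the expected dialect (duplicates, bad time order, ...)."""


class InvalidParameterError(WormstatesError):
    """A parameter is outside its admissible range."""


class InvalidPerturbationError(WormstatesError):
    """A strain perturbation spec is inconsistent (e.g. stationary distribution not preserved)."""


class InvalidDistributionError(WormstatesError):
    """An input claimed to be a probability distribution is not one."""


class InvalidInputError(WormstatesError):
    """Generic invalid input to a statistical routine (empty sample, p outside [0,1], ...)."""


class InsufficientSampleError(WormstatesError):
    """Too few sampled frames to fit the requested model."""


class EmptySelectionError(WormstatesError):
    """A frame mask selected no frames."""


class TooShortError(WormstatesError):
    """A series has too few frames for the requested operation."""


class CannotInterpolateError(WormstatesError):
    """Gap interpolation is impossible (all frames missing)."""


class UpsamplingError(WormstatesError):
    """Requested target frame rate exceeds the source frame rate."""


class SamplingError(WormstatesError):
    """Not enough individuals to draw the requested comparison set."""


class ModelMismatchError(WormstatesError):
    """Objects built from different postural-state models were combined."""


class DegenerateFitError(WormstatesError):
    """A regression cannot be fitted (zero variance in the explanatory variable)."""
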