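"""Exception hierarchy shared across the pipeline stages."""


class TiltomoError(Exception):
    """Base class for all package-specific errors."""


class InvalidGridError(TiltomoError, ValueError):
    """Angle grid parameters violate their invariants."""


class InvalidSpecError(TiltomoError, ValueError):
    """Phantom specification violates its invariants."""


class InvalidParameterError(TiltomoError, ValueError):
    """A numeric parameter is outside its admissible range."""


class ContractError(TiltomoError, ValueError):
    """An operation precondition (shape, index, presence of reference) failed."""


class DegenerateInputError(TiltomoError, ValueError):
    """Input is formally valid but information-free (e.g. constant image)."""


class DegenerateCropError(TiltomoError, ValueError):
    """Measured shifts are so large that no common field of view remains."""


class ConfigError(TiltomoError, ValueError):
    """Unknown option value (filter name, plane name, subsample step...)."""


class InstabilityError(TiltomoError, RuntimeError):
    """Iterative reconstruction diverged (residual norm grew past its bound)."""
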