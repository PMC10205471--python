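"""Exception hierarchy shared across the package."""


class HgTradeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HgTradeError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(HgTradeError):
    """Inputs violate a structural precondition (shape, sign, consistency)."""


class GenerationError(HgTradeError):
    """The synthetic-world generator could not satisfy its constraints."""


class NumericalError(HgTradeError):
    """A linear system is singular or outside its convergence region."""


class AllocationError(HgTradeError):
    """A counterfactual country total cannot be spatially allocated."""


class WeightingError(HgTradeError):
    """A spatial weighting has zero total weight."""


class ScalingError(HgTradeError):
    """A scenario scaling ratio is undefined (zero with-trade proxy)."""


class NormalizationError(HgTradeError):
    """A statistic's normalizing constant is zero."""


class MonteCarloError(HgTradeError):
    """Too many Monte Carlo draws failed to evaluate."""
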