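"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input specification or parameter failed validation.

    The message always names the offending field/argument.
    """


class QualityGateError(RuntimeError):
    """Image rejected by the signal-strength-index quality gate."""


class EmptyRegionError(ValueError):
    """A density was requested over a region containing no pixels.

    Density over an empty region is undefined, not zero.
    """


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. constant covariate)."""


class AchievabilityError(RuntimeError):
    """The generator could not realise the requested ground-truth configuration."""
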