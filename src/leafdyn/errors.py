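"""Exception hierarchy for leafdyn."""


class LeafDynError(Exception):
    """Base class for all leafdyn errors."""


class FormatError(LeafDynError):
    """A file or table does not follow the expected layout."""


class EmptyInputError(LeafDynError):
    """No usable rows survived validation."""


class InvalidFluorescenceError(LeafDynError):
    """Fluorescence counts violate Fm >= Fm' >= F > 0 style orderings."""


class DomainError(LeafDynError):
    """A numeric argument is outside the physical domain of an operation."""


class UnderDeterminedError(LeafDynError):
    """Fewer observations than free parameters."""


class IllConditionedError(LeafDynError):
    """The regressor range is too narrow for a stable fit."""


class PhotorespirationInconsistencyError(DomainError):
    """J <= 4(A + Rd): the variable-J expression has no physical solution."""


class NoInductionError(LeafDynError):
    """Final steady A does not exceed initial steady A."""


class UndefinedMetricError(LeafDynError):
    """A crossing-time metric is undefined because the series never crosses."""


class NumericError(LeafDynError):
    """A root-finding or optimisation step failed; inputs are in the message."""


class ScenarioError(LeafDynError):
    """A simulation scenario is internally inconsistent."""
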