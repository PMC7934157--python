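"""Exception hierarchy shared across the package.

Every contract violation raises a typed exception rather than returning
NaN or an empty result, so that pipeline stages fail loudly and the CLI
can map failures to nonzero exit codes.
"""


class RankcomError(Exception):
    """Base class for all package errors."""


class CohortValidationError(RankcomError):
    """A respondent record violates the questionnaire schema.

    Messages name the offending respondent id and field.
    """


class ParameterError(RankcomError):
    """An operation received an invalid parameter (e.g. nonpositive
    Plackett-Luce worth, non-increasing Likert cutpoints)."""


class ContractError(RankcomError):
    """An operation's precondition was violated (empty group,
    mismatched item sets, invited = 0, ...)."""


class EmptyCohortError(ContractError):
    """No respondents contribute to a statistic (T = 0)."""


class DegenerateFitError(ContractError):
    """A regression cannot be fitted (constant predictor or n < 2)."""
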