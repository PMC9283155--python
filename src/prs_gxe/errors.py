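"""Exception hierarchy.

Validation errors (bad inputs, malformed files, inconsistent configs) are
kept distinct from computation errors (model non-convergence, degenerate
statistics) so the CLI can map them to distinct exit codes.
"""


class PrsGxeError(Exception):
    """Base class for all package errors."""


class ValidationError(PrsGxeError):
    """Input, configuration or file-format problem detected before compute."""


class ComputationError(PrsGxeError):
    """A statistical or numerical procedure could not produce a valid result."""


class UndefinedStatisticError(ComputationError):
    """A statistic is undefined for the given data (e.g. MAF of an
    all-missing variant, r-squared of a monomorphic pair)."""


class EmptyScoreError(ComputationError):
    """No variant survived the inclusion threshold, so the score is empty."""


class NoDataSurvivesQCError(ComputationError):
    """Every sample or every variant was removed by quality control."""


class ModelFitError(ComputationError):
    """Regression failed: non-convergence, separation, or a singular design."""
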