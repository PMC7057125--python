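"""Exception hierarchy.

Every error class carries a distinct ``exit_code`` so the command-line
entry point can translate failures into stable shell exit statuses.
"""


class CocktailLSSError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(CocktailLSSError):
    """Invalid kinetic or statistical parameter (non-positive rate, CV < 0...)."""

    exit_code = 2


class ConfigurationError(CocktailLSSError):
    """Inconsistent study design, probe map or population configuration."""

    exit_code = 3


class DataValidationError(CocktailLSSError):
    """Malformed concentration data (unsorted times, negative values, duplicates)."""

    exit_code = 4


class InsufficientDataError(CocktailLSSError):
    """Too few points/subjects for the requested computation."""

    exit_code = 5


class UndefinedRatioError(CocktailLSSError):
    """Parent:metabolite ratio requested where the metabolite AUC is zero."""

    exit_code = 6


class FitError(CocktailLSSError):
    """Rank-deficient or otherwise impossible least-squares fit."""

    exit_code = 7


class PredictionError(CocktailLSSError):
    """Model applied to data lacking a required sampling time."""

    exit_code = 8


class EmptyAdmissibleSetError(CocktailLSSError):
    """Every candidate sampling time is disqualified by BLQ records."""

    exit_code = 9


class DegenerateVarianceError(CocktailLSSError):
    """ANOVA requested on groups with no within-group variance anywhere."""

    exit_code = 10


class RegistryError(CocktailLSSError):
    """Published-model registry file is missing, corrupt or fails its checksum."""

    exit_code = 11


class PipelineError(CocktailLSSError):
    """A pipeline stage failed; the message carries the stage tag."""

    exit_code = 12
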