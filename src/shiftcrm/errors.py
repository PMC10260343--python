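"""Exception hierarchy for shiftcrm.

Every validation failure raises a distinct subclass so callers (and the CLI)
can report precisely which design constraint was violated.
"""


class ShiftCrmError(Exception):
    """Base class for all shiftcrm errors."""


class InvalidHalfwidthError(ShiftCrmError, ValueError):
    """Indifference-interval halfwidth outside [0, min(theta, 1 - theta))."""


class SkeletonCalibrationError(ShiftCrmError, ValueError):
    """Skeleton recursion produced a value outside (0, 1) or broke monotonicity."""


class ScenarioValidationError(ShiftCrmError, ValueError):
    """Base class for dose-toxicity scenario violations."""


class RowMonotonicityError(ScenarioValidationError):
    """DLT probabilities decrease along a row (dose level axis)."""


class ColumnOrderingError(ScenarioValidationError):
    """Combination-therapy row less toxic than the monotherapy row at some level."""


class ShiftConstraintError(ScenarioValidationError):
    """True MTD locations in adjacent rows differ by more than the allowed shift."""


class HeterogeneityRequiredError(ShiftCrmError, ValueError):
    """Likelihood estimation attempted before both a DLT and a non-DLT exist."""


class WrongStageError(ShiftCrmError, ValueError):
    """A stage-specific operation was called in the other conduct stage."""


class ScenarioGenerationError(ShiftCrmError, RuntimeError):
    """Random-curve rejection sampling exhausted its attempt budget."""


class ConfigError(ShiftCrmError, ValueError):
    """Configuration file missing keys, containing unknown keys, or invalid values."""


class TrialDataError(ShiftCrmError, ValueError):
    """Patient-level trial CSV malformed (indices, duplicates, outcome coding)."""


class OutOfDomainError(ShiftCrmError, ValueError):
    """Sample-size specification outside the calculator's supported domain."""
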