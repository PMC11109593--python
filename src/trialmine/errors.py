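"""Exception hierarchy shared across the package."""


class TrialMineError(Exception):
    """Base class for all package errors."""


class SchemaError(TrialMineError):
    """Malformed or inconsistent entity schema."""


class ValidationError(TrialMineError):
    """A domain object violates one of its invariants."""


class NormalizationError(TrialMineError):
    """A value string could not be reduced to a decimal number."""


class AlignmentError(TrialMineError):
    """A mention does not align with token boundaries."""


class TrainingError(TrialMineError):
    """A model cannot be trained from the given inputs."""


class ClusteringError(TrialMineError):
    """Arm-mention clustering received inconsistent inputs."""


class EvaluationError(TrialMineError):
    """Scoring inputs are unusable (empty, disjoint document sets, ...)."""
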