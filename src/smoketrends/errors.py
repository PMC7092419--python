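"""Exception hierarchy.

The CLI maps these onto distinct exit codes: configuration problems (bad
parameters, malformed config files), data problems (schema violations,
degenerate study data), and numerical problems (non-convergence).
"""


class SmokeTrendsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SmokeTrendsError):
    """Invalid parameters, designs, weights or config files."""


class DataError(SmokeTrendsError):
    """Input data violate the documented schema or preconditions."""


class StudyExclusionError(DataError):
    """A study cannot contribute a first-stage effect (separation,
    absent education category); carries the reason for the exclusion log."""

    def __init__(self, study: str, reason: str):
        self.study = study
        self.reason = reason
        super().__init__(f"study {study!r} excluded: {reason}")


class NumericalError(SmokeTrendsError):
    """Iterative estimation failed (non-convergence, ill-conditioning)."""


class PipelineError(SmokeTrendsError):
    """A pipeline stage failed; names the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
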