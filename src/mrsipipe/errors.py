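"""Exception hierarchy shared across the pipeline stages."""


class MrsipipeError(Exception):
    """Base class for all package-specific errors."""


class VolumeFormatError(MrsipipeError):
    """A file could not be parsed as the requested volume format."""


class GridMismatchError(MrsipipeError):
    """Volumes expected to share a grid differ in geometry."""


class ContouringError(MrsipipeError):
    """Contour generation failed (e.g. unstable NAWM threshold)."""


class RegistrationError(MrsipipeError):
    """Transform estimation failed or diverged."""


class ApprovalRequiredError(MrsipipeError):
    """A non-identity transform was applied without user approval."""


class HarmonizationError(MrsipipeError):
    """No common spectral-quality support between the two scans."""


class UndefinedMetricError(MrsipipeError):
    """Overlap statistics are undefined for the given mask pair."""


class StratificationError(MrsipipeError):
    """Median stratification cannot split the cohort."""


class DegenerateTestError(MrsipipeError):
    """The log-rank test is degenerate (e.g. no observed events)."""


class EstimationError(MrsipipeError):
    """Survival-curve estimation received unusable input."""


class PhantomSpecError(MrsipipeError):
    """A synthetic phantom specification is internally inconsistent."""


class ConfigError(MrsipipeError):
    """Pipeline configuration is invalid."""


class CohortError(MrsipipeError):
    """A cohort-level run cannot proceed (too few usable patients)."""


class StageError(MrsipipeError):
    """A pipeline stage failed; carries the stage name for logging."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
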