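"""Exception hierarchy shared across the package."""


class XshadowError(Exception):
    """Base class for all package-specific errors."""


class FormatError(XshadowError):
    """An input file violates the expected tabular format."""


class EmptyTableError(XshadowError):
    """An input table parsed to zero usable records."""


class CohortError(XshadowError):
    """Cohort alignment produced an empty patient intersection."""


class DegenerateDataError(XshadowError):
    """Data carry no variation (e.g. constant vector) so a fit is undefined."""


class MixtureUnfitError(XshadowError):
    """Too few or degenerate observations to fit a mixture model."""


class SampleSizeError(XshadowError):
    """A statistic's minimum sample size is not met."""


class EnumerationSizeError(XshadowError):
    """Requested exhaustive enumeration exceeds the size guard."""


class UndefinedAUCError(XshadowError):
    """AUROC requested with a single-class truth vector."""


class PipelineError(XshadowError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
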