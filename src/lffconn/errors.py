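"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`LffConnError`,
so callers can catch one type at pipeline level while tests target the
specific failure mode.
"""


class LffConnError(Exception):
    """Base class for all errors raised by lffconn."""


class ParameterError(LffConnError, ValueError):
    """A numeric parameter is outside its valid range (band > Nyquist, df < 3, ...)."""


class GeometryError(LffConnError, ValueError):
    """A region, ROI or coordinate does not fit the voxel grid."""


class DimensionalityError(LffConnError, ValueError):
    """An image does not have the expected number of axes."""


class MetadataError(LffConnError, ValueError):
    """Required image metadata (e.g. the repetition time) is absent or invalid."""


class DegenerateSeedError(LffConnError, ValueError):
    """A seed/reference timecourse has zero variance and cannot be correlated."""


class DegenerateInputError(LffConnError, ValueError):
    """An input is degenerate for the requested operation (e.g. zero temporal mean)."""


class SampleSizeError(LffConnError, ValueError):
    """Too few subjects/observations for the requested statistic."""


class PipelineError(LffConnError, RuntimeError):
    """A pipeline stage failed; the message names the stage and the run."""
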