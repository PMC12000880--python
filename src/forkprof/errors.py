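"""Exception hierarchy.

Everything raised on purpose by forkprof derives from :class:`ForkprofError`,
so callers (and the CLI) can catch one type. Subclasses separate input-format
problems from parameter problems from degenerate-data problems.
"""


class ForkprofError(Exception):
    """Base class for all forkprof errors."""


class FormatError(ForkprofError):
    """Malformed input file (bad bedGraph/BED/TSV/YAML content)."""


class BoundsError(ForkprofError):
    """Coordinates outside the chromosome."""


class ParameterError(ForkprofError):
    """Invalid parameter value (bin size, span, pad width, window ...)."""


class NormalizationError(ForkprofError):
    """A normalization step is undefined (all-zero track, masked region ...)."""


class PadRegionError(ForkprofError):
    """A coordinate query landed inside the duplicated pad region."""


class ConfigError(ForkprofError):
    """Inconsistent simulation or pipeline configuration."""
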