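"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses)
to exit code 3.
"""


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class DataError(ValueError):
    """Invalid input data (grids, times, masks, labels)."""


class GridMismatchError(DataError):
    """Volumes are not on a common grid; registration would be required."""


class SizingError(DataError):
    """Requested grid is too small to contain the phantom lungs."""


class ParameterError(ValueError):
    """A model or algorithm parameter is out of its valid range."""


class DegenerateMapError(DataError):
    """Perfusion map is degenerate (non-positive upper quartile)."""


class UndefinedStatisticError(DataError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
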