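"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`ChromostatError`, so callers (and the CLI) can catch one type.
"""


class ChromostatError(Exception):
    """Base class for all chromostat errors."""


class ParameterError(ChromostatError, ValueError):
    """A numeric argument violates its documented precondition."""


class GridError(ChromostatError, ValueError):
    """Wavelength grids are mismatched, non-overlapping, or missing anchors."""


class DegenerateSpectrumError(ChromostatError, ValueError):
    """A spectrum carries no usable signal (all-zero, or zero at a required anchor)."""


class ActuationError(ChromostatError, ValueError):
    """An LED power command lies outside [0, 1]."""


class CalibrationError(ChromostatError, ValueError):
    """Electrode calibration is impossible or unusable (too few points, zero slope)."""


class ConfigError(ChromostatError, ValueError):
    """A configuration file or gain-parameter file cannot be used."""


class LogFormatError(ChromostatError, ValueError):
    """A log/table file does not follow the fixed tab-delimited dialect."""
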