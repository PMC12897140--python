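"""Exception hierarchy shared by the pipeline stages.

Each stage failure maps to a distinct CLI exit code so that batch callers
can tell a bad template from a bad scan.
"""


class ArrayQuantError(Exception):
    """Base class; exit code 1."""

    exit_code = 1


class ConfigError(ArrayQuantError):
    exit_code = 2


class FormatError(ConfigError):
    """Unreadable or unsupported image/table format."""


class DetectionError(ArrayQuantError):
    exit_code = 3


class GriddingError(ArrayQuantError):
    exit_code = 4


class AlignmentError(ArrayQuantError):
    exit_code = 5


class MeasurementError(ArrayQuantError):
    exit_code = 6


class StatsError(ArrayQuantError):
    exit_code = 7
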