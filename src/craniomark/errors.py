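"""Exception hierarchy.

All errors derive from :class:`CraniomarkError` (itself a ``ValueError``)
so callers can catch broadly while tests can assert on the precise class.
"""


class CraniomarkError(ValueError):
    """Base class for all package errors."""


class InputError(CraniomarkError):
    """Invalid or inconsistent input data (missing files, mismatched cases)."""


class FormatError(CraniomarkError):
    """Malformed file or container (bad DICOM series, bad CSV layout, corrupt weights)."""


class ParameterError(CraniomarkError):
    """Invalid parameter value (non-positive sizes, non-divisible shift grids)."""


class CapacityError(CraniomarkError):
    """Data exceeds a configured capacity (more slices than the depth template)."""


class ConfigurationError(CraniomarkError):
    """Missing or inconsistent model/pipeline configuration."""
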