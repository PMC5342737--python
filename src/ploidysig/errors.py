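"""Exception hierarchy shared by all pipeline stages."""


class PloidysigError(Exception):
    """Base class for all package errors."""


class FormatError(PloidysigError):
    """Malformed input file; message names file, line and offending field."""


class ConfigError(PloidysigError):
    """Invalid configuration value; message names the offending field."""


class DesignError(PloidysigError):
    """Experimental design inconsistent with the requested analysis."""


class DegenerateDataError(PloidysigError):
    """Data admit no meaningful estimate (e.g. all variances zero)."""
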