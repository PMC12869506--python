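"""Exception hierarchy shared across the package.

``ParameterError`` signals a caller-supplied parameter that violates a documented
precondition; ``FormatError`` a malformed input file; ``DataError`` data that parse
but are scientifically invalid (e.g. non-cumulative seizure counts). The CLI maps
``ConfigError`` to exit code 2 and the data-level errors to exit code 3.
"""


class ComodmapError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ComodmapError, ValueError):
    """A parameter violates a documented precondition."""


class FormatError(ComodmapError, ValueError):
    """An input file does not conform to its declared format."""


class DataError(ComodmapError, ValueError):
    """Input data are well-formed but scientifically invalid."""


class ConfigError(ComodmapError, ValueError):
    """A pipeline configuration file is missing, unparseable or inconsistent."""
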