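"""Exception hierarchy.

``InputError`` subclasses map to CLI exit code 1 (bad user input);
anything else escaping the pipeline maps to exit code 2.
"""


class AlloNetError(Exception):
    """Base class for all package errors."""


class InputError(AlloNetError):
    """Invalid or unusable user input."""


class AlignmentFormatError(InputError):
    """Malformed alignment file (ragged rows, unknown format, empty)."""


class EmptyAlignmentError(InputError):
    """No columns (or sequences) survive filtering."""


class MappingError(InputError):
    """Alignment reference cannot be mapped onto the structure sequence."""


class EnsembleError(InputError):
    """Inconsistent multi-model structure or unusable ensemble."""


class GraphError(InputError):
    """Residue graph unusable for the requested computation."""


class ConfigError(InputError):
    """Invalid configuration value."""
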