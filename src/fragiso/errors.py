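"""Exception hierarchy shared across the package.

CLI exit-code mapping: ConfigError/ValidationError -> 2, ProcessingError -> 3.
"""


class FragisoError(Exception):
    """Base class for all package errors."""


class ConfigError(FragisoError):
    """Invalid or incomplete run/simulation configuration."""


class ValidationError(FragisoError):
    """Input data violate a documented precondition or invariant."""


class ProcessingError(FragisoError):
    """A pipeline stage failed on otherwise well-formed inputs."""


class AmbiguousPeakError(FragisoError):
    """An observed m/z matches more than one catalog isotopologue."""
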