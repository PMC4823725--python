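"""Exception hierarchy shared across the package."""


class MarspaceError(Exception):
    """Base class for all package errors."""


class LoadError(MarspaceError):
    """A file could not be parsed; the message names the offending line."""


class DataError(MarspaceError):
    """Input data violates an invariant (bad coordinates, missing role, ...)."""


class ConfigError(MarspaceError):
    """A run configuration is incomplete or inconsistent."""


class MotifCompileError(MarspaceError):
    """A motif grammar string could not be compiled; message gives position."""
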