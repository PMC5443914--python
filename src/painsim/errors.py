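"""Exception hierarchy.

``ConfigurationError`` maps to CLI exit code 2, every other
:class:`PainSimError` to exit code 3.
"""


class PainSimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PainSimError):
    """A config file is missing, unparseable, or violates its schema."""


class ScriptingError(PainSimError):
    """A player policy emitted an unknown or malformed action."""


class ContractViolation(PainSimError):
    """A caller violated an operation precondition."""


class IntegrityError(PainSimError):
    """A telemetry log is internally inconsistent (e.g. unordered)."""


class UsageError(PainSimError):
    """Bad argument to a library-level operation (e.g. unknown export format)."""
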