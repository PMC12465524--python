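"""Exception hierarchy shared across the toolkit."""


class EvoscreenError(Exception):
    """Base class for all toolkit errors."""


class LibraryValidationError(EvoscreenError):
    """A building rule or building block failed validation."""


class EmptyLibraryError(EvoscreenError):
    """An operation requires at least one usable reaction."""


class AssemblyError(EvoscreenError):
    """A reaction template could not be applied to the given substrates."""


class UsageError(EvoscreenError):
    """A substrate was used in a slot where it is not allowed."""


class OracleConfigError(EvoscreenError):
    """The docking-oracle configuration is invalid."""


class ScoreTableError(EvoscreenError):
    """An external docking score table could not be parsed."""


class InputError(EvoscreenError):
    """Generic invalid-input error for filter and analysis operations."""
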