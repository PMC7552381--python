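"""Exception hierarchy shared across the package.

All errors derive from :class:`MirsigError` so callers can catch the package's
failures with one clause; each subclass also derives from the closest builtin
(``ValueError`` for bad data, ``RuntimeError`` for stage failures) so existing
generic handlers keep working.
"""


class MirsigError(Exception):
    """Base class for all package errors."""


class FormatError(MirsigError, ValueError):
    """A file does not conform to the expected dialect (missing column, bad row)."""


class InputError(MirsigError, ValueError):
    """An input is structurally valid but unusable (empty file, zero retained rows)."""


class ValidationError(MirsigError, ValueError):
    """A value violates a domain invariant (p outside [0,1], empty gene symbol...)."""


class ConfigurationError(MirsigError, ValueError):
    """A configuration references missing inputs or inconsistent settings."""


class PipelineError(MirsigError, RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
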