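"""Exception hierarchy shared across the toolkit.

Every error a caller is expected to handle derives from :class:`NmmError`,
so CLI commands can map the whole family onto a single non-zero exit code.
"""


class NmmError(Exception):
    """Base class for all domain errors raised by nmmkit."""


class NmmValidationError(NmmError):
    """Input violates a type invariant (malformed token, missing component)."""


class NmmParseError(NmmError):
    """Text could not be parsed (systematic name, NMM ID, strict MLMD)."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class NotFoundError(NmmError):
    """A record, section, or revision id does not exist."""


class CycleError(NmmError):
    """Coreference edges form a cycle; the offending cycle is attached."""

    def __init__(self, message: str, cycle: list | None = None):
        super().__init__(message)
        self.cycle = cycle or []


class KbLoadError(NmmError):
    """A knowledge-base directory failed validation (missing file,
    duplicate id, dangling reference); the message names the offender."""


class StateError(NmmError):
    """An operation was applied in an illegal state (e.g. re-reviewing a
    revision that is no longer pending)."""


class IntegrityError(NmmError):
    """A backend's output failed post-hoc validation (dropped annotation,
    citation outside the retrieval context in strict settings)."""
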