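"""Exception hierarchy shared across the package."""


class EntrezAgentError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EntrezAgentError):
    """A prompt configuration names an unknown component or one with no body."""


class ValidationError(EntrezAgentError):
    """A request or record violates a structural invariant (names the field)."""


class ExtractionError(EntrezAgentError):
    """A URL or RID could not be extracted from the given text."""


class TransportError(EntrezAgentError):
    """An HTTP request failed after the retry policy was exhausted."""

    def __init__(self, message: str, status: int | None = None):
        super().__init__(message)
        self.status = status


class CassetteMissError(EntrezAgentError):
    """Replay transport has no recorded entry for the requested URL."""


class PollTimeoutError(EntrezAgentError):
    """BLAST polling exceeded max_wait; carries the last response body."""

    def __init__(self, message: str, last_body: str = ""):
        super().__init__(message)
        self.last_body = last_body
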