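"""Exception hierarchy shared by all skiff modules."""

from __future__ import annotations


class SkiffError(Exception):
    """Base class for all errors raised by skiff."""


class ConfigurationError(SkiffError):
    """Invalid server or module configuration (malformed URL, missing credentials...)."""


class AuthenticationError(SkiffError):
    """Token exchange, refresh and reauthentication all failed."""


class TransportError(SkiffError):
    """The HTTP request never produced a response (connection refused, reset...)."""


class HttpError(SkiffError):
    """A non-success HTTP status after retries were exhausted."""

    def __init__(self, status: int, url: str, body_excerpt: str = ""):
        self.status = status
        self.url = url
        self.body_excerpt = body_excerpt[:400]
        super().__init__(f"HTTP {status} for {url}: {self.body_excerpt!r}")


class NotFoundError(HttpError):
    """HTTP 404 mapped onto a dedicated type for callers that treat it specially."""

    def __init__(self, url: str, body_excerpt: str = ""):
        super().__init__(404, url, body_excerpt)


class ParseError(SkiffError):
    """Response body was not valid JSON."""


class MalformedBundleError(SkiffError):
    """A search response was not a FHIR Bundle."""


class PathSyntaxError(SkiffError):
    """A FHIRPath expression falls outside the supported grammar.

    ``position`` is the character offset of the offending token.
    """

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at position {position})")


class PathTypeError(SkiffError):
    """A string function (replace/join) was applied to non-string values."""


class ExtractionError(SkiffError):
    """Flattening a resource or running a processing function failed."""


class CorruptSeriesError(SkiffError):
    """A DICOM series could not be stored in a usable form (e.g. zero instances)."""


class WriteError(SkiffError):
    """Filesystem failure while storing a DICOM series."""
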