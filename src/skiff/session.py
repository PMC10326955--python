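"""Authenticated HTTP sessions for FHIR servers.

A :class:`Session` bundles a validated :class:`ServerConfig` with the headers
that encode the chosen authentication method (none, HTTP basic, or bearer
token) and is the single HTTP entry point used by every other module.  Token
sessions are kept fresh both proactively (when the token age exceeds
``token_refresh_interval``) and reactively (on a 401 response), by first
attempting a refresh and then falling back to full reauthentication.

The actual wire transfer is delegated to a :class:`Transport`, so the same
session logic runs against a real server (:class:`UrllibTransport`) or an
in-process mock (see :mod:`skiff.synthetic`).
"""

from __future__ import annotations

import base64
import json
import logging
import os
import ssl
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import (
    AuthenticationError,
    ConfigurationError,
    HttpError,
    NotFoundError,
    ParseError,
    TransportError,
)

logger = logging.getLogger(__name__)

AUTH_METHODS = ("none", "basic", "token")

ParamsLike = Mapping[str, "str | Sequence[str]"] | Sequence[tuple[str, str]] | None


def normalize_base_url(url: str) -> str:
    """Strip trailing slashes and validate that ``url`` looks like an HTTP URL.

    Normalization is idempotent: ``normalize_base_url(normalize_base_url(u))``
    equals ``normalize_base_url(u)``.
    """
    url = url.strip().rstrip("/")
    parsed = urllib.parse.urlparse(url)
    if parsed.scheme not in ("http", "https") or not parsed.netloc:
        raise ConfigurationError(f"base_url is not a valid http(s) URL: {url!r}")
    return url


@dataclass
class ServerConfig:
    """Connection settings for one FHIR server.

    Credentials never live in config files; :meth:`from_file` reads them from
    the ``SKIFF_USERNAME`` / ``SKIFF_PASSWORD`` / ``SKIFF_TOKEN`` environment
    variables.
    """

    base_url: str
    auth_method: str = "none"
    username: str | None = None
    password: str | None = None
    token: str | None = None
    token_url: str | None = None
    token_refresh_interval: float | None = None
    extra_headers: dict[str, str] = field(default_factory=dict)
    timeout: float = 30.0
    max_retries: int = 3
    retry_backoff_base: float = 1.0
    verify_tls: bool = True

    def __post_init__(self) -> None:
        self.base_url = normalize_base_url(self.base_url)
        if self.auth_method not in AUTH_METHODS:
            raise ConfigurationError(
                f"auth_method must be one of {AUTH_METHODS}, got {self.auth_method!r}"
            )
        if self.auth_method == "basic" and not (self.username and self.password):
            raise ConfigurationError("basic auth requires username and password")
        if self.auth_method == "token" and not (
            self.token or (self.username and self.password)
        ):
            raise ConfigurationError(
                "token auth requires either a token or username/password "
                "for the initial exchange"
            )
        if self.max_retries < 0:
            raise ConfigurationError("max_retries must be >= 0")
        if self.token_url is None:
            self.token_url = self.base_url + "/token"

    @classmethod
    def from_file(cls, path: str, **overrides) -> "ServerConfig":
        """Load the ``[server]`` section of a TOML file.

        Recognized keys: base_url, auth_method, timeout, max_retries,
        retry_backoff_base, token_refresh_interval, token_url, verify_tls.
        """
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        server = data.get("server", {})
        if "base_url" not in server:
            raise ConfigurationError(f"{path}: missing server.base_url")
        for forbidden in ("username", "password", "token"):
            if forbidden in server:
                raise ConfigurationError(
                    f"{path}: credentials must not appear in config files; "
                    f"use the SKIFF_{forbidden.upper()} environment variable"
                )
        kwargs = {
            key: server[key]
            for key in (
                "base_url",
                "auth_method",
                "timeout",
                "max_retries",
                "retry_backoff_base",
                "token_refresh_interval",
                "token_url",
                "verify_tls",
            )
            if key in server
        }
        kwargs["username"] = os.environ.get("SKIFF_USERNAME")
        kwargs["password"] = os.environ.get("SKIFF_PASSWORD")
        kwargs["token"] = os.environ.get("SKIFF_TOKEN")
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class TransportResponse:
    status: int
    headers: dict[str, str]
    data: bytes


class Transport:
    """Minimal HTTP transport interface: one blocking request, bytes in/out."""

    def request(
        self,
        method: str,
        url: str,
        headers: Mapping[str, str] | None = None,
        body: bytes | None = None,
        timeout: float = 30.0,
    ) -> TransportResponse:
        raise NotImplementedError


class UrllibTransport(Transport):
    """Stdlib transport. TLS verification is on unless explicitly disabled."""

    def __init__(self, verify_tls: bool = True):
        self._context = None
        if not verify_tls:
            self._context = ssl.create_default_context()
            self._context.check_hostname = False
            self._context.verify_mode = ssl.CERT_NONE

    def request(self, method, url, headers=None, body=None, timeout=30.0):
        req = urllib.request.Request(url, data=body, method=method)
        for key, value in (headers or {}).items():
            req.add_header(key, value)
        try:
            with urllib.request.urlopen(
                req, timeout=timeout, context=self._context
            ) as resp:
                return TransportResponse(resp.status, dict(resp.headers), resp.read())
        except urllib.error.HTTPError as exc:
            return TransportResponse(exc.code, dict(exc.headers or {}), exc.read())
        except (urllib.error.URLError, OSError) as exc:
            raise TransportError(f"{method} {url}: {exc}") from exc


def _encode_params(params: ParamsLike) -> str:
    if not params:
        return ""
    if isinstance(params, Mapping):
        pairs: list[tuple[str, str]] = []
        for key, value in params.items():
            if isinstance(value, (list, tuple)):
                pairs.extend((key, str(v)) for v in value)
            else:
                pairs.append((key, str(value)))
    else:
        pairs = [(k, str(v)) for k, v in params]
    return urllib.parse.urlencode(pairs)


class Session:
    """An authenticated HTTP context bound to one FHIR server.

    Use :func:`create_session` rather than constructing directly.
    """

    def __init__(self, config: ServerConfig, transport: Transport | None = None):
        self.config = config
        self.transport = transport or UrllibTransport(verify_tls=config.verify_tls)
        self.token: str | None = config.token
        self.token_issued_at: float | None = None
        self.headers: dict[str, str] = {}
        self._rebuild_headers()

    def _rebuild_headers(self) -> None:
        headers = {"Accept": "application/fhir+json, application/json"}
        headers.update(self.config.extra_headers)
        if self.config.auth_method == "basic":
            raw = f"{self.config.username}:{self.config.password}".encode()
            headers["Authorization"] = "Basic " + base64.b64encode(raw).decode()
        elif self.config.auth_method == "token" and self.token:
            headers["Authorization"] = f"Bearer {self.token}"
        self.headers = headers

    # -- token lifecycle ---------------------------------------------------

    def _token_age(self) -> float | None:
        if self.token_issued_at is None:
            return None
        return time.monotonic() - self.token_issued_at

    def _exchange_token(self) -> str:
        """Full reauthentication: POST credentials to the token endpoint."""
        if not (self.config.username and self.config.password):
            raise AuthenticationError(
                "cannot reauthenticate: no username/password configured"
            )
        body = urllib.parse.urlencode(
            {"username": self.config.username, "password": self.config.password}
        ).encode()
        try:
            resp = self.transport.request(
                "POST",
                self.config.token_url,
                headers={"Content-Type": "application/x-www-form-urlencoded"},
                body=body,
                timeout=self.config.timeout,
            )
        except TransportError as exc:
            raise AuthenticationError(f"token endpoint unreachable: {exc}") from exc
        if resp.status != 200:
            raise AuthenticationError(
                f"token exchange rejected with HTTP {resp.status}"
            )
        return _parse_token_body(resp.data)

    def _refresh_current_token(self) -> str:
        """Rotate the current token via the refresh endpoint."""
        if not self.token:
            raise AuthenticationError("no token to refresh")
        resp = self.transport.request(
            "POST",
            self.config.token_url + "/refresh",
            headers={"Authorization": f"Bearer {self.token}"},
            timeout=self.config.timeout,
        )
        if resp.status != 200:
            raise AuthenticationError(f"token refresh rejected with HTTP {resp.status}")
        return _parse_token_body(resp.data)

    # -- request loop ------------------------------------------------------

    def get_json(self, url: str, params: ParamsLike = None) -> dict:
        """GET ``url`` and parse the body as JSON.

        Retries transport failures and 5xx responses up to
        ``config.max_retries`` times with exponential backoff; on a 401 with
        token auth, refreshes the token and retries once more.
        """
        query = _encode_params(params)
        if query:
            url = url + ("&" if "?" in url else "?") + query
        if self.config.auth_method == "token":
            interval = self.config.token_refresh_interval
            age = self._token_age()
            if interval is not None and age is not None and age >= interval:
                refresh_token(self)

        attempts = self.config.max_retries + 1
        delay = self.config.retry_backoff_base
        reauthed = False
        last_error: Exception | None = None
        attempt = 0
        while attempt < attempts:
            try:
                resp = self.transport.request(
                    "GET", url, headers=self.headers, timeout=self.config.timeout
                )
            except TransportError as exc:
                last_error = exc
                attempt += 1
                if attempt < attempts:
                    logger.warning(
                        "retrying after transport error (%d/%d): %s",
                        attempt,
                        self.config.max_retries,
                        exc,
                    )
                    time.sleep(delay)
                    delay *= 2
                continue
            if resp.status == 401 and self.config.auth_method == "token" and not reauthed:
                logger.info("401 received; refreshing token and retrying once")
                refresh_token(self, force=True)
                reauthed = True
                continue
            if 200 <= resp.status < 300:
                try:
                    return json.loads(resp.data.decode("utf-8"))
                except (ValueError, UnicodeDecodeError) as exc:
                    raise ParseError(f"non-JSON body from {url}: {exc}") from exc
            if resp.status >= 500:
                last_error = HttpError(resp.status, url, resp.data.decode("utf-8", "replace"))
                attempt += 1
                if attempt < attempts:
                    logger.warning(
                        "retrying after HTTP %d (%d/%d)",
                        resp.status,
                        attempt,
                        self.config.max_retries,
                    )
                    time.sleep(delay)
                    delay *= 2
                continue
            excerpt = resp.data.decode("utf-8", "replace")
            if resp.status == 404:
                raise NotFoundError(url, excerpt)
            raise HttpError(resp.status, url, excerpt)
        assert last_error is not None
        raise last_error


def _parse_token_body(data: bytes) -> str:
    try:
        payload = json.loads(data.decode("utf-8"))
        token = payload["access_token"]
    except (ValueError, KeyError, UnicodeDecodeError) as exc:
        raise AuthenticationError(f"malformed token response: {exc}") from exc
    if not token:
        raise AuthenticationError("token endpoint returned an empty token")
    return token


def create_session(config: ServerConfig, transport: Transport | None = None) -> Session:
    """Build a :class:`Session` whose headers encode ``config.auth_method``.

    Side-effect-free for auth_method ``none`` and ``basic``; for ``token``
    without a pre-supplied token, performs the initial token exchange.
    """
    session = Session(config, transport)
    if config.auth_method == "token" and session.token is None:
        session.token = session._exchange_token()
        session.token_issued_at = time.monotonic()
        session._rebuild_headers()
    elif config.auth_method == "token":
        session.token_issued_at = time.monotonic()
    return session


def refresh_token(session: Session, force: bool = False) -> Session:
    """Ensure ``session`` carries a live token.

    A no-op when the token is younger than ``token_refresh_interval`` (unless
    ``force``).  Tries the refresh endpoint first, then falls back to full
    reauthentication; raises :class:`AuthenticationError` if both fail.
    """
    if session.config.auth_method != "token":
        raise ConfigurationError("refresh_token requires auth_method='token'")
    interval = session.config.token_refresh_interval
    age = session._token_age()
    if not force and interval is not None and age is not None and age < interval:
        return session
    old_token = session.token
    try:
        new_token = session._refresh_current_token()
    except (AuthenticationError, TransportError) as exc:
        logger.info("token refresh failed (%s); attempting full reauthentication", exc)
        new_token = session._exchange_token()
    session.token = new_token
    session.token_issued_at = time.monotonic()
    session._rebuild_headers()
    if old_token == new_token:
        logger.debug("token endpoint returned an unchanged token")
    return session
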