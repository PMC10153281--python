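"""NCBI Web API client: URL construction, transports, record/replay.

Two URL families are supported.  The Entrez Programming Utilities (E-utils)
use a fixed syntax ``https://eutils.ncbi.nlm.nih.gov/entrez/eutils/
{function}.fcgi`` with ``function`` one of esearch (term -> identifier
list), efetch (identifiers -> full records), or esummary (identifiers ->
text summaries).  The BLAST URL API at ``https://blast.ncbi.nlm.nih.gov/
blast/Blast.cgi`` takes a mandatory ``CMD`` parameter: ``CMD=Put`` submits a
query sequence and returns an RID; ``CMD=Get`` with that RID retrieves the
results once the server-side job finishes.

URL building is a pure function: parameters are rendered db-first (CMD-first
for BLAST) then in sorted key order, so the same request always produces the
same URL — which doubles as the cassette key for record/replay.  Live
requests go through stdlib ``urllib`` under a rate limit (NCBI allows 3
requests/s without an API key, 10 with one) and a small retry policy
(3 attempts, exponential backoff, retrying only 429 and 5xx responses).
Replay mode never touches the network and fails loudly on a cassette miss.
"""

from __future__ import annotations

import json
import re
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal

from entrez_agent.errors import (
    CassetteMissError,
    ExtractionError,
    PollTimeoutError,
    TransportError,
    ValidationError,
)

EUTILS_BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/{function}.fcgi"
BLAST_BASE = "https://blast.ncbi.nlm.nih.gov/blast/Blast.cgi"

EUTILS_FUNCTIONS = ("esearch", "efetch", "esummary")


@dataclass(frozen=True)
class EutilsRequest:
    """One E-utils call: function, target database, query parameters."""

    function: Literal["esearch", "efetch", "esummary"]
    db: str
    params: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.function not in EUTILS_FUNCTIONS:
            raise ValidationError(f"unknown E-utils function: {self.function!r}")
        if not self.db:
            raise ValidationError("db must be non-empty")
        if self.function == "esearch" and not self.params.get("term"):
            raise ValidationError("esearch requires a non-empty 'term' parameter")
        if self.function in ("efetch", "esummary") and not self.params.get("id"):
            raise ValidationError(
                f"{self.function} requires a non-empty 'id' parameter"
            )


@dataclass(frozen=True)
class BlastRequest:
    """One BLAST URL API call (CMD=Put submission or CMD=Get retrieval)."""

    cmd: Literal["Put", "Get"]
    program: str = ""
    database: str = ""
    query: str = ""
    rid: str = ""

    def __post_init__(self) -> None:
        if self.cmd not in ("Put", "Get"):
            raise ValidationError(f"CMD must be Put or Get, got {self.cmd!r}")
        if self.cmd == "Put":
            for name, value in (
                ("PROGRAM", self.program),
                ("DATABASE", self.database),
                ("QUERY", self.query),
            ):
                if not value:
                    raise ValidationError(f"CMD=Put requires a non-empty {name}")
        else:
            if not self.rid:
                raise ValidationError("CMD=Get requires a non-empty RID")


@dataclass
class ApiResponse:
    """A fetched (or replayed) response body plus transport metadata."""

    url: str
    status: int
    body: str
    truncated: bool = False
    fetched_at: str = ""


def build_eutils_url(req: EutilsRequest) -> str:
    """Render the E-utils URL: db first, remaining keys sorted, all encoded."""
    base = EUTILS_BASE.format(function=req.function)
    pairs = [("db", req.db)] + sorted(req.params.items())
    return base + "?" + urllib.parse.urlencode(pairs)


def build_blast_url(req: BlastRequest) -> str:
    """Render the BLAST URL: CMD first, then the command's own parameters."""
    if req.cmd == "Put":
        pairs = [
            ("CMD", "Put"),
            ("PROGRAM", req.program),
            ("DATABASE", req.database),
            ("QUERY", req.query),
        ]
    else:
        pairs = [("CMD", "Get"), ("RID", req.rid)]
    return BLAST_BASE + "?" + urllib.parse.urlencode(pairs)


_RID_RE = re.compile(r"\bRID\s*=\s*(\S+)")


def extract_rid(put_response_body: str) -> str:
    """Pull the request identifier out of a CMD=Put response.

    The first ``RID = <token>`` field wins; a body with no RID field means
    the BLAST submission failed.
    """
    match = _RID_RE.search(put_response_body)
    if match is None:
        raise ExtractionError("no RID field found in BLAST Put response")
    return match.group(1)


def normalize_url(url: str) -> str:
    """Canonical cassette key: same scheme/host/path, query keys sorted."""
    parts = urllib.parse.urlsplit(url)
    pairs = sorted(urllib.parse.parse_qsl(parts.query, keep_blank_values=True))
    query = urllib.parse.urlencode(pairs)
    return urllib.parse.urlunsplit(
        (parts.scheme, parts.netloc, parts.path, query, "")
    )


class Cassette:
    """URL-keyed store of recorded responses, persisted as one JSON file.

    Each normalized URL maps to an *ordered list* of entries so that
    polling sequences (repeated CMD=Get calls) replay in order.  Replay
    consumes the list and then keeps returning the final entry.
    """

    def __init__(self, entries: dict[str, list[dict]] | None = None):
        self.entries: dict[str, list[dict]] = entries or {}
        self._cursor: dict[str, int] = {}

    @classmethod
    def load(cls, path: str | Path) -> "Cassette":
        data = json.loads(Path(path).read_text("utf-8"))
        return cls(entries=data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.entries, indent=1, sort_keys=True), "utf-8"
        )

    def record(self, url: str, status: int, body: str, fetched_at: str = "") -> None:
        key = normalize_url(url)
        self.entries.setdefault(key, []).append(
            {"status": status, "body": body, "fetched_at": fetched_at}
        )

    def replay(self, url: str) -> dict:
        key = normalize_url(url)
        if key not in self.entries or not self.entries[key]:
            raise CassetteMissError(f"no cassette entry for {key}")
        seq = self.entries[key]
        i = self._cursor.get(key, 0)
        entry = seq[min(i, len(seq) - 1)]
        self._cursor[key] = i + 1
        return entry

    def rewind(self) -> None:
        self._cursor.clear()


class RateLimiter:
    """Enforce a minimum interval between consecutive live requests."""

    def __init__(self, requests_per_second: float = 3.0):
        self.min_interval = 1.0 / requests_per_second
        self._last = 0.0

    def wait(self) -> None:
        now = time.monotonic()
        remaining = self._last + self.min_interval - now
        if remaining > 0:
            time.sleep(remaining)
        self._last = time.monotonic()


class Transport:
    """Base transport; subclasses implement :meth:`fetch`."""

    def fetch(self, url: str) -> ApiResponse:  # pragma: no cover - interface
        raise NotImplementedError


class LiveTransport(Transport):
    """HTTP GET via urllib with rate limiting and bounded retries.

    ``tool``, ``email``, and ``api_key`` identify the caller to NCBI and are
    appended to every E-utils URL when configured; an API key raises the
    permitted request rate from 3/s to 10/s.
    """

    def __init__(
        self,
        requests_per_second: float | None = None,
        max_attempts: int = 3,
        backoff: float = 1.0,
        timeout: float = 30.0,
        tool: str = "",
        email: str = "",
        api_key: str = "",
    ):
        if requests_per_second is None:
            requests_per_second = 10.0 if api_key else 3.0
        self.limiter = RateLimiter(requests_per_second)
        self.max_attempts = max_attempts
        self.backoff = backoff
        self.timeout = timeout
        self.identity = {
            k: v
            for k, v in (("tool", tool), ("email", email), ("api_key", api_key))
            if v
        }

    def _decorate(self, url: str) -> str:
        if not self.identity or not url.startswith("https://eutils."):
            return url
        extra = urllib.parse.urlencode(sorted(self.identity.items()))
        sep = "&" if "?" in url else "?"
        return url + sep + extra

    def fetch(self, url: str) -> ApiResponse:
        url = self._decorate(url)
        last_status: int | None = None
        for attempt in range(1, self.max_attempts + 1):
            self.limiter.wait()
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    body = resp.read().decode("utf-8", errors="replace")
                    return ApiResponse(
                        url=url,
                        status=resp.status,
                        body=body,
                        fetched_at=datetime.now(timezone.utc).isoformat(),
                    )
            except urllib.error.HTTPError as err:
                last_status = err.code
                retryable = err.code == 429 or err.code >= 500
                if not retryable or attempt == self.max_attempts:
                    raise TransportError(
                        f"HTTP {err.code} fetching {url}", status=err.code
                    ) from err
            except urllib.error.URLError as err:
                if attempt == self.max_attempts:
                    raise TransportError(f"network error fetching {url}: {err.reason}") from err
            time.sleep(self.backoff * 2 ** (attempt - 1))
        raise TransportError(f"retries exhausted for {url}", status=last_status)


class ReplayTransport(Transport):
    """Offline transport: every fetch is served from the cassette.

    Never opens a network connection; an unrecorded URL raises
    :class:`CassetteMissError` rather than silently falling back to live.
    """

    def __init__(self, cassette: Cassette):
        self.cassette = cassette

    def fetch(self, url: str) -> ApiResponse:
        entry = self.cassette.replay(url)
        return ApiResponse(
            url=url,
            status=entry.get("status", 200),
            body=entry["body"],
            fetched_at=entry.get("fetched_at", ""),
        )


class RecordTransport(Transport):
    """Live transport that also persists every response into a cassette."""

    def __init__(self, live: LiveTransport, cassette: Cassette, path: str | Path):
        self.live = live
        self.cassette = cassette
        self.path = Path(path)

    def fetch(self, url: str) -> ApiResponse:
        resp = self.live.fetch(url)
        self.cassette.record(url, resp.status, resp.body, resp.fetched_at)
        self.cassette.save(self.path)
        return resp


def execute(url: str, transport: Transport) -> ApiResponse:
    """Run one API call through the given transport."""
    return transport.fetch(url)


@dataclass
class PollPolicy:
    """BLAST retrieval cadence: seconds between Gets and total wait budget."""

    interval: float = 10.0
    max_wait: float = 300.0


@dataclass
class PollResult:
    response: ApiResponse
    attempts: int


def _blast_ready(body: str) -> bool:
    # QBlast reports Status=WAITING in its comment block until the job ends.
    return "WAITING" not in body


def blast_poll(
    rid: str, transport: Transport, policy: PollPolicy | None = None
) -> PollResult:
    """Poll CMD=Get until the result is ready or the wait budget runs out."""
    if not rid:
        raise ValidationError("rid must be non-empty")
    policy = policy or PollPolicy()
    url = build_blast_url(BlastRequest(cmd="Get", rid=rid))
    deadline = time.monotonic() + policy.max_wait
    attempts = 0
    last_body = ""
    while True:
        attempts += 1
        resp = execute(url, transport)
        last_body = resp.body
        if _blast_ready(resp.body):
            return PollResult(response=resp, attempts=attempts)
        if time.monotonic() >= deadline:
            raise PollTimeoutError(
                f"BLAST RID {rid} not ready after {attempts} attempts",
                last_body=last_body,
            )
        if policy.interval:
            time.sleep(policy.interval)
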