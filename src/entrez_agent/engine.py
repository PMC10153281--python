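"""Interleaved decode-execute loop.

The agent answers a question by letting a text-generation backend continue
the assembled prompt at temperature 0, watching the emitted text for two
signals learned from the in-context demonstrations:

* the **call indicator** ``–>`` right after a bracketed URL — generation is
  paused, the last URL in the context is extracted and executed against the
  NCBI API (live or replayed), and the raw result is spliced back into the
  context before generation resumes;
* the **answer indicator** — an ``Answer:`` line terminated by a blank line
  (``\\n\\n``) — which ends the episode; the answer is the text after the
  last ``Answer:``.

Generation is chunked rather than token-by-token: the backend is asked to
continue until it hits one of the stop signals, which is observably
equivalent at temperature 0.  Budgets on the number of API calls and on
total context length guarantee termination even for a backend that never
produces an answer.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol

from entrez_agent.client import ApiResponse, Transport, execute
from entrez_agent.errors import ExtractionError
from entrez_agent.prompts import ComponentStore, PromptConfig, assemble_prompt

#: Canonical call indicator as printed in the demonstrations (en dash).
CALL_INDICATOR = "–>"
#: Episode terminator: blank line after the answer.
ANSWER_TERMINATOR = "\n\n"
#: Marker appended to API bodies cut down to the per-result budget.
TRUNCATION_MARKER = "[...truncated]"

# The indicator may be rendered with an en dash ("–>"), in ASCII ("->"),
# or spaced (" – > "); all three trigger a call.
_INDICATOR_RE = re.compile(r"[-–]\s?>")

_URL_RE = re.compile(r"https?://[^\s\]\[]+")
_ANSWER_RE = re.compile(r"Answer:\s*")


class GenerationBackend(Protocol):
    """Anything that can deterministically continue a text prefix."""

    deterministic: bool

    def generate(
        self, prefix: str, stop_signals: Iterable[str], max_new: int
    ) -> str:
        """Return the next chunk, ending at (and including) the first stop
        signal it emits, or after ``max_new`` characters."""
        ...


class ScriptExhausted(Exception):
    """A scripted backend ran out of chunks before the episode finished."""


class ScriptedBackend:
    """Replays a fixed transcript of chunks, ignoring the prefix.

    This is the deterministic stand-in for a real language model: each call
    to :meth:`generate` returns the next chunk of the script verbatim.  Used
    by the test fixtures and by episode replay.
    """

    deterministic = True

    def __init__(self, chunks: Iterable[str]):
        self.chunks = list(chunks)
        self._next = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "ScriptedBackend":
        data = json.loads(Path(path).read_text("utf-8"))
        return cls(data["chunks"] if isinstance(data, dict) else data)

    def generate(self, prefix: str, stop_signals: Iterable[str], max_new: int) -> str:
        if self._next >= len(self.chunks):
            raise ScriptExhausted(
                f"script exhausted after {self._next} chunks"
            )
        chunk = self.chunks[self._next]
        self._next += 1
        return chunk

    def reset(self) -> None:
        self._next = 0


@dataclass
class EngineLimits:
    """Termination budgets, all positive.

    ``max_calls`` caps API calls per episode (the longest observed multi-hop
    chain needs 4; the default leaves headroom).  ``context_budget`` bounds
    the total character length of prompt plus generated tail, standing in
    for the backend's context window.  ``result_budget`` bounds each spliced
    API body.
    """

    max_calls: int = 10
    context_budget: int = 32000
    result_budget: int = 4000

    def __post_init__(self) -> None:
        if min(self.max_calls, self.context_budget, self.result_budget) <= 0:
            raise ValueError("all engine limits must be positive")


@dataclass
class Segment:
    kind: str  # "generated" | "api_result"
    text: str


@dataclass
class CallRecord:
    url: str
    status: int
    truncated: bool


@dataclass
class Episode:
    """Full trace of one question: segments, calls, termination state."""

    question: str
    config_name: str
    segments: list[Segment] = field(default_factory=list)
    calls: list[CallRecord] = field(default_factory=list)
    finished: bool = False
    answer: str | None = None
    halt_reason: str = ""  # answered | call_budget | context_budget | backend_error

    @property
    def tail(self) -> str:
        """Concatenation of all segments: the context appended after the prompt."""
        return "".join(s.text for s in self.segments)

    def to_json(self) -> str:
        return json.dumps(
            {
                "question": self.question,
                "config": self.config_name,
                "segments": [{"kind": s.kind, "text": s.text} for s in self.segments],
                "calls": [
                    {"url": c.url, "status": c.status, "truncated": c.truncated}
                    for c in self.calls
                ],
                "finished": self.finished,
                "answer": self.answer,
                "halt_reason": self.halt_reason,
            },
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, line: str) -> "Episode":
        d = json.loads(line)
        ep = cls(question=d["question"], config_name=d["config"])
        ep.segments = [Segment(**s) for s in d["segments"]]
        ep.calls = [CallRecord(**c) for c in d["calls"]]
        ep.finished = d["finished"]
        ep.answer = d["answer"]
        ep.halt_reason = d["halt_reason"]
        return ep


def detect_call_indicator(chunk: str) -> tuple[bool, int]:
    """Does the chunk stop on a call indicator?  Returns (flag, position).

    The position is the start of the last indicator occurrence; -1 when
    absent.  Only an indicator at the chunk's stop point (its end, modulo
    trailing whitespace) counts as a call request.
    """
    last = None
    for m in _INDICATOR_RE.finditer(chunk):
        last = m
    if last is None:
        return False, -1
    if chunk[last.end():].strip() == "":
        return True, last.start()
    return False, last.start()


def extract_last_url(context: str) -> str:
    """Rightmost URL in the context, with markup brackets stripped."""
    matches = _URL_RE.findall(context)
    if not matches:
        raise ExtractionError("no URL found in context")
    return matches[-1].rstrip(".,;")


def extract_answer(context: str) -> str:
    """Text between the last ``Answer:`` and the following blank line.

    Surrounding whitespace and one level of ``[ ]`` markup are stripped.
    Returns the empty string when no answer line is present.
    """
    last = None
    for m in _ANSWER_RE.finditer(context):
        last = m
    if last is None:
        return ""
    rest = context[last.end():]
    end = rest.find(ANSWER_TERMINATOR)
    answer = rest if end < 0 else rest[:end]
    answer = answer.strip()
    if answer.startswith("[") and answer.endswith("]"):
        answer = answer[1:-1].strip()
    return answer


def truncate_result(body: str, result_budget: int) -> str:
    """Head-keep truncation to the per-result budget, idempotent."""
    if result_budget <= 0:
        raise ValueError("result_budget must be positive")
    if len(body) <= result_budget:
        return body
    if body.endswith(TRUNCATION_MARKER) and len(body) <= result_budget + len(
        TRUNCATION_MARKER
    ):
        return body
    return body[:result_budget] + TRUNCATION_MARKER


def run_episode(
    question: str,
    config: PromptConfig,
    backend: GenerationBackend,
    transport: Transport,
    limits: EngineLimits | None = None,
    store: ComponentStore | None = None,
) -> Episode:
    """Run the decode-execute loop for one question.

    Answer extraction is scoped to the generated tail only, so the
    ``Answer:`` lines inside the in-prompt demonstrations never leak into
    the extracted answer.
    """
    limits = limits or EngineLimits()
    prompt = assemble_prompt(config, question, store)
    if len(prompt) > limits.context_budget:
        raise ValueError(
            f"prompt length {len(prompt)} exceeds context budget "
            f"{limits.context_budget}"
        )
    episode = Episode(question=question, config_name=config.name or "custom")
    stop_signals = (CALL_INDICATOR, ANSWER_TERMINATOR)

    while True:
        context = prompt + episode.tail
        remaining = limits.context_budget - len(context)
        if remaining <= 0:
            episode.halt_reason = "context_budget"
            break
        try:
            chunk = backend.generate(context, stop_signals, max_new=remaining)
        except Exception:
            episode.halt_reason = "backend_error"
            break
        episode.segments.append(Segment(kind="generated", text=chunk))

        is_call, _ = detect_call_indicator(chunk)
        if is_call:
            if len(episode.calls) >= limits.max_calls:
                episode.halt_reason = "call_budget"
                break
            try:
                url = extract_last_url(prompt + episode.tail)
            except ExtractionError:
                episode.halt_reason = "backend_error"
                break
            response = _execute_with_retry(url, transport)
            body = truncate_result(response.body, limits.result_budget)
            truncated = body != response.body
            episode.calls.append(
                CallRecord(url=url, status=response.status, truncated=truncated)
            )
            episode.segments.append(Segment(kind="api_result", text=f"[{body}]"))
            continue

        if ANSWER_TERMINATOR in chunk or chunk.endswith("\n\n"):
            answer = extract_answer(episode.tail)
            if answer:
                episode.answer = answer
                episode.finished = True
                episode.halt_reason = "answered"
            else:
                # terminator without an answer line: flagged, not answered
                episode.halt_reason = "backend_error"
            break
        # no stop signal in the chunk (max_new reached): loop; the context
        # budget check at the top guarantees termination.


    return episode


def _execute_with_retry(url: str, transport: Transport) -> ApiResponse:
    """One retry of the same URL; on final failure the error text becomes
    the result so the backend can see it and recover."""
    for attempt in (1, 2):
        try:
            return execute(url, transport)
        except Exception as err:  # TransportError, cassette miss, ...
            if attempt == 2:
                return ApiResponse(url=url, status=0, body=f"API error: {err}")
    raise AssertionError("unreachable")


def write_episode_log(episodes: Iterable[Episode], path: str | Path) -> None:
    """Persist episodes as one JSON record per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for ep in episodes:
            fh.write(ep.to_json() + "\n")


def read_episode_log(path: str | Path) -> list[Episode]:
    with open(path, encoding="utf-8") as fh:
        return [Episode.from_json(line) for line in fh if line.strip()]
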