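# Methods

## The agent loop

The core procedure interleaves text generation with Web API execution.
Let `P` be the assembled prompt and `T` the generated tail (initially
empty).  Repeatedly ask the backend to continue `P + T` at temperature 0
until it emits one of two stop signals:

* **call indicator** — the token `–>` immediately after a bracketed URL.
  The rightmost `http(s)://…` substring of `P + T` is extracted, executed,
  its body truncated to the per-result budget, and spliced back into `T`
  wrapped in `[ ]`, after which generation resumes;
* **answer indicator** — a blank line (`\n\n`) terminating an `Answer:`
  line.  The episode ends; the answer is the text after the *last*
  `Answer:` in `T` (never in `P`, whose demonstrations also contain answer
  lines), stripped of whitespace and one level of bracket markup.

The loop is chunked rather than token-by-token: the backend runs until it
hits a stop signal.  At temperature 0 this is observationally equivalent to
single-token decoding with the same stop checks, and it matches how modern
completion APIs expose stop sequences.  The indicator is accepted in three
renderings — en dash `–>`, ASCII `->`, and spaced ` – > ` — because
tokenizers differ in how they emit it; only an indicator at the chunk's
stop point triggers a call.

Termination is guaranteed by three budgets (`EngineLimits`):

| parameter | default | meaning |
|---|---|---|
| `max_calls` | 10 | API calls per episode; the longest multi-hop chain observed in practice needs 4, so 10 leaves headroom without permitting runaway loops |
| `context_budget` | 32 000 chars | total prompt + tail length, standing in for the backend's context window (an 8k-token window is roughly this size) |
| `result_budget` | 4 000 chars | per-response splice size; head-keep truncation with an explicit marker, since E-utils responses put identifiers and summaries early |

Transport failures are not fatal: the same URL is retried once, and on
final failure the error text itself is spliced in as the result, letting
the backend see the failure and re-issue a corrected call; the failed
status is recorded on the episode.

## Prompt design

Seven components render in a fixed order: instruction, two API
documentations (E-utils; BLAST), four demonstrations covering
(gene, esearch→efetch), (snp, esummary), (omim, esearch→esummary), and
(nt, blastn Put→Get), then the task question.  The *full* configuration
uses all seven; the *slim* configuration keeps the instruction plus the
gene-alias and alignment demonstrations only, which probing shows to be the
two load-bearing demonstrations.  Ablation configurations drop one
component each; probing configurations keep one each (the instruction is
retained in both families — the conservative reading, since dropping it is
untested).  Components are separated by a single blank line; demonstration
lines use single newlines with a double newline ending each answer block,
so the prompt's own structure matches the engine's stop signals.  In
multi-hop mode the chain-of-thought sentence ("Let’s decompose the question
to sub-questions and solve them step by step.", typographic apostrophe
preserved byte-exactly) is the final line before the generation point.

The shipped component bodies are synthetic placeholders: they honor every
structural invariant the engine depends on (bracketed URLs, the indicator,
answer lines, the Table-style database/function coverage) but their wording
and entities are invented.  Users substituting their own texts only need to
preserve that structure.

## NCBI client

URL building is pure and deterministic: E-utils URLs render `db` first and
remaining parameters in sorted key order; BLAST URLs render `CMD` first.
Parameter order in a query string is semantically irrelevant to the server,
so the fixed order exists for reproducibility — the normalized URL
(sorted parameters) is also the cassette key.  `retmode` is left unset
unless a caller provides it.  RID extraction takes the first
`RID = <token>` field of a `CMD=Put` response.

Live transport uses stdlib `urllib` with a token-interval rate limiter
(3 requests/s by default, 10/s when an `api_key` is configured; `tool` and
`email` are appended to E-utils URLs when set), three attempts with
exponential backoff on 429/5xx, and no retry on other 4xx.  BLAST polling
issues `CMD=Get` every `interval` seconds (default 10) up to `max_wait`
(default 300); a body still containing `WAITING` is not ready.  Replay
transport serves bodies verbatim from the cassette, consuming per-URL entry
lists in order (so polling sequences replay faithfully) and raising on any
miss — it can never silently fall back to the network.

## Evaluation

Exact-match normalization is minimal: trim, collapse internal whitespace,
case-fold, unify en dash with hyphen.  Recall is
`|pred ∩ gold| / |gold|` over normalized items; free-text list answers are
split on commas, semicolons, newlines, and " and ", with surrounding
bracket markup removed.  The species mapping ships with ~15 common model
organisms (only the yeast pair is externally attested; the rest follow the
same convention) and is user-extensible.  Genome-alignment scoring returns
1 when chromosome and interval both match, 0.5 when the chromosomes match
but the intervals differ or exactly one side lacks an interval
(chromosome-only predictions get the benefit of the doubt, since the task
fixes no reference genome), and 0 otherwise; an unparseable prediction
scores 0.  Two chromosome-only locations on the same chromosome count as a
full match, since both sides agree at the stated precision.

Location parsing accepts `chrN`, `chrN:start–end` (en dash, hyphen, or
`..`), bare `N:start-end` with the `chr` prefix inferred, thousands
separators, and chromosomes 1–22, X, Y, M; printing and re-parsing is a
fixed point.

Aggregation is macro throughout: per-task means over questions, per-module
means over member-task means, and the overall score an unweighted mean of
task means.  Values are reported at two decimals, half-up, with raw values
retained.  The gene–SNP association task is scored as exact match by
default (a recall switch exists, since a gene set is also defensible).
Free-text multi-hop answers (gene-function summaries) are not judged
automatically: they are stored for manual annotation, and only structured
sub-answers (location lists, alias sets) are scored by recall.  Error
labels E1–E4/O are annotations supplied by a human on questions with less
than full credit; the harness only validates and tallies them.

## Synthetic fixtures

`make_fixture(seed, n_calls, answer, api_flavor)` builds a scripted
transcript (each call chunk a bracketed, builder-validated NCBI URL ending
in the indicator; a final answer chunk), a cassette of matching synthetic
bodies (E-utils-like `idlist`/summary JSON; BLAST-like RID blocks and
alignment lines with a consistent RID threaded from Put body to Get URL),
and an expected digest `{calls, answer}` computed from the construction —
never by running the engine, so the engine/fixture comparison is a genuine
two-sided check.  `make_multihop_qa` instantiates the three multi-hop task
shapes with gold answers reachable only by chaining calls (the SNP body
embeds the gene id the second call resolves, etc.).  All randomness flows
from one `random.Random(seed)` per bundle, making bundles byte-reproducible.

What the fixtures do *not* emulate: real Entrez/BLAST response schemas
(bodies are minimal look-alikes), model behavior (the scripted backend
ignores its prefix, so nothing here measures whether any actual LLM learns
the API from the prompt), network latency and server-side state, or the
actual benchmark question texts.  Passing the offline suites therefore
demonstrates that the *machinery* — prompt, loop, client, scorer — is
correct and deterministic, not that any particular backend achieves any
particular benchmark score.

## Problem sizes

The integration suite replays 200 seeded bundles spanning 0–6 calls; the
URL round-trip property runs 1 000 randomized requests against the stdlib
parser; the aggregation oracle checks 100 random score tables.  These sizes
keep the full suite in a few seconds while exercising every flavor and
chain length the design distinguishes.

## Known limitations

* No live-model adapter ships with the package; `GenerationBackend` is a
  two-method protocol and adapters are user-supplied.
* Temperature 0 only; no sampling, beam search, or model-side
  function-calling protocols.
* Entrez record semantics are not parsed — raw bodies are passed to the
  backend — so nothing validates that a response actually answers the
  question.
* The automatic scorer is stricter than human grading: paraphrases of a
  correct free-text answer score 0 unless manually annotated.
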