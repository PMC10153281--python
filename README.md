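# entrez-agent

A tool-augmented question-answering agent for genomics, built around the
NCBI Web APIs, together with the automatic evaluation harness for the
GeneTuring-style genomics QA tasks it targets.

Large language models answer *data-intensive* genomics questions badly:
which chromosome carries a gene, which gene an rsID maps to, where a DNA
sequence aligns — these require reciting database entries, not reasoning,
and neither pre-training nor web retrieval covers them.  The approach
implemented here teaches a text-generation backend to call the databases
instead.  A prompt shows the model documentations and worked demonstrations
of two URL APIs:

* **E-utils** — `https://eutils.ncbi.nlm.nih.gov/entrez/eutils/{function}.fcgi`
  with `function` ∈ {`esearch`, `efetch`, `esummary`} over Entrez databases
  (`gene`, `snp`, `omim`, `nt`, …), parameterized by `term`, `id`, `retmax`,
  `retmode`;
* **BLAST URL API** — `https://blast.ncbi.nlm.nih.gov/blast/Blast.cgi` with a
  mandatory `CMD` parameter: `CMD=Put` submits `PROGRAM`/`DATABASE`/`QUERY`
  and returns an RID, `CMD=Get&RID=…` retrieves the finished alignment.

At inference time the decode–execute loop generates at temperature 0 and
watches for two signals learned from the demonstrations: the call indicator
`–>` after a bracketed URL (pause, execute the last URL, splice the raw
result back into the context, resume) and the answer indicator (`Answer: …`
terminated by a blank line, ending the episode).  Chains longer than any
demonstrated example emerge naturally, which is what lets the agent answer
multi-hop questions ("What is the function of the gene associated with SNP
rs…?") with a chain-of-thought instruction appended to the question.

The backend is an interface, not a dependency: any completion-style model
can drive the loop, and a deterministic **scripted backend** plus a JSON
**cassette** record/replay transport make every component — prompt assembly,
URL building, the loop, scoring — fully testable offline.

Scoring follows the benchmark's strict automatic protocol: exact match for
nomenclature and location tasks, recall over exact gene matches for
gene-set tasks, a small vocabulary mapping (yes/no → TRUE/NA, Latin species
names → informal names) where formats differ, half credit for a correct
chromosome with wrong coordinates in genome alignment, and unweighted
macro-averaging of per-task means.  A five-way error taxonomy (E1 wrong
API, E2 wrong arguments, E3 wrong comprehension, E4 unanswerable, O other)
is supported as manual annotations tallied per task.

## Worked example

Generate a seeded synthetic multi-hop fixture (a disease → genes →
locations chain), run the decode–execute loop offline against its cassette,
and score the answer:

```python
from entrez_agent.client import ReplayTransport
from entrez_agent.engine import ScriptedBackend, run_episode
from entrez_agent.fixtures import make_multihop_qa
from entrez_agent.prompts import SLIM
from entrez_agent.scoring import QuestionScore, aggregate, score_recall

qa, bundle = make_multihop_qa(seed=5, template="disease_gene_location")
episode = run_episode(
    qa.question, SLIM,
    backend=ScriptedBackend(bundle.transcript),
    transport=ReplayTransport(bundle.cassette),
)
print("question:   ", qa.question)
print("api calls:  ", len(episode.calls))
print("answer:     ", episode.answer)
print("halt reason:", episode.halt_reason)

score = score_recall(episode.answer, list(qa.gold))
report = aggregate([QuestionScore(id=qa.id, task=qa.task, score=score)])
print("recall:     ", score)
print("overall:    ", report.rounded(report.overall))
```

prints

```
question:    List chromosome locations of the genes related to Model disease C.
api calls:   3
answer:      chr6, chr4
halt reason: answered
recall:      1.0
overall:     1.0
```

The episode made three API calls (one `esearch` against `omim`, then one
`esummary` per gene), the answer lists the two chromosome locations threaded
through the cassette bodies, and recall over parsed locations gives the
question full credit.

A CLI exposes the same operations: `entrez-agent prompt render`,
`entrez-agent api eutils|blast` (with `--transport live|replay|record`),
`entrez-agent run` over a QA file, `entrez-agent score`, and
`entrez-agent fixtures make`.  Live use respects NCBI etiquette: 3
requests/s without an API key (10 with one), bounded retries on transient
errors.

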