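"""QA corpus loading and seeded synthetic fixture generation.

A QA file is line-delimited JSON, one record per line with fields ``id``,
``task``, ``question``, ``gold`` (list of acceptable answers), and ``hop``
(``single`` or ``multi``) — the shape of the genomics QA benchmarks the
agent targets (12 single-hop tasks and 3 multi-hop tasks of 50 pairs each).

Fixture bundles make the whole stack testable offline: a bundle is a
scripted generation transcript whose chunks contain bracketed NCBI URLs
ending in the call indicator, a cassette holding matching synthetic
response bodies, and the expected episode digest (call count and final
answer) computed from the construction itself, never by running the engine.
Running the scripted backend against the replayed cassette and checking
the digest is the repository's primary integration oracle.

The synthetic bodies mimic the field names of real E-utils and BLAST
responses (``idlist``, summaries, ``RID =``, alignment lines) at minimal
fidelity; they are deliberately not schema-complete.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from entrez_agent.client import (
    BlastRequest,
    Cassette,
    EutilsRequest,
    build_blast_url,
    build_eutils_url,
)
from entrez_agent.errors import ValidationError

CALL_INDICATOR = "–>"

_GENE_SYLLABLES = ["ZQ", "GX", "TB", "KL", "MR", "PX", "VD", "HN"]
_FUNCTIONS = [
    "regulates DNA repair in response to replication stress",
    "encodes a transmembrane transporter of zinc ions",
    "mediates microtubule attachment during mitosis",
    "controls hepatic lipid metabolism",
    "acts as a transcriptional repressor of ciliogenesis",
]
_DISEASES = [
    "Example syndrome A",
    "Synthetic disorder B",
    "Model disease C",
]


@dataclass(frozen=True)
class QARecord:
    """One question with its gold answer set."""

    id: str
    task: str
    question: str
    gold: tuple[str, ...]
    hop: str = "single"  # single | multi

    def __post_init__(self) -> None:
        if not self.question.strip():
            raise ValidationError(f"record {self.id}: empty question")
        if not self.gold:
            raise ValidationError(f"record {self.id}: empty gold answer set")
        if self.hop not in ("single", "multi"):
            raise ValidationError(f"record {self.id}: hop must be single|multi")


def load_qa(path: str | Path) -> list[QARecord]:
    """Read a line-delimited JSON QA file, preserving order.

    Malformed lines raise with their line number; duplicate ids raise; an
    empty file returns an empty list with a warning.
    """
    records: list[QARecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                d = json.loads(line)
                rec = QARecord(
                    id=str(d["id"]),
                    task=d["task"],
                    question=d["question"],
                    gold=tuple(d["gold"]),
                    hop=d.get("hop", "single"),
                )
            except (KeyError, ValueError, TypeError, ValidationError) as err:
                raise ValidationError(f"{path}:{lineno}: malformed record: {err}") from err
            if rec.id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            records.append(rec)
    if not records:
        warnings.warn(f"QA file {path} contains no records")
    return records


def write_qa(records: list[QARecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "id": r.id,
                        "task": r.task,
                        "question": r.question,
                        "gold": list(r.gold),
                        "hop": r.hop,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


@dataclass
class FixtureBundle:
    """Transcript + cassette + the digest an episode over them must produce."""

    qa: QARecord
    transcript: list[str]
    cassette: Cassette
    expected: dict = field(default_factory=dict)  # {"calls": int, "answer": str}

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_qa([self.qa], directory / "qa.jsonl")
        (directory / "transcript.json").write_text(
            json.dumps({"chunks": self.transcript}, ensure_ascii=False, indent=1),
            "utf-8",
        )
        self.cassette.save(directory / "cassette.json")
        (directory / "expected.json").write_text(
            json.dumps(self.expected, ensure_ascii=False), "utf-8"
        )


def _gene_name(rng: random.Random) -> str:
    return rng.choice(_GENE_SYLLABLES) + rng.choice(_GENE_SYLLABLES) + str(
        rng.randint(1, 99)
    )


def _eutils_call(rng: random.Random, i: int) -> tuple[str, str]:
    """One synthetic E-utils (url, body) pair."""
    db = rng.choice(["gene", "snp", "omim"])
    if i % 2 == 0:
        term = _gene_name(rng)
        url = build_eutils_url(
            EutilsRequest("esearch", db, {"term": term, "retmode": "json"})
        )
        ids = [str(rng.randint(10_000, 999_999)) for _ in range(rng.randint(1, 3))]
        body = json.dumps({"esearchresult": {"count": str(len(ids)), "idlist": ids}})
    else:
        uid = str(rng.randint(10_000, 999_999))
        fn = rng.choice(["esummary", "efetch"])
        url = build_eutils_url(EutilsRequest(fn, db, {"id": uid, "retmode": "json"}))
        body = json.dumps(
            {"result": {uid: {"uid": uid, "name": _gene_name(rng), "chr": str(rng.randint(1, 22))}}}
        )
    return url, body


def _blast_pair(rng: random.Random) -> list[tuple[str, str]]:
    """A Put/Get pair with a consistent RID threaded through."""
    seq = "".join(rng.choice("ACGT") for _ in range(40))
    rid = f"SYN{rng.randint(0, 10**8):08d}"
    put_url = build_blast_url(BlastRequest("Put", program="blastn", database="nt", query=seq))
    put_body = f"QBlastInfoBegin\n    RID = {rid}\nQBlastInfoEnd"
    get_url = build_blast_url(BlastRequest("Get", rid=rid))
    chrom = rng.randint(1, 22)
    get_body = (
        f"Status=READY\nHomo sapiens chromosome {chrom}, GRCh38 reference assembly\n"
        f"Identities = 40/40 (100%)"
    )
    return [(put_url, put_body), (get_url, get_body)]


def make_fixture(
    seed: int,
    n_calls: int = 0,
    answer: str = "chr2",
    api_flavor: str = "eutils_chain",
) -> FixtureBundle:
    """Deterministically generate a transcript/cassette pair.

    The transcript contains ``n_calls`` chunks, each a bracketed well-formed
    NCBI URL ending in the call indicator, followed by a final answer chunk.
    ``api_flavor`` selects E-utils-style calls, BLAST Put/Get pairs, or a
    mix.  The expected digest is written down from the construction.
    """
    if n_calls < 0:
        raise ValidationError("n_calls must be >= 0")
    if api_flavor not in ("eutils_chain", "blast_chain", "mixed"):
        raise ValidationError(f"unknown api_flavor {api_flavor!r}")
    rng = random.Random(seed)
    pairs: list[tuple[str, str]] = []
    while len(pairs) < n_calls:
        if api_flavor == "eutils_chain":
            pairs.append(_eutils_call(rng, len(pairs)))
        elif api_flavor == "blast_chain":
            pairs.extend(_blast_pair(rng))
        else:  # mixed
            if rng.random() < 0.5 and n_calls - len(pairs) >= 2:
                pairs.extend(_blast_pair(rng))
            else:
                pairs.append(_eutils_call(rng, len(pairs)))
    pairs = pairs[:n_calls]

    cassette = Cassette()
    transcript: list[str] = []
    for url, body in pairs:
        transcript.append(f"[{url}]{CALL_INDICATOR}")
        cassette.record(url, 200, body)
    transcript.append(f"Answer: {answer}\n\n")

    qa = QARecord(
        id=f"fx-{seed}-{n_calls}",
        task="gene_alias",
        question=f"Synthetic fixture question (seed {seed})?",
        gold=(answer,),
    )
    expected = {"calls": n_calls, "answer": answer}
    return FixtureBundle(qa=qa, transcript=transcript, cassette=cassette, expected=expected)


def make_multihop_qa(seed: int, template: str) -> tuple[QARecord, FixtureBundle]:
    """A synthetic multi-hop question whose answer is threaded through the
    cassette, so the right answer is derivable only by chaining calls.

    Templates mirror the three multi-hop task shapes: the function of the
    gene associated with a SNP; the chromosome locations of the genes
    associated with a disease; the aliases of the gene containing a given
    DNA sequence.
    """
    rng = random.Random(seed)
    cassette = Cassette()
    transcript: list[str] = []

    if template == "snp_gene_function":
        rsid = f"rs{rng.randint(10**6, 10**9)}"
        gene = _gene_name(rng)
        gene_id = str(rng.randint(10_000, 999_999))
        function = rng.choice(_FUNCTIONS)
        url1 = build_eutils_url(
            EutilsRequest("esummary", "snp", {"id": rsid[2:], "retmode": "json"})
        )
        body1 = json.dumps(
            {"result": {rsid[2:]: {"snp_id": int(rsid[2:]), "genes": [{"name": gene, "gene_id": gene_id}]}}}
        )
        url2 = build_eutils_url(
            EutilsRequest("esummary", "gene", {"id": gene_id, "retmode": "json"})
        )
        body2 = json.dumps({"result": {gene_id: {"name": gene, "summary": function}}})
        question = f"What is the function of the gene associated with SNP {rsid}?"
        gold = (function,)
        calls = [(url1, body1), (url2, body2)]
        task = "snp_gene_function"
    elif template == "disease_gene_location":
        disease = rng.choice(_DISEASES)
        genes = [_gene_name(rng) for _ in range(2)]
        gene_ids = [str(rng.randint(10_000, 999_999)) for _ in genes]
        locations = [f"chr{rng.randint(1, 22)}" for _ in genes]
        url1 = build_eutils_url(
            EutilsRequest("esearch", "omim", {"term": disease, "retmode": "json"})
        )
        body1 = json.dumps({"esearchresult": {"count": "2", "idlist": gene_ids}})
        calls = [(url1, body1)]
        for gid, g, loc in zip(gene_ids, genes, locations):
            url = build_eutils_url(
                EutilsRequest("esummary", "gene", {"id": gid, "retmode": "json"})
            )
            body = json.dumps({"result": {gid: {"name": g, "location": loc}}})
            calls.append((url, body))
        question = f"List chromosome locations of the genes related to {disease}."
        gold = tuple(locations)
        task = "disease_gene_location"
    elif template == "sequence_gene_alias":
        seq = "".join(rng.choice("ACGT") for _ in range(40))
        gene = _gene_name(rng)
        aliases = [gene + "-A", gene + "L"]
        put, get = _blast_pair(rng)
        get_body = get[1] + f"\nGene: {gene}"
        gene_id = str(rng.randint(10_000, 999_999))
        url3 = build_eutils_url(
            EutilsRequest("esearch", "gene", {"term": gene, "retmode": "json"})
        )
        body3 = json.dumps({"esearchresult": {"count": "1", "idlist": [gene_id]}})
        url4 = build_eutils_url(
            EutilsRequest("efetch", "gene", {"id": gene_id, "retmode": "json"})
        )
        body4 = json.dumps(
            {"result": {gene_id: {"name": gene, "otheraliases": ", ".join(aliases)}}}
        )
        calls = [put, (get[0], get_body), (url3, body3), (url4, body4)]
        question = f"What are the aliases of the gene that contains this sequence: {seq}?"
        gold = tuple(aliases)
        task = "sequence_gene_alias"
    else:
        raise ValidationError(f"unknown multi-hop template {template!r}")

    answer = ", ".join(gold)
    for url, body in calls:
        transcript.append(f"[{url}]{CALL_INDICATOR}")
        cassette.record(url, 200, body)
    transcript.append(f"Answer: {answer}\n\n")

    qa = QARecord(
        id=f"mh-{template}-{seed}",
        task=task,
        question=question,
        gold=gold,
        hop="multi",
    )
    bundle = FixtureBundle(
        qa=qa,
        transcript=transcript,
        cassette=cassette,
        expected={"calls": len(calls), "answer": answer},
    )
    return qa, bundle
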