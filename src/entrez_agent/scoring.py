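"""Automatic evaluation of genomics QA predictions.

Scoring is deliberately strict: nomenclature and genomic-location answers
count only on exact match after a minimal normalization (trim, whitespace
collapse, case fold, en-dash/hyphen unification).  Gene-set answers
(gene-disease association) are scored by recall over exact individual gene
matches, so extra predicted genes are not penalized.  Two tasks apply a
small vocabulary mapping first: yes/no is mapped to TRUE/NA for the
protein-coding task, and Latin binomials are mapped to informal species
names (e.g. *Saccharomyces cerevisiae* -> yeast) for the multi-species
alignment task.  DNA-to-human-genome alignment gets half credit when the
predicted chromosome is right but the coordinate interval is not, since the
task does not pin a reference genome and positions shift between builds.

Aggregation is macro: per-task means, per-module means over member tasks,
and an overall unweighted mean across tasks.  Error annotations follow a
five-way taxonomy — E1 wrong API, E2 wrong arguments, E3 wrong
comprehension of results, E4 not answerable via the API, O other — assigned
manually to less-than-full-credit questions and tallied per task.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from statistics import mean

from entrez_agent.errors import ValidationError

ERROR_LABELS = ("E1", "E2", "E3", "E4", "O")

#: Latin binomial -> informal species name.  Only common model organisms;
#: user-extensible via the ``extra`` argument of :func:`normalize_vocab`.
SPECIES_INFORMAL = {
    "saccharomyces cerevisiae": "yeast",
    "danio rerio": "zebrafish",
    "mus musculus": "mouse",
    "rattus norvegicus": "rat",
    "drosophila melanogaster": "fruit fly",
    "caenorhabditis elegans": "worm",
    "homo sapiens": "human",
    "gallus gallus": "chicken",
    "xenopus laevis": "frog",
    "bos taurus": "cow",
    "sus scrofa": "pig",
    "canis lupus familiaris": "dog",
    "felis catus": "cat",
    "oryza sativa": "rice",
    "arabidopsis thaliana": "thale cress",
}

YES_NO_MAP = {"yes": "TRUE", "no": "NA"}


@dataclass(frozen=True)
class TaskSpec:
    """A benchmark task: its module and which scorer applies."""

    name: str
    module: str  # nomenclature | genomic_location | functional_analysis |
    #             sequence_alignment | multi_hop
    scorer: str  # exact | recall | exact_with_vocab | alignment_human | manual
    vocab: str = ""  # yes_no | species (for exact_with_vocab)


#: The nine single-hop benchmark tasks plus the three multi-hop ones.
DEFAULT_TASKS = {
    t.name: t
    for t in [
        TaskSpec("gene_alias", "nomenclature", "exact"),
        TaskSpec("gene_name_conversion", "nomenclature", "exact"),
        TaskSpec("gene_snp_association", "genomic_location", "exact"),
        TaskSpec("gene_location", "genomic_location", "exact"),
        TaskSpec("snp_location", "genomic_location", "exact"),
        TaskSpec("gene_disease_association", "functional_analysis", "recall"),
        TaskSpec("protein_coding_genes", "functional_analysis", "exact_with_vocab", "yes_no"),
        TaskSpec("dna_human_genome", "sequence_alignment", "alignment_human"),
        TaskSpec("dna_multi_species", "sequence_alignment", "exact_with_vocab", "species"),
        TaskSpec("snp_gene_function", "multi_hop", "manual"),
        TaskSpec("disease_gene_location", "multi_hop", "recall"),
        TaskSpec("sequence_gene_alias", "multi_hop", "recall"),
    ]
}

_WS_RE = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Trim, collapse internal whitespace, case-fold, unify dashes."""
    return _WS_RE.sub(" ", text.strip()).casefold().replace("–", "-")


def score_exact(pred: str, gold: set[str] | list[str]) -> int:
    """1 iff the normalized prediction equals any normalized gold answer."""
    if not gold:
        raise ValidationError("gold answer set must be non-empty")
    norm = normalize_text(pred)
    return int(any(norm == normalize_text(g) for g in gold))


_LIST_SEP_RE = re.compile(r"[,;\n]| and ")


def split_prediction_list(pred: str) -> set[str]:
    """Split a free-text list answer into items (commas/semicolons/newlines)."""
    pred = pred.strip().strip("[]")
    return {p.strip() for p in _LIST_SEP_RE.split(pred) if p.strip()}


def score_recall(pred: set[str] | list[str] | str, gold: set[str] | list[str]) -> float:
    """|pred ∩ gold| / |gold| on normalized items; precision not penalized."""
    if not gold:
        raise ValidationError("gold answer set must be non-empty")
    if isinstance(pred, str):
        pred = split_prediction_list(pred)
    pred_norm = {normalize_text(p) for p in pred}
    gold_norm = {normalize_text(g) for g in gold}
    return len(pred_norm & gold_norm) / len(gold_norm)


def normalize_vocab(task: TaskSpec, pred: str, extra: dict[str, str] | None = None) -> str:
    """Apply the task's vocabulary mapping; unmapped strings pass through."""
    if task.scorer != "exact_with_vocab":
        return pred
    key = normalize_text(pred)
    if task.vocab == "yes_no":
        return YES_NO_MAP.get(key, pred)
    if task.vocab == "species":
        table = dict(SPECIES_INFORMAL)
        if extra:
            table.update({normalize_text(k): v for k, v in extra.items()})
        return table.get(key, pred)
    return pred


@dataclass(frozen=True)
class GenomicLocation:
    """A chromosome plus an optional 1-based coordinate interval."""

    chromosome: str  # normalized "chrN" with N in 1..22, X, Y, M
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if (self.start is None) != (self.end is None):
            raise ValidationError("start and end must be given together")
        if self.start is not None and self.end < self.start:
            raise ValidationError("end must be >= start")

    def __str__(self) -> str:
        if self.start is None:
            return self.chromosome
        return f"{self.chromosome}:{self.start}-{self.end}"


_CHROM_TOKENS = {str(i) for i in range(1, 23)} | {"X", "Y", "M"}
_LOC_RE = re.compile(
    r"^(?:chr)?\s*([0-9]{1,2}|[XYMxym])\s*"
    r"(?::\s*([\d,]+)\s*(?:[-–]|\.\.)\s*([\d,]+)\s*)?$"
)


def parse_location(text: str) -> GenomicLocation:
    """Parse ``chrN`` or ``chrN:start-end`` (en dash, hyphen, or ``..``).

    A bare ``8:100-200`` gets the ``chr`` prefix inferred.  Raises
    :class:`ValidationError` when no chromosome token is found.
    """
    m = _LOC_RE.match(text.strip())
    if m is None:
        raise ValidationError(f"cannot parse genomic location: {text!r}")
    token = m.group(1).upper()
    if token not in _CHROM_TOKENS:
        raise ValidationError(f"not a chromosome: {token!r}")
    start = int(m.group(2).replace(",", "")) if m.group(2) else None
    end = int(m.group(3).replace(",", "")) if m.group(3) else None
    return GenomicLocation(chromosome=f"chr{token}", start=start, end=end)


def score_alignment_human(
    pred: GenomicLocation | str, gold: GenomicLocation | str
) -> float:
    """Half-credit genome-alignment scoring.

    1.0 when chromosome and interval both match; 0.5 when the chromosomes
    match but the intervals differ or exactly one side gives no interval;
    0.0 when the chromosomes differ or the prediction does not parse.
    """
    try:
        if isinstance(pred, str):
            pred = parse_location(pred)
    except ValidationError:
        return 0.0
    if isinstance(gold, str):
        gold = parse_location(gold)
    if pred.chromosome.upper() != gold.chromosome.upper():
        return 0.0
    if (pred.start, pred.end) == (gold.start, gold.end):
        return 1.0
    return 0.5


@dataclass
class QuestionScore:
    id: str
    task: str
    score: float
    error_label: str | None = None


@dataclass
class ScoreReport:
    """Per-question scores with macro-averaged rollups."""

    per_question: list[QuestionScore]
    per_task: dict[str, float] = field(default_factory=dict)
    per_module: dict[str, float] = field(default_factory=dict)
    overall: float = 0.0

    def rounded(self, value: float) -> float:
        """Report at 2 decimals, half-up, matching benchmark convention."""
        return float(Decimal(repr(value)).quantize(Decimal("0.01"), ROUND_HALF_UP))

    def summary(self) -> str:
        lines = ["task\tmodule\tscore"]
        modules = {t: DEFAULT_TASKS[t].module if t in DEFAULT_TASKS else "?"
                   for t in self.per_task}
        for task, s in self.per_task.items():
            lines.append(f"{task}\t{modules[task]}\t{self.rounded(s):.2f}")
        for module, s in self.per_module.items():
            lines.append(f"[module {module}]\t\t{self.rounded(s):.2f}")
        lines.append(f"[overall]\t\t{self.rounded(self.overall):.2f}")
        return "\n".join(lines)


def aggregate(
    per_question: list[QuestionScore],
    task_registry: dict[str, TaskSpec] | None = None,
) -> ScoreReport:
    """Macro-average: task means, module means of task means, overall mean.

    Tasks with no questions are excluded from every mean with a warning.
    """
    registry = task_registry or DEFAULT_TASKS
    by_task: dict[str, list[float]] = {}
    for q in per_question:
        if not 0.0 <= q.score <= 1.0:
            raise ValidationError(f"score out of [0,1] for question {q.id}")
        by_task.setdefault(q.task, []).append(q.score)

    per_task = {task: mean(scores) for task, scores in by_task.items() if scores}
    empty = [t for t, scores in by_task.items() if not scores]
    if empty:
        warnings.warn(f"tasks with no questions excluded: {empty}")

    by_module: dict[str, list[float]] = {}
    for task, task_mean in per_task.items():
        spec = registry.get(task)
        module = spec.module if spec else "unknown"
        by_module.setdefault(module, []).append(task_mean)
    per_module = {m: mean(v) for m, v in by_module.items()}
    overall = mean(per_task.values()) if per_task else 0.0
    return ScoreReport(
        per_question=per_question,
        per_task=per_task,
        per_module=per_module,
        overall=overall,
    )


def tally_errors(report: ScoreReport) -> dict[str, dict[str, int]]:
    """Count error labels per task; labels are valid only when score < 1."""
    counts: dict[str, dict[str, int]] = {}
    for q in report.per_question:
        if q.error_label is None:
            continue
        if q.error_label not in ERROR_LABELS:
            raise ValidationError(f"unknown error label {q.error_label!r}")
        if q.score >= 1.0:
            raise ValidationError(
                f"question {q.id} has full credit but carries label {q.error_label}"
            )
        row = counts.setdefault(q.task, {lab: 0 for lab in ERROR_LABELS})
        row[q.error_label] += 1
    return counts
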