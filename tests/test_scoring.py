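"""Scorers, location parsing, macro-aggregation, error tallies."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entrez_agent.errors import ValidationError
from entrez_agent.scoring import (
    DEFAULT_TASKS,
    GenomicLocation,
    QuestionScore,
    aggregate,
    normalize_vocab,
    parse_location,
    score_alignment_human,
    score_exact,
    score_recall,
    split_prediction_list,
    tally_errors,
)

# ---------------------------------------------------------------- exact match

@pytest.mark.parametrize(
    "pred,gold,expected",
    [
        ("chr2", {"chr2"}, 1),
        ("chr2 ", {"chr2"}, 1),
        ("CHR2", {"chr2"}, 1),
        ("chr3", {"chr2"}, 0),
        ("BRCA  2", {"brca 2"}, 1),      # whitespace collapse + case fold
        ("chr8:1–2", {"chr8:1-2"}, 1),   # en-dash unified with hyphen
        ("TP53", {"TP53", "P53"}, 1),    # any gold alternative counts
    ],
)
def test_score_exact(pred, gold, expected):
    assert score_exact(pred, gold) == expected


def test_score_exact_requires_gold():
    with pytest.raises(ValidationError):
        score_exact("x", set())


# --------------------------------------------------------------------- recall

@pytest.mark.parametrize(
    "pred,gold,expected",
    [
        ({"A"}, {"A", "B"}, 0.5),
        ({"A", "C"}, {"A"}, 1.0),   # precision not penalized
        (set(), {"A"}, 0.0),
        ("GeneA, GeneB; GeneC", {"genea", "genec", "gened"}, 2 / 3),
    ],
)
def test_score_recall(pred, gold, expected):
    assert score_recall(pred, gold) == pytest.approx(expected)


@given(gold=st.sets(st.text(min_size=1, max_size=8).filter(str.strip), min_size=1, max_size=6))
@settings(max_examples=50, deadline=None)
def test_recall_of_gold_against_itself_is_one(gold):
    assert score_recall(gold, gold) == 1.0


@given(
    gold=st.sets(st.text(min_size=1, max_size=6).filter(str.strip), min_size=1, max_size=5),
    pred=st.sets(st.text(min_size=1, max_size=6).filter(str.strip), max_size=5),
    extra=st.sets(st.text(min_size=1, max_size=6).filter(str.strip), max_size=5),
)
@settings(max_examples=50, deadline=None)
def test_recall_monotone_under_prediction_growth(gold, pred, extra):
    assert score_recall(pred | extra, gold) >= score_recall(pred, gold)
    assert 0.0 <= score_recall(pred, gold) <= 1.0


def test_list_splitting_handles_markup_and_separators():
    assert split_prediction_list("[GeneA, GeneB; GeneC and GeneD]") == {
        "GeneA", "GeneB", "GeneC", "GeneD"
    }


# --------------------------------------------------------------- vocab mapping

@pytest.mark.parametrize(
    "task,pred,expected",
    [
        ("protein_coding_genes", "yes", "TRUE"),
        ("protein_coding_genes", "Yes", "TRUE"),
        ("protein_coding_genes", "no", "NA"),
        ("protein_coding_genes", "maybe", "maybe"),
        ("dna_multi_species", "Saccharomyces cerevisiae", "yeast"),
        ("dna_multi_species", "Danio rerio", "zebrafish"),
        ("dna_multi_species", "zebrafish", "zebrafish"),  # already informal
    ],
)
def test_vocabulary_mapping(task, pred, expected):
    assert normalize_vocab(DEFAULT_TASKS[task], pred) == expected


def test_vocab_table_is_user_extensible():
    spec = DEFAULT_TASKS["dna_multi_species"]
    assert normalize_vocab(spec, "Macaca mulatta", extra={"Macaca mulatta": "macaque"}) == "macaque"


# ------------------------------------------------------------ location parsing

@pytest.mark.parametrize(
    "text,chrom,start,end",
    [
        ("chr8:7081648–7081782", "chr8", 7081648, 7081782),
        ("chr2", "chr2", None, None),
        ("8:100-200", "chr8", 100, 200),
        ("chrX:5..50", "chrX", 5, 50),
        (" chrM ", "chrM", None, None),
        ("chr1:1,000-2,000", "chr1", 1000, 2000),
    ],
)
def test_parse_location(text, chrom, start, end):
    loc = parse_location(text)
    assert (loc.chromosome, loc.start, loc.end) == (chrom, start, end)


@pytest.mark.parametrize("bad", ["", "gene BRCA2", "chr99", "chr8:10-5", "chr8:10-"])
def test_unparseable_locations_raise(bad):
    with pytest.raises(ValidationError):
        parse_location(bad)


@pytest.mark.parametrize("text", ["chr8:7081648–7081782", "chr2", "8:100-200", "chrY"])
def test_parse_print_parse_is_a_fixed_point(text):
    once = parse_location(text)
    assert parse_location(str(once)) == once


# -------------------------------------------------------- alignment half-credit

def test_matching_chromosome_wrong_interval_scores_half():
    pred = parse_location("chr8:7081648–7081782")
    gold = parse_location("chr8:1207812–1207946")
    assert score_alignment_human(pred, gold) == 0.5


@pytest.mark.parametrize(
    "pred,gold,expected",
    [
        ("chr8:1-10", "chr8:1-10", 1.0),
        ("chr7:1-10", "chr8:1-10", 0.0),
        ("chr8", "chr8:1-10", 0.5),      # chromosome-only prediction
        ("chr8", "chr8", 1.0),
        ("not a location", "chr8:1-10", 0.0),  # unparseable -> zero
    ],
)
def test_alignment_scoring_cases(pred, gold, expected):
    assert score_alignment_human(pred, gold) == expected


def test_alignment_scores_are_discrete():
    rng = random.Random(5)
    for _ in range(100):
        pred = GenomicLocation(f"chr{rng.randint(1, 22)}",
                               *(rng.choice([(None, None), (1, rng.randint(1, 9))])))
        gold = GenomicLocation(f"chr{rng.randint(1, 22)}",
                               *(rng.choice([(None, None), (1, rng.randint(1, 9))])))
        assert score_alignment_human(pred, gold) in (0.0, 0.5, 1.0)


# ----------------------------------------------------------------- aggregation

def _report(task_scores):
    qs = [
        QuestionScore(id=f"{t}-{i}", task=t, score=s)
        for t, scores in task_scores.items()
        for i, s in enumerate(scores)
    ]
    return aggregate(qs)


def test_aggregate_matches_brute_force_oracle_on_random_tables():
    rng = random.Random(99)
    for _ in range(100):
        table = {
            f"task{k}": [rng.random() for _ in range(rng.randint(1, 8))]
            for k in range(rng.randint(1, 6))
        }
        report = _report(table)
        expected_means = {t: sum(v) / len(v) for t, v in table.items()}
        assert report.per_task == pytest.approx(expected_means)
        assert report.overall == pytest.approx(
            sum(expected_means.values()) / len(expected_means)
        )


def test_aggregate_is_order_invariant():
    qs = [
        QuestionScore("a1", "gene_alias", 1.0),
        QuestionScore("a2", "gene_alias", 0.0),
        QuestionScore("b1", "snp_location", 0.5),
    ]
    fwd = aggregate(qs)
    rev = aggregate(list(reversed(qs)))
    assert fwd.per_task == rev.per_task and fwd.overall == rev.overall


def test_module_means_average_member_task_means():
    report = _report({
        "gene_alias": [1.0, 0.5],           # nomenclature, mean 0.75
        "gene_name_conversion": [0.25],     # nomenclature, mean 0.25
        "snp_location": [1.0],              # genomic_location
    })
    assert report.per_module["nomenclature"] == pytest.approx(0.5)
    assert report.per_module["genomic_location"] == pytest.approx(1.0)


def test_out_of_range_scores_rejected():
    with pytest.raises(ValidationError):
        aggregate([QuestionScore("x", "gene_alias", 1.5)])


def test_reported_rounding_is_half_up():
    report = _report({"gene_alias": [0.825]})
    assert report.rounded(report.overall) == 0.83
    assert report.rounded(0.005) == 0.01


# --------------------------------------------------------------- error tallies

def test_error_tally_counts_labels_per_task():
    qs = [QuestionScore(f"q{i}", "sequence_gene_alias", 0.0, error_label="E2")
          for i in range(30)]
    qs += [QuestionScore(f"r{i}", "sequence_gene_alias", 0.5, error_label="E3")
           for i in range(8)]
    qs.append(QuestionScore("ok", "sequence_gene_alias", 1.0))
    report = aggregate(qs)
    counts = tally_errors(report)
    row = counts["sequence_gene_alias"]
    assert row == {"E1": 0, "E2": 30, "E3": 8, "E4": 0, "O": 0}
    assert sum(row.values()) == 38


def test_label_on_full_credit_question_is_invalid():
    report = aggregate([QuestionScore("q", "gene_alias", 1.0, error_label="E4")])
    with pytest.raises(ValidationError):
        tally_errors(report)


def test_no_annotations_gives_empty_tally():
    report = aggregate([QuestionScore("q", "gene_alias", 0.0)])
    assert tally_errors(report) == {}
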