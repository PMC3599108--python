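import datetime

import numpy as np
import pytest

from notedup import (
    Corpus,
    ReductionConfig,
    SynthEhrConfig,
    document_fingerprints,
    fingerprint_similarity,
    generate_ehr_corpus,
    last_note_baseline,
    line_fingerprints,
    reduce_corpus,
)
from notedup.fingerprint import _hash64

from _oracles import sequential_reduction, substring_set
from conftest import make_doc


@pytest.mark.parametrize(
    "line, n, scheme, expected",
    [
        ("abcdefgh", 3, "full", ["abc", "bcd", "cde", "def", "efg", "fgh"]),
        ("abcdefgh", 3, "selective", ["abc", "def"]),
        ("abcdefgh", 4, "selective", ["abcd", "efgh"]),
        ("ab", 3, "full", []),
        ("ab", 3, "selective", []),
    ],
)
def test_line_fingerprint_schemes(line, n, scheme, expected):
    assert line_fingerprints(line, n, scheme) == expected


def test_line_fingerprint_counts_match_formulas():
    line = "x" * 47
    assert len(line_fingerprints(line, 5, "full")) == 47 - 5 + 1
    assert len(line_fingerprints(line, 5, "selective")) == 47 // 5


def test_granularity_must_be_at_least_two():
    with pytest.raises(ValueError):
        line_fingerprints("abc", 1)


def test_document_fingerprints_use_set_semantics():
    config = ReductionConfig(cutoff=0.5, n=4)
    once = document_fingerprints(make_doc("a", ["abcdefgh"]), config)
    twice = document_fingerprints(make_doc("b", ["abcdefgh", "abcdefgh"]), config)
    assert once.fingerprints == twice.fingerprints
    assert once.fingerprints == frozenset({_hash64("abcd"), _hash64("efgh")})


def test_document_fingerprints_equal_substring_set_oracle():
    rng = np.random.default_rng(5)
    for scheme in ("full", "selective"):
        config = ReductionConfig(cutoff=0.5, n=6, scheme=scheme)
        lines = [
            "".join(chr(97 + c) for c in rng.integers(0, 4, size=rng.integers(0, 30)))
            for _ in range(8)
        ]
        doc = make_doc("d", lines)
        got = document_fingerprints(doc, config, hashed=False).fingerprints
        assert got == substring_set(lines, 6, scheme)


def test_similarity_identity_disjoint_and_ratio():
    config = ReductionConfig(cutoff=0.5, n=4)
    a = document_fingerprints(make_doc("a", ["abcdefgh", "ijklmnop"]), config)
    b = document_fingerprints(make_doc("b", ["abcdefgh", "qrstuvwx"]), config)
    z = document_fingerprints(make_doc("z", ["zzzzyyyy"]), config)
    assert fingerprint_similarity(a, a) == 1.0
    assert fingerprint_similarity(z, a) == 0.0
    # a has 4 fingerprints, shares 2 with b
    assert fingerprint_similarity(b, a) == pytest.approx(0.5)
    empty = document_fingerprints(make_doc("e", ["ab"]), config)
    assert fingerprint_similarity(a, empty) == 0.0


def test_similarity_requires_matching_granularity_and_scheme():
    a = document_fingerprints(make_doc("a", ["abcdefgh"]), ReductionConfig(0.5, n=4))
    b = document_fingerprints(make_doc("b", ["abcdefgh"]), ReductionConfig(0.5, n=3))
    with pytest.raises(ValueError):
        fingerprint_similarity(b, a)


def test_identical_documents_collapse_to_one():
    docs = [make_doc(f"d{i}", ["the same note line repeated verbatim"]) for i in range(5)]
    reduced, report = reduce_corpus(Corpus(docs), ReductionConfig(cutoff=0.5, n=10))
    assert reduced.doc_ids == ["d0"]
    assert len(report.rejected) == 4
    assert (report.rejected["similarity"] == 1.0).all()
    assert report.counts == (5, 1)


def test_disjoint_documents_all_retained_at_cutoff_zero():
    docs = [
        make_doc("a", ["aaaaaaaaaaaaaaaaaaaaaaaa"]),
        make_doc("b", ["bbbbbbbbbbbbbbbbbbbbbbbb"]),
        make_doc("c", ["cccccccccccccccccccccccc"]),
    ]
    reduced, report = reduce_corpus(Corpus(docs), ReductionConfig(cutoff=0.0, n=8))
    assert reduced.doc_ids == ["a", "b", "c"]
    assert report.rejected.empty


def test_cutoff_one_rejects_nothing():
    docs = [make_doc(f"d{i}", ["identical identical identical"]) for i in range(4)]
    reduced, _ = reduce_corpus(Corpus(docs), ReductionConfig(cutoff=1.0, n=8))
    assert len(reduced) == 4


@pytest.mark.parametrize("cutoff", [0.20, 0.25, 0.33])
def test_reduction_equals_quadratic_oracle(cutoff):
    """Inverted-index greedy reduction = naive sequential rescan, and the
    retained set satisfies the pairwise similarity bound both ways."""
    corpus = generate_ehr_corpus(
        SynthEhrConfig(n_patients=20, notes_per_patient=(5, 5), copy_fraction=0.6, seed=21)
    )
    assert len(corpus) == 100
    config = ReductionConfig(cutoff=cutoff, n=20)
    reduced, report = reduce_corpus(corpus, config)
    oracle = sequential_reduction(
        {d.doc_id: d.raw_lines for d in corpus}, config.n, config.scheme, cutoff
    )
    assert reduced.doc_ids == oracle
    profiles = [document_fingerprints(d, config) for d in reduced]
    for i, pa in enumerate(profiles):
        for pb in profiles[i + 1 :]:
            assert fingerprint_similarity(pb, pa) <= cutoff
            assert fingerprint_similarity(pa, pb) <= cutoff
    assert set(report.retained_ids) | set(report.rejected["doc_id"]) == set(
        corpus.doc_ids
    )
    assert (report.rejected["similarity"] > cutoff).all()


def test_date_order_visits_oldest_first():
    docs = [
        make_doc("late", ["aaaaaaaaaaaaaaaa"], patient="p", date="2021-06-01"),
        make_doc("early", ["bbbbbbbbbbbbbbbb"], patient="p", date="2021-01-01"),
    ]
    reduced, _ = reduce_corpus(
        Corpus(docs), ReductionConfig(cutoff=0.2, n=8, order="date")
    )
    assert reduced.doc_ids == ["early", "late"]


def test_last_note_baseline_keeps_one_latest_note_per_patient():
    docs = []
    for p, n_notes in zip("abc", (2, 3, 4)):
        for i in range(n_notes):
            docs.append(
                make_doc(f"{p}{i}", ["note text"], patient=p, date=f"2021-0{i+1}-01")
            )
    baseline = last_note_baseline(Corpus(docs))
    assert len(baseline) == 3
    assert set(baseline.doc_ids) == {"a1", "b2", "c3"}


def test_last_note_baseline_tie_breaks_by_file_position():
    docs = [
        make_doc("first", ["x"], patient="p", date="2021-01-01"),
        make_doc("second", ["y"], patient="p", date="2021-01-01"),
    ]
    assert last_note_baseline(Corpus(docs)).doc_ids == ["second"]


def test_last_note_baseline_requires_dates():
    corpus = Corpus([make_doc("undated", ["x"], patient="p")])
    with pytest.raises(ValueError, match="undated"):
        last_note_baseline(corpus)


def test_reduction_config_validation():
    with pytest.raises(ValueError):
        ReductionConfig(cutoff=1.5)
    with pytest.raises(ValueError):
        ReductionConfig(cutoff=0.5, n=1)
    with pytest.raises(ValueError):
        ReductionConfig(cutoff=0.5, scheme="minhash")
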