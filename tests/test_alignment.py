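import numpy as np
import pytest

from notedup import (
    AlignmentScoring,
    Corpus,
    align_local,
    pair_redundancy,
    redundancy_profile,
    shared_word_identity,
)

from _oracles import naive_smith_waterman
from conftest import make_doc

SENT_A = "pt developed abd pain and acute cholecystitis".split()
SENT_B = "pt developed acute abd pain and cholecystitis".split()


def test_identical_sequences_align_fully():
    toks = "a b c d e f g".split()
    res = align_local(toks, toks)
    assert res.matched_tokens == 7
    assert res.score == pytest.approx(14.0)


def test_disjoint_vocabularies_share_nothing():
    res = align_local(list("abcd"), list("wxyz"))
    assert res.matched_tokens == 0
    assert res.aligned_segments == []


def test_empty_input_yields_empty_alignment():
    assert align_local([], list("ab")).matched_tokens == 0


def test_worked_sentence_pair_word_vs_sequence_identity():
    """The same seven words in permuted order: full bag identity, but the
    sequence alignment only matches 6 tokens across 8 columns (75%)."""
    assert shared_word_identity(SENT_A, SENT_B) == pytest.approx(1.0)
    oracle_score, oracle_matched = naive_smith_waterman(SENT_A, SENT_B)
    res = align_local(SENT_A, SENT_B, AlignmentScoring(repeated=False))
    assert (res.score, res.matched_tokens) == (oracle_score, oracle_matched)
    assert res.matched_tokens == 6
    assert res.score == pytest.approx(10.0)


def test_matches_naive_oracle_on_random_pairs():
    """Single-alignment mode equals a full-matrix reference on 200 pairs."""
    rng = np.random.default_rng(1234)
    scoring = AlignmentScoring(repeated=False)
    for _ in range(200):
        la, lb = rng.integers(0, 41, size=2)
        vocab = [f"t{i}" for i in range(rng.integers(2, 12))]
        a = [vocab[i] for i in rng.integers(0, len(vocab), size=la)]
        b = [vocab[i] for i in rng.integers(0, len(vocab), size=lb)]
        res = align_local(a, b, scoring)
        score, matched = naive_smith_waterman(a, b)
        assert res.score == pytest.approx(score)
        assert res.matched_tokens == matched


def test_repeated_extraction_finds_disjoint_copied_segments():
    # two shared blocks separated by long unrelated stretches: bridging
    # them in one local alignment costs more than it gains, so only
    # repeated extraction recovers both copied blocks
    mid_a = [f"x{i}" for i in range(8)]
    mid_b = [f"y{i}" for i in range(8)]
    a = "s1 s2 s3".split() + mid_a + "s4 s5 s6".split()
    b = "s1 s2 s3".split() + mid_b + "s4 s5 s6".split()
    single = align_local(a, b, AlignmentScoring(repeated=False))
    rep = align_local(a, b, AlignmentScoring(repeated=True))
    assert single.matched_tokens == 3
    assert rep.matched_tokens == 6
    assert len(rep.aligned_segments) == 2


def test_min_segment_score_suppresses_single_token_matches():
    res = align_local("a x b".split(), "c a d".split())
    assert res.matched_tokens == 0  # lone shared token scores 2 < 4


def test_segments_do_not_overlap_and_matched_bounded():
    rng = np.random.default_rng(7)
    for _ in range(50):
        a = [str(t) for t in rng.integers(0, 6, size=30)]
        b = [str(t) for t in rng.integers(0, 6, size=25)]
        res = align_local(a, b)
        assert res.matched_tokens <= min(len(a), len(b))
        for seq_slice in ((0, 1), (2, 3)):
            ivals = sorted(
                (seg[seq_slice[0]], seg[seq_slice[1]]) for seg in res.aligned_segments
            )
            for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
                assert e1 <= s2


def test_appending_novel_tokens_never_decreases_matched():
    rng = np.random.default_rng(11)
    a = [str(t) for t in rng.integers(0, 5, size=20)]
    b = [str(t) for t in rng.integers(0, 5, size=20)]
    base = align_local(a, b).matched_tokens
    extended = align_local(a, b + ["zz1", "zz2", "zz3"]).matched_tokens
    assert extended >= base


def test_pair_redundancy_identity_and_containment():
    doc = make_doc("d", ["a b c d", "e f g h"])
    assert pair_redundancy(doc, doc) == (1.0, 1.0, 1.0)
    # b contains all of a's lines plus as many novel ones
    bigger = make_doc("e", ["a b c d", "e f g h", "n1 n2 n3 n4", "n5 n6 n7 n8"])
    ra, rb, rs = pair_redundancy(doc, bigger)
    assert ra == pytest.approx(1.0)
    assert rb == pytest.approx(0.5)
    assert rs == pytest.approx(0.75)


def test_pair_redundancy_is_symmetric_and_bounded():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = make_doc("a", [" ".join(str(t) for t in rng.integers(0, 8, size=10))])
        b = make_doc("b", [" ".join(str(t) for t in rng.integers(0, 8, size=12))])
        ra, rb, rs = pair_redundancy(a, b)
        rb2, ra2, rs2 = pair_redundancy(b, a)
        assert rs == pytest.approx(rs2)
        assert ra == pytest.approx(ra2) and rb == pytest.approx(rb2)
        assert 0.0 <= min(ra, rb, rs) and max(ra, rb, rs) <= 1.0


def test_zero_length_document_has_zero_redundancy():
    empty = make_doc("z", [])
    other = make_doc("o", ["a b c d"])
    assert pair_redundancy(empty, other) == (0.0, 0.0, 0.0)


def test_profile_uses_all_pairs_when_sample_exceeds_them(clinic_corpus):
    profile = redundancy_profile(clinic_corpus, "same_patient", pair_sample=10, seed=0)
    assert len(profile.pair_records) == 1  # p1 has the only same-patient pair
    assert profile.histogram.sum() == 1


def test_profile_of_duplicated_notes_is_total_redundancy():
    docs = [
        make_doc(f"d{i}", ["pt seen today in clinic", "plan continue meds"], patient="p1")
        for i in range(3)
    ]
    profile = redundancy_profile(Corpus(docs), "same_patient", pair_sample=10, seed=0)
    assert len(profile.pair_records) == 3
    assert profile.mean_sym == pytest.approx(1.0)
    assert profile.histogram[-1] == 3


def test_profile_requires_eligible_pairs(clinic_corpus):
    solo = Corpus([make_doc("d", ["a b"], patient="p1")])
    with pytest.raises(ValueError, match="same_patient"):
        redundancy_profile(solo, "same_patient", pair_sample=5, seed=0)


def test_scoring_validation():
    with pytest.raises(ValueError):
        AlignmentScoring(match=-1.0)
    with pytest.raises(ValueError):
        AlignmentScoring(gap=0.5)
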