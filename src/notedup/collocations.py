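"""Bigram collocation extraction with PMI/TMI and patient-support auditing.

A collocation is a word pair that co-occurs more often than chance.  Two
association measures are scored from a corpus-wide bigram contingency
table: pointwise mutual information, PMI = log2(n11*npp / (n1p*np1)),
and true mutual information, the mutual information of the full 2x2
table, TMI = sum_ij (nij/npp) * log2(nij*npp / (ni+*n+j)) with empty
cells contributing 0.  Counts are kept as exact integers so uniform
duplication of a corpus leaves every score bit-identical.

In a copy-paste-redundant corpus, bigrams repeated across one patient's
notes acquire inflated counts; auditing the number of distinct patients
supporting each extracted collocation (low support = likely copy-paste
artifact) quantifies that bias.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .corpus_io import Corpus

__all__ = [
    "BigramTable",
    "Collocation",
    "SupportStats",
    "bigram_counts",
    "score_bigram",
    "extract_collocations",
    "support_stats",
]

Bigram = tuple[str, str]


@dataclass
class BigramTable:
    """Corpus-wide bigram contingency counts.

    ``n11`` maps each bigram to its count, ``n1p``/``np1`` are the word
    marginals as left/right element, ``npp`` the total number of counted
    bigram tokens.
    """

    n11: Counter
    n1p: Counter
    np1: Counter
    npp: int


@dataclass
class Collocation:
    bigram: Bigram
    score: float
    measure: str
    count: int
    patient_support: int | None = None


@dataclass
class SupportStats:
    """Patient-support summary over an extracted collocation list."""

    n_collocations: int
    mean_patients: float
    frac_low_support: float  # fraction supported by <= 3 patients


def bigram_counts(corpus: Corpus, vocab: set[str] | None = None) -> BigramTable:
    """Count adjacent in-line token pairs over the corpus.

    No bigram spans a line boundary.  When ``vocab`` is given, a bigram
    is counted only if both of its words are in the vocabulary, and
    ``npp`` counts only counted bigrams.
    """
    n11: Counter = Counter()
    n1p: Counter = Counter()
    np1: Counter = Counter()
    npp = 0
    for doc in corpus:
        for line in corpus.doc_token_lines(doc):
            for w1, w2 in zip(line, line[1:]):
                if vocab is not None and (w1 not in vocab or w2 not in vocab):
                    continue
                n11[(w1, w2)] += 1
                n1p[w1] += 1
                np1[w2] += 1
                npp += 1
    return BigramTable(n11, n1p, np1, npp)


def _xlog2x_term(nij: int, ni: int, nj: int, npp: int) -> float:
    """(nij/npp) * log2(nij*npp / (ni*nj)); 0 when the cell is empty."""
    if nij == 0:
        return 0.0
    return (nij / npp) * math.log2(nij * npp / (ni * nj))


def score_bigram(table: BigramTable, bigram: Bigram, measure: str) -> float:
    """PMI or TMI score of one bigram from the contingency table.

    Integer arithmetic throughout, so uniformly scaled tables (xK
    corpora) give bit-identical scores.
    """
    if table.npp == 0:
        raise ValueError("empty bigram table")
    n11 = table.n11[bigram]
    if n11 < 1:
        raise ValueError(f"bigram {bigram!r} has zero count")
    w1, w2 = bigram
    n1p, np1, npp = table.n1p[w1], table.np1[w2], table.npp
    if measure == "pmi":
        return math.log2(n11 * npp / (n1p * np1))
    if measure == "tmi":
        n12 = n1p - n11
        n21 = np1 - n11
        n22 = npp - n1p - np1 + n11
        n2p = npp - n1p
        np2 = npp - np1
        return (
            _xlog2x_term(n11, n1p, np1, npp)
            + _xlog2x_term(n12, n1p, np2, npp)
            + _xlog2x_term(n21, n2p, np1, npp)
            + _xlog2x_term(n22, n2p, np2, npp)
        )
    raise ValueError(f"unknown measure {measure!r}")


def extract_collocations(
    corpus: Corpus,
    measure: str = "pmi",
    threshold: float | None = None,
    top_n: int | None = None,
    min_count: int = 1,
    vocab: set[str] | None = None,
) -> list[Collocation]:
    """Extract scored bigram collocations from a corpus.

    Exactly one of ``threshold`` (keep score >= threshold) or ``top_n``
    (keep the n best) must be given.  Bigrams below ``min_count`` are not
    scored.  Output is sorted deterministically by score descending, then
    count descending, then lexicographically.  ``patient_support`` is
    filled when any document carries a patient_id.
    """
    if (threshold is None) == (top_n is None):
        raise ValueError("give exactly one of threshold or top_n")
    table = bigram_counts(corpus, vocab)
    if table.npp == 0:
        return []
    scored = [
        Collocation(bg, score_bigram(table, bg, measure), measure, count)
        for bg, count in table.n11.items()
        if count >= min_count
    ]
    scored.sort(key=lambda c: (-c.score, -c.count, c.bigram))
    if threshold is not None:
        kept = [c for c in scored if c.score >= threshold]
    else:
        kept = scored[:top_n]
    _fill_patient_support(kept, corpus)
    return kept


def _fill_patient_support(collocations: list[Collocation], corpus: Corpus) -> None:
    targets = {c.bigram for c in collocations}
    if not targets or not any(d.patient_id is not None for d in corpus):
        return
    patients: dict[Bigram, set[str]] = {bg: set() for bg in targets}
    for doc in corpus:
        if doc.patient_id is None:
            continue
        seen: set[Bigram] = set()
        for line in corpus.doc_token_lines(doc):
            for bg in zip(line, line[1:]):
                if bg in patients:
                    seen.add(bg)
        for bg in seen:
            patients[bg].add(doc.patient_id)
    for c in collocations:
        c.patient_support = len(patients[c.bigram])


def support_stats(collocations: list[Collocation], corpus: Corpus) -> SupportStats:
    """Patient-support summary: mean support and fraction with <= 3 patients."""
    if not collocations:
        return SupportStats(0, 0.0, 0.0)
    if any(c.patient_support is None for c in collocations):
        _fill_patient_support(collocations, corpus)
    supports = [c.patient_support or 0 for c in collocations]
    low = sum(1 for s in supports if s <= 3)
    return SupportStats(
        len(supports), sum(supports) / len(supports), low / len(supports)
    )
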