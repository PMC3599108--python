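"""Token-sequence redundancy via Smith-Waterman local alignment.

Copy-paste between sequential notes of one patient reproduces whole
spans of text.  Bag-of-words overlap misses the sequential structure, so
redundancy between two documents is measured as the fraction of tokens
that participate in matched columns of local alignments between their
token streams.  Because a pair of notes can share several disjoint
copied blocks, the default mode repeatedly extracts the best local
alignment, masks the aligned spans, and continues while the best segment
score stays above a floor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .corpus_io import Corpus, Document

__all__ = [
    "AlignmentScoring",
    "AlignmentResult",
    "RedundancyProfile",
    "align_local",
    "shared_word_identity",
    "pair_redundancy",
    "redundancy_profile",
]


@dataclass(frozen=True)
class AlignmentScoring:
    """Scoring for token-level local alignment.

    Linear gap penalties.  ``min_segment_score`` is the floor for the
    repeated-extraction mode: with the defaults (+2 match) a segment must
    contain at least two consecutive matching tokens to be kept, which
    suppresses single shared-token noise.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -1.0
    min_segment_score: float = 4.0
    repeated: bool = True

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap > 0:
            raise ValueError("mismatch and gap scores must be <= 0")
        if self.min_segment_score <= 0:
            raise ValueError("min_segment_score must be positive")


@dataclass
class AlignmentResult:
    """Matched-token statistics of (possibly repeated) local alignment.

    ``aligned_segments`` holds half-open token intervals
    ``(start_a, end_a, start_b, end_b)``, one per extracted alignment,
    non-overlapping within each sequence.  ``matched_tokens`` counts exact
    match columns summed over segments.
    """

    matched_tokens: int
    aligned_segments: list[tuple[int, int, int, int]]
    score: float


@dataclass
class RedundancyProfile:
    """Corpus-level summary of sampled pairwise redundancy."""

    pair_records: pd.DataFrame
    histogram: np.ndarray  # counts over the 10 deciles of redundancy_sym
    mean_sym: float
    grouping: str


@njit(cache=True)
def _sw_matrix(a, b, match, mismatch, gap):  # pragma: no cover - jitted
    n = a.shape[0]
    m = b.shape[0]
    h = np.zeros((n + 1, m + 1), np.float64)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            best = h[i - 1, j - 1] + s
            up = h[i - 1, j] + gap
            if up > best:
                best = up
            left = h[i, j - 1] + gap
            if left > best:
                best = left
            if best < 0.0:
                best = 0.0
            h[i, j] = best
    return h


def _traceback(h, a, b, scoring):
    """Walk back from the matrix maximum; returns (score, matched, segment).

    Ties resolved diagonal-first (standard convention).
    """
    i, j = np.unravel_index(int(np.argmax(h)), h.shape)
    i, j = int(i), int(j)
    score = float(h[i, j])
    if score <= 0.0:
        return 0.0, 0, None
    end_a, end_b = i, j
    matched = 0
    eps = 1e-9
    while h[i, j] > 0.0:
        if i > 0 and j > 0:
            s = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            if abs(h[i, j] - (h[i - 1, j - 1] + s)) < eps:
                if a[i - 1] == b[j - 1]:
                    matched += 1
                i -= 1
                j -= 1
                continue
        if i > 0 and abs(h[i, j] - (h[i - 1, j] + scoring.gap)) < eps:
            i -= 1
            continue
        j -= 1
    return score, matched, (i, end_a, j, end_b)


def _encode(a, b):
    vocab: dict[str, int] = {}
    for tok in itertools.chain(a, b):
        if tok not in vocab:
            vocab[tok] = len(vocab)
    ia = np.array([vocab[t] for t in a], dtype=np.int64)
    ib = np.array([vocab[t] for t in b], dtype=np.int64)
    return ia, ib


def align_local(
    a: list[str],
    b: list[str],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> AlignmentResult:
    """Local alignment of two token sequences.

    With ``scoring.repeated`` off, the single best Smith-Waterman local
    alignment is returned.  With it on, best local alignments are
    extracted iteratively: after each extraction the aligned spans are
    masked (so no token takes part in two segments) and extraction
    continues while the best score is at least ``min_segment_score``;
    ``matched_tokens`` and ``score`` accumulate over segments.
    """
    if len(a) == 0 or len(b) == 0:
        return AlignmentResult(0, [], 0.0)
    ia, ib = _encode(a, b)
    if not scoring.repeated:
        h = _sw_matrix(ia, ib, scoring.match, scoring.mismatch, scoring.gap)
        score, matched, seg = _traceback(h, ia, ib, scoring)
        return AlignmentResult(matched, [seg] if seg else [], score)

    # masked tokens get unique negative ids so they can never match anything
    ia = ia.copy()
    ib = ib.copy()
    total_matched = 0
    total_score = 0.0
    segments: list[tuple[int, int, int, int]] = []
    while True:
        h = _sw_matrix(ia, ib, scoring.match, scoring.mismatch, scoring.gap)
        score, matched, seg = _traceback(h, ia, ib, scoring)
        if seg is None or score < scoring.min_segment_score:
            break
        sa, ea, sb, eb = seg
        segments.append(seg)
        total_matched += matched
        total_score += score
        ia[sa:ea] = -(np.arange(sa, ea) + 1)
        ib[sb:eb] = -(np.arange(sb, eb) + 1 + len(ia))
    return AlignmentResult(total_matched, segments, total_score)


def shared_word_identity(a: list[str], b: list[str]) -> float:
    """Bag-of-words identity: shared token multiset over mean length.

    Order-insensitive counterpart of alignment redundancy; two sentences
    that permute the same words score 1.0 here while scoring lower under
    sequence alignment.
    """
    if len(a) == 0 or len(b) == 0:
        return 0.0
    from collections import Counter

    ca, cb = Counter(a), Counter(b)
    shared = sum(min(ca[w], cb[w]) for w in ca)
    return shared / ((len(a) + len(b)) / 2)


def pair_redundancy(
    a: Document,
    b: Document,
    scoring: AlignmentScoring = AlignmentScoring(),
    layer: str = "word",
) -> tuple[float, float, float]:
    """Directional and symmetric alignment redundancy of two documents.

    Runs :func:`align_local` on the flattened token streams and
    normalizes matched tokens by each document's length; the symmetric
    redundancy is the mean of the two directions.  A zero-length document
    contributes redundancy 0 for its direction.
    """
    ta, tb = a.tokens(layer), b.tokens(layer)
    if len(ta) == 0 and len(tb) == 0:
        return 0.0, 0.0, 0.0
    res = align_local(ta, tb, scoring)
    red_a = res.matched_tokens / len(ta) if ta else 0.0
    red_b = res.matched_tokens / len(tb) if tb else 0.0
    return red_a, red_b, (red_a + red_b) / 2


def _eligible_pairs(corpus: Corpus, grouping: str):
    groups = corpus.patients()
    if grouping == "same_patient":
        if not groups:
            raise ValueError("same_patient grouping requires patient_id metadata")
        pairs = []
        for docs in groups.values():
            pairs.extend(itertools.combinations(docs, 2))
        return pairs
    if grouping == "cross_patient":
        if not groups:
            raise ValueError("cross_patient grouping requires patient_id metadata")
        docs = [d for d in corpus if d.patient_id is not None]
        pairs = [
            (x, y)
            for x, y in itertools.combinations(docs, 2)
            if x.patient_id != y.patient_id
        ]
        return pairs
    raise ValueError(f"unknown grouping {grouping!r}")


def redundancy_profile(
    corpus: Corpus,
    grouping: str = "same_patient",
    pair_sample: int = 2000,
    seed: int = 0,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> RedundancyProfile:
    """Sampled distribution of pairwise redundancy over a corpus.

    Samples ``pair_sample`` unordered document pairs uniformly without
    replacement from the eligible set (all of them if fewer exist),
    aligns each pair, and reports per-pair records, the decile histogram
    of symmetric redundancy (10%-wide bands), and its mean.
    """
    if pair_sample < 1:
        raise ValueError("pair_sample must be >= 1")
    pairs = _eligible_pairs(corpus, grouping)
    if not pairs:
        raise ValueError(f"no eligible document pairs for grouping {grouping!r}")
    rng = np.random.default_rng(seed)
    if len(pairs) > pair_sample:
        idx = rng.choice(len(pairs), size=pair_sample, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    records = []
    for x, y in pairs:
        ra, rb, rs = pair_redundancy(x, y, scoring, layer=corpus.layer)
        records.append((x.doc_id, y.doc_id, ra, rb, rs))
    df = pd.DataFrame(
        records,
        columns=["doc_a", "doc_b", "redundancy_a", "redundancy_b", "redundancy_sym"],
    )
    hist, _ = np.histogram(df["redundancy_sym"], bins=np.linspace(0.0, 1.0, 11))
    return RedundancyProfile(df, hist, float(df["redundancy_sym"].mean()), grouping)
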