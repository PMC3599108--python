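"""Line-based document fingerprinting and greedy redundancy-bounded reduction.

A fingerprint is a fixed-length character substring of a document line
(no fingerprint spans a line boundary).  Full fingerprinting takes every
window (a line of length m yields m-n+1 fingerprints); selective
fingerprinting takes consecutive non-overlapping windows from offset 0
(floor(m/n) fingerprints), which is the cheap scheme that still flags
verbatim copied lines.  Similarity of document B to document A is the
fraction of A's fingerprint set that B shares.

The reduction algorithm visits documents one by one and adds a candidate
to the output sub-corpus only if its fingerprint similarity against every
already-retained document stays at or below a cutoff, in either
direction.  An inverted index from fingerprint to retained documents
makes each candidate's scoring proportional to its own fingerprint count
times the average posting length; the behavior is identical to the
quadratic pairwise scan.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus_io import Corpus, Document

__all__ = [
    "FingerprintProfile",
    "ReductionConfig",
    "ReductionReport",
    "line_fingerprints",
    "document_fingerprints",
    "fingerprint_similarity",
    "reduce_corpus",
    "last_note_baseline",
]


def _hash64(s: str) -> int:
    """Stable 64-bit hash of a substring (collisions negligible at corpus scale)."""
    return int.from_bytes(
        hashlib.blake2b(s.encode("utf-8"), digest_size=8).digest(), "big"
    )


@dataclass(frozen=True)
class FingerprintProfile:
    """Set of (hashed) length-n line substrings of one document."""

    doc_id: str
    fingerprints: frozenset
    n: int
    scheme: str


@dataclass(frozen=True)
class ReductionConfig:
    """Parameters of the greedy redundancy-bounded sub-corpus construction.

    cutoff
        Maximum allowed fingerprint similarity between a retained pair,
        in [0, 1].
    n
        Fingerprint granularity in characters (default 20: long enough to
        be specific, short enough that typical note lines yield at least
        two selective fingerprints).
    scheme
        ``selective`` (default) or ``full``.
    order
        Visit order: ``input``, ``date`` (stable within equal dates) or
        ``random`` (seeded).
    """

    cutoff: float
    n: int = 20
    scheme: str = "selective"
    order: str = "input"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError("cutoff must be in [0, 1]")
        if self.n < 2:
            raise ValueError("granularity n must be >= 2")
        if self.scheme not in ("full", "selective"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.order not in ("input", "date", "random"):
            raise ValueError(f"unknown order {self.order!r}")


@dataclass
class ReductionReport:
    """Outcome of :func:`reduce_corpus`."""

    retained_ids: list[str]
    rejected: pd.DataFrame  # doc_id, blocking_doc_id, similarity
    counts: tuple[int, int]  # (input_docs, retained_docs)


def line_fingerprints(line: str, n: int, scheme: str = "selective") -> list[str]:
    """Length-n substrings of one line.

    ``full``: all m-n+1 sliding windows; ``selective``: consecutive
    non-overlapping windows starting at offset 0, with any trailing
    remainder shorter than n discarded.  Lines shorter than n contribute
    nothing.
    """
    if n < 2:
        raise ValueError("granularity n must be >= 2")
    m = len(line)
    if m < n:
        return []
    if scheme == "full":
        return [line[i : i + n] for i in range(m - n + 1)]
    if scheme == "selective":
        return [line[i : i + n] for i in range(0, (m // n) * n, n)]
    raise ValueError(f"unknown scheme {scheme!r}")


def document_fingerprints(
    doc: Document, config: ReductionConfig, hashed: bool = True
) -> FingerprintProfile:
    """Fingerprint set of a document, extracted line by line (set semantics)."""
    fps: set = set()
    for line in doc.raw_lines:
        for sub in line_fingerprints(line, config.n, config.scheme):
            fps.add(_hash64(sub) if hashed else sub)
    return FingerprintProfile(doc.doc_id, frozenset(fps), config.n, config.scheme)


def fingerprint_similarity(b: FingerprintProfile, a: FingerprintProfile) -> float:
    """Similarity of B to A: |FP(a) & FP(b)| / |FP(a)| (0 if A is empty)."""
    if a.n != b.n or a.scheme != b.scheme:
        raise ValueError(
            "profiles built with different granularity or scheme are not comparable"
        )
    if not a.fingerprints:
        return 0.0
    return len(a.fingerprints & b.fingerprints) / len(a.fingerprints)


def _visit_order(corpus: Corpus, config: ReductionConfig) -> list[Document]:
    docs = list(corpus)
    if config.order == "input":
        return docs
    if config.order == "date":
        missing = [d.doc_id for d in docs if d.date is None]
        if missing:
            raise ValueError(f"order='date' but document {missing[0]!r} has no date")
        return sorted(docs, key=lambda d: d.date)  # stable for equal dates
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(docs))
    return [docs[i] for i in perm]


def reduce_corpus(
    corpus: Corpus, config: ReductionConfig
) -> tuple[Corpus, ReductionReport]:
    """Greedy construction of a sub-corpus with bounded pairwise similarity.

    Documents are visited in ``config.order``.  A candidate is rejected
    iff some already-retained document d has
    ``shared/|FP(candidate)| > cutoff`` or ``shared/|FP(d)| > cutoff``
    (the symmetric test guarantees the bound both ways in the final set);
    otherwise it is retained and its fingerprints are indexed.  Returns
    the retained corpus in visit order plus a report of rejections, each
    with the most-similar blocking document.
    """
    docs = _visit_order(corpus, config)
    retained: list[Document] = []
    sizes: list[int] = []  # fingerprint-set size per retained doc
    index: dict[int, list[int]] = {}  # fingerprint -> retained positions
    rejected_rows = []
    for doc in docs:
        profile = document_fingerprints(doc, config)
        fps = profile.fingerprints
        shared: Counter = Counter()
        for fp in fps:
            for pos in index.get(fp, ()):
                shared[pos] += 1
        blocking = None
        worst = -1.0
        for pos, count in shared.items():
            sim_candidate = count / len(fps) if fps else 0.0
            sim_retained = count / sizes[pos] if sizes[pos] else 0.0
            sim = max(sim_candidate, sim_retained)
            if sim > config.cutoff and sim > worst:
                worst = sim
                blocking = pos
        if blocking is not None:
            rejected_rows.append((doc.doc_id, retained[blocking].doc_id, worst))
            continue
        pos = len(retained)
        retained.append(doc)
        sizes.append(len(fps))
        for fp in fps:
            index.setdefault(fp, []).append(pos)
    report = ReductionReport(
        retained_ids=[d.doc_id for d in retained],
        rejected=pd.DataFrame(
            rejected_rows, columns=["doc_id", "blocking_doc_id", "similarity"]
        ),
        counts=(len(docs), len(retained)),
    )
    return Corpus(retained, layer=corpus.layer), report


def last_note_baseline(corpus: Corpus) -> Corpus:
    """Metadata baseline: keep only each patient's most recent note.

    Requires patient_id and date on every document; date ties are broken
    by the later position in the input.  Output preserves the input order
    of the selected notes.
    """
    best: dict[str, tuple] = {}
    for pos, doc in enumerate(corpus):
        if doc.patient_id is None:
            raise ValueError(f"document {doc.doc_id!r} has no patient_id")
        if doc.date is None:
            raise ValueError(f"document {doc.doc_id!r} has no date")
        key = (doc.date, pos)
        if doc.patient_id not in best or key > best[doc.patient_id][0]:
            best[doc.patient_id] = (key, doc)
    keep = {d.doc_id for _, d in best.values()}
    return Corpus((d for d in corpus if d.doc_id in keep), layer=corpus.layer)
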