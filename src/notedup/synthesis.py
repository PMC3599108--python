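"""Synthetic corpora with controlled redundancy.

Three generators cover the study conditions every experiment here needs:

* ``duplicate_corpus`` — uniform duplication (xK): every document appears
  exactly K times.  Association scores that depend only on relative
  frequencies are exactly invariant under this scheme.
* ``sample_corpus`` — non-uniform duplication (sK): each document's
  multiplicity is drawn i.i.d. uniform on {1..K}.  This is the scheme
  that distorts collocation and topic statistics.
* ``generate_ehr_corpus`` — an EHR-like simulator: patients with
  longitudinal notes, Zipfian vocabulary, latent topic structure,
  patient-specific name tokens, and copy-paste modeled as verbatim
  line carry-over from each note to the next, controlled by a copy
  fraction rho.  Chain copying compounds across a patient's notes the
  way clinical copy-paste does.

All generators are byte-for-byte reproducible for a fixed (config, seed).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, replace

import numpy as np

from .corpus_io import Corpus, Document

__all__ = [
    "SynthEhrConfig",
    "duplicate_corpus",
    "sample_corpus",
    "generate_ehr_corpus",
]


@dataclass(frozen=True)
class SynthEhrConfig:
    """Knobs of the EHR-like note simulator.

    copy_fraction
        Fraction rho of a note's lines copied verbatim from the patient's
        previous note (first note copies nothing).  rho around 1/3
        emulates the same-patient redundancy level reported for real
        informative-note corpora.
    zipf_exponent
        Shape of the vocabulary's power-law; each latent topic is the
        same Zipfian weight profile over its own random permutation of
        the vocabulary, so topics are well separated while the corpus
        stays Zipfian overall.
    name_tokens_per_patient
        Patient-unique pseudo-name tokens inserted as an adjacent pair on
        one line of every note (0 disables); these reconstruct the
        single-patient "signature" collocation artifact.
    burstiness
        Probability that a token repeats a word already used earlier in
        the same note instead of being drawn fresh from the topic
        mixture.  Natural language is bursty — a content word used once
        in a document tends to recur in it — and this document-specific
        concentration is what non-uniform duplication amplifies.  Default
        0.3.
    n_phrases / phrase_rate
        Genuine two-word collocations ("heart attack"-style frozen
        phrases), each tied to a topic and shared by every patient using
        that topic.  At each token position a phrase is emitted with
        probability ``phrase_rate``.  These give the corpus real
        high-support collocations against which copy-paste artifacts can
        be contrasted.
    """

    n_patients: int = 50
    notes_per_patient: tuple[int, int] = (3, 8)
    lines_per_note: tuple[int, int] = (4, 10)
    tokens_per_line: tuple[int, int] = (5, 10)
    copy_fraction: float = 0.3
    vocab_size: int = 2000
    zipf_exponent: float = 1.1
    n_topics: int = 20
    name_tokens_per_patient: int = 2
    topic_concentration: float = 0.3
    burstiness: float = 0.3
    n_phrases: int = 40
    phrase_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.copy_fraction <= 1.0:
            raise ValueError("copy_fraction must be in [0, 1]")
        if not 0.0 <= self.burstiness < 1.0:
            raise ValueError("burstiness must be in [0, 1)")
        if not 0.0 <= self.phrase_rate < 1.0 or self.n_phrases < 0:
            raise ValueError("invalid phrase settings")
        for name in ("notes_per_patient", "lines_per_note", "tokens_per_line"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.vocab_size <= self.n_topics * 10:
            raise ValueError("vocab_size must exceed 10 * n_topics")


def _copy_doc(doc: Document, new_id: str) -> Document:
    return Document(
        new_id,
        list(doc.raw_lines),
        [list(line) for line in doc.token_lines],
        patient_id=doc.patient_id,
        date=doc.date,
        note_type=doc.note_type,
        concept_tokens=list(doc.concept_tokens)
        if doc.concept_tokens is not None
        else None,
    )


def duplicate_corpus(base: Corpus, K: int) -> Corpus:
    """Uniform duplication: each document appears exactly K times.

    Copies carry doc_ids ``<base_id>#<copy-index>`` and are grouped per
    base document, in base order.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    out = Corpus(layer=base.layer)
    for doc in base:
        for k in range(1, K + 1):
            out.add(_copy_doc(doc, f"{doc.doc_id}#{k}"))
    return out


def sample_corpus(base: Corpus, max_copies: int, seed: int = 0) -> Corpus:
    """Non-uniform duplication: multiplicity i.i.d. uniform on {1..max_copies}."""
    if max_copies < 1:
        raise ValueError("max_copies must be >= 1")
    rng = np.random.default_rng(seed)
    mult = rng.integers(1, max_copies + 1, size=len(base))
    out = Corpus(layer=base.layer)
    for doc, m in zip(base, mult):
        for k in range(1, int(m) + 1):
            out.add(_copy_doc(doc, f"{doc.doc_id}#{k}"))
    return out


def _zipf_weights(vocab_size: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, vocab_size + 1) ** exponent
    return w / w.sum()


def generate_ehr_corpus(
    config: SynthEhrConfig, return_truth: bool = False
) -> Corpus | tuple[Corpus, dict]:
    """Generate a patient-note corpus with controlled copy-paste redundancy.

    Each patient gets a Dirichlet topic mixture and unique name tokens.
    Notes are generated in date order (evenly spaced); note i > 0 copies
    ``round(rho * L)`` randomly chosen lines of note i-1 verbatim and
    fills the remaining lines with fresh text from the patient's topic
    mixture.  The patient's name tokens are appended, adjacent, to one
    line per note.

    With ``return_truth`` the generative state (topic-word distributions,
    patient mixtures, name tokens) is returned alongside the corpus.
    """
    rng = np.random.default_rng(config.seed)
    V, T = config.vocab_size, config.n_topics
    words = np.array([f"w{i:05d}" for i in range(V)])
    base_weights = _zipf_weights(V, config.zipf_exponent)
    # each topic: the Zipf profile over its own permutation of the vocabulary
    topic_word = np.empty((T, V))
    for t in range(T):
        topic_word[t, rng.permutation(V)] = base_weights
    topic_cdf = np.cumsum(topic_word, axis=1)
    # frozen two-word phrases, each owned by one topic
    phrases_by_topic: list[list[tuple[str, str]]] = [[] for _ in range(T)]
    phrase_list = []
    for i in range(config.n_phrases):
        pair = (f"ph{i:03d}a", f"ph{i:03d}b")
        phrases_by_topic[i % T].append(pair)
        phrase_list.append(pair)

    note_types = ("primary-provider", "clinical-note", "follow-up-note")
    start_date = datetime.date(2020, 1, 1)
    corpus = Corpus()
    mixtures = {}
    names = {}
    for p in range(config.n_patients):
        pid = f"p{p:04d}"
        mixture = rng.dirichlet(np.full(T, config.topic_concentration))
        mixtures[pid] = mixture
        name_tokens = [
            f"zz{pid}n{i}" for i in range(config.name_tokens_per_patient)
        ]
        names[pid] = name_tokens
        n_notes = int(rng.integers(*config.notes_per_patient, endpoint=True))
        prev_lines: list[list[str]] = []
        for i in range(n_notes):
            n_lines = int(rng.integers(*config.lines_per_note, endpoint=True))
            n_copy = min(round(config.copy_fraction * n_lines), len(prev_lines))
            token_lines: list[list[str]] = []
            if n_copy:
                picked = sorted(
                    rng.choice(len(prev_lines), size=n_copy, replace=False)
                )
                token_lines.extend([list(prev_lines[j]) for j in picked])
            note_bag = [t for line in token_lines for t in line]
            for _ in range(n_lines - n_copy):
                n_tok = int(rng.integers(*config.tokens_per_line, endpoint=True))
                topics = rng.choice(T, size=n_tok, p=mixture)
                draws = rng.random(n_tok)
                burst = rng.random(n_tok) < config.burstiness
                phr = rng.random(n_tok) < config.phrase_rate
                line = []
                for t, u, is_burst, is_phrase in zip(topics, draws, burst, phr):
                    if is_burst and note_bag:
                        tok = note_bag[int(rng.integers(len(note_bag)))]
                    elif is_phrase and phrases_by_topic[t]:
                        pa, pb = phrases_by_topic[t][
                            int(rng.integers(len(phrases_by_topic[t])))
                        ]
                        line.extend((pa, pb))
                        note_bag.extend((pa, pb))
                        continue
                    else:
                        tok = str(words[np.searchsorted(topic_cdf[t], u)])
                    line.append(tok)
                    note_bag.append(tok)
                token_lines.append(line)
            if len(name_tokens) >= 2:
                j = int(rng.integers(len(token_lines)))
                token_lines[j] = list(token_lines[j]) + list(name_tokens)
            raw_lines = [" ".join(line) for line in token_lines]
            corpus.add(
                Document(
                    f"{pid}-n{i:03d}",
                    raw_lines,
                    token_lines,
                    patient_id=pid,
                    date=start_date + datetime.timedelta(days=30 * i),
                    note_type=note_types[i % len(note_types)],
                )
            )
            prev_lines = token_lines
    if return_truth:
        return corpus, {
            "topic_word": topic_word,
            "vocabulary": [str(w) for w in words],
            "patient_mixtures": mixtures,
            "name_tokens": names,
            "phrases": phrase_list,
        }
    return corpus
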