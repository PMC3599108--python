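"""LDA topic modeling by collapsed Gibbs sampling, with held-out evaluation.

Latent Dirichlet Allocation models each document as a mixture over T
latent topics, each topic being a distribution over the vocabulary, with
symmetric Dirichlet priors alpha (document-topic) and beta (topic-word).
Inference is the standard collapsed Gibbs sampler: topic assignments z
are resampled token by token from

    p(z_i = t | rest)  ~  (n_dt + alpha) * (n_tw + beta) / (n_t + V*beta)

Model fit is compared across corpora by the log-likelihood the fitted
model assigns to withheld documents, estimated with the sequential
left-to-right method: each word's predictive probability is averaged
over particle states of topic assignments to the preceding words (with
resampling of those assignments at every position).  Per-token natural-
log values make curves comparable across corpus sizes.

The phenomenon of interest: training on a copy-paste-redundant corpus
yields a worse held-out fit than training on its non-redundant source,
even though the redundant corpus is larger.

Hot loops are numba-jitted; all randomness is seeded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .corpus_io import Corpus

__all__ = [
    "LdaConfig",
    "TopicModel",
    "HeldoutEstimate",
    "fit_lda",
    "heldout_loglik",
    "topic_curve",
]


@dataclass(frozen=True)
class LdaConfig:
    """Collapsed-Gibbs LDA settings.

    ``alpha`` defaults to 50/T and ``beta`` to 0.01 (fixed symmetric
    priors; no hyper-parameter optimization).  ``min_word_count`` sets the
    training-vocabulary floor: words rarer than this in the training
    corpus are dropped.
    """

    T: int
    alpha: float | None = None
    beta: float = 0.01
    iterations: int = 1000
    seed: int = 0
    min_word_count: int = 2

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")

    @property
    def effective_alpha(self) -> float:
        return self.alpha if self.alpha is not None else 50.0 / self.T


@dataclass
class TopicModel:
    """Final Gibbs state: count matrices plus the indexed vocabulary."""

    topic_word_counts: np.ndarray  # T x V
    doc_topic_counts: np.ndarray  # D x T
    vocabulary: list[str]
    config: LdaConfig
    doc_ids: list[str] = field(default_factory=list)

    @property
    def vocab_index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.vocabulary)}

    def phi(self) -> np.ndarray:
        """Smoothed topic-word distributions, rows summing to 1."""
        beta = self.config.beta
        counts = self.topic_word_counts
        return (counts + beta) / (
            counts.sum(axis=1, keepdims=True) + beta * counts.shape[1]
        )

    def top_words(self, k: int = 20) -> list[list[str]]:
        """Top-k words per topic by topic-word count (phi order)."""
        out = []
        for row in self.phi():
            idx = np.argsort(-row, kind="stable")[:k]
            out.append([self.vocabulary[i] for i in idx])
        return out


@dataclass
class HeldoutEstimate:
    """Left-to-right held-out log-likelihood (natural log)."""

    total_loglik: float
    n_tokens: int
    particles: int
    n_oov: int

    @property
    def per_token(self) -> float:
        return self.total_loglik / self.n_tokens if self.n_tokens else 0.0


@njit(cache=True)
def _gibbs(tokens, doc_of, z, ntw, nt, ndt, T, alpha, beta, iterations, seed):
    # pragma: no cover - jitted
    np.random.seed(seed)
    V = ntw.shape[1]
    p = np.empty(T, np.float64)
    for _ in range(iterations):
        for i in range(tokens.shape[0]):
            w = tokens[i]
            d = doc_of[i]
            t = z[i]
            ntw[t, w] -= 1
            nt[t] -= 1
            ndt[d, t] -= 1
            total = 0.0
            for k in range(T):
                pk = (ndt[d, k] + alpha) * (ntw[k, w] + beta) / (nt[k] + V * beta)
                p[k] = pk
                total += pk
            u = np.random.random() * total
            acc = 0.0
            k = T - 1
            for kk in range(T):
                acc += p[kk]
                if acc >= u:
                    k = kk
                    break
            z[i] = k
            ntw[k, w] += 1
            nt[k] += 1
            ndt[d, k] += 1


@njit(cache=True)
def _left_to_right_doc(words, phi, T, alpha, particles, seed):
    # pragma: no cover - jitted
    np.random.seed(seed)
    n_words = words.shape[0]
    z = np.zeros((particles, n_words), np.int64)
    ndt = np.zeros((particles, T), np.float64)
    p = np.empty(T, np.float64)
    total = 0.0
    for n in range(n_words):
        w = words[n]
        psum = 0.0
        for r in range(particles):
            # resample assignments of all preceding positions
            for j in range(n):
                t_old = z[r, j]
                ndt[r, t_old] -= 1.0
                wj = words[j]
                tot = 0.0
                for k in range(T):
                    pk = (ndt[r, k] + alpha) * phi[k, wj]
                    p[k] = pk
                    tot += pk
                u = np.random.random() * tot
                acc = 0.0
                k = T - 1
                for kk in range(T):
                    acc += p[kk]
                    if acc >= u:
                        k = kk
                        break
                z[r, j] = k
                ndt[r, k] += 1.0
            # predictive probability of the current word
            denom = n + T * alpha
            pw = 0.0
            for k in range(T):
                pw += (ndt[r, k] + alpha) / denom * phi[k, w]
            psum += pw
            # assign the current word
            tot = 0.0
            for k in range(T):
                pk = (ndt[r, k] + alpha) * phi[k, w]
                p[k] = pk
                tot += pk
            u = np.random.random() * tot
            acc = 0.0
            k = T - 1
            for kk in range(T):
                acc += p[kk]
                if acc >= u:
                    k = kk
                    break
            z[r, n] = k
            ndt[r, k] += 1.0
        total += np.log(psum / particles)
    return total


def _derive_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2**31 - 1))


def fit_lda(
    corpus: Corpus, config: LdaConfig, vocabulary: list[str] | None = None
) -> TopicModel:
    """Fit LDA on a corpus by collapsed Gibbs sampling.

    The vocabulary defaults to the words occurring at least
    ``config.min_word_count`` times in the corpus (under its layer);
    out-of-vocabulary tokens are dropped from training.  When models
    trained on different corpora are compared on the same held-out set,
    pass an explicit shared ``vocabulary`` — per-token likelihoods are
    only comparable over a common vocabulary.  Same corpus, config and
    seed give identical count matrices.
    """
    streams = [corpus.doc_tokens(d) for d in corpus]
    if vocabulary is None:
        counts: Counter = Counter(t for s in streams for t in s)
        vocabulary = sorted(w for w, c in counts.items() if c >= config.min_word_count)
    else:
        vocabulary = list(vocabulary)
    if not vocabulary:
        raise ValueError("empty vocabulary after frequency filtering")
    vindex = {w: i for i, w in enumerate(vocabulary)}
    tokens_list, doc_of_list = [], []
    for d, stream in enumerate(streams):
        for t in stream:
            w = vindex.get(t)
            if w is not None:
                tokens_list.append(w)
                doc_of_list.append(d)
    tokens = np.array(tokens_list, dtype=np.int64)
    doc_of = np.array(doc_of_list, dtype=np.int64)
    T, V, D = config.T, len(vocabulary), len(streams)
    rng = np.random.default_rng(config.seed)
    z = rng.integers(0, T, size=tokens.shape[0]).astype(np.int64)
    ntw = np.zeros((T, V), dtype=np.int64)
    nt = np.zeros(T, dtype=np.int64)
    ndt = np.zeros((D, T), dtype=np.int64)
    np.add.at(ntw, (z, tokens), 1)
    np.add.at(nt, z, 1)
    np.add.at(ndt, (doc_of, z), 1)
    _gibbs(
        tokens,
        doc_of,
        z,
        ntw,
        nt,
        ndt,
        T,
        config.effective_alpha,
        config.beta,
        config.iterations,
        _derive_seed(config.seed, 17),
    )
    return TopicModel(ntw, ndt, vocabulary, config, doc_ids=list(corpus.doc_ids))


def heldout_loglik(
    model: TopicModel,
    heldout: Corpus,
    particles: int = 10,
    seed: int = 0,
) -> HeldoutEstimate:
    """Left-to-right estimate of the model's log-likelihood on new documents.

    Words are mapped through the model's vocabulary; out-of-vocabulary
    tokens are dropped (and counted in ``n_oov``).  The estimate is a sum
    of natural logs and is always <= 0.
    """
    if particles < 1:
        raise ValueError("particles must be >= 1")
    phi = model.phi()
    vindex = model.vocab_index
    alpha = model.config.effective_alpha
    total = 0.0
    n_tokens = 0
    n_oov = 0
    for d, doc in enumerate(heldout):
        stream = heldout.doc_tokens(doc)
        ids = [vindex[t] for t in stream if t in vindex]
        n_oov += len(stream) - len(ids)
        if not ids:
            continue
        words = np.array(ids, dtype=np.int64)
        total += _left_to_right_doc(
            words, phi, model.config.T, alpha, particles, _derive_seed(seed, d)
        )
        n_tokens += len(ids)
    return HeldoutEstimate(float(total), n_tokens, particles, n_oov)


def topic_curve(
    train: Corpus,
    heldout: Corpus,
    T_grid: list[int],
    seed: int = 0,
    alpha: float | None = None,
    beta: float = 0.01,
    iterations: int = 1000,
    particles: int = 10,
    min_word_count: int = 2,
    vocabulary: list[str] | None = None,
) -> pd.DataFrame:
    """Held-out log-likelihood as a function of the number of topics.

    One fit plus evaluation per T, with per-T seeds derived from the base
    seed.  The held-out corpus must share no documents with the training
    corpus, and for patient corpora no patients either (copies of
    training text in the test set would contaminate the comparison).
    When curves for corpora of different sizes are to be compared, pass a
    shared ``vocabulary``.
    """
    overlap_docs = set(train.doc_ids) & set(heldout.doc_ids)
    if overlap_docs:
        raise ValueError(f"train/heldout share doc_ids, e.g. {sorted(overlap_docs)[0]!r}")
    train_pat = {d.patient_id for d in train if d.patient_id is not None}
    held_pat = {d.patient_id for d in heldout if d.patient_id is not None}
    overlap_pat = train_pat & held_pat
    if overlap_pat:
        raise ValueError(
            f"train/heldout share patients, e.g. {sorted(overlap_pat)[0]!r}"
        )
    rows = []
    for T in T_grid:
        config = LdaConfig(
            T=T,
            alpha=alpha,
            beta=beta,
            iterations=iterations,
            seed=_derive_seed(seed, T),
            min_word_count=min_word_count,
        )
        model = fit_lda(train, config, vocabulary=vocabulary)
        est = heldout_loglik(model, heldout, particles, _derive_seed(seed, 7919 + T))
        rows.append((T, est.per_token, est.total_loglik, est.n_tokens))
    return pd.DataFrame(rows, columns=["T", "per_token", "total_loglik", "n_tokens"])
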