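"""Redundancy hurts topic modeling even though it adds data.

Three training corpora drawn from one generator — a 300-document base, a
non-uniformly duplicated version of it (each document 1-5 times), and a
3x larger clean corpus — are fit with collapsed-Gibbs LDA over a grid of
topic counts and scored on one shared held-out set with the left-to-right
estimator.  More clean data helps; duplicated data of the same documents
hurts at every T.
"""

from collections import Counter

from notedup import SynthEhrConfig, generate_ehr_corpus, sample_corpus, topic_curve

full = generate_ehr_corpus(
    SynthEhrConfig(
        n_patients=1300,
        notes_per_patient=(1, 1),
        copy_fraction=0.0,
        name_tokens_per_patient=0,
        n_topics=20,
        vocab_size=2000,
        seed=42,
    )
)
ids = full.doc_ids
base = full.subset(ids[:300])
larger = full.subset(ids[:900])
heldout = full.subset(ids[1000:])
redundant = sample_corpus(base, 5, seed=100)

# one shared vocabulary: per-token likelihoods are only comparable when
# every model scores the same held-out tokens
counts = Counter(t for d in base for t in base.doc_tokens(d))
vocab = sorted(w for w, c in counts.items() if c >= 2)

print(f"{'T':>4} {'base (300 docs)':>16} {'s5 redundant':>14} {'3x clean':>10}")
curves = {
    name: topic_curve(c, heldout, [10, 20, 40], seed=0, iterations=300,
                      particles=15, vocabulary=vocab)
    for name, c in (("base", base), ("s5", redundant), ("big", larger))
}
for i, T in enumerate((10, 20, 40)):
    row = [curves[n]["per_token"].iloc[i] for n in ("base", "s5", "big")]
    print(f"{T:>4} {row[0]:>16.4f} {row[1]:>14.4f} {row[2]:>10.4f}")
print("(held-out log-likelihood per token, natural log; higher is better)")
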