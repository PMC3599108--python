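"""How copy-paste redundancy corrupts collocation extraction.

Two effects are shown.  First, uniform duplication (every document K
times) leaves PMI scores bit-identical — pure duplication changes no
relative frequency.  Second, realistic non-uniform copying inflates
patient-specific word pairs (here, planted pseudo-name tokens) into
high-PMI collocations supported by a single patient; fingerprint
reduction removes most of them while keeping genuine cross-patient
phrases.
"""

from notedup import (
    ReductionConfig,
    SynthEhrConfig,
    duplicate_corpus,
    extract_collocations,
    generate_ehr_corpus,
    reduce_corpus,
    support_stats,
)

corpus = generate_ehr_corpus(
    SynthEhrConfig(n_patients=50, notes_per_patient=(4, 8), copy_fraction=0.6, seed=7)
)

base_list = [(c.bigram, c.score) for c in extract_collocations(corpus, "pmi", threshold=0.01)]
x2_list = [
    (c.bigram, c.score)
    for c in extract_collocations(duplicate_corpus(corpus, 2), "pmi", threshold=0.01)
]
print(f"uniform x2 duplication: lists identical = {base_list == x2_list}")

reduced, _ = reduce_corpus(corpus, ReductionConfig(cutoff=0.25))
for label, c in (("full corpus", corpus), ("reduced corpus", reduced)):
    found = extract_collocations(c, "pmi", threshold=0.01, min_count=5)
    stats = support_stats(found, c)
    print(
        f"{label:>14}: {stats.n_collocations:4d} collocations, "
        f"mean patient support {stats.mean_patients:5.1f}, "
        f"{100 * stats.frac_low_support:.0f}% supported by <=3 patients"
    )

# the planted single-patient signature pairs behave like 'Doe NP'
names = [
    c
    for c in extract_collocations(corpus, "pmi", threshold=0.01, min_count=5)
    if c.bigram[0].startswith("zz")
]
print(f"single-patient signature collocations in full corpus: {len(names)}")
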