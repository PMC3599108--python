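"""Build a redundancy-bounded sub-corpus by selective fingerprinting.

Each document is reduced to a set of 20-character line substrings; a
greedy pass keeps a document only if its fingerprint similarity to every
already-kept document stays at or below the cutoff.  Lower cutoffs give
smaller, cleaner corpora.  The printed redundancy figures show that the
fingerprint cutoff really does control alignment-level redundancy, and
how the metadata baseline (one latest note per patient) compares.
"""

from notedup import (
    ReductionConfig,
    SynthEhrConfig,
    generate_ehr_corpus,
    last_note_baseline,
    redundancy_profile,
    reduce_corpus,
)

corpus = generate_ehr_corpus(
    SynthEhrConfig(n_patients=50, notes_per_patient=(4, 8), copy_fraction=0.6, seed=7)
)
full = redundancy_profile(corpus, "same_patient", 300, seed=1)
print(f"input corpus: {len(corpus)} notes, same-patient redundancy {100*full.mean_sym:.1f}%")

for cutoff in (0.33, 0.25, 0.20):
    reduced, report = reduce_corpus(corpus, ReductionConfig(cutoff=cutoff))
    profile = redundancy_profile(reduced, "same_patient", 300, seed=1)
    print(
        f"cutoff {cutoff:.2f}: kept {report.counts[1]:3d}/{report.counts[0]} notes, "
        f"same-patient redundancy {100 * profile.mean_sym:.1f}%"
    )

baseline = last_note_baseline(corpus)
print(f"last-note baseline: kept {len(baseline)}/{len(corpus)} notes (one per patient)")
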