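"""Frequency-of-frequencies diagnostics: spotting redundancy without metadata.

A clean corpus follows Zipf's law: the number of terms occurring exactly
f times falls off monotonically in f.  Duplicating the corpus five times
shifts every term count by a factor of five, emptying the low bins and
piling the former singletons into the bin [4, 8) — a secondary peak that
flags redundancy from the shape of the distribution alone.
"""

from notedup import (
    SynthEhrConfig,
    duplicate_corpus,
    frequency_spectrum,
    generate_ehr_corpus,
    spectrum_shape,
)

base = generate_ehr_corpus(
    SynthEhrConfig(
        n_patients=80,
        notes_per_patient=(2, 4),
        copy_fraction=0.0,
        name_tokens_per_patient=0,
        n_topics=1,
        vocab_size=3000,
        n_phrases=0,
        burstiness=0.0,
        seed=13,
    )
)

for label, corpus in (("clean corpus", base), ("x5 duplicated", duplicate_corpus(base, 5))):
    spec = frequency_spectrum(corpus)
    diag = spectrum_shape(spec)
    bins = [spec.log2_bins[k] for k in sorted(spec.log2_bins)]
    peak = (
        "none"
        if diag.secondary_peak is None
        else f"bin {diag.secondary_peak} = frequencies {spec.bin_bounds(diag.secondary_peak)}"
    )
    print(f"{label}: log2-binned spectrum {bins}")
    print(f"{' ' * len(label)}  slope {diag.zipf_slope:.2f}, secondary peak: {peak}")
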