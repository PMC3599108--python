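"""Frequency-of-frequencies (Zipf) diagnostics for redundancy.

Natural corpora have long-tailed term-frequency distributions: most
terms occur once or twice, few occur often, and the number of terms
occurring exactly f times falls off as a power law in f.  Copy-paste
redundancy breaks this shape: terms that would occur once are replicated
k times, piling mass into mid-range frequency bins and producing a
secondary peak in the frequency-of-frequencies histogram.  This module
computes the spectrum, a log2-binned coarsening of it, a fitted log-log
slope, and a detector for that secondary peak.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .corpus_io import Corpus

__all__ = [
    "FrequencySpectrum",
    "SpectrumDiagnostics",
    "frequency_spectrum",
    "spectrum_shape",
]


@dataclass
class FrequencySpectrum:
    """Term counts, their frequency-of-frequencies, and a log2 coarsening.

    ``spectrum[f]`` is the number of terms occurring exactly f times.
    ``log2_bins[k]`` is the number of terms with frequency in
    [2**k, 2**(k+1)); keys run contiguously from 0 to the bin of the
    maximum frequency, with empty bins present as zeros.
    """

    term_counts: dict[str, int]
    spectrum: dict[int, int]
    log2_bins: dict[int, int]

    @staticmethod
    def bin_bounds(k: int) -> tuple[int, int]:
        return 2**k, 2 ** (k + 1)


@dataclass
class SpectrumDiagnostics:
    """Shape diagnostics of a frequency spectrum.

    ``zipf_slope`` is the least-squares slope of log2(number of terms)
    against log2(frequency) over non-empty spectrum cells (None when
    fewer than two cells).  ``secondary_peak`` is the first log2 bin
    whose count rises above its predecessor (None when the binned
    spectrum is non-increasing after its first bin) — the signature of a
    redundant corpus.
    """

    zipf_slope: float | None
    monotone_fraction: float
    secondary_peak: int | None


def frequency_spectrum(corpus: Corpus, layer: str | None = None) -> FrequencySpectrum:
    """Frequency spectrum of the corpus under the chosen token layer."""
    if layer is None:
        layer = corpus.layer
    counts: Counter = Counter()
    for doc in corpus:
        counts.update(doc.tokens(layer))
    spectrum: Counter = Counter(counts.values())
    if spectrum:
        kmax = max(spectrum).bit_length() - 1  # exact floor(log2 f)
        log2_bins = {k: 0 for k in range(kmax + 1)}
        for f, n_terms in spectrum.items():
            log2_bins[f.bit_length() - 1] += n_terms
    else:
        log2_bins = {}
    return FrequencySpectrum(dict(counts), dict(spectrum), log2_bins)


def spectrum_shape(spectrum: FrequencySpectrum) -> SpectrumDiagnostics:
    """Zipf slope, bin monotonicity and secondary-peak detection.

    Peak detection runs on the log2 bins (not raw frequencies) to
    suppress small-count jitter.
    """
    if not spectrum.spectrum:
        raise ValueError("empty spectrum")
    fs = np.array(sorted(spectrum.spectrum), dtype=float)
    ns = np.array([spectrum.spectrum[int(f)] for f in fs], dtype=float)
    slope = None
    if len(fs) >= 2:
        slope = float(np.polyfit(np.log2(fs), np.log2(ns), 1)[0])
    bins = [spectrum.log2_bins[k] for k in sorted(spectrum.log2_bins)]
    keys = sorted(spectrum.log2_bins)
    if len(bins) < 2:
        return SpectrumDiagnostics(slope, 1.0, None)
    non_increasing = sum(1 for a, b in zip(bins, bins[1:]) if b <= a)
    monotone_fraction = non_increasing / (len(bins) - 1)
    # a peak must rise above its predecessor AND carry real mass: rises of
    # one or two terms in the sparse tail are sampling jitter, not the
    # redundancy signature
    floor = max(2.0, 0.05 * max(bins))
    secondary_peak = None
    for i in range(1, len(bins)):
        if bins[i] > bins[i - 1] and bins[i] >= floor:
            secondary_peak = keys[i]
            break
    return SpectrumDiagnostics(slope, monotone_fraction, secondary_peak)
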