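# Methods

`notedup` treats copy-paste redundancy in longitudinal note corpora as a
measurable corpus property: it quantifies it by sequence alignment,
diagnoses it from frequency distributions, demonstrates its effect on two
standard text-mining methods, and removes it by fingerprint-based corpus
reduction. This note records the models, the defaults and why, the
numerical choices, and what the synthetic evaluation does and does not
show.

## Redundancy by token alignment

Redundancy between two documents is measured on their flattened token
streams with Smith–Waterman local alignment (match +2, mismatch −1, gap
−1, linear gaps). These scoring values are conventional text-alignment
defaults and are configurable; nothing downstream depends on their exact
magnitudes, only on match > 0 ≥ mismatch, gap.

A single local alignment captures one shared segment, but two notes
related by copy-paste typically share several disjoint blocks. The
default mode therefore extracts the best local alignment, masks the
aligned spans in both sequences (masked positions get unique sentinel
ids that can match nothing), and repeats while the best segment score is
at least `min_segment_score = 4`. With the default match score this
floor means a segment must contain at least two consecutive matching
tokens, which suppresses single shared-token noise — important because
any two notes share frequent function words.

Directional redundancy of a pair is matched tokens over each document's
length; the symmetric redundancy is the mean of the two directions. A
zero-length document has redundancy 0 by definition. Corpus-level
profiles sample unordered pairs uniformly without replacement from the
same-patient or cross-patient pair set, seeded, and report per-pair
records, a decile histogram (10%-wide bands) and the mean.

On the classic illustration of why sequence identity is stricter than
bag-of-words identity — two sentences that permute the same seven words
("pt developed abd pain and acute cholecystitis" vs "pt developed acute
abd pain and cholecystitis") — the shared-word identity is 100% while the
default alignment matches 6 tokens across 8 columns (75%). Published
discussions of this example have quoted ~73% sequence identity; no
token-level parameterization we explored reproduces 73% exactly (it
plausibly reflects character-level normalization), and we deliberately do
not force-fit it. The bag-of-words figure of 100% is exact and
parameter-free.

Tie-breaks in the traceback are diagonal-first, then up, then left; the
brute-force reference implementation in the tests uses the same stated
convention, so score *and* matched-token equality are well-defined.

## Fingerprinting and greedy reduction

A fingerprint is a length-`n` character substring of a document line; no
fingerprint spans a line boundary. Full fingerprinting takes all
`m − n + 1` windows of a line of length `m`; selective fingerprinting
takes the `floor(m/n)` consecutive non-overlapping windows starting at
offset 0, discarding a trailing remainder shorter than `n`. The default
granularity is `n = 20` characters: long enough that a shared fingerprint
almost certainly reflects a copied line fragment, short enough that a
typical 40–80-character note line yields at least two selective
fingerprints. Documents are represented by the *set* (not multiset) of
their hashed fingerprints, which makes the measure robust to boilerplate
lines repeated within one document. Hashes are stable 64-bit blake2b
digests; collisions are negligible at corpus scale and tests also run
unhashed.

Similarity of document B to document A is `|FP(A) ∩ FP(B)| / |FP(A)|`
(0 when A has no fingerprints). The greedy reduction visits documents in
a configurable order (input, date, or seeded random), and retains a
candidate only if for every already-retained document the similarity is
at or below the cutoff *in both directions*; the source description of
the algorithm defines the ratio with one denominator but not which
document plays that role inside the loop, and the symmetric test is the
conservative reading that guarantees the pairwise bound both ways in the
final set. An inverted index from fingerprint to retained documents
scores each candidate in time proportional to its fingerprint count
times average posting length; its behavior is identical to a quadratic
pairwise rescan (asserted against one in the tests).

Cutoff semantics: rejection requires similarity strictly greater than
the cutoff, so cutoff 1.0 rejects nothing and cutoff 0.0 keeps a maximal
prefix-greedy set of pairwise fingerprint-disjoint documents.

The metadata baseline keeps each patient's most recent note (ties broken
by later input position); it guarantees non-redundancy at the price of
discarding most of the corpus.

## Collocations and the patient-support audit

Bigrams are adjacent token pairs within a line (never across lines, for
consistency with line-based fingerprinting and note structure). PMI and
TMI are computed from the corpus-wide contingency table in log base 2:

    PMI = log2( n11 · npp / (n1p · np1) )
    TMI = Σ_ij (nij / npp) · log2( nij · npp / (ni+ · n+j) )

with empty cells contributing 0 to TMI. All counts are exact integers
and the score arithmetic divides integer products, so uniformly
duplicated corpora (xK) give bit-identical scores — the duplication
invariance is exact, not approximate. An optional vocabulary restriction
counts a bigram only when both words belong to a given word set (used to
control vocabulary when comparing corpora of different sizes).

Each extracted collocation is audited by its *patient support*: the
number of distinct patients whose notes contain the bigram. Support ≤ 3
flags a likely copy-paste artifact. The extraction default is
`min_count = 1`, but the redundancy-bias experiments in the tests and
acceptance script use `min_count = 5`: with no frequency floor, bigrams
occurring once (support 1 by construction) dominate the extraction from
any corpus, redundant or not, and the low-support fraction saturates on
both sides of the comparison. A floor of 5 matches the scale at which
copy-paste manufactures apparently-frequent bigrams (a signature pair
pasted across a handful of notes) and is conventional practice for
count-based collocation tools.

## Frequency-spectrum diagnostics

The frequency spectrum maps each occurrence count `f` to the number of
terms occurring exactly `f` times, and is coarsened into log2 bins
`[2^k, 2^(k+1))` (kept contiguous from k = 0, empty bins as zeros).
Under uniform duplication the spectrum shifts exactly:
`spectrum_xK[K·f] = spectrum_base[f]`, with no mass off multiples of K.

Diagnostics: a least-squares slope of log2(term count) vs log2(f) over
non-empty cells (unweighted; a diagnostic, not an estimator of record),
the fraction of adjacent bin pairs that are non-increasing, and a
secondary-peak detector. A secondary peak is the first bin that rises
above its predecessor *and* carries real mass — at least
`max(2, 5% of the largest bin)` terms. The mass floor matters: a clean
Zipfian sample almost always has an empty bin just below the bin of its
single most frequent term, and a literal "any rise" rule would flag that
one-term tail jitter as a peak. With the floor, a clean corpus yields no
peak, a ×5 duplicate peaks in the bin [4, 8) that received the shifted
singleton mass, and non-uniform (s5) duplication peaks in the bins
covering frequencies 2–8.

## LDA and held-out evaluation

LDA is fit by the standard collapsed Gibbs sampler with fixed symmetric
priors α = 50/T and β = 0.01 and seeded initialization; hyper-parameter
optimization is deliberately out of scope because the redundancy
phenomenon is a corpus property and its directional reproduction does
not require tuned priors. The training vocabulary defaults to words
occurring ≥ 2 times; out-of-vocabulary held-out tokens are dropped and
counted.

Held-out fit is the left-to-right sequential estimator: per document,
each word's predictive probability is averaged over particle states of
topic assignments to the preceding words, with resampling of those
assignments at every position, using the fitted model's smoothed
topic-word distributions. Reporting is in natural log, normalized per
token so curves are comparable across corpus sizes. The default is 10
particles; the corpus-comparison experiments use 15 particles and 300
Gibbs sweeps to keep estimator noise well below the effects measured.

One evaluation caveat is enforced by design: when models trained on
*different* corpora are compared on one held-out set, all of them must
share a single vocabulary (`fit_lda(..., vocabulary=...)`). With
per-corpus vocabularies a larger training corpus retains rarer held-out
tokens and its per-token likelihood is mechanically depressed, inverting
the benefit of more data. Curves built for a single corpus need no such
control. `topic_curve` also refuses held-out sets that share documents
or patients with the training corpus, since copies of training text in
the test set would contaminate the comparison.

Gibbs sampling and the left-to-right scorer are numba-jitted; all
randomness (initialization, sampling, particles) is seeded and runs are
bit-reproducible for a fixed seed.

## The synthetic generators

Uniform duplication (xK) appends each document exactly K times;
non-uniform sampling (sK) draws each document's multiplicity i.i.d.
uniform on {1..K}, seeded. Both derive copy ids from the base ids.

The EHR simulator generates patients with longitudinal notes:

- **Vocabulary / topics.** A Zipf(s = 1.1) weight profile over
  `vocab_size` words; each of `n_topics` topics applies that profile to
  its own random permutation of the vocabulary, so topics are well
  separated while the corpus stays power-law overall. Each patient draws
  a Dirichlet(0.3) topic mixture.
- **Copy-paste.** Note i > 0 copies `round(ρ·L)` randomly chosen lines
  of note i−1 verbatim (chain copying, which compounds across a
  patient's notes the way clinical copy-paste does) and generates the
  remaining lines fresh from the patient's mixture. ρ = 0 gives
  same-patient redundancy at the cross-patient level; ρ ≈ 0.33 puts
  adjacent-note redundancy near one third; the pairwise mean grows
  monotonically in ρ.
- **Burstiness.** With probability 0.3 a token repeats a word already
  used earlier in the same note. Natural text is bursty, and this
  document-specific concentration is precisely what non-uniform
  duplication amplifies; without it the LDA redundancy penalty does not
  emerge from the simulator.
- **Phrases.** A small inventory (40 two-word frozen phrases, emitted at
  rate 0.04, each owned by a topic) gives the corpus genuine
  cross-patient collocations, so the collocation experiments have a
  non-artifact class to contrast against.
- **Name tokens.** Each patient gets a unique adjacent token pair
  appended to one line per note — the "signature" that copy-paste
  inflates into a single-patient collocation.
- **Metadata.** Dates are evenly spaced per patient (so the last-note
  baseline is well defined); note types cycle through the informative
  kinds.

Generation is byte-reproducible for a fixed (config, seed).

What the simulator does *not* model: real clinical language, section or
template structure, within-copy edits, misspellings, de-identification
artifacts, or concept annotation (the concept layer is supported as an
input but not synthesized). Consequently, passing tests show that the
algorithms behave as designed on corpora with the *statistical*
structure of redundant note collections — Zipfian vocabulary, latent
topics, burstiness, verbatim line carry-over — not that effect sizes on
real EHR data will match.

## Problem sizes and runtimes

The test and acceptance experiments use deliberately modest sizes chosen
to make every stochastic direction stable across seeds: redundancy
profiles of 300–350 sampled pairs; reduction oracle checks on 100
documents; the collocation-bias corpus of 50 patients at ρ = 0.6
(~300 notes); and LDA corpora of 300 training documents (vocab ≈ 2,000,
~16k tokens), their s5-sampled versions, a 3× clean corpus, and a
300-document held-out set, at T ∈ {10, 20, 40} for 3 seeds. The full
suite runs in well under five minutes on one CPU.

## Known limitations

- Alignment is token-level only; a character-level mode is not offered.
- The repeated-extraction redundancy depends on `min_segment_score`;
  pairs sharing only isolated single tokens score 0 by design.
- Fingerprint similarity is whitespace-sensitive within lines (no
  normalization beyond the tokenizer's line splitting), matching its use
  on verbatim copies.
- The left-to-right estimator is O(length²) per document per particle;
  for very long documents a cheaper document-completion estimator would
  be preferable (not implemented).
- The secondary-peak detector's mass floor (5% of the largest bin) is a
  heuristic; corpora with genuinely multi-modal frequency profiles that
  are not redundancy-induced will also trigger it.
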