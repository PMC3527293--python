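# Methods

## Spectral rhythmicity score

A uniformly sampled signal `x_0 … x_{n−1}` (sampling step `Δt` hours, span
`nΔt`) is mean-centered and transformed with the FFT. Writing `X_k` for the
complex coefficient at frequency index `k`, the g-factor for a target period
`T` (default 24 h) is

    g = |X_k|² / Σ_{j=1..⌊n/2⌋} |X_j|² ,  k = nΔt / T.

Conventions and numerical choices:

* **DC exclusion.** The zero frequency is excluded from numerator and
  denominator (the signal is mean-centered first). Including it would
  compress every g toward 0 for positive-valued data and break the property
  that g ranges over the full [0, 1].
* **Positive frequencies only** (`k = 1 … ⌊n/2⌋`): the conjugate half of the
  spectrum of a real signal is redundant.
* **Grid match is a hard error.** `nΔt/T` must be an integer, otherwise the
  24-h component leaks across bins and silently corrupts g; the caller must
  truncate the record to whole periods (the behavioral scorer does this
  automatically). Non-uniform sampling and `n < 4` are likewise errors.
* **Zero variance ⇒ g = 0** with undefined (NaN) phase: a constant signal is
  maximally non-rhythmic, and every permutation of it is itself.
* **Phase** is the CT at which the fitted cosine peaks:
  `phase = (t_0 − arg(X_k)·T/2π) mod 24`, with `t_0` the CT of the first
  sample. **Relative amplitude** is `2|X_k|/n` (`|X_k|/n` at the Nyquist
  index), the amplitude of the fitted cosine in the data's units.
* A **harmonic variant** (flag `include_harmonics`) adds `|X_{2k}|², |X_{3k}|², …`
  to the numerator; on pure cosine signals it calls identical sets, and it is
  exposed only as a sensitivity check.
* g is invariant under affine maps `x → ax + b` (`a ≠ 0`), verified by
  property test.

## Permutation calibration and cutoff choice

For each of `R` repetitions (default 1000; the test suite and acceptance
script use 200), every transcript's time points are shuffled independently
(Fisher–Yates via a single seeded generator; a column-coherent variant that
shuffles all transcripts with one shared permutation is available behind a
flag as a sensitivity check). Per repetition, the number of transcripts with
`g ≥ c` is recorded on a cutoff grid (1000 evenly spaced points on [0, 1] by
default). The across-repetition mean is the random detection function — the
expected false-positive count at each cutoff — and the across-repetition
standard deviation is kept as the Monte-Carlo spread of a single null data
set.

The TP rate `(detection − random)/detection` is stored raw: Monte-Carlo noise
can push it slightly negative, and it is undefined (NaN) where nothing is
detected; a clamped copy is provided for reporting. The call set for a
demanded TP rate is taken at the **smallest** qualifying cutoff, because the
detection function is non-increasing in the cutoff, so the smallest cutoff
maximizes detections at the demanded precision. If no cutoff qualifies the
result is an explicit "unattainable" object carrying the best achievable
rate — never a silent empty set.

Calibration testing uses the band `3·max(sd, 1)` counts around the random
detection function, where `sd` is the permutation replicate spread: the real
null data set is one draw from the same conditional distribution given each
transcript's value multiset, the replicate spread is the natural SE estimate,
and the one-count floor acknowledges that the spread estimate is itself noisy
in the extreme tail where counts are fractional. At small problem sizes the
worst standardized deviation over a 1000-point grid is an extreme statistic
with visible seed-to-seed variance, so the unit-level check asserts its
median over five independent null data sets instead of a single draw; the
full-scale check (5000 transcripts, 200 permutations) asserts the band at
every cutoff.

## Pre-processing

Expression matrices are log2-transformed (`log2(x + pseudocount)`, default
pseudocount 1 for counts; 0 allowed for strictly positive intensities) and
quantile-normalized on the log scale: each column is replaced by the
row-wise mean of the column-sorted matrix at its ranks. Ties within a column
receive the mean of the reference values their rank span covers, so tied
entries stay tied and the column total is preserved; for tie-free columns
all columns end up with exactly the same sorted values. Whether RNA-seq
quantile normalization should act on raw or log counts is not uniquely
determined by convention; log scale is the default, overridable by flag.

The RNA-seq counting rule operates on SAM input (via pysam): primary
alignments only; both mates mapped to the same chromosome; uniqueness from
the NH tag (absent ⇒ unique); at most `max_mismatches` (default 2, NM tag)
per read. PCR duplicates are collapsed on the key (chromosome, pair
orientation, ordered pair of both mates' leftmost coordinates) — the
standard positional-duplicate definition. A surviving pair is counted for a
gene iff both mates' leftmost positions fall inside that gene's coding
intervals and that gene is unique; pairs straddling two genes are discarded
(conservative). Coordinates are 0-based half-open internally; BED is native,
SAM's 1-based positions are converted on ingestion. The operation is
idempotent and conserving (counted ≤ surviving ≤ input pairs). Mixed read
lengths across samples are not length-corrected; quantile normalization is
relied on instead.

## Behavioral analysis

Activity records are distance moved per uniform bin (10 min by default).
Spectral scoring always uses the **raw** trace truncated (never padded) to
the largest whole number of target periods — zero-padding would shift the
frequency grid off 24 h, and moving-average smoothing (centered window,
shrinking at the edges) concentrates power at low frequencies and inflates
g, so smoothing is presentation-only. No detrending is applied beyond mean
centering (flagged as an interpretation). Group comparison is the two-sample
two-sided Kolmogorov–Smirnov test on per-individual g-factors (scipy's
implementation; ties make the asymptotic p conservative), plus the fraction
of individuals with `g ≥ c` per group over the cutoff sweep 0.05–0.3 in
steps of 0.05, and each group's median-g individual for representative
traces. "Surpassing the median control signal" is implemented as a strict
inequality against the median control g-factor. The dark-flash control
compares per-larva mean distance during flash windows between groups with a
two-sided Student's t-test. Cropping records to the analysis days is the
caller's responsibility.

## Enrichment and validation

Gene-set enrichment is the exact binomial upper tail `P(X ≥ k)`,
`X ~ Binomial(n, p)` with `p` = (called genes)/(background genes), `n` the
gene-set size after restriction to the background, `k` the overlap — summed
exactly (scipy's `binom.sf`), no normal approximation, and `≥` rather than
`>` per standard cumulative-distribution usage. The default background
semantics is the full annotated-gene universe (14,263 RefSeq genes in the
reference application; both published bounds hold under it), overridable by
the caller since the original background choice is not documented. No
multiple-testing correction is applied to individual tests; a
Benjamini–Hochberg option exists for batch screens. Cross-platform agreement
is a 2×2 table on the universe of genes measured by both platforms, and
profile validation is the Pearson correlation of pre-aligned CT profiles
(≥3 points, zero-variance profiles rejected).

## Synthetic data

The generators define the conditions every statistical guarantee is tested
under.

* **Expression** (defaults): 12 time points, 4-h interval, starting CT14
  (two full periods); rhythmic fraction 0.1; amplitude U(0.5, 2.0) log2
  units; phases uniform on [0, 24) or fixed; additive Gaussian noise,
  SD 0.5 log2 units; baseline U(4, 10) log2 units. Rhythmic rows are
  `baseline + A·cos(2π(t − φ)/24) + ε`; others `baseline + ε`. Gaussian
  noise on the log scale matches what the detector consumes
  (log-transformed, quantile-normalized intensities); the noise SD of ~0.5
  log2 units is a typical replicate spread for array/RNA-seq time courses
  without biological replication. φ is defined as the CT of the cosine
  maximum.
* **Activity** (defaults): 10-min bins; baseline 10 distance units/bin;
  day:night mean ratio 3 (larval zebrafish are several-fold more active in
  subjective day), giving modulation depth m = (r−1)/(r+1) = 0.5 peaking at
  CT6 (mid subjective day); Gaussian noise SD 4; traces clipped at zero
  because distance moved is non-negative (with these defaults clipping is
  rare, and g of a noiseless rhythmic trace is 1 up to clipping distortion).
  Arrhythmic individuals share the same daily mean, constant in time.
* **Alignments**: proper read pairs (50 bp) placed uniformly so each read
  lies wholly inside a coding interval; a stated fraction of pairs are exact
  positional copies of previously drawn pairs (fresh names), emulating PCR
  duplicates; models overlapping on a strand are rejected. No sequencing
  errors or base-level simulation.

What the generators do **not** emulate: probe effects and background of real
microarrays, count overdispersion and library-size variation of real
RNA-seq, transcript-level correlation, non-sinusoidal waveforms, behavioral
ultradian structure, or missing data. Passing tests therefore demonstrate
the correctness and calibration of the statistics under their stated model,
not performance on any particular real data set.

## Problem sizes in the tests

The test suite and acceptance script run the calibration and precision
checks at 5,000 transcripts with 200 permutations, the behavioral power
check at 200 replicates of 75 vs 75 individuals over 3 days, and the oracle
comparison at 1,000 random vectors — sizes at which every Monte-Carlo margin
asserted is comfortably stable while the whole suite completes in seconds.

## Known limitations

* Uniform sampling only; no Lomb–Scargle support for irregular designs, and
  only the single target period (plus its harmonics behind the flag) is
  scanned.
* The TP rate is an expectation-based precision estimate, not a per-gene
  q-value; genes near the cutoff are not individually calibrated.
* The KS p-value is asymptotic for large samples; heavy ties (e.g. many
  exactly-zero g-factors) make it conservative.
* The enrichment null assumes genes are called independently with equal
  probability; co-regulation violates this in real data.
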