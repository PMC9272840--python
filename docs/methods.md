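# Methods

## Peak calling: the POM/POI cascade

Peak calling operates on transcript coordinates (0-based, half-open
throughout; motif positions refer to the index of the modified A). For each
transcript and sample, full 50-nt windows are placed at starts 0, 25, 50, …
(trailing partial windows are dropped) and scored as

POM = (window mean coverage) / (transcript-wide median coverage),

with the median taken over *all* positions, zeros included. Two classes of
transcript yield no windows and are logged: those shorter than one window,
and those with zero median coverage, where POM is undefined. We deliberately
do not fall back to a pseudocount median — it would inflate POM on
near-empty transcripts and manufacture peaks out of noise.

Retention uses a strict inequality for enrichment (POM > 3) and an
inclusive floor for coverage (mean ≥ 10). IP windows that overlap a
retained input window on the same transcript by at least one nucleotide are
discarded as shared regions; requiring exact coordinate identity instead is
available via `PeakParams(shared="exact")` since either reading of "shared"
is defensible, with the overlap rule being the more conservative
false-positive filter and therefore the default.

POI divides the IP POM by the input POM at identical coordinates, whether
or not that input window passed retention. The denominator is floored at
`epsilon` (default 0.1) so transcripts absent or empty in the input — whose
input POM is undefined — still get a finite, flagged POI. POI is reported
but not thresholded: after shared-region removal, the only further
selection is that a window fully contains a DRACH motif. Full containment
(not mere overlap of the 5-mer with the window edge) is required, since a
motif only partially inside a scored region cannot be said to carry the
window's enrichment. A transcript is *methylated* iff at least one window
survives the cascade; grouping is by transcript identity, not by site,
because the modified position may wander between nearby DRACH motifs across
replicates.

## DRACH scanning

DRACH (D = A/G/T, R = A/G, A, C, H = T/A/C on the DNA alphabet; U in RNA)
is a fully specified degenerate 5-mer class, so exhaustive scanning of
every position is exact and replaces any external motif tool. All
overlapping occurrences are reported; `N` never matches; no
reverse-complement scan is performed because transcripts are
single-stranded. The scanner is vectorized over byte arrays and is
cross-checked in the tests against both a regex-lookahead and a
per-5-mer brute-force oracle.

## Rank-sum testing

All group comparisons use the two-sided Mann–Whitney U with midranks.
Three branches share one interface: (1) full enumeration over every
labeling of the pooled midranks when C(n_a+n_b, n_a) ≤ 20,000 — exact even
under ties, and the only branch that returns exactly p = 1 for identical
tied samples; (2) the tie-free exact null distribution of U for
n_a·n_b ≤ 400 (via scipy's dynamic program); (3) the normal approximation
with tie correction and continuity correction otherwise. Two-sided p is
min(1, 2·min(P(U′≥U), P(U′≤U))). The per-offset metaprofile comparisons
report raw p-values — no multiplicity adjustment is applied to the 21 zoom
offsets by default, with an optional Benjamini–Hochberg column available —
because the per-offset tests are read as a profile, not as independent
discoveries.

## PARS scores and metaprofiles

Raw V1/S1 counts are normalized to reads per million (RPM) of their
libraries; the PARS score is log2((V1+c)/(S1+c)) with pseudocount
c = 1 RPM (configurable; c ∈ {0.1, 1, 5} is a reasonable sensitivity
range). The pseudocount guarantees finite scores at uncovered positions but
also shrinks scores toward 0 wherever per-position RPM is small relative to
c — deeply sequenced libraries spread over many positions therefore show
attenuated profile amplitudes, a known trade-off of pseudocounted log
ratios. Metaprofiles aggregate per offset (mean by default, median
available) over −50..+50 around each site's A; sites within 50 nt of a
transcript end contribute their in-bounds offsets rather than being
discarded (a strict complete-window mode exists for boundary analyses).
The control profile is built from A-positions of unmethylated DRACH motifs,
so the two groups share an identical local nucleotide signature and differ
only in methylation status.

## Recovery accounting

Pool membership is detection-based: pooled monosome+polysome raw count ≥ 1
(configurable), with fraction counts summed before thresholding. RPKM
(count · 10⁹ / (length · library size)) is computed on the pooled library
and used only for reporting and abundance comparison, not for membership.
Recovery percentages are rounded half-up to integer percent for reporting;
the unrounded fractions are always carried alongside. Boxplot summaries use
linear interpolation between order statistics for quartiles.

## The synthetic-data generator

The generator is the package's validation instrument: it emulates the
statistical structure the analysis assumes, with every planted feature
recorded as ground truth.

| parameter | default | rationale |
| --- | --- | --- |
| `frac_methylated` | 0.47 | methylated share of SG clients (2,461 of 5,219) |
| `mean_length_methylated` / `non` | 3,200 / 2,500 nt | reported group means; log-normal with σ = 0.45 on the log scale, a typical mRNA length spread |
| `coverage_mean`, `coverage_dispersion` | 30×, 0.1 | realistic m6A-seq depth; NB dispersion typical of bulk RNA-seq coverage |
| `ip_peak_fold`, `ip_peak_width` | 5, 50 nt | clear antibody enrichment; Gaussian bump with sd = width/4 |
| `pars_baseline`, `pars_dip`, `pars_elevation` | 0.5, 0.3, 0.2 | neutral pairing propensity; dip at the modified A, elevation at ±1..10 nt |
| `pars_depth` | 50 reads/nt | moderate PARS coverage (Poisson digests) |
| `p_meth`, `p_non` | 0.96, 0.84 | programmed recovery probabilities |
| `abundance_mean_methylated` / `non` | 60 / 25 | methylated mRNAs more abundant in the translating fraction |

Coverage is negative-binomial (var = m + 0.1·m²) because RNA-seq coverage
is overdispersed; the PARS digests are Poisson for simplicity. Planted
motifs stay ≥ 60 nt from transcript ends by default so metaprofile windows
are complete; one planted site per methylated transcript by default
(multi-site mode exists). Randomness is streamed through
`numpy.random.default_rng([seed, stage_key])` with a fixed key per stage,
giving byte-identical outputs per seed and independence between stages.

**What the generator does not emulate:** isoform structure and UTR/CDS
architecture, read-level artifacts (GC bias, mappability, fragmentation
bias), antibody off-target binding, correlated noise between IP and input,
and biological covariation between length, methylation and abundance beyond
the programmed group shifts. Passing the synthetic recovery tests therefore
demonstrates that the implementation measures what it claims under the
assumed noise model — not that the assumed model captures every property of
real libraries.

## Problem sizes used in validation

The test suite and the acceptance script run the pipeline at 500–2,000
synthetic transcripts (≈2,000 per group for recovery-rate estimation,
≈300+ sites per group for metaprofiles), sizes at which binomial sampling
error is comfortably inside the asserted tolerances (SE ≈ 0.8 pp for a
0.84 proportion at n = 2,000). The null calibration of the rank-sum test
uses 10,000 simulated pairs at n = 20 per group.

## Known limitations

* POM is undefined on zero-median transcripts; such transcripts can never
  be called methylated regardless of local enrichment. This mirrors the
  statistic's design but means sparse, long transcripts are conservatively
  handled.
* The POI epsilon floor makes input-empty transcripts callable but assigns
  them large, flagged POI values; downstream consumers should treat flagged
  calls with care.
* The pseudocounted PARS score compresses structure signal at low
  per-position RPM (see above); comparisons remain valid because both
  groups are compressed identically.
* Recovery accounting is set-based; it deliberately does not model
  abundance changes between stress and recovery (no differential
  expression), and actinomycin-D conditions are treated as ordinary labeled
  conditions.
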