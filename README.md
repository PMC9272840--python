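# sgrecover

Tools for asking what happens to mRNAs sequestered in stress granules (SGs)
once stress is lifted: do they return to translation, and does the
N6-methyladenosine (m6A) modification give them an edge? `sgrecover`
implements the downstream computational analysis for this question as a
reusable, tested Python package, exercisable end-to-end on synthetic data
with known ground truth.

## What it computes

**m6A peak calling (POM/POI).** From per-nucleotide coverage of an
m6A-immunoprecipitated library (IP) and its matched input, each transcript
is scanned with 50-nt sliding windows (25-nt step). The enrichment statistic
is the *peak over median*,

```
POM(w) = mean coverage in window w / median coverage of the whole transcript
```

Windows with POM > 3 and mean coverage ≥ 10 are retained; windows that are
also enriched in the input are discarded as shared false positives; for the
survivors the *peak over input* POI = POM_IP / POM_input is computed at
identical coordinates. Only windows that fully contain a DRACH motif
(D=A/G/U, R=A/G, central A, C, H=U/A/C — the m6A installation consensus)
count; a transcript with at least one such window is classified
*methylated*.

**Recovery accounting.** Monosome and polysome fractions per condition are
pooled into a "translating mRNA" set (detection: pooled raw count ≥ 1);
the recovery fraction of an SG transcript group is
|group ∩ pool| / |group|. Group length summaries and RPKM abundance
comparisons (two-sided Mann–Whitney U) complete the picture.

**PARS structural metaprofiles.** Per-nucleotide PARS scores,
`log2((V1_RPM + c) / (S1_RPM + c))` with pseudocount c = 1 (V1: double-strand
RNase; S1: single-strand nuclease; positive = structured), are aggregated
in a ±50-nt window centered on methylated DRACH adenines and compared,
offset by offset in a ±10-nt zoom, against unmethylated DRACH controls with
the rank-sum test.

**Synthetic data.** `sgrecover.simulate` generates a fully labeled
transcriptome with planted DRACH sites, negative-binomial IP/input coverage
with Gaussian enrichment bumps, Poisson V1/S1 digests encoding a
single-strandedness dip at the modified A with elevated pairing in its
±10-nt vicinity, and per-condition translating pools with group-specific
recovery probabilities (0.96 methylated / 0.84 non-methylated by default).

## Worked example

```
$ sgrecover run-all --seed 1 --outdir out/
{
  "methylated": 931,
  "recovery": {
    "methylated@30min": 96,
    "non_methylated@30min": 86,
    "methylated@4h": 96,
    "non_methylated@4h": 82
  }
}
```

With the default configuration (2,000 synthetic SG client transcripts),
931 transcripts are called methylated; 96% of them are found back in the
translating pool at both sampled recovery time points, against 86%/82% of
the non-methylated group — the methylated group recovers more completely.
`out/` additionally contains the peak calls (`peaks.bed`), the per-offset
PARS comparison (`pars_comparison.tsv`, showing the structure dip at the
modified A), group length and abundance summaries, and a `manifest.json`
with per-stage record counts and file checksums.

The same stages are available individually (`sgrecover simulate`,
`callpeaks`, `pars-profile`, `recovery`, `scan-drach`) and as library
functions, e.g.:

```python
from sgrecover import call_methylation, scan_drach, read_fasta, read_coverage

transcripts = read_fasta("transcriptome.fa")
tome = {t.transcript_id: t for t in transcripts}
ip = read_coverage("ip_coverage.tsv", tome)
inp = read_coverage("input_coverage.tsv", tome)
calls = call_methylation(ip, inp, {t.transcript_id: scan_drach(t) for t in transcripts})
```

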