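"""Ground-truth-labeled synthetic data for every pipeline stage.

The generator emulates the statistical structure the analysis assumes for
stress-granule client transcripts, at configurable scale:

* a transcriptome split into methylated and non-methylated groups, with
  log-normal lengths (methylated longer on average) and one DRACH motif
  planted per methylated transcript;
* m6A-seq IP/input coverage: negative-binomial per-nucleotide input, IP
  multiplied by a Gaussian enrichment bump centered on the planted A;
* PARS V1/S1 digests: Poisson counts driven by a per-nucleotide structure
  propensity with a single-strandedness dip at the modified A and elevated
  double-strandedness at offsets within +/-10 nt;
* translating pools per condition: Bernoulli membership with group-specific
  recovery probabilities and overdispersed counts, methylated transcripts
  more abundant.

Every draw flows through ``numpy.random.default_rng`` seeded from
``SimConfig.seed`` plus a fixed per-stage stream key, so each stage is
individually reproducible and a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .drach import DrachSite
from .formats_io import CountTable, CoverageTrack, Transcript
from .pars import ParsTrack

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# per-stage RNG stream keys (second word of the seed sequence)
_STREAM_TRANSCRIPTOME = 1
_STREAM_M6A = 2
_STREAM_PARS = 3
_STREAM_POOLS = 4
_STREAM_CONTROL = 5


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator; defaults mirror the reported data.

    Lengths are log-normal with group means 3.2 kb (methylated) and 2.5 kb
    (non-methylated); the methylated share of SG clients is 2,461/5,219;
    recovery probabilities are 0.96/0.84; IP peaks are 5-fold Gaussian
    bumps ~50 nt wide on ~30x coverage; the PARS signal is a dip of 0.3 in
    pairing propensity at the modified A and a +0.2 elevation within
    +/-10 nt.
    """

    n_transcripts: int = 500
    frac_methylated: float = 0.47
    mean_length_methylated: float = 3200.0
    mean_length_non_methylated: float = 2500.0
    length_sigma: float = 0.45  # sd of log-length
    min_length: int = 300
    coverage_mean: float = 30.0
    coverage_dispersion: float = 0.1
    ip_peak_fold: float = 5.0
    ip_peak_width: float = 50.0  # ~ +/- 2 sd of the Gaussian bump
    pars_baseline: float = 0.5
    pars_dip: float = 0.3
    pars_elevation: float = 0.2
    pars_vicinity: int = 10
    pars_depth: float = 50.0
    p_meth: float = 0.96
    p_non: float = 0.84
    conditions: tuple[str, ...] = ("30min", "4h")
    abundance_mean_methylated: float = 60.0
    abundance_mean_non_methylated: float = 25.0
    edge_margin: int = 60  # planted motifs keep this distance from ends
    sites_per_transcript: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.frac_methylated, self.p_meth, self.p_non):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        if self.ip_peak_fold <= 1.0:
            raise ValueError("ip_peak_fold must exceed 1")
        if not 0.0 < self.pars_baseline < 1.0:
            raise ValueError("pars_baseline must lie in (0,1)")


@dataclass
class GroundTruth:
    """What the generator actually planted, for scoring the pipeline."""

    transcripts: list[Transcript] = field(default_factory=list)
    methylated: set[str] = field(default_factory=set)
    site_positions: dict[str, list[int]] = field(default_factory=dict)
    pools: dict[str, set[str]] = field(default_factory=dict)
    structure_propensity: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def non_methylated(self) -> set[str]:
        return {t.transcript_id for t in self.transcripts} - self.methylated

    @property
    def transcriptome(self) -> dict[str, Transcript]:
        return {t.transcript_id: t for t in self.transcripts}


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _lognormal_lengths(
    rng: np.random.Generator, n: int, mean: float, sigma: float, floor: int
) -> np.ndarray:
    # choose mu so the log-normal mean hits the configured group mean
    mu = np.log(mean) - sigma**2 / 2
    return np.maximum(rng.lognormal(mu, sigma, size=n).astype(int), floor)


def _random_drach(rng: np.random.Generator) -> str:
    return (
        rng.choice(list("AGT")) + rng.choice(list("AG")) + "AC" + rng.choice(list("TAC"))
    )


def simulate_transcriptome(cfg: SimConfig) -> GroundTruth:
    """Random transcriptome with planted DRACH motifs on methylated transcripts.

    Methylated transcripts carry ``cfg.sites_per_transcript`` planted motifs,
    each at least ``cfg.edge_margin`` nt from either end; non-methylated
    transcripts may still contain DRACH motifs by chance (they supply the
    unmethylated control sites for structural metaprofiles).
    """
    rng = _rng(cfg, _STREAM_TRANSCRIPTOME)
    n = cfg.n_transcripts
    n_meth = int(round(n * cfg.frac_methylated))
    is_meth = np.zeros(n, dtype=bool)
    is_meth[rng.permutation(n)[:n_meth]] = True
    truth = GroundTruth()
    width = len(str(max(n - 1, 1)))
    for i in range(n):
        mean_len = cfg.mean_length_methylated if is_meth[i] else cfg.mean_length_non_methylated
        length = int(
            _lognormal_lengths(rng, 1, mean_len, cfg.length_sigma, cfg.min_length)[0]
        )
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        tx_id = f"TX{i:0{width}d}"
        positions: list[int] = []
        if is_meth[i]:
            seq_arr = bytearray(seq, "ascii")
            lo, hi = cfg.edge_margin, length - cfg.edge_margin - 5
            if hi <= lo:  # degenerate short transcript: plant centrally
                lo, hi = 0, max(1, length - 5)
            for _ in range(cfg.sites_per_transcript):
                start = int(rng.integers(lo, hi))
                motif = _random_drach(rng)
                seq_arr[start : start + 5] = motif.encode("ascii")
                positions.append(start + 2)
            seq = seq_arr.decode("ascii")
            truth.methylated.add(tx_id)
        tx = Transcript(tx_id, f"G{i:0{width}d}", seq)
        truth.transcripts.append(tx)
        truth.site_positions[tx_id] = sorted(set(positions))
    return truth


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def simulate_m6a_coverage(
    cfg: SimConfig, truth: GroundTruth
) -> tuple[dict[str, CoverageTrack], dict[str, CoverageTrack]]:
    """IP and input coverage tracks for every transcript.

    Input coverage is negative-binomial around ``cfg.coverage_mean``. The IP
    mean is the input mean times a Gaussian enrichment profile peaking at
    ``cfg.ip_peak_fold`` over each planted A (sd = width/4); unmethylated
    transcripts get IP noise around the same flat mean as the input.
    """
    rng = _rng(cfg, _STREAM_M6A)
    sd = cfg.ip_peak_width / 4.0
    ip_tracks: dict[str, CoverageTrack] = {}
    input_tracks: dict[str, CoverageTrack] = {}
    for tx in truth.transcripts:
        n = tx.length
        base = np.full(n, cfg.coverage_mean)
        enrich = np.ones(n)
        for a in truth.site_positions.get(tx.transcript_id, []):
            pos = np.arange(n)
            enrich += (cfg.ip_peak_fold - 1.0) * np.exp(-((pos - a) ** 2) / (2 * sd**2))
        input_tracks[tx.transcript_id] = CoverageTrack(
            tx.transcript_id, _nb(rng, base, cfg.coverage_dispersion), "input"
        )
        ip_tracks[tx.transcript_id] = CoverageTrack(
            tx.transcript_id, _nb(rng, base * enrich, cfg.coverage_dispersion), "ip"
        )
    return ip_tracks, input_tracks


def structure_propensity(cfg: SimConfig, truth: GroundTruth, tx: Transcript) -> np.ndarray:
    """Per-nucleotide pairing propensity with the programmed m6A signal."""
    q = np.full(tx.length, cfg.pars_baseline)
    for a in truth.site_positions.get(tx.transcript_id, []):
        lo = max(0, a - cfg.pars_vicinity)
        hi = min(tx.length, a + cfg.pars_vicinity + 1)
        q[lo:hi] = cfg.pars_baseline + cfg.pars_elevation
        q[a] = cfg.pars_baseline - cfg.pars_dip
    return np.clip(q, 0.01, 0.99)


def simulate_pars(
    cfg: SimConfig, truth: GroundTruth, pseudocount: float = 1.0
) -> dict[str, ParsTrack]:
    """Poisson V1/S1 digests of the programmed structure propensity.

    V1 counts ~ Poisson(depth * q), S1 ~ Poisson(depth * (1 - q)); library
    sizes are the realized totals, so RPM reflects sequencing-depth
    normalization exactly as on real libraries.
    """
    rng = _rng(cfg, _STREAM_PARS)
    v1_counts: dict[str, np.ndarray] = {}
    s1_counts: dict[str, np.ndarray] = {}
    for tx in truth.transcripts:
        q = structure_propensity(cfg, truth, tx)
        truth.structure_propensity[tx.transcript_id] = q
        v1_counts[tx.transcript_id] = rng.poisson(cfg.pars_depth * q).astype(float)
        s1_counts[tx.transcript_id] = rng.poisson(cfg.pars_depth * (1 - q)).astype(float)
    v1_lib = max(1.0, sum(float(v.sum()) for v in v1_counts.values()))
    s1_lib = max(1.0, sum(float(v.sum()) for v in s1_counts.values()))
    return {
        tx_id: ParsTrack.from_counts(
            tx_id, v1_counts[tx_id], s1_counts[tx_id], v1_lib, s1_lib, pseudocount
        )
        for tx_id in v1_counts
    }


def simulate_pools(cfg: SimConfig, truth: GroundTruth) -> dict[str, CountTable]:
    """Per-condition translating-fraction count tables.

    Every SG transcript enters a condition's pool with its group's recovery
    probability. Members get a pooled count of at least 1, drawn negative-
    binomially around the group abundance scale and split binomially between
    a monosome and a polysome fraction column; non-members get zeros.
    """
    import pandas as pd

    rng = _rng(cfg, _STREAM_POOLS)
    tx_ids = [t.transcript_id for t in truth.transcripts]
    tables: dict[str, CountTable] = {}
    for cond in cfg.conditions:
        meth_mask = np.array([t in truth.methylated for t in tx_ids])
        p = np.where(meth_mask, cfg.p_meth, cfg.p_non)
        member = rng.random(len(tx_ids)) < p
        scale = np.where(
            meth_mask, cfg.abundance_mean_methylated, cfg.abundance_mean_non_methylated
        )
        totals = 1 + _nb(rng, np.maximum(scale - 1, 0.0), cfg.coverage_dispersion)
        totals = np.where(member, totals, 0.0).astype(int)
        mono = rng.binomial(totals, 0.3)
        poly = totals - mono
        counts = pd.DataFrame(
            {f"{cond}_monosome": mono, f"{cond}_polysome": poly},
            index=pd.Index(tx_ids, name="transcript_id"),
        )
        lib = int(max(1, totals.sum()))
        tables[cond] = CountTable(
            counts, {f"{cond}_monosome": lib, f"{cond}_polysome": lib}
        )
        truth.pools[cond] = {t for t, m in zip(tx_ids, member) if m}
    return tables


def control_sites(
    cfg: SimConfig, truth: GroundTruth, max_sites: int | None = None
) -> list[DrachSite]:
    """Unmethylated DRACH adenines from non-methylated transcripts.

    These are the structural control set: the same 5-mer signature as
    methylated sites but no modification. At most one chance site per
    transcript is taken (the one nearest its middle, keeping contributed
    windows mostly complete); ``max_sites`` caps and subsamples
    deterministically.
    """
    from .drach import scan_drach

    rng = _rng(cfg, _STREAM_CONTROL)
    sites: list[DrachSite] = []
    for tx in truth.transcripts:
        if tx.transcript_id in truth.methylated:
            continue
        found = scan_drach(tx)
        if not found:
            continue
        mid = tx.length // 2
        sites.append(min(found, key=lambda s: abs(s.a_position - mid)))
    if max_sites is not None and len(sites) > max_sites:
        idx = rng.permutation(len(sites))[:max_sites]
        sites = [sites[i] for i in sorted(idx)]
    return sites


def config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["conditions"] = list(d["conditions"])
    return d
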