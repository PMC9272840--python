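"""PARS structure scores and m6A-centered metaprofiles.

PARS (parallel analysis of RNA structure) probes each nucleotide with two
enzymes: RNase V1 cleaves double-stranded RNA, nuclease S1 single-stranded.
After library-size normalization to reads per million (RPM), the per-
nucleotide PARS score is

    pars[i] = log2((v1_rpm[i] + c) / (s1_rpm[i] + c))

with pseudocount ``c`` (default 1 RPM) keeping the score finite at
uncovered positions. Positive scores mean a propensity to be base-paired.

Metaprofiles aggregate the score in a +/-50-nt window centered on the
modified adenine of methylated DRACH motifs, against a control profile
centered on unmethylated DRACH adenines — the same nucleotide signature,
differing only in methylation status. Sites near a transcript end
contribute only their in-bounds offsets. Per-offset group differences are
tested with the two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drach import DrachSite
from .rank_stats import benjamini_hochberg, mann_whitney

logger = logging.getLogger(__name__)


def rpm_normalize(raw, library_size: float) -> np.ndarray:
    """Reads per million: ``raw * 1e6 / library_size``."""
    if library_size <= 0:
        raise ValueError(f"library size must be positive, got {library_size}")
    return np.asarray(raw, dtype=float) * 1e6 / library_size


def pars_score(v1_rpm, s1_rpm, pseudocount: float = 1.0) -> np.ndarray:
    """Elementwise log2 ratio of V1 over S1 RPM, pseudocounted."""
    v1 = np.asarray(v1_rpm, dtype=float)
    s1 = np.asarray(s1_rpm, dtype=float)
    if v1.shape != s1.shape:
        raise ValueError("V1 and S1 arrays must have equal length")
    return np.log2((v1 + pseudocount) / (s1 + pseudocount))


@dataclass
class ParsTrack:
    """Per-nucleotide V1/S1 RPM and PARS score for one transcript."""

    transcript_id: str
    v1_rpm: np.ndarray
    s1_rpm: np.ndarray
    pars: np.ndarray

    @classmethod
    def from_counts(
        cls,
        transcript_id: str,
        v1_raw,
        s1_raw,
        v1_library_size: float,
        s1_library_size: float,
        pseudocount: float = 1.0,
    ) -> "ParsTrack":
        v1 = rpm_normalize(v1_raw, v1_library_size)
        s1 = rpm_normalize(s1_raw, s1_library_size)
        return cls(transcript_id, v1, s1, pars_score(v1, s1, pseudocount))


@dataclass
class ParsProfile:
    """Aggregated PARS scores per offset around (un)methylated DRACH adenines.

    ``samples[k]`` holds one PARS value per contributing site at offset
    ``k`` (offset 0 is the A). The aggregate is the per-offset mean by
    default; the median is available for robustness checks.
    """

    group: str
    half_window: int
    samples: dict[int, list[float]] = field(default_factory=dict)
    statistic: str = "mean"

    @property
    def offsets(self) -> list[int]:
        return list(range(-self.half_window, self.half_window + 1))

    def n(self, offset: int) -> int:
        return len(self.samples.get(offset, []))

    def aggregate(self, offset: int) -> float:
        vals = self.samples.get(offset, [])
        if not vals:
            return float("nan")
        agg = np.mean if self.statistic == "mean" else np.median
        return float(agg(vals))

    def aggregates(self) -> np.ndarray:
        return np.array([self.aggregate(k) for k in self.offsets])


def metaprofile(
    tracks: dict[str, ParsTrack],
    sites: list[DrachSite],
    half_window: int = 50,
    group: str = "methylated",
    statistic: str = "mean",
    complete_windows_only: bool = False,
) -> ParsProfile:
    """Collect PARS scores at every offset in ``-half_window..+half_window``
    around each site's A.

    Sites on transcripts absent from ``tracks`` are skipped and logged.
    With ``complete_windows_only`` sites too close to a transcript end are
    discarded entirely instead of contributing partial windows.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    profile = ParsProfile(group, half_window, {k: [] for k in range(-half_window, half_window + 1)}, statistic)
    for site in sites:
        track = tracks.get(site.transcript_id)
        if track is None:
            logger.info("%s: no PARS track, site at %d skipped", site.transcript_id, site.a_position)
            continue
        n = track.pars.size
        a = site.a_position
        if complete_windows_only and (a - half_window < 0 or a + half_window >= n):
            continue
        lo = max(-half_window, -a)
        hi = min(half_window, n - 1 - a)
        for k in range(lo, hi + 1):
            profile.samples[k].append(float(track.pars[a + k]))
    return profile


def compare_profiles(
    methylated: ParsProfile,
    control: ParsProfile,
    zoom: int = 10,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-offset two-sided rank-sum comparison of two profiles.

    Covers offsets ``-zoom..+zoom``; an offset with fewer than two samples
    in either group gets an NA p-value (logged). ``adjust`` adds a
    Benjamini-Hochberg column (raw p-values are always reported; no
    adjustment is applied by default).
    """
    rows = []
    for k in range(-zoom, zoom + 1):
        m = methylated.samples.get(k, [])
        c = control.samples.get(k, [])
        if len(m) < 2 or len(c) < 2:
            logger.info("offset %+d: <2 samples in a group, p undefined", k)
            p = float("nan")
        else:
            p = mann_whitney(m, c).p_value
        rows.append(
            {
                "offset": k,
                "n_meth": len(m),
                "mean_meth": methylated.aggregate(k),
                "n_ctrl": len(c),
                "mean_ctrl": control.aggregate(k),
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows).set_index("offset")
    if adjust:
        df["p_adjusted"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df


def profile_table(methylated: ParsProfile, control: ParsProfile) -> pd.DataFrame:
    """Full-width per-offset summary of both profiles (no testing)."""
    rows = []
    for k in methylated.offsets:
        rows.append(
            {
                "offset": k,
                "n_meth": methylated.n(k),
                "mean_meth": methylated.aggregate(k),
                "n_ctrl": control.n(k),
                "mean_ctrl": control.aggregate(k),
            }
        )
    return pd.DataFrame(rows).set_index("offset")
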