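"""m6A peak calling from IP/input coverage: the POM/POI cascade.

The enrichment statistic is the peak-over-median (POM): the mean coverage of
a 50-nt sliding window (25-nt step) divided by the median coverage across
the entire transcript, zeros included. The cascade per transcript is

1. score IP windows, keep POM > ``pom_threshold`` and mean >= ``min_mean_cov``;
2. score the input sample the same way and discard IP windows that overlap a
   retained input window ("shared regions", presumed false positives);
3. for surviving IP windows compute the peak-over-input (POI), the ratio of
   the IP POM to the input POM at identical coordinates (floored at
   ``epsilon`` to stay finite);
4. keep only windows that fully contain at least one DRACH motif.

A transcript is *methylated* iff at least one window survives the whole
cascade. POI is reported but not further thresholded: DRACH containment is
the only selection applied after shared-region removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .drach import DrachSite, sites_in_window
from .formats_io import CoverageTrack

logger = logging.getLogger(__name__)

METHYLATED = "methylated"
NON_METHYLATED = "non_methylated"


@dataclass(frozen=True)
class Window:
    """A scored sliding window on one transcript (0-based, half-open)."""

    transcript_id: str
    start: int
    end: int
    mean_cov: float
    pom: float


@dataclass
class PeakCall:
    """A retained IP window with its input POM, POI and DRACH anchors."""

    window: Window
    pom_input: float
    poi: float
    drach_sites: list[DrachSite]
    flagged: bool = False  # input transcript median was 0; POI used the epsilon floor


@dataclass
class MethylationCall:
    transcript_id: str
    status: str
    peaks: list[PeakCall] = field(default_factory=list)


@dataclass(frozen=True)
class PeakParams:
    """Tunable parameters of the cascade, defaulting to the published values."""

    window_size: int = 50
    step: int = 25
    pom_threshold: float = 3.0
    min_mean_cov: float = 10.0
    epsilon: float = 0.1
    shared: str = "overlap"  # or "exact": drop only coordinate-identical windows

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.step <= 0 or self.step > self.window_size:
            raise ValueError("require 0 < step <= window_size")
        if self.shared not in ("overlap", "exact"):
            raise ValueError(f"unknown shared-region mode {self.shared!r}")


def transcript_median(track: CoverageTrack) -> float:
    """Median coverage across the entire transcript, zero positions included."""
    return float(np.median(track.values))


def window_mean(track: CoverageTrack, start: int, end: int) -> float:
    return float(np.mean(track.values[start:end]))


def sliding_windows(
    track: CoverageTrack, window_size: int = 50, step: int = 25
) -> list[Window]:
    """Score every full sliding window of a transcript.

    Transcripts shorter than one window, or with zero median coverage (POM
    undefined), yield no windows; both cases are logged. Trailing partial
    windows are dropped.
    """
    n = len(track)
    if n < window_size:
        logger.info("%s: length %d < window %d, skipped", track.transcript_id, n, window_size)
        return []
    median = transcript_median(track)
    if median == 0:
        logger.info("%s: zero median coverage, skipped", track.transcript_id)
        return []
    starts = np.arange(0, n - window_size + 1, step)
    csum = np.concatenate([[0.0], np.cumsum(track.values)])
    means = (csum[starts + window_size] - csum[starts]) / window_size
    return [
        Window(track.transcript_id, int(s), int(s) + window_size, float(m), float(m / median))
        for s, m in zip(starts, means)
    ]


def retain_windows(
    windows: list[Window], pom_threshold: float = 3.0, min_mean_cov: float = 10.0
) -> list[Window]:
    """Windows with POM strictly above threshold and mean coverage at least the floor."""
    return [w for w in windows if w.pom > pom_threshold and w.mean_cov >= min_mean_cov]


def _overlaps(a: Window, b: Window) -> bool:
    return a.start < b.end and b.start < a.end


def remove_shared(
    ip_retained: list[Window], input_retained: list[Window], mode: str = "overlap"
) -> list[Window]:
    """Drop IP windows shared with retained input windows (false positives).

    ``mode='overlap'`` removes IP windows overlapping any retained input
    window on the same transcript by at least one nucleotide;
    ``mode='exact'`` removes only coordinate-identical windows.
    """
    by_tx: dict[str, list[Window]] = {}
    for w in input_retained:
        by_tx.setdefault(w.transcript_id, []).append(w)
    out = []
    for w in ip_retained:
        others = by_tx.get(w.transcript_id, [])
        if mode == "overlap":
            shared = any(_overlaps(w, o) for o in others)
        else:
            shared = any(o.start == w.start and o.end == w.end for o in others)
        if not shared:
            out.append(w)
    return out


def compute_poi(
    ip_window: Window, input_track: CoverageTrack, epsilon: float = 0.1
) -> tuple[float, float, bool]:
    """POI of an IP window: IP POM over the input POM at the same coordinates.

    The input POM is computed whether or not the input window passed
    retention. A zero input transcript median makes the input POM undefined;
    the POI is then computed against the ``epsilon`` floor and flagged.
    Returns ``(poi, pom_input, flagged)``.
    """
    input_median = transcript_median(input_track)
    mean_in = window_mean(input_track, ip_window.start, ip_window.end)
    if input_median > 0:
        pom_input = mean_in / input_median
        flagged = False
    else:
        pom_input = 0.0
        flagged = True
    poi = ip_window.pom / max(pom_input, epsilon)
    return poi, pom_input, flagged


def call_methylation(
    ip_tracks: dict[str, CoverageTrack],
    input_tracks: dict[str, CoverageTrack],
    drach_index: dict[str, list[DrachSite]],
    params: PeakParams = PeakParams(),
    stats: dict | None = None,
) -> dict[str, MethylationCall]:
    """Run the full POM/POI cascade and classify every IP transcript.

    ``drach_index`` maps transcript_id to its DRACH sites (see
    :func:`sgrecover.drach.scan_drach`). Transcripts present in the IP
    sample but absent from the input are treated as input all-zero and
    logged. Deterministic for fixed input. A ``stats`` dict, if given, is
    filled with cascade counts (windows scored/retained/after shared
    removal/DRACH-anchored), which are non-increasing along the cascade.
    """
    if stats is None:
        stats = {}
    stats.update(
        transcripts=0, windows_scored=0, windows_retained=0,
        windows_after_shared=0, windows_drach=0,
    )
    calls: dict[str, MethylationCall] = {}
    for tx_id in sorted(ip_tracks):
        ip = ip_tracks[tx_id]
        if tx_id in input_tracks:
            inp = input_tracks[tx_id]
        else:
            logger.info("%s: no input coverage, treating as all-zero", tx_id)
            inp = CoverageTrack(tx_id, np.zeros(len(ip)), "input")
        ip_windows = sliding_windows(ip, params.window_size, params.step)
        ip_ret = retain_windows(ip_windows, params.pom_threshold, params.min_mean_cov)
        in_ret = retain_windows(
            sliding_windows(inp, params.window_size, params.step),
            params.pom_threshold,
            params.min_mean_cov,
        )
        survivors = remove_shared(ip_ret, in_ret, params.shared)
        peaks: list[PeakCall] = []
        sites = drach_index.get(tx_id, [])
        for w in survivors:
            contained = sites_in_window(sites, w.start, w.end)
            if not contained:
                continue
            poi, pom_input, flagged = compute_poi(w, inp, params.epsilon)
            peaks.append(PeakCall(w, pom_input, poi, contained, flagged))
        status = METHYLATED if peaks else NON_METHYLATED
        calls[tx_id] = MethylationCall(tx_id, status, peaks)
        stats["transcripts"] += 1
        stats["windows_scored"] += len(ip_windows)
        stats["windows_retained"] += len(ip_ret)
        stats["windows_after_shared"] += len(survivors)
        stats["windows_drach"] += len(peaks)
    return calls


def status_table(calls: dict[str, MethylationCall]):
    """Methylation status summary as a DataFrame (transcript_id, status, n_peaks)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "transcript_id": list(calls),
            "status": [c.status for c in calls.values()],
            "n_peaks": [len(c.peaks) for c in calls.values()],
        }
    ).set_index("transcript_id")
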