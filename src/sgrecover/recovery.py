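"""Translating-pool recovery accounting.

After stress relief, monosome and polysome sucrose-gradient fractions are
pooled into a "translating mRNA" set per condition (e.g. 30 min, 4 h, with
or without actinomycin D). The recovery fraction of an SG transcript group
(methylated or non-methylated clients) is the share of that group detected
in the translating pool. The module also summarizes group lengths and
compares group abundances (RPKM) with the rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .formats_io import CountTable, Transcript
from .rank_stats import RankTestResult, mann_whitney

logger = logging.getLogger(__name__)


def rpkm(raw_count: float, transcript_length_nt: float, library_size: float) -> float:
    """Reads per kilobase per million mapped reads."""
    if transcript_length_nt <= 0:
        raise ValueError(f"transcript length must be positive, got {transcript_length_nt}")
    if library_size <= 0:
        raise ValueError(f"library size must be positive, got {library_size}")
    return raw_count * 1e9 / (transcript_length_nt * library_size)


@dataclass(frozen=True)
class TranslatingPool:
    """Transcripts detected in the pooled monosome+polysome fractions."""

    condition: str
    transcript_ids: frozenset[str]

    def __contains__(self, tx_id: str) -> bool:
        return tx_id in self.transcript_ids

    def __len__(self) -> int:
        return len(self.transcript_ids)


@dataclass(frozen=True)
class RecoveryResult:
    group: str
    condition: str
    n_sg: int
    n_recovered: int

    @property
    def fraction(self) -> float:
        return self.n_recovered / self.n_sg

    @property
    def pct_rounded(self) -> int:
        """Integer percent, rounded half-up (97.5 -> 98)."""
        pct = Decimal(100 * self.n_recovered) / Decimal(self.n_sg)
        return int(pct.quantize(0, rounding=ROUND_HALF_UP))


def build_pool(
    count_table: CountTable,
    condition: str,
    samples: list[str] | None = None,
    min_count: int = 1,
) -> TranslatingPool:
    """Detection-based translating pool for one condition.

    Raw counts of the pooled fraction samples (by default every column whose
    name starts with ``condition``) are summed per transcript; transcripts
    with a pooled count of at least ``min_count`` are members.
    """
    if samples is None:
        samples = [s for s in count_table.samples if s.startswith(condition)]
    if not samples:
        raise ValueError(f"no samples for condition {condition!r}")
    pooled = count_table.counts[samples].sum(axis=1)
    members = frozenset(pooled.index[pooled >= min_count])
    return TranslatingPool(condition, members)


def recovery_fraction(
    sg_group: set[str], pool: TranslatingPool, group: str = ""
) -> RecoveryResult:
    """Fraction of an SG transcript group present in the translating pool."""
    if not sg_group:
        raise ValueError("SG group is empty")
    n_recovered = len(set(sg_group) & pool.transcript_ids)
    return RecoveryResult(group, pool.condition, len(sg_group), n_recovered)


def group_lengths(
    groups: dict[str, set[str]],
    transcriptome: dict[str, Transcript],
    regions: dict[str, tuple[int, int, int]] | None = None,
) -> pd.DataFrame:
    """Per-group transcript length summary.

    Returns mean/median length in nt and the mean in kb to one decimal (the
    reporting convention). With a ``regions`` map of per-transcript
    (5'UTR, CDS, 3'UTR) lengths, per-region means are added. Group members
    missing from the transcriptome are excluded and logged; an empty group
    yields NaNs.
    """
    rows = []
    for name, members in groups.items():
        lengths = []
        region_lengths: list[tuple[int, int, int]] = []
        for tx_id in members:
            tx = transcriptome.get(tx_id)
            if tx is None:
                logger.info("group %s: %s missing from transcriptome, excluded", name, tx_id)
                continue
            lengths.append(tx.length)
            if regions is not None and tx_id in regions:
                region_lengths.append(regions[tx_id])
        if not lengths:
            logger.info("group %s: no measurable members", name)
        row = {
            "group": name,
            "n": len(lengths),
            "mean_length_nt": float(np.mean(lengths)) if lengths else float("nan"),
            "median_length_nt": float(np.median(lengths)) if lengths else float("nan"),
        }
        row["mean_length_kb"] = (
            round(row["mean_length_nt"] / 1000, 1) if lengths else float("nan")
        )
        if regions is not None:
            for i, part in enumerate(("utr5", "cds", "utr3")):
                vals = [r[i] for r in region_lengths]
                row[f"mean_{part}_nt"] = float(np.mean(vals)) if vals else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def quartiles(values) -> tuple[float, float, float]:
    """(Q1, median, Q3) by linear interpolation between order statistics."""
    q1, q2, q3 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
    return float(q1), float(q2), float(q3)


def compare_abundance(group_a_rpkm, group_b_rpkm) -> dict:
    """Rank-sum comparison of two RPKM samples plus boxplot-style summaries."""
    a = np.asarray(group_a_rpkm, dtype=float)
    b = np.asarray(group_b_rpkm, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    test: RankTestResult = mann_whitney(a, b)
    return {
        "test": test,
        "p_value": test.p_value,
        "quartiles_a": quartiles(a),
        "quartiles_b": quartiles(b),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }


def recovery_table(results: list[RecoveryResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "condition": r.condition,
                "n_sg": r.n_sg,
                "n_recovered": r.n_recovered,
                "fraction": r.fraction,
                "pct_rounded": r.pct_rounded,
            }
            for r in results
        ]
    )
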