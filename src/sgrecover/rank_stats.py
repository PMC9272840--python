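"""Two-sided Mann-Whitney U (rank-sum) test.

Used for the abundance comparison between methylated and non-methylated
translating mRNAs and for the per-offset PARS metaprofile comparison. Three
computational branches share one interface:

* full enumeration over all C(n_a+n_b, n_a) group labelings of the pooled
  midranks — exact even under ties, used when the labeling count is small;
* the tie-free exact null distribution of U (dynamic programming), used for
  moderate samples without ties;
* normal approximation with midrank tie correction and continuity
  correction otherwise.

Two-sided p is min(1, 2 * min(P(U' >= U), P(U' <= U))) in the exact
branches, matching the doubled-one-sided convention of the asymptotic
branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

#: Max number of labelings for the full-enumeration branch.
ENUMERATION_CAP = 20_000
#: Max n_a * n_b for the tie-free DP-exact branch.
EXACT_CAP = 400


@dataclass(frozen=True)
class RankTestResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"
    n_a: int
    n_b: int


def _u_from_ranks(rank_sum_a: float, n_a: int) -> float:
    return rank_sum_a - n_a * (n_a + 1) / 2.0


def _enumerate_p(pooled_ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Exact two-sided p over every labeling of the pooled midranks."""
    n = pooled_ranks.size
    offset = n_a * (n_a + 1) / 2.0
    n_ge = n_le = 0
    total = comb(n, n_a)
    eps = 1e-9
    for idx in combinations(range(n), n_a):
        u = pooled_ranks[list(idx)].sum() - offset
        if u >= u_obs - eps:
            n_ge += 1
        if u <= u_obs + eps:
            n_le += 1
    one_sided = min(n_ge, n_le) / total
    return min(1.0, 2.0 * one_sided)


def mann_whitney(a, b, mode: str = "auto") -> RankTestResult:
    """Two-sided Mann-Whitney U test between samples ``a`` and ``b``.

    ``mode`` is ``auto`` (pick a branch as described in the module
    docstring), ``exact`` (force an exact branch; falls back to enumeration
    under ties) or ``normal`` (force the tie-corrected normal
    approximation). U is reported for sample ``a`` from midrank assignment.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = _u_from_ranks(ranks[:n_a].sum(), n_a)
    has_ties = np.unique(pooled).size < pooled.size

    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")

    use_enumeration = comb(n_a + n_b, n_a) <= ENUMERATION_CAP
    use_dp = not has_ties and n_a * n_b <= EXACT_CAP
    if mode == "normal":
        branch = "normal"
    elif mode == "exact":
        if use_enumeration:
            branch = "enumeration"
        elif not has_ties:
            branch = "dp"
        else:
            raise ValueError(
                f"exact test infeasible: ties with C({n_a + n_b},{n_a}) > "
                f"{ENUMERATION_CAP} labelings"
            )
    else:
        branch = "enumeration" if use_enumeration else ("dp" if use_dp else "normal")

    if branch == "enumeration":
        p = _enumerate_p(ranks, n_a, u_a)
        return RankTestResult(float(u_a), float(p), "exact", n_a, n_b)
    if branch == "dp":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return RankTestResult(float(u_a), float(res.pvalue), "exact", n_a, n_b)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return RankTestResult(float(u_a), float(res.pvalue), "normal_approx", n_a, n_b)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values; NaNs are passed through untouched."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = stats.false_discovery_control(p[mask], method="bh")
    return out
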