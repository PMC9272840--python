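"""Independent brute-force oracles used only by the test suite.

Each oracle reimplements one pipeline operation with explicit loops and
standard-library primitives so that agreement with the package is a real
cross-check, not a tautology.
"""

from __future__ import annotations

import re
from itertools import combinations
from math import comb

# --- DRACH ----------------------------------------------------------------

_DRACH_RE = re.compile(r"(?=([AGT][AG]AC[TAC]))")


def regex_drach_a_positions(sequence: str) -> list[int]:
    """A-positions of all (overlapping) DRACH matches via regex lookahead."""
    return [m.start() + 2 for m in _DRACH_RE.finditer(sequence)]


def bruteforce_drach_a_positions(sequence: str) -> list[int]:
    """Check every 5-mer against the degenerate pattern, no regex."""
    out = []
    for i in range(len(sequence) - 4):
        k = sequence[i : i + 5]
        if (
            k[0] in "AGT"
            and k[1] in "AG"
            and k[2] == "A"
            and k[3] == "C"
            and k[4] in "TAC"
        ):
            out.append(i + 2)
    return out


# --- POM/POI cascade ------------------------------------------------------


def naive_median(values) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return float(s[mid]) if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def naive_windows(values, window_size=50, step=25):
    """(start, end, mean, pom) tuples; [] for short or zero-median tracks."""
    n = len(values)
    if n < window_size:
        return []
    median = naive_median(values)
    if median == 0:
        return []
    out = []
    start = 0
    while start + window_size <= n:
        chunk = values[start : start + window_size]
        mean = sum(chunk) / window_size
        out.append((start, start + window_size, mean, mean / median))
        start += step
    return out


def naive_methylation_status(
    ip_values,
    input_values,
    sequence,
    window_size=50,
    step=25,
    pom_threshold=3.0,
    min_mean_cov=10.0,
    epsilon=0.1,
):
    """Full cascade by explicit loops; returns (status, surviving windows)."""
    ip_ret = [
        w
        for w in naive_windows(ip_values, window_size, step)
        if w[3] > pom_threshold and w[2] >= min_mean_cov
    ]
    in_ret = [
        w
        for w in naive_windows(input_values, window_size, step)
        if w[3] > pom_threshold and w[2] >= min_mean_cov
    ]
    not_shared = [
        w
        for w in ip_ret
        if not any(w[0] < o[1] and o[0] < w[1] for o in in_ret)
    ]
    drach = bruteforce_drach_a_positions(sequence)
    surviving = []
    for start, end, mean, pom in not_shared:
        anchors = [a for a in drach if a - 2 >= start and a + 3 <= end]
        if anchors:
            surviving.append((start, end, mean, pom, anchors))
    status = "methylated" if surviving else "non_methylated"
    return status, surviving


# --- Mann-Whitney ---------------------------------------------------------


def midranks(pooled):
    """Midrank assignment without scipy."""
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def enumerate_mann_whitney(a, b):
    """(U_a, two-sided exact p) by exhausting every labeling of the pool."""
    n_a, n_b = len(a), len(b)
    pooled = list(a) + list(b)
    ranks = midranks(pooled)
    u_obs = sum(ranks[:n_a]) - n_a * (n_a + 1) / 2.0
    total = comb(n_a + n_b, n_a)
    n_ge = n_le = 0
    for idx in combinations(range(n_a + n_b), n_a):
        u = sum(ranks[i] for i in idx) - n_a * (n_a + 1) / 2.0
        if u >= u_obs - 1e-9:
            n_ge += 1
        if u <= u_obs + 1e-9:
            n_le += 1
    p = min(1.0, 2.0 * min(n_ge, n_le) / total)
    return u_obs, p
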