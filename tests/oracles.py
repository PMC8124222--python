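"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the code paths they check: digestion is a naive
character scan, the Fisher test is exact integer hypergeometric enumeration,
and the rank-sum test enumerates label assignments.
"""

from __future__ import annotations

import bisect
import itertools
from math import comb

TIE_SCALE = 10**7  # integer form of the 1e-7 relative tie tolerance


def naive_cut_positions(sequence: str) -> list[int]:
    """Sliding-window CCGG scan; cut one base after each occurrence."""
    seq = sequence.upper()
    return [i + 1 for i in range(len(seq) - 3) if seq[i : i + 4] == "CCGG"]


def naive_fragments(sequence: str) -> list[tuple[int, int]]:
    cuts = naive_cut_positions(sequence)
    return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]


def naive_cpgs(sequence: str, start: int, end: int) -> list[int]:
    seq = sequence.upper()
    return [p for p in range(start, end - 1) if seq[p : p + 2] == "CG"]


def fisher_enumeration(M1: int, U1: int, M2: int, U2: int) -> float:
    """Exact two-sided Fisher p by integer hypergeometric enumeration."""
    r1, r2 = M1 + U1, M2 + U2
    c1 = M1 + M2
    n = r1 + r2
    if min(r1, r2, c1, U1 + U2) == 0:
        return 1.0
    k_min, k_max = max(0, c1 - r2), min(c1, r1)
    nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(k_min, k_max + 1)]
    obs = nums[M1 - k_min]
    threshold = (obs * (TIE_SCALE + 1)) // TIE_SCALE
    total = sum(v for v in nums if v <= threshold)
    return total / comb(n, c1)


def fisher_enumeration_family(r1: int, r2: int, c1: int) -> list[float]:
    """Two-sided p for every table with the given margins, indexed by M1-k_min."""
    n = r1 + r2
    k_min, k_max = max(0, c1 - r2), min(c1, r1)
    nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(k_min, k_max + 1)]
    denom = comb(n, c1)
    sorted_nums = sorted(nums)
    prefix = list(itertools.accumulate(sorted_nums))
    out = []
    for v in nums:
        threshold = (v * (TIE_SCALE + 1)) // TIE_SCALE
        idx = bisect.bisect_right(sorted_nums, threshold)
        out.append(prefix[idx - 1] / denom if idx else 0.0)
    return out


def ranksum_enumeration(x, y) -> float:
    """Exact two-sided rank-sum p over all label assignments (midranks)."""
    from scipy.stats import rankdata
    import numpy as np

    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n1n2 = n1 * (len(pooled) - n1)
    lo, hi = min(u_obs, n1n2 - u_obs), max(u_obs, n1n2 - u_obs)
    count = 0
    total = 0
    eps = 1e-9
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2
        count += (u <= lo + eps) + (u >= hi - eps)
        total += 1
    return min(count / total, 1.0)


def hypergeom_tail_enumeration(N: int, K: int, n: int, k_obs: int) -> float:
    """P(X >= k_obs) for hypergeometric(N, K, n) by direct summation."""
    total = comb(N, n)
    return sum(comb(K, k) * comb(N - K, n - k) for k in range(k_obs, min(K, n) + 1)) / total
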