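"""Differentially methylated fragment (DMF) calling and cross-pair concordance.

Each fragment testable in a tissue/cell-line pair (coverage filter passed in
both samples) is tested on the 2x2 table of pooled methylated/unmethylated
read counts with a two-sided Fisher exact test. A fragment is a DMF when its
p-value survives a Bonferroni correction over the fragments actually tested
(family-wise significance level ``alpha``, default 0.01) *and* the
methylation difference is at least ``min_diff`` (default 0.25). DMFs called
in two independent pairs are intersected by exact fragment coordinates and
classified by direction concordance.

The two-sided p-value follows the conventional exact definition: the sum of
hypergeometric probabilities of every table with the same margins whose
probability does not exceed the observed table's (a small relative tolerance
makes floating-point ties deterministic).
"""

from __future__ import annotations

import math
import warnings
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "fisher_exact_two_sided",
    "fisher_exact_margin_family",
    "call_dmfs",
    "intersect_common",
    "concordance_summary",
    "write_dmf_table",
    "read_dmf_table",
]

#: relative tolerance used to treat near-equal table probabilities as ties
TIE_RTOL = 1e-7

DMF_COLUMNS = [
    "fragment_id",
    "contig",
    "start",
    "end",
    "M1",
    "U1",
    "M2",
    "U2",
    "level1",
    "level2",
    "diff",
    "p_value",
    "n_tests",
    "p_threshold",
    "significant",
    "direction",
]

HYPER = "hyper_in_cell_line"
HYPO = "hypo_in_cell_line"

BOTH_HYPER = "both_hyper"
BOTH_HYPO = "both_hypo"
DISCORDANT = "discordant"


def _log_pmf(k: np.ndarray, n: int, K: int, draws: int) -> np.ndarray:
    """log hypergeometric pmf for draws from a population of n with K successes."""
    return (
        gammaln(K + 1)
        - gammaln(k + 1)
        - gammaln(K - k + 1)
        + gammaln(n - K + 1)
        - gammaln(draws - k + 1)
        - gammaln(n - K - draws + k + 1)
        - (gammaln(n + 1) - gammaln(draws + 1) - gammaln(n - draws + 1))
    )


def fisher_exact_margin_family(r1: int, r2: int, c1: int) -> np.ndarray:
    """Two-sided Fisher p-values for every table with row margins (r1, r2)
    and first-column margin c1.

    Returns an array indexed by k = M1 over the support
    [max(0, c1-r2), min(c1, r1)]; entry j is the p-value of the table with
    M1 = support_min + j. Shares the tie rule of
    :func:`fisher_exact_two_sided`.
    """
    n = r1 + r2
    k_min = max(0, c1 - r2)
    k_max = min(c1, r1)
    k = np.arange(k_min, k_max + 1)
    pmf = np.exp(_log_pmf(k, n, c1, r1))
    pmf = pmf / pmf.sum()  # renormalise away floating-point drift
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    # p(k) = sum of probabilities <= pmf(k) * (1 + tol)
    idx = np.searchsorted(sorted_pmf, pmf * (1.0 + TIE_RTOL), side="right")
    pvals = np.where(idx > 0, csum[np.maximum(idx - 1, 0)], 0.0)
    pvals = np.where(idx == len(pmf), 1.0, pvals)  # whole support qualifies
    return np.minimum(pvals, 1.0)


def fisher_exact_two_sided(M1: int, U1: int, M2: int, U2: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[M1, U1], [M2, U2]].

    p is the total probability of all tables with the observed margins that
    are no more probable than the observed one (ties compared with relative
    tolerance 1e-7). A degenerate margin (all reads methylated in both
    samples, an empty row, ...) carries no information and returns 1.0.
    """
    if min(M1, U1, M2, U2) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2 = M1 + U1, M2 + U2
    c1, c2 = M1 + M2, U1 + U2
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    pvals = fisher_exact_margin_family(r1, r2, c1)
    k_min = max(0, c1 - r2)
    return float(pvals[M1 - k_min])


def call_dmfs(
    sample_a: pd.DataFrame,
    sample_b: pd.DataFrame,
    alpha: float = 0.01,
    min_diff: float = 0.25,
) -> pd.DataFrame:
    """Test every fragment passing the coverage filter in both samples.

    ``sample_a`` is the reference (tissue) and ``sample_b`` the comparison
    (cell line); ``diff = level_b - level_a`` so positive differences are
    hypermethylation in the cell line. The Bonferroni family size is the
    number of fragments actually tested. Returns one row per tested
    fragment, sorted by coordinates, with ``significant`` true when
    p <= alpha/n_tests and \\|diff\\| >= min_diff.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if not 0 <= min_diff <= 1:
        raise ValueError("min_diff must be in [0, 1]")
    a = sample_a[sample_a["passes_filter"]].set_index("fragment_id")
    b = sample_b[sample_b["passes_filter"]].set_index("fragment_id")
    shared = a.index.intersection(b.index)
    n_tests = len(shared)
    if n_tests == 0:
        warnings.warn("no fragment passes the coverage filter in both samples")
        return pd.DataFrame(columns=DMF_COLUMNS)
    a = a.loc[shared]
    b = b.loc[shared]
    threshold = alpha / n_tests
    rows = []
    for frag_id in shared:
        m1, u1 = int(a.at[frag_id, "pooled_M"]), int(a.at[frag_id, "pooled_U"])
        m2, u2 = int(b.at[frag_id, "pooled_M"]), int(b.at[frag_id, "pooled_U"])
        level1 = m1 / (m1 + u1)
        level2 = m2 / (m2 + u2)
        diff = level2 - level1
        p = fisher_exact_two_sided(m1, u1, m2, u2)
        rows.append(
            (
                frag_id,
                a.at[frag_id, "contig"],
                int(a.at[frag_id, "start"]),
                int(a.at[frag_id, "end"]),
                m1,
                u1,
                m2,
                u2,
                level1,
                level2,
                diff,
                p,
                n_tests,
                threshold,
                bool(p <= threshold and abs(diff) >= min_diff),
                HYPER if diff > 0 else HYPO,
            )
        )
    out = pd.DataFrame(rows, columns=DMF_COLUMNS)
    return out.sort_values(["contig", "start"], ignore_index=True)


def intersect_common(dmfs_pair1: pd.DataFrame, dmfs_pair2: pd.DataFrame) -> pd.DataFrame:
    """Fragments significant in both pairwise comparisons, with concordance.

    Matching is by exact fragment coordinates (all samples are aggregated on
    one MspI catalogue). Symmetric in its arguments up to column naming.
    """
    cols = ["fragment_id", "contig", "start", "end", "diff", "p_value", "direction"]
    if dmfs_pair1.empty or dmfs_pair2.empty:
        return pd.DataFrame(
            columns=["fragment_id", "contig", "start", "end"]
            + [f"{c}_pair1" for c in cols[4:]]
            + [f"{c}_pair2" for c in cols[4:]]
            + ["concordance"]
        )
    sig1 = dmfs_pair1[dmfs_pair1["significant"]][cols]
    sig2 = dmfs_pair2[dmfs_pair2["significant"]][cols]
    common = sig1.merge(
        sig2,
        on=["fragment_id", "contig", "start", "end"],
        suffixes=("_pair1", "_pair2"),
    )
    both_hyper = (common["direction_pair1"] == HYPER) & (common["direction_pair2"] == HYPER)
    both_hypo = (common["direction_pair1"] == HYPO) & (common["direction_pair2"] == HYPO)
    common["concordance"] = np.select(
        [both_hyper, both_hypo], [BOTH_HYPER, BOTH_HYPO], default=DISCORDANT
    )
    return common.sort_values(["contig", "start"], ignore_index=True)


def _round_half_up_1dp(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def concordance_summary(
    common: pd.DataFrame | Mapping[str, int] | Sequence[int],
) -> dict[str, dict[str, float]]:
    """Counts and percentages of direction concordance among common DMFs.

    Accepts a common-DMF table (tallies its ``concordance`` column) or
    pre-tabulated counts as ``(both_hyper, both_hypo, discordant)`` or a
    mapping with those keys. Percentages are 100*count/total rounded
    half-up to one decimal; an empty input yields an all-zero summary.
    """
    if isinstance(common, pd.DataFrame):
        tally = common["concordance"].value_counts() if len(common) else {}
        counts = {k: int(tally.get(k, 0)) for k in (BOTH_HYPER, BOTH_HYPO, DISCORDANT)}
    elif isinstance(common, Mapping):
        counts = {k: int(common.get(k, 0)) for k in (BOTH_HYPER, BOTH_HYPO, DISCORDANT)}
    else:
        hyper, hypo, disc = common
        counts = {BOTH_HYPER: int(hyper), BOTH_HYPO: int(hypo), DISCORDANT: int(disc)}
    total = sum(counts.values())
    summary: dict[str, dict[str, float]] = {"total": {"count": total, "percent": 100.0 if total else 0.0}}
    for key, count in counts.items():
        pct = _round_half_up_1dp(100.0 * count / total) if total else 0.0
        summary[key] = {"count": count, "percent": pct}
    return summary


def write_dmf_table(table: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_dmf_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_dmf_bed(table: pd.DataFrame, path: str | Path) -> None:
    """BED6 export of significant DMFs (score = |diff| in per cent)."""
    sig = table[table["significant"]]
    with open(path, "w") as fh:
        for _, row in sig.iterrows():
            score = int(round(abs(row["diff"]) * 100))
            strand = "+" if row["direction"] == HYPER else "-"
            fh.write(
                f"{row['contig']}\t{row['start']}\t{row['end']}\t"
                f"{row['fragment_id']}\t{score}\t{strand}\n"
            )
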