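"""Per-CpG methylation calls and fragment-level aggregation.

Input is the 6-column Bismark-coverage dialect (chrom, start, end — both
1-based and equal for a single cytosine — methylation %, methylated count,
unmethylated count). CpG methylation is palindromic, so a call on the
reverse-strand cytosine (the G position of the forward-strand CG) is merged
into the forward-strand site by summing counts.

Fragments are then quantified by pooling read counts over all covered CpGs,
and kept for differential analysis only when they carry high-quality
information: at least ``min_cpgs`` distinct CpG sites each with at least
``min_reads`` total reads (defaults 2 and 10).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import GenomeFragment

__all__ = [
    "CpGCall",
    "read_cpg_calls",
    "merge_strands",
    "aggregate",
    "methylation_level",
    "write_fragment_methylation",
    "read_fragment_methylation",
]

logger = logging.getLogger(__name__)

#: column schema of a strand-merged call table
CALL_COLUMNS = ["contig", "pos", "count_M", "count_U"]

#: column schema of a per-sample fragment methylation table
FRAGMENT_COLUMNS = [
    "fragment_id",
    "contig",
    "start",
    "end",
    "n_cpgs_covered",
    "n_qualifying",
    "pooled_M",
    "pooled_U",
    "level",
    "passes_filter",
]


@dataclass(frozen=True)
class CpGCall:
    """One strand-merged CpG site: 0-based forward-strand C position and counts."""

    contig: str
    pos: int
    count_M: int
    count_U: int

    @property
    def depth(self) -> int:
        return self.count_M + self.count_U


def methylation_level(pooled_M: int, pooled_U: int) -> float:
    """Methylated fraction pooled_M / (pooled_M + pooled_U), in [0, 1]."""
    total = pooled_M + pooled_U
    if total <= 0:
        raise ValueError("methylation level undefined for zero total reads")
    return pooled_M / total


def read_cpg_calls(
    path: str | Path,
    genome: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a Bismark-coverage-style call file into a strand-merged table.

    Returns a DataFrame with columns ``contig, pos, count_M, count_U`` where
    ``pos`` is the 0-based forward-strand C of the CpG. When ``genome`` is
    given (contig -> uppercase sequence), reverse-strand calls are folded
    onto the forward strand and calls at non-CpG positions are dropped with
    a warning; a ``n_dropped_non_cpg`` attribute records the QC tally.
    """
    rows: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 tab-separated columns")
            try:
                contig = fields[0]
                pos1 = int(fields[1])
                count_m = int(fields[4])
                count_u = int(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
            if pos1 < 1 or count_m < 0 or count_u < 0:
                raise ValueError(f"{path}:{lineno}: negative count or non-positive position")
            rows.append((contig, pos1 - 1, count_m, count_u))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return merge_strands(calls, genome)


def merge_strands(
    calls: pd.DataFrame, genome: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Fold reverse-strand CpG calls onto the forward-strand C and sum duplicates.

    A call at position p is reassigned to p-1 when the genome shows a CG
    starting at p-1 (p is the G of the site). Idempotent: forward-strand
    positions are left alone. Without a genome only duplicate positions are
    summed.
    """
    n_dropped = 0
    if genome is not None and len(calls):
        pos = calls["pos"].to_numpy().copy()
        keep = np.ones(len(calls), dtype=bool)
        contigs = calls["contig"].to_numpy()
        for i in range(len(calls)):
            seq = genome.get(contigs[i])
            if seq is None:
                keep[i] = False
                continue
            p = pos[i]
            if seq[p : p + 2] == "CG":
                continue
            if p >= 1 and seq[p - 1 : p + 1] == "CG":
                pos[i] = p - 1
            else:
                keep[i] = False
        n_dropped = int((~keep).sum())
        if n_dropped:
            warnings.warn(
                f"dropped {n_dropped} call(s) at non-CpG positions", stacklevel=2
            )
        calls = calls.assign(pos=pos)[keep]
    merged = (
        calls.groupby(["contig", "pos"], as_index=False)[["count_M", "count_U"]]
        .sum()
        .sort_values(["contig", "pos"], ignore_index=True)
    )
    merged.attrs["n_dropped_non_cpg"] = n_dropped
    return merged


def aggregate(
    fragments: Sequence[GenomeFragment],
    calls: pd.DataFrame,
    min_reads: int = 10,
    min_cpgs: int = 2,
) -> pd.DataFrame:
    """Pool strand-merged CpG calls into per-fragment methylation levels.

    Each fragment receives the calls at its catalogued CpG positions. The
    pooled level uses all covered CpGs; ``n_qualifying`` counts CpGs with
    depth >= ``min_reads`` and ``passes_filter`` is true when at least
    ``min_cpgs`` such sites exist. Fragments with no covered CpG are omitted.
    """
    if min_reads < 0 or min_cpgs < 0:
        raise ValueError("min_reads and min_cpgs must be non-negative")
    index_rows = [
        (f.contig, p, i)
        for i, f in enumerate(fragments)
        for p in f.cpg_positions
    ]
    if not index_rows or calls.empty:
        return pd.DataFrame(columns=FRAGMENT_COLUMNS)
    site_index = pd.DataFrame(index_rows, columns=["contig", "pos", "frag_idx"])
    joined = site_index.merge(calls, on=["contig", "pos"], how="inner")
    if joined.empty:
        return pd.DataFrame(columns=FRAGMENT_COLUMNS)
    depth = joined["count_M"] + joined["count_U"]
    covered = joined[depth > 0].copy()
    covered["qualifying"] = (covered["count_M"] + covered["count_U"]) >= min_reads
    grouped = covered.groupby("frag_idx").agg(
        n_cpgs_covered=("pos", "size"),
        n_qualifying=("qualifying", "sum"),
        pooled_M=("count_M", "sum"),
        pooled_U=("count_U", "sum"),
    )
    out_rows = []
    for idx, row in grouped.iterrows():
        f = fragments[idx]
        out_rows.append(
            (
                f.fragment_id,
                f.contig,
                f.start,
                f.end,
                int(row["n_cpgs_covered"]),
                int(row["n_qualifying"]),
                int(row["pooled_M"]),
                int(row["pooled_U"]),
                methylation_level(int(row["pooled_M"]), int(row["pooled_U"])),
                bool(row["n_qualifying"] >= min_cpgs),
            )
        )
    out = pd.DataFrame(out_rows, columns=FRAGMENT_COLUMNS)
    return out.sort_values(["contig", "start"], ignore_index=True)


def write_fragment_methylation(
    table: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_fragment_methylation(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = set(FRAGMENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table
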