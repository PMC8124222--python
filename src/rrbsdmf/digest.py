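"""In-silico MspI digestion of a reference genome.

RRBS libraries are built from MspI-digested, size-selected genomic DNA, so
the natural unit of analysis is the MspI fragment: the interval between two
consecutive C^CGG cleavage sites on a contig. This module finds those
fragments, applies the library size selection, and enumerates the CpG sites
each fragment carries.

Coordinate conventions
----------------------
All intervals are 0-based, half-open. MspI cleaves between the first and
second base of its CCGG recognition site, so a cut site is placed at
``motif_index + 1``: every internal fragment begins with ``CGG`` and ends
with the leading ``C`` of the next site. Terminal pieces (contig start to
the first cut, last cut to the contig end) have only one MspI end and are
excluded, as they are in a real RRBS library.

CpG positions are the forward-strand coordinates of the C of each CG
dinucleotide; the reverse-strand cytosine of the same palindromic site is
merged into this coordinate downstream (see :mod:`rrbsdmf.methylation`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pyfaidx

__all__ = [
    "GenomeFragment",
    "find_cut_positions",
    "digest",
    "size_select",
    "enumerate_cpgs",
    "load_genome",
    "write_fragment_bed",
    "read_fragment_bed",
]

_CCGG = re.compile(r"(?=CCGG)")
_CG = re.compile(r"(?=CG)")


@dataclass(frozen=True)
class GenomeFragment:
    """An MspI fragment: [start, end) on ``contig`` with its CpG sites."""

    contig: str
    start: int
    end: int
    cpg_positions: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment {self.contig}:{self.start}-{self.end}: start must be < end"
            )
        for p in self.cpg_positions:
            if not (self.start <= p < self.end):
                raise ValueError(f"CpG position {p} outside fragment [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def fragment_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


def load_genome(fasta: str | Path | Mapping[str, str]) -> dict[str, str]:
    """Return contig name -> uppercase sequence, from a FASTA path or a mapping."""
    if isinstance(fasta, Mapping):
        return {name: str(seq).upper() for name, seq in fasta.items()}
    fa = pyfaidx.Fasta(str(fasta))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def find_cut_positions(sequence: str) -> list[int]:
    """MspI cut positions in ``sequence``: one base after each CCGG occurrence.

    Matching is case-insensitive and overlap-allowed (in CCGGCCGG both motifs
    cut); ambiguous bases never match.
    """
    return [m.start() + 1 for m in _CCGG.finditer(sequence.upper())]


def enumerate_cpgs(sequence: str, start: int, end: int) -> tuple[int, ...]:
    """Forward-strand CG start positions p with start <= p and p+1 < end.

    A CG whose G falls outside the interval (p == end-1) is excluded: the
    site does not lie wholly within the fragment.
    """
    if start < 0 or end > len(sequence) or start >= end:
        raise ValueError(f"interval [{start},{end}) outside sequence of length {len(sequence)}")
    sub = sequence[start:end].upper()
    return tuple(start + m.start() for m in _CG.finditer(sub) if m.start() + 2 <= end - start)


def digest(genome: Mapping[str, str] | str | Path) -> list[GenomeFragment]:
    """All internal MspI fragments of ``genome``, sorted by contig then start.

    Fragments span consecutive cut positions on the same contig; the two
    terminal pieces of each contig are dropped. Contigs with fewer than two
    CCGG sites therefore yield no fragments.
    """
    seqs = load_genome(genome)
    fragments: list[GenomeFragment] = []
    for contig in sorted(seqs):
        seq = seqs[contig]
        cuts = find_cut_positions(seq)
        for left, right in zip(cuts, cuts[1:]):
            fragments.append(
                GenomeFragment(contig, left, right, enumerate_cpgs(seq, left, right))
            )
    return fragments


def size_select(
    fragments: Iterable[GenomeFragment], min_len: int = 40, max_len: int = 220
) -> list[GenomeFragment]:
    """Keep fragments with min_len <= length <= max_len (inclusive bounds)."""
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) must be <= max_len ({max_len})")
    return [f for f in fragments if min_len <= f.length <= max_len]


def write_fragment_bed(fragments: Iterable[GenomeFragment], path: str | Path) -> None:
    """Write a BED6+1 fragment catalogue (name=id, score=length, col7=n_cpgs)."""
    with open(path, "w") as fh:
        for f in fragments:
            cpgs = ",".join(map(str, f.cpg_positions))
            fh.write(
                f"{f.contig}\t{f.start}\t{f.end}\t{f.fragment_id}\t{f.length}\t.\t"
                f"{f.n_cpgs}\t{cpgs}\n"
            )


def read_fragment_bed(path: str | Path) -> list[GenomeFragment]:
    """Read a catalogue written by :func:`write_fragment_bed`."""
    fragments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected 8 columns, got {len(fields)}")
            cpgs = tuple(int(p) for p in fields[7].split(",") if p)
            fragments.append(GenomeFragment(fields[0], int(fields[1]), int(fields[2]), cpgs))
    return fragments
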