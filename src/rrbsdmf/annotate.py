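"""Genomic-context annotation of fragments and gene-set enrichment.

Every fragment receives exactly one gene context and one CGI context, so
context proportions over any fragment set partition to 100%:

* gene context: ``promoter`` (any overlap with the strand-aware window from
  2 kb upstream to 1 kb downstream of a TSS) > ``junction`` (spans an
  exon-intron boundary) > ``exon`` > ``intron`` > ``intergenic``;
* CGI context: ``core`` (overlaps a CpG island) > ``shore`` (within 2 kb of
  an island) > ``shelf`` (2-4 kb) > ``open_sea``.

The flank widths follow the community convention of 2 kb shores and 2 kb
shelves. Enrichment of a query gene list against a user-supplied GMT library
uses the one-sided hypergeometric tail with Benjamini-Hochberg correction
across sets, with the background restricted to genes the assay can see.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .digest import GenomeFragment

__all__ = [
    "GeneModel",
    "read_gene_models",
    "read_bed_intervals",
    "promoter_interval",
    "classify_gene_context",
    "classify_cgi_context",
    "annotate_fragments",
    "overlap_features",
    "genes_for_common_dmfs",
    "enrich_gene_set",
    "read_gmt",
]

PROMOTER_UP = 2000
PROMOTER_DOWN = 1000
SHORE_BP = 2000
SHELF_BP = 4000

GENE_CONTEXTS = ("promoter", "junction", "exon", "intron", "intergenic")
CGI_CONTEXTS = ("core", "shore", "shelf", "open_sea")


@dataclass(frozen=True)
class GeneModel:
    """A gene: span [start, end) on contig, strand, and merged exons."""

    name: str
    contig: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.name}: strand must be + or -")
        if self.start >= self.end:
            raise ValueError(f"gene {self.name}: empty span")

    @property
    def tss(self) -> int:
        """0-based transcription start site (span start on +, end-1 on -)."""
        return self.start if self.strand == "+" else self.end - 1


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def read_gene_models(gtf_path: str | Path) -> list[GeneModel]:
    """Load gene models from a GTF with gene and exon features.

    Gene names come from the ``gene_name`` attribute, falling back to
    ``gene_id``. Exons of all transcripts of a gene are merged.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    genes = []
    for gene in db.features_of_type("gene"):
        name = (gene.attributes.get("gene_name") or gene.attributes.get("gene_id"))[0]
        exons = [
            (exon.start - 1, exon.end)  # GTF is 1-based inclusive
            for exon in db.children(gene, featuretype="exon")
        ]
        genes.append(
            GeneModel(
                name=name,
                contig=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                exons=_merge_intervals(exons),
            )
        )
    return genes


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file (0-based half-open) into contig/start/end rows."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
            rows.append((fields[0], start, end))
    return (
        pd.DataFrame(rows, columns=["contig", "start", "end"])
        .sort_values(["contig", "start"], ignore_index=True)
    )


def promoter_interval(gene: GeneModel, contig_length: int | None = None) -> tuple[int, int]:
    """Strand-aware promoter window: 2 kb upstream to 1 kb downstream of the TSS.

    On + the window is [TSS-2000, TSS+1000); on - it is the mirror image
    [TSS-999, TSS+2001). Clipped at contig bounds.
    """
    if gene.strand == "+":
        start, end = gene.tss - PROMOTER_UP, gene.tss + PROMOTER_DOWN
    else:
        start, end = gene.tss - (PROMOTER_DOWN - 1), gene.tss + PROMOTER_UP + 1
    start = max(start, 0)
    if contig_length is not None:
        end = min(end, contig_length)
    return start, end


def _introns(gene: GeneModel) -> tuple[tuple[int, int], ...]:
    out = []
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        if e1 < s2:
            out.append((e1, s2))
    return tuple(out)


def _exon_intron_boundaries(gene: GeneModel) -> tuple[int, ...]:
    """Interior exon edges of a gene — the exon/intron junction coordinates."""
    bounds = []
    for s, e in gene.exons:
        if s > gene.start:
            bounds.append(s)
        if e < gene.end:
            bounds.append(e)
    return tuple(sorted(set(bounds)))


class _GeneIndex:
    """Interval trees over promoters, junctions, exons and gene spans."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.promoters: dict[str, IntervalTree] = {}
        self.exons: dict[str, IntervalTree] = {}
        self.introns: dict[str, IntervalTree] = {}
        self.spans: dict[str, IntervalTree] = {}
        self.boundaries: dict[str, list[tuple[int, GeneModel]]] = {}
        for g in genes:
            ps, pe = promoter_interval(g)
            if ps < pe:
                self.promoters.setdefault(g.contig, IntervalTree()).addi(ps, pe, g)
            for s, e in g.exons:
                self.exons.setdefault(g.contig, IntervalTree()).addi(s, e, g)
            for s, e in _introns(g):
                self.introns.setdefault(g.contig, IntervalTree()).addi(s, e, g)
            self.spans.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g)
            for b in _exon_intron_boundaries(g):
                self.boundaries.setdefault(g.contig, []).append((b, g))


def _closest_gene(candidates: Iterable[GeneModel], start: int, end: int) -> GeneModel:
    def key(g: GeneModel) -> tuple[int, str]:
        mid = (start + end) // 2
        return (abs(g.tss - mid), g.name)

    return min(candidates, key=key)


def classify_gene_context(
    fragment: GenomeFragment, genes: Sequence[GeneModel] | _GeneIndex
) -> tuple[str, str | None]:
    """Gene context of a fragment with precedence
    promoter > junction > exon > intron > intergenic, and the assigned gene.

    Any 1 bp overlap counts. Junction means the fragment spans an
    exon-intron boundary of a single gene. Ties between genes offering the
    same context break by TSS distance, then gene name.
    """
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(genes)
    s, e, contig = fragment.start, fragment.end, fragment.contig

    hits = index.promoters.get(contig, IntervalTree()).overlap(s, e)
    if hits:
        gene = _closest_gene((h.data for h in hits), s, e)
        return "promoter", gene.name
    junction_genes = {
        g for b, g in index.boundaries.get(contig, []) if s < b < e
    }
    if junction_genes:
        gene = _closest_gene(junction_genes, s, e)
        return "junction", gene.name
    hits = index.exons.get(contig, IntervalTree()).overlap(s, e)
    if hits:
        gene = _closest_gene((h.data for h in hits), s, e)
        return "exon", gene.name
    hits = index.introns.get(contig, IntervalTree()).overlap(s, e)
    if hits:
        gene = _closest_gene((h.data for h in hits), s, e)
        return "intron", gene.name
    return "intergenic", None


def classify_cgi_context(
    fragment: GenomeFragment, islands: pd.DataFrame
) -> str:
    """CGI context: core > shore (<=2 kb) > shelf (2-4 kb) > open_sea.

    ``islands`` is a BED-like frame of merged island intervals.
    """
    contig_islands = islands[islands["contig"] == fragment.contig]
    s, e = fragment.start, fragment.end
    starts = contig_islands["start"].to_numpy()
    ends = contig_islands["end"].to_numpy()
    if len(starts) == 0:
        return "open_sea"

    def overlaps(flank: int) -> bool:
        return bool(np.any((starts - flank < e) & (ends + flank > s)))

    if overlaps(0):
        return "core"
    if overlaps(SHORE_BP):
        return "shore"
    if overlaps(SHELF_BP):
        return "shelf"
    return "open_sea"


def annotate_fragments(
    fragments: Sequence[GenomeFragment],
    genes: Sequence[GeneModel],
    islands: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-fragment gene and CGI context table."""
    index = _GeneIndex(genes)
    merged_islands = None
    if islands is not None and len(islands):
        rows = []
        for contig, sub in islands.groupby("contig"):
            for s, e in _merge_intervals(zip(sub["start"], sub["end"])):
                rows.append((contig, s, e))
        merged_islands = pd.DataFrame(rows, columns=["contig", "start", "end"])
    out = []
    for f in fragments:
        gene_context, gene = classify_gene_context(f, index)
        cgi_context = (
            classify_cgi_context(f, merged_islands) if merged_islands is not None else "open_sea"
        )
        out.append((f.fragment_id, f.contig, f.start, f.end, gene_context, gene, cgi_context))
    return pd.DataFrame(
        out,
        columns=["fragment_id", "contig", "start", "end", "gene_context", "gene", "cgi_context"],
    )


def overlap_features(
    fragments: Sequence[GenomeFragment], features: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Per-fragment any-overlap flag against a BED feature set, plus the
    fraction of fragments overlapping."""
    flags = []
    by_contig = {c: sub for c, sub in features.groupby("contig")}
    for f in fragments:
        sub = by_contig.get(f.contig)
        if sub is None:
            flags.append(False)
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        flags.append(bool(np.any((starts < f.end) & (ends > f.start))))
    series = pd.Series(flags, index=[f.fragment_id for f in fragments], name="overlaps")
    fraction = float(series.mean()) if len(series) else 0.0
    return series, fraction


def genes_for_common_dmfs(
    common: pd.DataFrame, annotations: pd.DataFrame
) -> dict[str, set[str]]:
    """Distinct genes behind promoter-context and gene-body-context common DMFs.

    Body context = exon, intron or junction. Returns ``promoter``, ``body``
    and their intersection ``both``.
    """
    if common.empty:
        return {"promoter": set(), "body": set(), "both": set()}
    annot = annotations.set_index("fragment_id")
    rows = annot.loc[annot.index.intersection(common["fragment_id"])]
    with_gene = rows[rows["gene"].notna()]
    promoter = set(with_gene[with_gene["gene_context"] == "promoter"]["gene"])
    body = set(
        with_gene[with_gene["gene_context"].isin(["exon", "intron", "junction"])]["gene"]
    )
    return {"promoter": promoter, "body": body, "both": promoter & body}


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set library: name <tab> description <tab> genes..."""
    library = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields")
            library[fields[0]] = {g for g in fields[2:] if g}
    return library


def enrich_gene_set(
    query: Iterable[str],
    background: Iterable[str],
    library: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each library set.

    The test population is ``background`` (the genes the assay could have
    reported); each set is intersected with the background first. Per set,
    p = P(X >= overlap) for X hypergeometric(N=|background|,
    K=|set ∩ background|, n=|query|); Benjamini-Hochberg across sets.
    """
    background = set(background)
    if not background:
        raise ValueError("background gene set is empty")
    query = set(query)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    names, pvals, overlaps, set_sizes = [], [], [], []
    for name, genes in library.items():
        in_bg = set(genes) & background
        overlap = in_bg & query
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, len(background), len(in_bg), len(query))) if in_bg else 1.0
        names.append(name)
        pvals.append(min(p, 1.0))
        overlaps.append(",".join(sorted(overlap)))
        set_sizes.append(len(in_bg))
    if not names:
        return pd.DataFrame(
            columns=["set", "set_size", "overlap_size", "p_value", "p_adjusted", "overlap_genes"]
        )
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "set": names,
            "set_size": set_sizes,
            "overlap_size": [len(o.split(",")) if o else 0 for o in overlaps],
            "p_value": pvals,
            "p_adjusted": p_adj,
            "overlap_genes": overlaps,
        }
    )
    return out.sort_values("p_value", ignore_index=True)
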