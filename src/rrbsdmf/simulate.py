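"""Synthetic paired tissue/cell-line RRBS count data with planted DMFs.

The generator builds a toy genome whose MspI fragment structure is known by
construction, together with gene models, CpG islands, and per-CpG
methylation count files for paired tumour-tissue and derived-cell-line
samples. A chosen set of fragments is "planted" with a methylation shift in
the cell-line sample (mostly upward, mirroring the hypermethylation bias of
cultured lines); everything else is an exact null, so sensitivity and
family-wise error of the downstream caller can be measured against the
emitted truth table.

Model
-----
* Fragment true methylation is drawn from a two-component beta mixture
  (a low and a high mode), reproducing the bimodal fragment-level
  methylation distribution of real RRBS methylomes.
* Per-CpG read depth is negative binomial (mean ``coverage_mean``,
  dispersion ``coverage_dispersion``; Poisson as dispersion → ∞), matching
  overdispersed RRBS coverage.
* Per-CpG methylated counts are binomial(depth, fragment level): CpGs of a
  fragment share one true level, the simplest structure that exercises
  count pooling at the analysis unit.
* Planted fragments shift the cell-line level by ±``planted_delta``; their
  base level is drawn from the mixture mode compatible with the shift
  direction, rescaled into the feasible range so the full shift never
  leaves [0, 1] (clipping is kept as a guard and the truth table records
  post-clip levels).

All randomness flows from ``config.seed`` through named substreams, so
identical configurations give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .digest import GenomeFragment, digest, size_select

__all__ = ["SimulationConfig", "GenomeArtifacts", "generate_genome", "simulate_pair", "simulate_study"]

TRUTH_COLUMNS = [
    "fragment_id",
    "contig",
    "start",
    "end",
    "pair_id",
    "true_tissue_level",
    "true_cell_line_level",
    "direction",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions the pipeline is meant to exercise:
    two tissue/cell-line pairs, 2000 size-selected fragments, 200 planted
    DMFs shared by both pairs, a 0.5 methylation shift with 88% of planted
    fragments hypermethylated in the cell line, and ~30x per-CpG coverage.
    """

    seed: int = 0
    n_contigs: int = 4
    contig_length: int = 150_000
    n_fragments: int = 2000
    fragment_length_range: tuple[int, int] = (60, 200)
    oversize_length_range: tuple[int, int] = (250, 600)
    cpg_density: tuple[int, int] = (3, 8)
    beta_mixture: tuple[float, float, float, float, float] = (1.0, 9.0, 9.0, 1.0, 0.45)
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0
    n_planted_dmf: int = 200
    planted_delta: float = 0.5
    planted_hyper_fraction: float = 0.88
    n_pairs: int = 2
    shared_planted_fraction: float = 1.0
    global_shift: float = 0.0
    n_genes_per_contig: int = 25
    n_islands_per_contig: int = 20

    def __post_init__(self) -> None:
        for name in ("planted_hyper_fraction", "shared_planted_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.planted_delta < 0 or self.planted_delta > 1:
            raise ValueError("planted_delta must be in [0, 1]")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage_mean and coverage_dispersion must be positive")
        if self.n_planted_dmf > self.n_fragments:
            raise ValueError("n_planted_dmf cannot exceed the number of size-selected fragments")
        if self.n_pairs < 1 or self.n_contigs < 1 or self.n_fragments < 0:
            raise ValueError("n_pairs, n_contigs must be >= 1 and n_fragments >= 0")
        lo, hi = self.fragment_length_range
        if not (40 <= lo <= hi <= 220):
            raise ValueError("fragment_length_range must lie within the 40-220 bp size selection")
        olo, ohi = self.oversize_length_range
        if not (220 < olo <= ohi):
            raise ValueError("oversize_length_range must exceed 220 bp")
        dlo, dhi = self.cpg_density
        if not (0 <= dlo <= dhi):
            raise ValueError("cpg_density must satisfy 0 <= lo <= hi")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        for key in ("fragment_length_range", "oversize_length_range", "cpg_density", "beta_mixture"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GenomeArtifacts:
    """Everything generate_genome produces, in memory."""

    config: SimulationConfig
    sequences: dict[str, str]
    fragments: list[GenomeFragment]  # size-selected analysis catalogue
    genes: pd.DataFrame  # gene_name, contig, start, end, strand, exon list
    islands: pd.DataFrame  # contig, start, end
    planted: pd.DataFrame  # fragment_id, pair ids, direction, shared flag


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *stream)))


def _random_at(rng: np.random.Generator, n: int) -> str:
    """Filler sequence of A/T only: creates no CG and no CCGG."""
    return "".join(np.array(["A", "T"])[rng.integers(0, 2, n)])


def _fragment_interior(rng: np.random.Generator, length: int, n_extra_cpgs: int) -> str:
    """Interior of a fragment between two CCGG motifs (length = frag_len - 4).

    Places ``n_extra_cpgs`` CG dinucleotides separated by A/T filler. The
    fragment will additionally carry the CpG created at its start by the
    leading C^CGG overhang.
    """
    interior_len = length - 4
    n_extra_cpgs = min(n_extra_cpgs, max(interior_len - 1, 0) // 3)
    if n_extra_cpgs == 0:
        return _random_at(rng, interior_len)
    # choose CG start offsets, each >=1 apart from the next with one spacer base
    free = interior_len - 2 * n_extra_cpgs
    gaps = rng.multinomial(free - (n_extra_cpgs + 1), [1.0 / (n_extra_cpgs + 1)] * (n_extra_cpgs + 1))
    gaps = gaps + 1  # at least one A/T between, before and after the CGs
    parts = [_random_at(rng, int(gaps[0]))]
    for i in range(n_extra_cpgs):
        parts.append("CG")
        parts.append(_random_at(rng, int(gaps[i + 1])))
    return "".join(parts)


def generate_genome(config: SimulationConfig) -> GenomeArtifacts:
    """Build the toy genome, fragment catalogue, gene models and CGIs.

    Fragments are laid out as chains of CCGG-delimited intervals whose
    lengths are drawn uniformly from ``fragment_length_range`` (hence all
    within the 40-220 bp size selection); chains are separated by long A/T
    runs that become oversize fragments, exercising size selection.
    Raises if ``contig_length`` cannot host the requested fragments.
    """
    rng = _rng(config.seed, 0)
    per_contig = [config.n_fragments // config.n_contigs] * config.n_contigs
    for i in range(config.n_fragments % config.n_contigs):
        per_contig[i] += 1

    sequences: dict[str, str] = {}
    for ci in range(config.n_contigs):
        contig = f"chr{ci + 1}"
        n_frags = per_contig[ci]
        parts = [_random_at(rng, int(rng.integers(100, 200)))]
        used = len(parts[0])
        placed = 0
        while placed < n_frags:
            chain_len = int(min(rng.integers(10, 30), n_frags - placed))
            parts.append("CCGG")
            used += 4
            for _ in range(chain_len):
                flen = int(rng.integers(config.fragment_length_range[0], config.fragment_length_range[1] + 1))
                n_cpg = int(rng.integers(config.cpg_density[0], config.cpg_density[1] + 1))
                interior = _fragment_interior(rng, flen, n_cpg)
                parts.append(interior + "CCGG")
                used += flen
                placed += 1
            if placed < n_frags:
                # inter-chain A/T spacer: bracketed by this chain's last CCGG
                # and the next chain's first, it becomes an oversize fragment
                # that size selection must drop
                spacer = int(
                    rng.integers(
                        config.oversize_length_range[0] - 4,
                        config.oversize_length_range[1] - 3,
                    )
                )
                parts.append(_random_at(rng, spacer))
                used += spacer
        tail = _random_at(rng, int(rng.integers(100, 200)))
        parts.append(tail)
        used += len(tail)
        if used > config.contig_length:
            raise ValueError(
                f"contig_length {config.contig_length} too small: contig {contig} "
                f"needs {used} bp for {n_frags} fragments"
            )
        parts.append(_random_at(rng, config.contig_length - used))
        sequences[contig] = "".join(parts)
        assert len(sequences[contig]) == config.contig_length

    all_fragments = digest(sequences)
    catalogue = size_select(all_fragments, 40, 220)
    if config.n_fragments and len(catalogue) != config.n_fragments:
        raise AssertionError(
            f"generator bookkeeping error: requested {config.n_fragments} in-window "
            f"fragments, digestion recovered {len(catalogue)}"
        )

    genes = _generate_genes(config, rng)
    islands = _generate_islands(config, rng, catalogue)
    planted = _choose_planted(config, catalogue)
    return GenomeArtifacts(config, sequences, catalogue, genes, islands, planted)


def _generate_genes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    gid = 0
    for ci in range(config.n_contigs):
        contig = f"chr{ci + 1}"
        for _ in range(config.n_genes_per_contig):
            span = int(rng.integers(3000, 12000))
            start = int(rng.integers(0, max(config.contig_length - span, 1)))
            end = start + span
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 6))
            edges = np.sort(rng.choice(np.arange(1, span), size=2 * n_exons - 2, replace=False))
            bounds = np.concatenate([[0], edges, [span]])
            exons = [
                (start + int(bounds[2 * i]), start + int(bounds[2 * i + 1]))
                for i in range(n_exons)
            ]
            gid += 1
            rows.append((f"GENE{gid:04d}", contig, start, end, strand, exons))
    return pd.DataFrame(rows, columns=["gene_name", "contig", "start", "end", "strand", "exons"])


def _generate_islands(
    config: SimulationConfig, rng: np.random.Generator, catalogue: list[GenomeFragment]
) -> pd.DataFrame:
    """CGI intervals anchored on a subset of fragments (CpG-dense by design),
    merged to disjointness."""
    rows = []
    by_contig: dict[str, list[GenomeFragment]] = {}
    for f in catalogue:
        by_contig.setdefault(f.contig, []).append(f)
    for ci in range(config.n_contigs):
        contig = f"chr{ci + 1}"
        frags = by_contig.get(contig, [])
        n = min(config.n_islands_per_contig, len(frags))
        if n == 0:
            continue
        chosen = rng.choice(len(frags), size=n, replace=False)
        intervals = []
        for idx in chosen:
            f = frags[int(idx)]
            pad = int(rng.integers(100, 600))
            intervals.append((max(f.start - pad, 0), min(f.end + pad, config.contig_length)))
        merged: list[list[int]] = []
        for s, e in sorted(intervals):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        rows.extend((contig, s, e) for s, e in merged)
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def _choose_planted(config: SimulationConfig, catalogue: list[GenomeFragment]) -> pd.DataFrame:
    """Assign planted fragments and directions, per pair.

    Only fragments with at least 2 CpGs are eligible (they can pass the
    coverage filter in expectation). A ``shared_planted_fraction`` of the
    planted set, with its directions, is common to all pairs; the remainder
    is drawn per pair.
    """
    rng = _rng(config.seed, 1)
    eligible = [i for i, f in enumerate(catalogue) if f.n_cpgs >= 2]
    if config.n_planted_dmf > len(eligible):
        raise ValueError("not enough eligible fragments to plant the requested DMFs")
    n_shared = int(round(config.shared_planted_fraction * config.n_planted_dmf))
    rows = []
    shared_idx = rng.choice(eligible, size=n_shared, replace=False) if n_shared else np.array([], dtype=int)
    shared_hyper = rng.random(n_shared) < config.planted_hyper_fraction
    remaining = sorted(set(eligible) - set(int(i) for i in shared_idx))
    for pair_id in range(1, config.n_pairs + 1):
        pair_rng = _rng(config.seed, 1, pair_id)
        n_own = config.n_planted_dmf - n_shared
        own_idx = (
            pair_rng.choice(remaining, size=n_own, replace=False) if n_own else np.array([], dtype=int)
        )
        own_hyper = pair_rng.random(n_own) < config.planted_hyper_fraction
        for idx, hyper, shared in (
            [(int(i), bool(h), True) for i, h in zip(shared_idx, shared_hyper)]
            + [(int(i), bool(h), False) for i, h in zip(own_idx, own_hyper)]
        ):
            f = catalogue[idx]
            rows.append((f.fragment_id, pair_id, "hyper" if hyper else "hypo", shared))
    return pd.DataFrame(rows, columns=["fragment_id", "pair_id", "direction", "shared"])


def _mixture_levels(rng: np.random.Generator, n: int, mixture: tuple[float, float, float, float, float]) -> np.ndarray:
    a_lo, b_lo, a_hi, b_hi, w_hi = mixture
    high = rng.random(n) < w_hi
    levels = np.where(high, rng.beta(a_hi, b_hi, n), rng.beta(a_lo, b_lo, n))
    return levels


def simulate_pair(
    artifacts: GenomeArtifacts, pair_id: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one tissue/cell-line pair.

    Returns (tissue_calls, cell_line_calls, truth_table). Call tables use
    the strand-merged schema of :mod:`rrbsdmf.methylation` (contig, pos,
    count_M, count_U). The truth table lists every planted fragment of this
    pair with its true levels and direction.
    """
    config = artifacts.config
    catalogue = artifacts.fragments
    rng_levels = _rng(config.seed, 2, pair_id)
    n = len(catalogue)
    tissue_levels = _mixture_levels(rng_levels, n, config.beta_mixture)

    planted = artifacts.planted
    mine = planted[planted["pair_id"] == pair_id]
    id_to_idx = {f.fragment_id: i for i, f in enumerate(catalogue)}
    delta = config.planted_delta
    a_lo, b_lo, a_hi, b_hi, _ = config.beta_mixture

    cell_levels = tissue_levels.copy()
    if config.global_shift:
        cell_levels = np.clip(cell_levels + config.global_shift, 0.0, 1.0)
    truth_rows = []
    for _, row in mine.iterrows():
        idx = id_to_idx[row["fragment_id"]]
        f = catalogue[idx]
        if row["direction"] == "hyper":
            # base drawn from the low mode, rescaled so the +delta shift fits
            base = float(rng_levels.beta(a_lo, b_lo)) * (1.0 - delta)
            shifted = base + delta
        else:
            base = delta + float(rng_levels.beta(a_hi, b_hi)) * (1.0 - delta)
            shifted = base - delta
        tissue_levels[idx] = base
        cell_levels[idx] = float(np.clip(shifted, 0.0, 1.0))
        truth_rows.append(
            (
                f.fragment_id,
                f.contig,
                f.start,
                f.end,
                pair_id,
                tissue_levels[idx],
                cell_levels[idx],
                "hyper" if row["direction"] == "hyper" else "hypo",
            )
        )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS).sort_values(
        ["contig", "start"], ignore_index=True
    )

    tissue_calls = _draw_counts(artifacts, tissue_levels, _rng(config.seed, 3, pair_id, 0))
    cell_calls = _draw_counts(artifacts, cell_levels, _rng(config.seed, 3, pair_id, 1))
    return tissue_calls, cell_calls, truth


def _draw_counts(
    artifacts: GenomeArtifacts, levels: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    config = artifacts.config
    contigs, positions, frag_idx = [], [], []
    for i, f in enumerate(artifacts.fragments):
        for p in f.cpg_positions:
            contigs.append(f.contig)
            positions.append(p)
            frag_idx.append(i)
    frag_idx = np.asarray(frag_idx)
    n_sites = len(positions)
    k = config.coverage_dispersion
    p_nb = k / (k + config.coverage_mean)
    depth = rng.negative_binomial(k, p_nb, n_sites)
    meth = rng.binomial(depth, levels[frag_idx])
    calls = pd.DataFrame(
        {
            "contig": contigs,
            "pos": positions,
            "count_M": meth,
            "count_U": depth - meth,
        }
    )
    return calls.sort_values(["contig", "pos"], ignore_index=True)


# ---------------------------------------------------------------------------
# file output


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_coverage_file(calls: pd.DataFrame, path: str | Path) -> None:
    """Bismark-coverage dialect: chrom, pos, pos (1-based), meth %, count_M, count_U."""
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            total = row.count_M + row.count_U
            pct = 100.0 * row.count_M / total if total else 0.0
            fh.write(
                f"{row.contig}\t{row.pos + 1}\t{row.pos + 1}\t{pct:.6g}\t{row.count_M}\t{row.count_U}\n"
            )


def write_gtf(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            attrs = f'gene_id "{row.gene_name}"; gene_name "{row.gene_name}";'
            fh.write(
                f"{row.contig}\tsim\tgene\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )
            for i, (es, ee) in enumerate(row.exons, 1):
                fh.write(
                    f"{row.contig}\tsim\texon\t{es + 1}\t{ee}\t.\t{row.strand}\t.\t"
                    f'{attrs} exon_number "{i}";\n'
                )


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.start}\t{row.end}\n")


def simulate_study(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full synthetic study on disk.

    Writes genome.fa, genes.gtf, cgi.bed, per-sample coverage files
    (pair<k>_tissue.cov / pair<k>_cell_line.cov), truth.tsv and a config
    echo, and returns the path of every artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = generate_genome(config)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_fasta(artifacts.sequences, paths["genome"])
    paths["genes"] = outdir / "genes.gtf"
    write_gtf(artifacts.genes, paths["genes"])
    paths["cgi"] = outdir / "cgi.bed"
    write_bed(artifacts.islands, paths["cgi"])

    truths = []
    for pair_id in range(1, config.n_pairs + 1):
        tissue, cell, truth = simulate_pair(artifacts, pair_id)
        t_path = outdir / f"pair{pair_id}_tissue.cov"
        c_path = outdir / f"pair{pair_id}_cell_line.cov"
        write_coverage_file(tissue, t_path)
        write_coverage_file(cell, c_path)
        paths[f"pair{pair_id}_tissue"] = t_path
        paths[f"pair{pair_id}_cell_line"] = c_path
        truths.append(truth)
    paths["truth"] = outdir / "truth.tsv"
    pd.concat(truths, ignore_index=True).to_csv(paths["truth"], sep="\t", index=False)
    paths["config"] = outdir / "config.json"
    paths["config"].write_text(config.to_json() + "\n")
    return paths
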