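"""End-to-end orchestration: simulate/ingest → digest → aggregate → DMF →
common → annotate → summarize, with a reproducible run configuration.

Every tabular output carries comment-line headers recording the tool
version, a hash of the run configuration, and checksums of the inputs, so a
run can be audited after the fact. All randomness flows from the single
config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import annotate_fragments, read_bed_intervals, read_gene_models
from .diffmeth import call_dmfs, concordance_summary, intersect_common, write_dmf_table
from .digest import digest, load_genome, size_select, write_fragment_bed
from .methylation import aggregate, read_cpg_calls, write_fragment_methylation
from .simulate import SimulationConfig, simulate_study
from .summarize import (
    build_matrix,
    cluster_samples,
    dendrogram_newick,
    methylation_histogram,
    pairwise_correlation,
    run_report,
    write_report,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    When ``simulate`` is true the synthetic study is generated into
    ``outdir/sim`` and its outputs become the run inputs; otherwise
    ``genome``, ``calls`` and ``pairs`` must point at existing files.
    ``pairs`` maps pair names to (tissue_sample, cell_line_sample) names,
    and ``calls`` maps sample names to coverage-file paths.
    """

    outdir: str
    seed: int = 0
    simulate: bool = True
    sim: SimulationConfig | None = None
    genome: str | None = None
    calls: dict[str, str] = field(default_factory=dict)
    pairs: dict[str, tuple[str, str]] = field(default_factory=dict)
    gtf: str | None = None
    cgi: str | None = None
    min_fragment_len: int = 40
    max_fragment_len: int = 220
    min_reads: int = 10
    min_cpgs: int = 2
    alpha: float = 0.01
    min_diff: float = 0.25
    n_bins: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 <= self.min_diff <= 1):
            raise ValueError("min_diff must be in [0, 1]")
        if self.min_fragment_len > self.max_fragment_len:
            raise ValueError("min_fragment_len must be <= max_fragment_len")
        if self.min_reads < 0 or self.min_cpgs < 0 or self.n_bins < 1:
            raise ValueError("min_reads/min_cpgs must be >= 0 and n_bins >= 1")

    def to_json(self) -> str:
        raw = dataclasses.asdict(self)
        return json.dumps(raw, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        if raw.get("sim") is not None:
            sim = dict(raw["sim"])
            for key in ("fragment_length_range", "oversize_length_range", "cpg_density", "beta_mixture"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["sim"] = SimulationConfig(**sim)
        if raw.get("pairs"):
            raw["pairs"] = {k: tuple(v) for k, v in raw["pairs"].items()}
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters only: file locations do not
        change the analysis, and input content is checksummed separately."""
        raw = dataclasses.asdict(self)
        for path_field in ("outdir", "genome", "gtf", "cgi"):
            raw.pop(path_field, None)
        raw["calls"] = sorted(raw.get("calls") or {})
        return hashlib.sha256(json.dumps(raw, sort_keys=True).encode()).hexdigest()[:12]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _headers(config: RunConfig, inputs: dict[str, Path]) -> list[str]:
    lines = [f"rrbsdmf_version={__version__}", f"config_hash={config.config_hash()}"]
    lines += [f"input_{name}={path.name} sha256={_checksum(path)}" for name, path in inputs.items()]
    return lines


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and return the run report.

    Writes all stage outputs under ``config.outdir``. On failure an
    ``.incomplete`` marker naming the failed stage is left in the output
    directory and the exception propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / ".incomplete"
    stage = "setup"
    try:
        marker.write_text(stage + "\n")

        if config.simulate:
            stage = "simulate"
            marker.write_text(stage + "\n")
            sim = config.sim or SimulationConfig(seed=config.seed)
            if sim.seed != config.seed:
                sim = dataclasses.replace(sim, seed=config.seed)
            sim_paths = simulate_study(sim, outdir / "sim")
            genome_path = sim_paths["genome"]
            gtf_path = sim_paths["genes"]
            cgi_path = sim_paths["cgi"]
            calls_paths = {
                f"pair{k}_{role}": sim_paths[f"pair{k}_{role}"]
                for k in range(1, sim.n_pairs + 1)
                for role in ("tissue", "cell_line")
            }
            pairs = {
                f"pair{k}": (f"pair{k}_tissue", f"pair{k}_cell_line")
                for k in range(1, sim.n_pairs + 1)
            }
        else:
            if config.genome is None or not config.calls or not config.pairs:
                raise ValueError("non-simulated runs need genome, calls and pairs")
            genome_path = Path(config.genome)
            gtf_path = Path(config.gtf) if config.gtf else None
            cgi_path = Path(config.cgi) if config.cgi else None
            calls_paths = {name: Path(p) for name, p in config.calls.items()}
            pairs = dict(config.pairs)
            for name, p in calls_paths.items():
                if not p.exists():
                    raise FileNotFoundError(f"calls file for sample {name!r} not found: {p}")
            if not genome_path.exists():
                raise FileNotFoundError(f"genome FASTA not found: {genome_path}")

        inputs = {"genome": genome_path, **calls_paths}
        headers = _headers(config, inputs)

        stage = "digest"
        marker.write_text(stage + "\n")
        logger.info("digesting %s", genome_path)
        genome = load_genome(genome_path)
        fragments = size_select(
            digest(genome), config.min_fragment_len, config.max_fragment_len
        )
        write_fragment_bed(fragments, outdir / "fragments.bed")

        stage = "aggregate"
        marker.write_text(stage + "\n")
        sample_tables: dict[str, pd.DataFrame] = {}
        for name, path in calls_paths.items():
            calls = read_cpg_calls(path, genome)
            table = aggregate(fragments, calls, config.min_reads, config.min_cpgs)
            sample_tables[name] = table
            write_fragment_methylation(table, outdir / f"{name}.frag.tsv", headers)

        stage = "dmf"
        marker.write_text(stage + "\n")
        dmf_tables: dict[str, pd.DataFrame] = {}
        for pair_name, (tissue, cell) in pairs.items():
            dmfs = call_dmfs(
                sample_tables[tissue], sample_tables[cell], config.alpha, config.min_diff
            )
            dmf_tables[pair_name] = dmfs
            write_dmf_table(dmfs, outdir / f"{pair_name}.dmf.tsv", headers)

        stage = "common"
        marker.write_text(stage + "\n")
        pair_names = list(pairs)
        common = None
        concordance = None
        if len(pair_names) >= 2:
            common = intersect_common(dmf_tables[pair_names[0]], dmf_tables[pair_names[1]])
            for extra_pair in pair_names[2:]:
                sig = dmf_tables[extra_pair]
                common = common[
                    common["fragment_id"].isin(sig.loc[sig["significant"], "fragment_id"])
                ].reset_index(drop=True)
            write_dmf_table(common, outdir / "common.dmf.tsv", headers)
            concordance = concordance_summary(common)

        stage = "annotate"
        marker.write_text(stage + "\n")
        annotations = None
        if gtf_path is not None:
            genes = read_gene_models(gtf_path)
            islands = read_bed_intervals(cgi_path) if cgi_path else None
            annotations = annotate_fragments(fragments, genes, islands)
            write_fragment_methylation(annotations, outdir / "annotations.tsv", headers)

        stage = "summarize"
        marker.write_text(stage + "\n")
        correlations = {}
        for pair_name, (tissue, cell) in pairs.items():
            try:
                correlations[pair_name] = pairwise_correlation(
                    sample_tables[tissue], sample_tables[cell]
                )
            except ValueError as exc:
                logger.warning("correlation for %s unavailable: %s", pair_name, exc)
        histograms = {
            name: methylation_histogram(
                tab.loc[tab["passes_filter"], "level"], config.n_bins
            ).tolist()
            for name, tab in sample_tables.items()
        }
        newick = None
        if len(sample_tables) >= 2:
            try:
                matrix = build_matrix(sample_tables)
                link = cluster_samples(matrix)
                newick = dendrogram_newick(link, sorted(matrix.columns))
                (outdir / "dendrogram.nwk").write_text(newick + "\n")
                matrix.to_csv(outdir / "matrix.tsv", sep="\t")
            except ValueError as exc:
                logger.warning("clustering unavailable: %s", exc)

        report = run_report(
            sample_tables=sample_tables,
            dmf_tables=dmf_tables,
            common=common,
            concordance=concordance,
            annotations=annotations,
            correlations=correlations,
            extra={
                "n_fragments_catalogue": len(fragments),
                "histograms": histograms,
                "dendrogram": newick,
                "version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.seed,
            },
        )
        write_report(report, outdir / "report.json")
    except Exception:
        marker.write_text(f"failed at stage: {stage}\n")
        raise
    marker.unlink(missing_ok=True)
    return report
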