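"""Global methylome summaries.

Histograms of fragment methylation levels, pairwise Pearson correlation of
samples, average-linkage hierarchical clustering of samples on a
1 - Pearson-r distance, element-wise level distributions with tissue vs
cell-line Wilcoxon rank-sum tests, and a machine-readable run report.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import mannwhitneyu, pearsonr, rankdata

__all__ = [
    "methylation_histogram",
    "pairwise_correlation",
    "build_matrix",
    "cluster_samples",
    "dendrogram_newick",
    "rank_sum_test",
    "element_distributions",
    "run_report",
]

#: at or below this combined sample size the rank-sum test is exact
EXACT_RANKSUM_N = 12


def methylation_histogram(levels: Sequence[float] | pd.Series, n_bins: int = 50) -> np.ndarray:
    """Counts of fragment levels in ``n_bins`` equal bins partitioning [0, 1].

    The last bin is right-closed so a level of exactly 1.0 is counted;
    counts always sum to the number of fragments.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    arr = np.asarray(levels, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("methylation levels must lie in [0, 1]")
    counts, _ = np.histogram(arr, bins=n_bins, range=(0.0, 1.0))
    return counts


def pairwise_correlation(sample_a: pd.DataFrame, sample_b: pd.DataFrame) -> float:
    """Pearson r between two samples over fragments passing the filter in both."""
    a = sample_a[sample_a["passes_filter"]].set_index("fragment_id")["level"]
    b = sample_b[sample_b["passes_filter"]].set_index("fragment_id")["level"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared passing fragments")
    x, y = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in a sample")
    return float(pearsonr(x, y).statistic)


def build_matrix(samples: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Fragment x sample matrix of levels over fragments passing in every sample."""
    series = {
        name: tab[tab["passes_filter"]].set_index("fragment_id")["level"]
        for name, tab in samples.items()
    }
    matrix = pd.DataFrame(series).dropna()
    if matrix.empty:
        raise ValueError("no fragment passes the filter in every sample")
    # sort rows by coordinates encoded in the fragment id (contig:start-end)
    def coord_key(frag_id: str) -> tuple[str, int]:
        contig, span = frag_id.rsplit(":", 1)
        return contig, int(span.split("-")[0])

    return matrix.loc[sorted(matrix.index, key=coord_key)]


def cluster_samples(matrix: pd.DataFrame) -> np.ndarray:
    """Average-linkage agglomerative clustering of samples, distance 1 - Pearson r.

    Columns are samples (taken in name order for deterministic ties).
    Returns a scipy linkage matrix. A single sample yields an empty linkage.
    """
    matrix = matrix[sorted(matrix.columns)]
    for name in matrix.columns:
        if np.ptp(matrix[name].to_numpy()) == 0:
            raise ValueError(f"sample {name!r} has zero variance; correlation distance undefined")
    if matrix.shape[1] < 2:
        return np.empty((0, 4))
    corr = np.corrcoef(matrix.to_numpy().T)
    dist = 1.0 - corr
    condensed = dist[np.triu_indices_from(dist, k=1)]
    condensed = np.clip(condensed, 0.0, None)
    return linkage(condensed, method="average")


def dendrogram_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Newick rendering of a scipy linkage over ``labels``."""
    labels = list(labels)
    if link.shape[0] == 0:
        return f"{labels[0]};" if labels else ";"
    tree = to_tree(link)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return f"({render(node.left)},{render(node.right)}):{node.dist:.6g}"

    return render(tree) + ";"


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by enumeration of all rank assignments (midranks for ties) when
    the combined sample size is at most 12; otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if n1 + n2 <= EXACT_RANKSUM_N:
        ranks = rankdata(np.concatenate([x, y]))
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        u_null = []
        for idx in itertools.combinations(range(n1 + n2), n1):
            u_null.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
        u_null = np.asarray(u_null)
        lo, hi = min(u_obs, n1 * n2 - u_obs), max(u_obs, n1 * n2 - u_obs)
        eps = 1e-9
        p = ((u_null <= lo + eps).sum() + (u_null >= hi - eps).sum()) / len(u_null)
        return float(min(p, 1.0))
    return float(
        mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def element_distributions(
    samples: Mapping[str, pd.DataFrame],
    annotations: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    element_classes: Sequence[str] = ("promoter", "exon", "intron", "junction", "intergenic"),
    context_column: str = "gene_context",
) -> pd.DataFrame:
    """Median level per element class and sample, and per-pair rank-sum tests.

    ``pairs`` lists (tissue, cell_line) sample-name pairs. Rows with no
    fragments in a class carry NaN medians and p-values and ``empty=True``.
    """
    annot = annotations.set_index("fragment_id")
    levels: dict[str, dict[str, pd.Series]] = {}
    for name, tab in samples.items():
        passing = tab[tab["passes_filter"]].set_index("fragment_id")
        ctx = annot.loc[annot.index.intersection(passing.index), context_column]
        for cls in element_classes:
            ids = ctx[ctx == cls].index
            levels.setdefault(cls, {})[name] = passing.loc[ids, "level"]
    rows = []
    for cls in element_classes:
        row: dict[str, object] = {"element": cls}
        empty = all(len(v) == 0 for v in levels[cls].values())
        row["empty"] = empty
        for name in samples:
            vec = levels[cls][name]
            row[f"median_{name}"] = float(vec.median()) if len(vec) else np.nan
        for tissue, cell in pairs:
            vx, vy = levels[cls][tissue], levels[cls][cell]
            key = f"p_{tissue}_vs_{cell}"
            row[key] = rank_sum_test(vx, vy) if len(vx) and len(vy) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_report(
    sample_tables: Mapping[str, pd.DataFrame] | None = None,
    dmf_tables: Mapping[str, pd.DataFrame] | None = None,
    common: pd.DataFrame | None = None,
    concordance: Mapping[str, Mapping[str, float]] | None = None,
    annotations: pd.DataFrame | None = None,
    correlations: Mapping[str, float] | None = None,
    extra: Mapping[str, object] | None = None,
) -> dict:
    """Assemble a single machine-readable summary of a pipeline run.

    Missing stages are recorded as absent rather than raising.
    """
    report: dict[str, object] = {}
    if sample_tables is not None:
        report["samples"] = {
            name: {
                "n_fragments_covered": int(len(tab)),
                "n_fragments_passing": int(tab["passes_filter"].sum()) if len(tab) else 0,
                "median_level_passing": (
                    round(float(tab.loc[tab["passes_filter"], "level"].median()), 2)
                    if len(tab) and tab["passes_filter"].any()
                    else None
                ),
            }
            for name, tab in sample_tables.items()
        }
    else:
        report["samples"] = "absent"
    if dmf_tables is not None:
        report["dmf"] = {
            name: {
                "n_tested": int(len(tab)),
                "n_significant": int(tab["significant"].sum()) if len(tab) else 0,
            }
            for name, tab in dmf_tables.items()
        }
    else:
        report["dmf"] = "absent"
    report["common_dmf"] = (
        {"n_common": int(len(common))} if common is not None else "absent"
    )
    report["concordance"] = dict(concordance) if concordance is not None else "absent"
    if annotations is not None and len(annotations):
        report["context_proportions"] = {
            "gene_context": annotations["gene_context"].value_counts(normalize=True).to_dict(),
            "cgi_context": annotations["cgi_context"].value_counts(normalize=True).to_dict(),
        }
    else:
        report["context_proportions"] = "absent"
    report["correlations"] = dict(correlations) if correlations is not None else "absent"
    if extra:
        report.update(extra)
    return report


def write_report(report: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
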