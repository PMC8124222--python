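"""Operating-characteristic measurements of the DMF caller on synthetic data.

These helpers run the full in-memory analysis chain (simulate counts →
aggregate → Fisher/Bonferroni DMF calling → cross-pair intersection) on a
genome with known planted truth, and measure sensitivity, direction
agreement, false-positive behaviour and null family-wise error. They are
used by the test suite and the reproduction script; the per-replicate cost
is small because one genome (and planted set) is reused across replicates
with fresh methylation and count randomness.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .diffmeth import BOTH_HYPER, BOTH_HYPO, call_dmfs, intersect_common
from .methylation import aggregate
from .simulate import GenomeArtifacts, simulate_pair

__all__ = ["reseed", "run_replicate", "planted_recovery", "null_rejections", "replicate_seeds"]


def reseed(artifacts: GenomeArtifacts, seed: int) -> GenomeArtifacts:
    """Same genome, catalogue and planted set; fresh level/count randomness."""
    return dataclasses.replace(
        artifacts, config=dataclasses.replace(artifacts.config, seed=seed)
    )


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """Independent 31-bit replicate seeds derived from one base seed."""
    return [int(s) for s in np.random.SeedSequence(base_seed).generate_state(n) % (2**31)]


def run_replicate(
    artifacts: GenomeArtifacts,
    seed: int,
    alpha: float = 0.01,
    min_diff: float = 0.25,
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame | None]:
    """Simulate every pair at ``seed`` and call DMFs; returns per-pair DMF
    tables and, when there are >=2 pairs, the common-DMF table."""
    art = reseed(artifacts, seed)
    dmfs: dict[int, pd.DataFrame] = {}
    for pair_id in range(1, art.config.n_pairs + 1):
        tissue, cell, _ = simulate_pair(art, pair_id)
        tissue_table = aggregate(art.fragments, tissue)
        cell_table = aggregate(art.fragments, cell)
        dmfs[pair_id] = call_dmfs(tissue_table, cell_table, alpha, min_diff)
    common = None
    if art.config.n_pairs >= 2:
        common = intersect_common(dmfs[1], dmfs[2])
        for pair_id in range(3, art.config.n_pairs + 1):
            sig = dmfs[pair_id]
            common = common[
                common["fragment_id"].isin(sig.loc[sig["significant"], "fragment_id"])
            ].reset_index(drop=True)
    return dmfs, common


def planted_recovery(artifacts: GenomeArtifacts, seed: int) -> dict[str, float]:
    """Recovery of the planted shared DMFs by the full pipeline at ``seed``.

    Returns sensitivity (planted shared fragments recovered as common DMFs),
    direction agreement among the recovered ones (both-pair concordance
    matching the planted direction), and the number of common-DMF calls at
    fragments that were never planted.
    """
    _, common = run_replicate(artifacts, seed)
    planted = artifacts.planted
    shared = planted[(planted["pair_id"] == 1) & planted["shared"]]
    if common is None or shared.empty:
        raise ValueError("planted recovery needs >=2 pairs and a shared planted set")
    recovered = common[common["fragment_id"].isin(shared["fragment_id"])]
    sensitivity = len(recovered) / len(shared)
    merged = recovered.merge(shared[["fragment_id", "direction"]], on="fragment_id")
    agree = (
        ((merged["direction"] == "hyper") & (merged["concordance"] == BOTH_HYPER))
        | ((merged["direction"] == "hypo") & (merged["concordance"] == BOTH_HYPO))
    )
    direction_agreement = float(agree.mean()) if len(merged) else float("nan")
    any_planted = set(planted["fragment_id"])
    n_unplanted_calls = int((~common["fragment_id"].isin(any_planted)).sum())
    return {
        "sensitivity": sensitivity,
        "direction_agreement": direction_agreement,
        "n_unplanted_calls": n_unplanted_calls,
        "n_common": len(common),
    }


def null_rejections(null_artifacts: GenomeArtifacts, seed: int) -> int:
    """Number of significant DMFs for one pair simulated under the null."""
    art = reseed(null_artifacts, seed)
    tissue, cell, _ = simulate_pair(art, 1)
    dmfs = call_dmfs(aggregate(art.fragments, tissue), aggregate(art.fragments, cell))
    return int(dmfs["significant"].sum()) if len(dmfs) else 0
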