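"""Recovery and calibration metrics on synthetic studies.

Runs the full analysis on generated data and scores it against the ground
truth: planted-DMP/DEG recall, edge-sign recovery among retained edges,
whether the planted reverser node ranks among the top-5% candidates, and
whether the planted reverser drug tops the screen.
"""

from __future__ import annotations

import numpy as np

from .containers import SignedGRN
from .pipeline import run_analysis
from .simulate import SimulationConfig, simulate_all

__all__ = ["replicate_metrics", "replicate_summary", "random_signed_network"]


def random_signed_network(rng: np.random.Generator, n_nodes: int) -> SignedGRN:
    """Random acyclic signed digraph used for solver property sweeps."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for j in range(1, n_nodes):
        for p in rng.choice(j, size=min(j, int(rng.integers(1, 4))), replace=False):
            edges.append((nodes[p], nodes[j], int(rng.choice([-1, 1]))))
    if not edges:
        edges = [(nodes[0], nodes[-1], 1)]
    return SignedGRN.from_edges(edges, inputs=[nodes[0]], outputs=[nodes[-1]])


def replicate_metrics(config: SimulationConfig) -> dict:
    """Simulate one study under ``config``, analyse it, and score recovery."""
    study = simulate_all(config)
    truth = study.truth
    edges = study.network.edge_table()[["source", "target"]]
    res = run_analysis(
        study.methylation,
        study.expression,
        study.cohort,
        truth.annotation,
        edges,
        study.profiles,
    )
    out: dict = {}
    dmp_called = set(res.dmps.loc[res.dmps["is_dmp"], "feature_id"])
    out["dmp_recall"] = len(dmp_called & set(truth.true_dmp_ids)) / len(truth.true_dmp_ids)
    deg_called = set(res.degs.loc[res.degs["is_deg"], "gene_id"])
    out["deg_recall"] = len(deg_called & set(truth.true_deg_ids)) / len(truth.true_deg_ids)

    out["sign_accuracy"] = np.nan
    out["reverser_is_candidate"] = False
    out["reverser_drug_first"] = False
    out["dac_consistent_frac"] = np.nan
    if res.network is not None:
        matched = total = 0
        for u, v in res.network.graph.edges:
            true_sign = truth.true_edge_signs.get((u, v))
            if true_sign is not None:
                total += 1
                matched += res.network.edge_sign(u, v) == true_sign
        out["sign_accuracy"] = matched / total if total else np.nan
        out["n_retained_edges"] = total
    if res.dacs is not None and len(res.dacs):
        out["dac_consistent_frac"] = float((res.dacs["class"] == "consistent").mean())
    if res.ranked_targets is not None:
        ranked = res.ranked_targets.set_index("node_id")
        node = truth.planted_reverser_nodes[0]
        if node in ranked.index:
            out["reverser_is_candidate"] = bool(ranked.loc[node, "candidate"])
            out["reverser_rank"] = int(ranked.loc[node, "rank"])
    if res.screen is not None and len(res.screen):
        out["reverser_drug_first"] = (
            res.screen.iloc[0]["drug"] in truth.planted_reverser_drugs
        )
    return out


def replicate_summary(n_replicates: int, base_seed: int, **config_overrides) -> dict:
    """Aggregate recovery metrics over independent replicate studies."""
    metrics = [
        replicate_metrics(SimulationConfig(seed=base_seed * 10_000 + i, **config_overrides))
        for i in range(n_replicates)
    ]
    return {
        "n_replicates": n_replicates,
        "mean_dmp_recall": float(np.mean([m["dmp_recall"] for m in metrics])),
        "mean_deg_recall": float(np.mean([m["deg_recall"] for m in metrics])),
        "mean_sign_accuracy": float(np.nanmean([m["sign_accuracy"] for m in metrics])),
        "mean_dac_consistent_frac": float(
            np.nanmean([m["dac_consistent_frac"] for m in metrics])
        ),
        "reverser_candidate_rate": float(
            np.mean([m["reverser_is_candidate"] for m in metrics])
        ),
        "reverser_drug_first_rate": float(
            np.mean([m["reverser_drug_first"] for m in metrics])
        ),
    }
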