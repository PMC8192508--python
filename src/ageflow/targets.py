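"""Per-sample activity prediction and reverse-aging target ranking.

Each sample's methylation state drives TF input signals through the signed
network; the resulting per-sample activity of every node is correlated with
age to get the direction of activity change (DAC). Output DEGs whose DAC is
significant and concordant with their RNA-seq direction are "validated".
Candidate reverse-aging targets are then found by assigning +1 / -1 input
signals to each intermediate node in turn and counting how many validated
DEGs move opposite to their aging direction; the top 5% of intermediate
nodes by that count are candidates.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import CohortTable, MethylationMatrix, SignedGRN
from .markers import pearson_p_from_r
from .sfa import (
    SFAProblem,
    build_weight_matrix,
    decompose_contributions,
    input_vector,
    methylation_to_input,
    solve_many,
)

__all__ = [
    "compute_sample_dacs",
    "dac_age_association",
    "input_influence",
    "perturb_node_scan",
    "rank_targets",
]

logger = logging.getLogger(__name__)


def _sample_inputs(
    network: SignedGRN,
    matrix: MethylationMatrix,
    links: pd.DataFrame,
    samples: list[str],
    alpha: float,
) -> tuple[SFAProblem, np.ndarray, list[str]]:
    problem = build_weight_matrix(network, alpha=alpha)
    cols, kept = [], []
    for s in samples:
        if s not in matrix.beta.columns:
            warnings.warn(f"sample {s} missing from methylation matrix; skipped", stacklevel=3)
            continue
        signals = methylation_to_input(matrix, links, s)
        cols.append(input_vector(problem, signals))
        kept.append(s)
    return problem, np.column_stack(cols), kept


def compute_sample_dacs(
    network: SignedGRN,
    matrix: MethylationMatrix,
    links: pd.DataFrame,
    cohort: CohortTable,
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Steady-state activity of every network node in every sample
    (nodes x samples), from that sample's DMP-derived TF inputs."""
    problem, B, kept = _sample_inputs(network, matrix, links, cohort.sample_ids, alpha)
    X = solve_many(problem, B)
    return pd.DataFrame(X, index=problem.nodes, columns=kept)


def dac_age_association(
    activities: pd.DataFrame,
    cohort: CohortTable,
    degs: pd.DataFrame,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Classify each output DEG's predicted DAC against its RNA-seq direction.

    Pearson correlation of per-sample activity with age; ``consistent`` when
    significant and the DAC sign matches sign(lfc_per_year), ``inconsistent``
    when significant but opposed, else ``nonsignificant``.
    """
    ages = cohort.ages.reindex(activities.columns).to_numpy(float)
    lfc = degs.set_index("gene_id")["lfc_per_year"]
    records = []
    for gene in degs["gene_id"]:
        if gene not in activities.index:
            continue
        act = activities.loc[gene].to_numpy(float)
        if act.std() == 0:
            r, p = 0.0, 1.0
        else:
            r = float(np.corrcoef(act, ages)[0, 1])
            p = float(pearson_p_from_r(np.array([r]), len(ages))[0])
        direction = int(np.sign(r))
        if p >= p_threshold:
            cls = "nonsignificant"
        elif direction == int(np.sign(lfc[gene])):
            cls = "consistent"
        else:
            cls = "inconsistent"
        records.append(
            {"gene_id": gene, "r_age": r, "p": p, "dac_direction": direction, "class": cls}
        )
    return pd.DataFrame(records)


def input_influence(
    network: SignedGRN,
    matrix: MethylationMatrix,
    links: pd.DataFrame,
    cohort: CohortTable,
    outputs: list[str] | None = None,
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Relative influence of each input TF on each output DEG's age trend.

    Per sample, the steady state is decomposed into per-input contributions;
    the age slope of each contribution is taken across samples, and each
    output's influences are normalized to |slope| fractions summing to 1.
    """
    problem, B, kept = _sample_inputs(network, matrix, links, cohort.sample_ids, alpha)
    ages = cohort.ages.reindex(kept).to_numpy(float)
    inputs = network.inputs
    outputs = outputs if outputs is not None else network.outputs
    # contribution of input i in sample s, for all nodes: solve per masked input
    slopes = pd.DataFrame(0.0, index=inputs, columns=outputs)
    ages_c = ages - ages.mean()
    denom = float(np.dot(ages_c, ages_c))
    for i in inputs:
        mask = np.zeros_like(B)
        mask[problem.node_index(i), :] = B[problem.node_index(i), :]
        X = solve_many(problem, mask)  # nodes x samples, input i alone
        for g in outputs:
            y = X[problem.node_index(g), :]
            slopes.loc[i, g] = float(np.dot(ages_c, y - y.mean()) / denom) if denom else 0.0
    influence = slopes.abs()
    colsum = influence.sum(axis=0)
    zero_cols = colsum[colsum == 0].index
    if len(zero_cols):
        logger.info("outputs with zero total influence: %s", list(zero_cols)[:5])
    influence = influence.divide(colsum.replace(0.0, np.nan), axis=1)
    influence.attrs["raw_slopes"] = slopes
    return influence


def perturb_node_scan(
    network: SignedGRN,
    validated_degs: pd.DataFrame,
    deg_directions: pd.Series | None = None,
    alpha: float = 0.5,
    epsilon: float = 1e-9,
) -> pd.DataFrame:
    """Scan +1/-1 input signals over intermediate nodes and count reversals.

    ``validated_degs`` is the DAC table restricted (by the caller or here)
    to class == consistent. A validated DEG g counts as reversed when
    sign(x_g) = -sign(lfc direction) and |x_g| > epsilon.
    """
    validated = validated_degs[validated_degs["class"] == "consistent"]
    if deg_directions is None:
        deg_directions = validated.set_index("gene_id")["dac_direction"]
    genes = [g for g in validated["gene_id"] if g in network.nodes]
    if not genes:
        raise ValueError("no validated DEGs present in the network")
    intermediates = network.intermediates
    if not intermediates:
        raise ValueError("network has no intermediate nodes")
    problem = build_weight_matrix(network, alpha=alpha)
    n = len(problem.nodes)
    B = np.zeros((n, len(intermediates)))
    for col, m in enumerate(intermediates):
        B[problem.node_index(m), col] = 1.0
    X = solve_many(problem, B)  # sigma=+1 solves; sigma=-1 is the negation
    gidx = [problem.node_index(g) for g in genes]
    directions = np.array([np.sign(deg_directions[g]) for g in genes])
    rows = []
    for col, m in enumerate(intermediates):
        for sigma in (1, -1):
            xg = sigma * X[gidx, col]
            reversed_mask = (np.sign(xg) == -directions) & (np.abs(xg) > epsilon)
            rows.append(
                {
                    "node_id": m,
                    "perturb_sign": sigma,
                    "n_reversed": int(reversed_mask.sum()),
                    "tiebreak_mass": float(np.abs(xg[reversed_mask]).sum()),
                }
            )
    return pd.DataFrame(rows)


def rank_targets(scores: pd.DataFrame, top_fraction: float = 0.05) -> pd.DataFrame:
    """Keep each node's best (sign) row, rank by reversal count, and flag the
    top ``floor(top_fraction * n_intermediates)`` nodes (minimum 1) as
    candidates."""
    if scores.empty:
        raise ValueError("empty score table")
    best = (
        scores.sort_values(
            ["node_id", "n_reversed", "tiebreak_mass", "perturb_sign"],
            ascending=[True, False, False, False],
        )
        .groupby("node_id", sort=False)
        .head(1)
    )
    ranked = best.sort_values(
        ["n_reversed", "tiebreak_mass", "node_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    n_nodes = scores["node_id"].nunique()
    n_candidates = max(int(np.floor(top_fraction * n_nodes)), 1)
    ranked["candidate"] = ranked["rank"] <= n_candidates
    return ranked
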