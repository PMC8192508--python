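"""Aging-subnetwork extraction and edge mode-of-action assignment.

From a canonical (unsigned) TF->target regulatory network, the aging
subnetwork keeps the DMP-linked input TFs, the DEG outputs, and every node
lying on a directed input->output path. Each surviving edge gets a sign
from the partial correlation of TF and target expression, controlling for
the target's other regulators; edges whose plain or partial correlation is
not significant are dropped, and path membership is re-enforced to a fixed
point.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, SignedGRN

__all__ = [
    "extract_subnetwork",
    "variance_filter",
    "partial_correlation",
    "assign_edge_signs",
]

logger = logging.getLogger(__name__)


def _path_nodes(g: nx.DiGraph, inputs: set[str], outputs: set[str]) -> set[str]:
    """Nodes reachable from some input AND from which some output is reachable."""
    down: set[str] = set()
    for i in inputs & set(g.nodes):
        down |= nx.descendants(g, i)
    up: set[str] = set()
    for o in outputs & set(g.nodes):
        up |= nx.ancestors(g, o)
    return down & up


def extract_subnetwork(
    canonical: pd.DataFrame,
    inputs: set[str] | list[str],
    outputs: set[str] | list[str],
) -> nx.DiGraph:
    """Restrict a canonical edge list to input->output path structure.

    ``canonical`` needs columns source, target (optional sign). Kept nodes
    are inputs, outputs, and intermediates on directed input->output paths;
    kept edges join a node reachable-from-inputs (or an input) to a node
    co-reachable-to-outputs (or an output). Self-loops are removed.
    """
    inputs, outputs = set(inputs), set(outputs)
    g = nx.DiGraph()
    n_loops = 0
    for row in canonical.itertuples(index=False):
        if row.source == row.target:
            n_loops += 1
            continue
        attrs = {}
        if hasattr(row, "sign") and not pd.isna(row.sign):
            attrs["sign"] = int(row.sign)
        g.add_edge(row.source, row.target, **attrs)
    if n_loops:
        logger.info("removed %d self-loops from canonical network", n_loops)
    present = set(g.nodes)
    for role, ids in (("input", inputs), ("output", outputs)):
        absent = ids - present
        if absent:
            logger.info("%d %s nodes absent from canonical network; dropped", len(absent), role)
    inputs &= present
    outputs &= present

    mids = _path_nodes(g, inputs, outputs)
    kept = inputs | outputs | mids
    # sources must be inputs or on-path; targets must be outputs or on-path
    sub = nx.DiGraph()
    for u, v, d in g.edges(data=True):
        if u in kept and v in kept and u in (inputs | mids) and v in (outputs | mids):
            sub.add_edge(u, v, **d)
    sub.add_nodes_from(kept & (inputs | outputs))
    # drop kept nodes that lost all path edges
    sub.remove_nodes_from([n for n in list(sub.nodes) if sub.degree(n) == 0 and n not in inputs | outputs])
    if sub.number_of_edges() == 0:
        raise ValueError(
            "empty subnetwork: no directed path from any input TF to any output DEG"
        )
    for n in sub.nodes:
        sub.nodes[n]["role"] = (
            "input" if n in inputs else "output" if n in outputs else "intermediate"
        )
    return sub


def variance_filter(
    expression: ExpressionMatrix,
    nodes: set[str] | list[str],
    fraction: float = 0.05,
) -> set[str]:
    """Drop genes in the lower ``fraction`` tail of expression variance.

    The variance quantile is computed over the candidate node set only;
    genes strictly below it are removed, so an all-tied set loses nothing.
    """
    nodes = [n for n in nodes if n in expression.counts.index]
    if not nodes:
        return set()
    variances = expression.log_normalized().loc[nodes].var(axis=1, ddof=1)
    order = np.sort(variances.to_numpy())
    cut_idx = int(np.floor(fraction * len(order)))
    threshold = order[cut_idx] if cut_idx < len(order) else np.inf
    return set(variances.index[variances >= threshold])


def partial_correlation(
    target_expr: np.ndarray,
    tf_expr: np.ndarray,
    control_exprs: np.ndarray | None = None,
) -> tuple[float, float]:
    """Partial Pearson correlation of target and TF given controls.

    Both vectors are residualized by least squares on the controls plus an
    intercept; rank-deficient control sets are pruned by QR with column
    pivoting. P value from the t transform with df = n - 2 - #controls.
    """
    y = np.asarray(target_expr, float)
    x = np.asarray(tf_expr, float)
    n = len(y)
    if control_exprs is None or len(control_exprs) == 0:
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.atleast_2d(np.asarray(control_exprs, float))
        if C.shape[0] == n and C.shape[1] != n:
            C = C.T  # accept controls as rows or columns
        C = C - C.mean(axis=1, keepdims=True)
        # prune collinear controls by pivoted QR rank detection
        from scipy.linalg import qr as _qr

        _, R, piv = _qr(C.T, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = max(C.T.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
        rank = int((diag > tol).sum())
        if rank < C.shape[0]:
            logger.info("pruned %d collinear controls", C.shape[0] - rank)
            C = C[np.sort(piv[:rank])] if rank else np.empty((0, n))
        k = C.shape[0]
        Z = np.column_stack([np.ones(n), C.T]) if k else np.ones((n, 1))
    coef_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    coef_x, *_ = np.linalg.lstsq(Z, x, rcond=None)
    ry = y - Z @ coef_y
    rx = x - Z @ coef_x
    sy, sx = ry.std(), rx.std()
    if sy == 0 or sx == 0:
        return 0.0, 1.0
    rho = float(np.dot(ry, rx) / (len(y) * ry.std() * rx.std()))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 2 - k
    if df <= 0:
        return rho, 1.0
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt(df) / np.sqrt(max(1.0 - rho * rho, 1e-300))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, min(p, 1.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if a.std() == 0 or b.std() == 0:
        return 0.0, 1.0
    r = float(np.corrcoef(a, b)[0, 1])
    df = len(a) - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df) / np.sqrt(max(1.0 - r * r, 1e-300))
    return r, float(min(2.0 * stats.t.sf(abs(t), df), 1.0))


def assign_edge_signs(
    subnetwork: nx.DiGraph,
    expression: ExpressionMatrix,
    p_threshold: float = 0.05,
) -> SignedGRN:
    """Assign each edge its mode of action and drop insignificant edges.

    For edge TF->g the controls are the other TFs with kept edges into g.
    An edge survives only if both the plain Pearson and the partial
    correlation are significant; its sign is sign(partial rho). Nodes
    isolated by removals are dropped and path membership re-enforced until
    a fixed point.
    """
    logn = expression.log_normalized()
    inputs = {n for n, d in subnetwork.nodes(data=True) if d.get("role") == "input"}
    outputs = {n for n, d in subnetwork.nodes(data=True) if d.get("role") == "output"}
    g = subnetwork.copy()
    missing = [n for n in g.nodes if n not in logn.index]
    if missing:
        raise ValueError(f"nodes without expression rows: {missing[:5]}")

    n_samples = logn.shape[1]
    stats_cache: dict[tuple[str, str], dict] = {}
    changed = True
    while changed:
        changed = False
        drop_edges = []
        for target in list(g.nodes):
            preds = list(g.predecessors(target))
            if not preds:
                continue
            y = logn.loc[target].to_numpy(float)
            for tf in preds:
                x = logn.loc[tf].to_numpy(float)
                controls = [c for c in preds if c != tf]
                if len(controls) >= n_samples - 4:
                    # keep the strongest marginal controls so df stays positive
                    strength = {
                        c: abs(_pearson(logn.loc[c].to_numpy(float), y)[0]) for c in controls
                    }
                    controls = sorted(controls, key=lambda c: -strength[c])[: n_samples - 5]
                    logger.info("controls for %s->%s capped at %d", tf, target, len(controls))
                C = (
                    np.array([logn.loc[c].to_numpy(float) for c in controls])
                    if controls
                    else None
                )
                r_plain, p_plain = _pearson(x, y)
                rho, p_part = partial_correlation(y, x, C)
                stats_cache[(tf, target)] = {
                    "pearson_r": r_plain,
                    "pearson_p": p_plain,
                    "partial_r": rho,
                    "partial_p": p_part,
                }
                if p_plain >= p_threshold or p_part >= p_threshold or rho == 0.0:
                    drop_edges.append((tf, target))
        if drop_edges:
            g.remove_edges_from(drop_edges)
            changed = True
        # re-enforce path membership
        mids = _path_nodes(g, inputs, outputs)
        kept = (inputs | outputs | mids) & set(g.nodes)
        bad_edges = [
            (u, v)
            for u, v in g.edges
            if not (u in (inputs | mids) and v in (outputs | mids))
        ]
        if bad_edges:
            g.remove_edges_from(bad_edges)
            changed = True
        lost = [n for n in list(g.nodes) if n not in kept or g.degree(n) == 0]
        lost = [n for n in lost if not (n in inputs | outputs and g.degree(n) > 0)]
        if lost:
            g.remove_nodes_from(lost)
            changed = True
    if g.number_of_edges() == 0:
        raise ValueError("no significant edges survive the correlation filters")
    out = nx.DiGraph()
    for u, v in g.edges:
        st = stats_cache[(u, v)]
        out.add_edge(u, v, sign=int(np.sign(st["partial_r"])), **st)
    for n in out.nodes:
        out.nodes[n]["role"] = (
            "input" if n in inputs else "output" if n in outputs else "intermediate"
        )
    return SignedGRN(out)
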