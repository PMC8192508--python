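"""Signal flow analysis on signed gene regulatory networks.

The model is linear: each node's steady-state activity balances the damped
signal flowing in from its regulators against its own basal input,

    x = alpha * W x + (1 - alpha) * b,

where ``W[i, j] = sign(j -> i) / in_degree(i)`` shares influence equally
among a node's regulators, ``alpha`` in [0, 1) damps upstream flow relative
to basal activity, and ``b`` holds the input signals. In-degree
normalization bounds ``||alpha W||_inf <= alpha < 1``, so the map is a
contraction and the steady state

    x = (1 - alpha) (I - alpha W)^{-1} b

exists, is unique, and is linear in ``b`` — which makes per-input
contribution decomposition exact superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SignedGRN

__all__ = [
    "SFAProblem",
    "SFAResult",
    "build_weight_matrix",
    "methylation_to_input",
    "solve_steady_state",
    "propagate_iterative",
    "decompose_contributions",
]

DEFAULT_ALPHA = 0.5


@dataclass
class SFAProblem:
    """Normalized weight matrix, damping and input vector for one solve.

    ``W`` is dense node x node with ``W[i, j] = sign(j->i)/d_in(i)``;
    rows of input nodes (in-degree 0) are identically zero.
    """

    W: np.ndarray
    nodes: list[str]
    alpha: float = DEFAULT_ALPHA
    b: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.W.shape != (n, n):
            raise ValueError("W shape does not match node list")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if np.abs(np.diag(self.W)).max(initial=0.0) > 0:
            raise ValueError("W has nonzero diagonal (self-loop)")
        if np.abs(self.W).sum(axis=1).max(initial=0.0) > 1.0 + 1e-12:
            raise ValueError("row sums of |W| must be <= 1")
        self._index = {n_: i for i, n_ in enumerate(self.nodes)}

    def node_index(self, node: str) -> int:
        return self._index[node]

    def with_b(self, b: np.ndarray | dict[str, float]) -> "SFAProblem":
        if isinstance(b, dict):
            vec = np.zeros(len(self.nodes))
            for node, value in b.items():
                vec[self._index[node]] = value
            b = vec
        return SFAProblem(self.W, self.nodes, self.alpha, np.asarray(b, float))


@dataclass
class SFAResult:
    """Steady-state activities and, optionally, per-input contributions."""

    x: pd.Series  # activity per node
    contributions: pd.DataFrame | None = None  # nodes x inputs

    def activity(self, node: str) -> float:
        return float(self.x[node])


def build_weight_matrix(network: SignedGRN, alpha: float = DEFAULT_ALPHA) -> SFAProblem:
    """Assemble ``W`` from edge signs with 1/in-degree normalization."""
    nodes = network.nodes
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    g = network.graph
    for target in nodes:
        preds = list(g.predecessors(target))
        if not preds:
            continue
        i = index[target]
        share = 1.0 / len(preds)
        for source in preds:
            W[i, index[source]] = g.edges[source, target]["sign"] * share
    return SFAProblem(W, nodes, alpha)


def solve_steady_state(problem: SFAProblem) -> SFAResult:
    """Direct solve of ``x = (1-alpha)(I - alpha W)^{-1} b``."""
    if problem.b is None:
        raise ValueError("problem has no input vector b")
    n = len(problem.nodes)
    A = np.eye(n) - problem.alpha * problem.W
    try:
        x = (1.0 - problem.alpha) * np.linalg.solve(A, problem.b)
    except np.linalg.LinAlgError as exc:  # cannot occur under the normalization
        raise np.linalg.LinAlgError(f"singular SFA system: {exc}") from exc
    return SFAResult(pd.Series(x, index=problem.nodes, name="activity"))


def propagate_iterative(
    problem: SFAProblem, tol: float = 1e-12, max_iter: int = 10_000
) -> np.ndarray:
    """Jacobi iteration ``x <- alpha W x + (1-alpha) b`` from ``x0 = b``.

    Serves as the independent oracle for the direct solve; the contraction
    bound guarantees geometric convergence at rate alpha.
    """
    if problem.b is None:
        raise ValueError("problem has no input vector b")
    x = np.asarray(problem.b, float).copy()
    base = (1.0 - problem.alpha) * problem.b
    for _ in range(max_iter):
        x_next = problem.alpha * (problem.W @ x) + base
        if np.max(np.abs(x_next - x), initial=0.0) < tol:
            return x_next
        x = x_next
    raise RuntimeError(f"Jacobi iteration did not converge in {max_iter} steps")


def solve_many(problem: SFAProblem, B: np.ndarray) -> np.ndarray:
    """Solve for a matrix of input vectors (columns of ``B``) in one pass."""
    n = len(problem.nodes)
    A = np.eye(n) - problem.alpha * problem.W
    return (1.0 - problem.alpha) * np.linalg.solve(A, B)


def decompose_contributions(problem: SFAProblem, input_nodes: list[str]) -> pd.DataFrame:
    """Per-input contribution matrix ``C`` with ``C[:, i]`` the steady state
    when ``b`` is masked to input ``i``; columns sum to the full solution."""
    if problem.b is None:
        raise ValueError("problem has no input vector b")
    idx = [problem.node_index(i) for i in input_nodes]
    support = np.flatnonzero(problem.b)
    if not set(support).issubset(set(idx)):
        raise ValueError("b has support outside the declared input nodes")
    B = np.zeros((len(problem.nodes), len(input_nodes)))
    for col, i in enumerate(idx):
        B[i, col] = problem.b[i]
    C = solve_many(problem, B)
    return pd.DataFrame(C, index=problem.nodes, columns=input_nodes)


@dataclass
class InputSignal:
    """One DMP-derived input: cohort Z-score scaled to [-1, 1] and signed by
    the methylation-expression correlation of its representative link."""

    dmp_id: str
    tf_gene_id: str
    z: float
    v: float
    b_value: float


def methylation_to_input(
    matrix,
    links: pd.DataFrame,
    sample: str,
) -> list[InputSignal]:
    """Convert one sample's methylation state into TF input signals.

    Per representative link: ``z`` is the sample's cohort Z-score at the DMP,
    ``v = z / max_samples |z|`` (max-abs scaling into [-1, 1]), and the TF's
    basal input is ``v * sign(link r)``. Positions with zero cohort SD
    contribute 0.
    """
    import warnings

    if sample not in matrix.beta.columns:
        raise KeyError(f"sample {sample!r} not in methylation matrix")
    reps = links[links["representative"]]
    signals: list[InputSignal] = []
    for _, row in reps.iterrows():
        dmp = row["dmp_id"]
        values = matrix.beta.loc[dmp].to_numpy(float)
        mean, sd = values.mean(), values.std(ddof=1)
        if sd == 0.0:
            warnings.warn(f"zero cohort SD at {dmp}; input set to 0", stacklevel=2)
            z = v = 0.0
        else:
            zs = (values - mean) / sd
            z = float(zs[list(matrix.beta.columns).index(sample)])
            zmax = float(np.abs(zs).max())
            v = z / zmax if zmax > 0 else 0.0
        b_value = v * (1.0 if row["r"] >= 0 else -1.0)
        signals.append(InputSignal(dmp, row["tf_gene_id"], z, v, b_value))
    return signals


def input_vector(problem: SFAProblem, signals: list[InputSignal]) -> np.ndarray:
    """Place signed input signals on their TF nodes; multiple signals on the
    same TF are averaged."""
    b = np.zeros(len(problem.nodes))
    counts = np.zeros(len(problem.nodes))
    for s in signals:
        if s.tf_gene_id not in problem._index:
            continue
        i = problem.node_index(s.tf_gene_id)
        b[i] += s.b_value
        counts[i] += 1
    many = counts > 1
    b[many] /= counts[many]
    return b
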