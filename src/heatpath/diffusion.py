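"""Raw node scores: stationary heat diffusion and personalised PageRank.

Heat diffusion runs on the undirected view.  Input compounds inject unit flow
(generation vector G), pathway nodes act as boundary sinks, and a node's score
is its stationary temperature, the solution of

    (L + B) T = G

with L the unnormalised graph Laplacian and B the diagonal pathway-boundary
indicator.  The conductance matrix KI = L + B is symmetric positive definite
whenever every connected component holds a pathway node, and the solution
conserves flow: sum_i B_ii T_i = n_in.

PageRank runs on the directed view (edges oriented upward), restarting
uniformly on the input compounds with damping d.  Dangling mass (pathways
have no out-edges) is redistributed to the restart vector; algebraically the
stationary distribution is then the L1-normalisation of v (I - d P)^{-1}, so
an exact linear-response route is available next to power iteration.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph import InputSet, LevelledGraph

logger = logging.getLogger(__name__)

#: Damping factor from the original PageRank publication.
DEFAULT_DAMPING = 0.85

#: Above this node count, solvers avoid dense factorisations where possible.
DENSE_LIMIT = 5000


@dataclass
class ScoreVector:
    """Per-node raw scores: temperatures (``hd``) or PageRank mass (``pr``)."""

    node_ids: tuple[str, ...]
    values: np.ndarray
    method: str  # "hd" | "pr"

    def __getitem__(self, node_id: str) -> float:
        return float(self.values[self.node_ids.index(node_id)])


@dataclass
class ResponseMatrix:
    """Linear response from compound-indexed inputs to per-node scores.

    Column j holds the score vector produced by a unit input on compound j;
    for any input set, scores equal the sum of its members' columns (for
    PageRank, on the pre-normalisation linear scale).
    """

    node_ids: tuple[str, ...]
    compound_ids: tuple[str, ...]
    matrix: np.ndarray  # shape (n_nodes, n_compounds)
    method: str

    def apply(self, indicator: np.ndarray) -> np.ndarray:
        return self.matrix @ indicator

    def rows(self, node_ids: Sequence[str]) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.node_ids)}
        return self.matrix[[idx[n] for n in node_ids], :]


class ConductanceSystem:
    """Assembled conductance matrix KI = L + B with a cached factorisation."""

    def __init__(self, graph: LevelledGraph):
        self.graph = graph
        self.node_ids = graph.node_ids
        boundary = np.array([lv == "pathway" for lv in graph.levels], dtype=float)
        for comp in nx.connected_components(graph.undirected):
            if not any(graph.level_of(n) == "pathway" for n in comp):
                raise ValueError(
                    "connected component without a pathway node: the conductance "
                    f"system is singular (component contains {min(comp)!r})"
                )
        lap = nx.laplacian_matrix(graph.undirected, nodelist=list(self.node_ids)).astype(float)
        self.KI = (sp.csc_matrix(lap) + sp.diags(boundary).tocsc()).tocsc()
        self.boundary = boundary
        self._factor = None

    @property
    def factor(self):
        if self._factor is None:
            self._factor = spla.splu(self.KI)
        return self._factor

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return self.factor.solve(rhs)


def conductance_system(graph: LevelledGraph) -> ConductanceSystem:
    """Assemble KI = L + B for ``graph`` (errors if any component lacks a pathway)."""
    return ConductanceSystem(graph)


def heat_diffusion_scores(system: ConductanceSystem, input_set: InputSet) -> ScoreVector:
    """Stationary temperatures T solving KI T = G for the given input."""
    g = system.graph.generation_vector(input_set)
    t = system.solve(g)
    return ScoreVector(system.node_ids, t, "hd")


def heat_response_matrix(
    system: ConductanceSystem, compound_ids: Sequence[str] | None = None
) -> ResponseMatrix:
    """Columns of KI^{-1} restricted to compound nodes.

    Column j is the temperature vector for the unit input {j}; by linearity
    the temperatures of any input set are the sum of its members' columns.
    """
    graph = system.graph
    if compound_ids is None:
        compound_ids = graph.compounds
    else:
        compound_ids = tuple(compound_ids)
        bad = [c for c in compound_ids if graph.level_of(c) != "compound"]
        if bad:
            raise ValueError(f"non-compound node(s) in compound_ids: {bad}")
    rhs = np.zeros((graph.n_nodes, len(compound_ids)))
    for j, cid in enumerate(compound_ids):
        rhs[graph.index[cid], j] = 1.0
    mat = system.factor.solve(rhs)
    return ResponseMatrix(system.node_ids, compound_ids, mat, "hd")


# ---------------------------------------------------------------------------
# PageRank
# ---------------------------------------------------------------------------


def _transition_matrix(graph: LevelledGraph) -> tuple[sp.csr_matrix, np.ndarray]:
    """Row-stochastic transition matrix of the directed (upward) view.

    Dangling rows (no out-edges, typically pathways) are left at zero and
    handled by the caller.
    """
    n = graph.n_nodes
    d = graph.directed
    rows, cols = [], []
    for u, v in d.edges():
        rows.append(graph.index[u])
        cols.append(graph.index[v])
    a = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    out = np.asarray(a.sum(axis=1)).ravel()
    dangling = out == 0
    inv = np.divide(1.0, out, out=np.zeros(n), where=~dangling)
    p = sp.diags(inv) @ a
    return sp.csr_matrix(p), dangling


def _restart_vector(graph: LevelledGraph, input_set: InputSet) -> np.ndarray:
    if input_set.n_in == 0:
        raise ValueError("empty input: PageRank restart distribution is undefined")
    v = graph.generation_vector(input_set)
    return v / v.sum()


def pagerank_power(
    graph: LevelledGraph,
    input_set: InputSet,
    damping: float = DEFAULT_DAMPING,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> ScoreVector:
    """Personalised PageRank by power iteration, dangling mass to the restart."""
    if not 0 <= damping < 1:
        raise ValueError("damping must lie in [0, 1)")
    v = _restart_vector(graph, input_set)
    p, dangling = _transition_matrix(graph)
    pt = p.T.tocsr()
    x = v.copy()
    for _ in range(max_iter):
        x_new = damping * (pt @ x + x[dangling].sum() * v) + (1.0 - damping) * v
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    x = x / x.sum()
    return ScoreVector(graph.node_ids, x, "pr")


def pagerank_linear(
    graph: LevelledGraph, input_set: InputSet, damping: float = DEFAULT_DAMPING
) -> ScoreVector:
    """Closed-form personalised PageRank: normalise v (I - d P)^{-1}."""
    if not 0 <= damping < 1:
        raise ValueError("damping must lie in [0, 1)")
    v = _restart_vector(graph, input_set)
    p, _ = _transition_matrix(graph)
    n = graph.n_nodes
    a = (sp.identity(n, format="csc") - damping * p.T).tocsc()
    u = spla.splu(a).solve(v)
    u = u / u.sum()
    return ScoreVector(graph.node_ids, u, "pr")


def pagerank_scores(
    graph: LevelledGraph,
    input_set: InputSet,
    damping: float = DEFAULT_DAMPING,
    solver: str = "auto",
) -> ScoreVector:
    """Personalised PageRank scores (values sum to one).

    ``solver`` is ``"linear"`` (sparse direct solve), ``"power"`` (iteration)
    or ``"auto"`` (linear below :data:`DENSE_LIMIT` nodes).  Both routes agree
    to solver tolerance.
    """
    if solver == "auto":
        solver = "linear" if graph.n_nodes <= DENSE_LIMIT else "power"
    if solver == "linear":
        return pagerank_linear(graph, input_set, damping)
    if solver == "power":
        return pagerank_power(graph, input_set, damping)
    raise ValueError(f"unknown solver {solver!r}")


def pagerank_response_matrix(
    graph: LevelledGraph,
    damping: float = DEFAULT_DAMPING,
    compound_ids: Sequence[str] | None = None,
) -> ResponseMatrix:
    """Linear PageRank response: column j is (1-d) (I - d P^T)^{-1} e_j.

    These are the un-normalised scores of a walk restarting entirely at
    compound j; the response is exactly linear in the restart indicator, which
    is what the analytic null model needs.  The displayed (sum-to-one)
    PageRank of an input is the normalisation of the mean of its columns.
    """
    if compound_ids is None:
        compound_ids = graph.compounds
    else:
        compound_ids = tuple(compound_ids)
    p, _ = _transition_matrix(graph)
    n = graph.n_nodes
    a = (sp.identity(n, format="csc") - damping * p.T).tocsc()
    factor = spla.splu(a)
    rhs = np.zeros((n, len(compound_ids)))
    for j, cid in enumerate(compound_ids):
        rhs[graph.index[cid], j] = 1.0 - damping
    mat = factor.solve(rhs)
    return ResponseMatrix(graph.node_ids, compound_ids, mat, "pr")
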