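"""Resistance-distance validation on the reaction–compound graph.

Reported reactions are validated against an independent second compound set
(e.g. NMR-derived metabolites) by their effective resistance distance on the
unweighted, maximal connected subgraph induced on reaction and compound
nodes.  Treating each edge as a unit resistor,

    Omega(i, j) = L+_ii + L+_jj - 2 L+_ij

with L+ the Moore–Penrose pseudoinverse of the subgraph Laplacian.  The
resistance distance accounts for all parallel paths, so hub-mediated
shortcuts (ATP-like compounds) do not mask specific connections the way
shortest paths do.

The first-neighbour comparison tests, per target compound, whether the
reported reactions sit closer than the full set of reactions adjacent to any
input compound (one-sided Mann–Whitney rank-sum), with Benjamini–Hochberg
adjustment across all (solution × target) comparisons.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg, stats

from .graph import LevelledGraph

logger = logging.getLogger(__name__)


class ReactionCompoundGraph:
    """Largest connected reaction/compound subgraph with cached L+."""

    def __init__(self, graph: nx.Graph, node_order: Iterable[str]):
        self.graph = graph
        self.node_ids = tuple(node_order)
        self.index = {n: i for i, n in enumerate(self.node_ids)}
        self._lpinv: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def laplacian_pinv(self) -> np.ndarray:
        if self._lpinv is None:
            lap = nx.laplacian_matrix(self.graph, nodelist=list(self.node_ids)).toarray().astype(float)
            self._lpinv = linalg.pinvh(lap)
        return self._lpinv

    def reactions(self) -> tuple[str, ...]:
        return tuple(n for n in self.node_ids if self.graph.nodes[n]["level"] == "reaction")

    def compounds(self) -> tuple[str, ...]:
        return tuple(n for n in self.node_ids if self.graph.nodes[n]["level"] == "compound")


def reaction_compound_graph(graph: LevelledGraph) -> ReactionCompoundGraph:
    """Induced subgraph on reaction and compound levels, largest CC kept."""
    keep = [n for n in graph.node_ids if graph.level_of(n) in ("reaction", "compound")]
    sub = graph.undirected.subgraph(keep).copy()
    if sub.number_of_nodes() == 0 or not any(
        sub.nodes[n]["level"] == "reaction" for n in sub
    ):
        raise ValueError("graph has no reaction nodes: reaction-compound graph is empty")
    comps = sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c)))
    largest = comps[0]
    if len(comps) > 1:
        logger.info("reaction-compound graph: keeping largest CC (%d of %d nodes)", len(largest), sub.number_of_nodes())
    order = [n for n in keep if n in largest]
    return ReactionCompoundGraph(sub.subgraph(largest).copy(), order)


def resistance_distance(rc_graph: ReactionCompoundGraph, i: str, j: str, method: str = "pinv") -> float:
    """Effective resistance Omega(i, j) between two nodes (unit resistors)."""
    for node in (i, j):
        if node not in rc_graph.index:
            raise ValueError(f"node {node!r} is not in the reaction-compound graph")
    if i == j:
        return 0.0
    if method == "pinv":
        lp = rc_graph.laplacian_pinv
        a, b = rc_graph.index[i], rc_graph.index[j]
        return float(lp[a, a] + lp[b, b] - 2.0 * lp[a, b])
    if method == "grounded":
        return _resistance_grounded(rc_graph, i, j)
    raise ValueError(f"unknown method {method!r}")


def _resistance_grounded(rc_graph: ReactionCompoundGraph, i: str, j: str) -> float:
    """Kirchhoff route: ground node j, inject unit current at i.

    Solves the grounded Laplacian (row/column of j removed); the potential at
    i is the effective resistance.  Kept as an independent computation path
    against the pseudoinverse route.
    """
    lap = nx.laplacian_matrix(rc_graph.graph, nodelist=list(rc_graph.node_ids)).toarray().astype(float)
    a, b = rc_graph.index[i], rc_graph.index[j]
    keep = [k for k in range(rc_graph.n_nodes) if k != b]
    lg = lap[np.ix_(keep, keep)]
    rhs = np.zeros(len(keep))
    rhs[keep.index(a)] = 1.0
    potential = np.linalg.solve(lg, rhs)
    return float(potential[keep.index(a)])


def _distance_block(
    rc_graph: ReactionCompoundGraph, sources: list[str], targets: list[str]
) -> np.ndarray:
    lp = rc_graph.laplacian_pinv
    si = np.array([rc_graph.index[s] for s in sources])
    ti = np.array([rc_graph.index[t] for t in targets])
    diag = np.diag(lp)
    return diag[si][:, None] + diag[ti][None, :] - 2.0 * lp[np.ix_(si, ti)]


def _present(rc_graph: ReactionCompoundGraph, nodes: Iterable[str], what: str) -> list[str]:
    nodes = list(nodes)
    present = [n for n in nodes if n in rc_graph.index]
    missing = sorted(set(nodes) - set(present))
    if missing:
        logger.warning("%d %s node(s) outside the reaction-compound graph dropped: %s", len(missing), what, missing)
    return present


def reaction_distance_summary(
    rc_graph: ReactionCompoundGraph,
    reaction_set: Iterable[str],
    target_compounds: Iterable[str],
) -> pd.DataFrame:
    """Mean and SD of resistance distances from a reaction set to each target."""
    reactions = _present(rc_graph, reaction_set, "reaction")
    targets = _present(rc_graph, target_compounds, "target compound")
    if not reactions:
        raise ValueError("reaction set is empty after dropping absent nodes")
    if not targets:
        raise ValueError("target compound set is empty after dropping absent nodes")
    block = _distance_block(rc_graph, reactions, targets)
    return pd.DataFrame(
        {
            "target": targets,
            "mean": block.mean(axis=0),
            "sd": block.std(axis=0, ddof=1) if len(reactions) > 1 else np.zeros(len(targets)),
            "n_reactions": len(reactions),
        }
    )


def neighbour_reactions(rc_graph: ReactionCompoundGraph, input_compounds: Iterable[str]) -> tuple[str, ...]:
    """All reactions adjacent to any input compound (their first neighbours)."""
    inputs = _present(rc_graph, input_compounds, "input compound")
    out = set()
    for c in inputs:
        for nb in rc_graph.graph.neighbors(c):
            if rc_graph.graph.nodes[nb]["level"] == "reaction":
                out.add(nb)
    return tuple(sorted(out))


def neighbour_comparison(
    rc_graph: ReactionCompoundGraph,
    reported_reactions: Iterable[str],
    input_compounds: Iterable[str],
    target_compounds: Iterable[str],
    adjust: bool = True,
) -> pd.DataFrame:
    """Reported reactions vs first-neighbour reactions, per target compound.

    One-sided Mann–Whitney rank-sum test of reported distances being smaller;
    BH adjustment across the targets when ``adjust`` is set (use
    :func:`validation_table` to adjust across several solutions jointly).
    Degenerate comparisons (fewer than two reactions on either side) are
    flagged and given NaN p-values.
    """
    frame = _comparison_frame(rc_graph, {"reported": set(reported_reactions)}, input_compounds, target_compounds)
    if adjust:
        frame = _bh_adjust(frame)
    return frame.drop(columns=["solution"])


def _comparison_frame(
    rc_graph: ReactionCompoundGraph,
    solutions: Mapping[str, Iterable[str]],
    input_compounds: Iterable[str],
    target_compounds: Iterable[str],
) -> pd.DataFrame:
    targets = _present(rc_graph, target_compounds, "target compound")
    neighbours = list(neighbour_reactions(rc_graph, input_compounds))
    if not neighbours:
        raise ValueError("no first-neighbour reactions found for the input compounds")
    nb_block = _distance_block(rc_graph, neighbours, targets)
    rows = []
    for name, reactions in solutions.items():
        reported = _present(rc_graph, reactions, "reported reaction")
        if not reported:
            raise ValueError(f"solution {name!r} has no reactions inside the reaction-compound graph")
        rep_block = _distance_block(rc_graph, reported, targets)
        for t, target in enumerate(targets):
            rep, nb = rep_block[:, t], nb_block[:, t]
            if len(rep) < 2 or len(nb) < 2:
                p = np.nan
                logger.warning("comparison %s/%s skipped: fewer than two reactions on one side", name, target)
            else:
                p = stats.mannwhitneyu(rep, nb, alternative="less").pvalue
            rows.append(
                {
                    "solution": name,
                    "target": target,
                    "mean_reported": rep.mean(),
                    "sd_reported": rep.std(ddof=1) if len(rep) > 1 else 0.0,
                    "mean_neighbours": nb.mean(),
                    "sd_neighbours": nb.std(ddof=1) if len(nb) > 1 else 0.0,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def _bh_adjust(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    mask = frame["p_value"].notna().to_numpy()
    adjusted = np.full(len(frame), np.nan)
    if mask.any():
        adjusted[mask] = stats.false_discovery_control(frame.loc[mask, "p_value"].to_numpy())
    frame["p_adjusted"] = adjusted
    return frame


def validation_table(
    graph: LevelledGraph,
    solutions: Mapping[str, Iterable[str]],
    input_compounds: Iterable[str],
    target_compounds: Iterable[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance table and rank-sum tests for several solutions at once.

    Returns ``(summary, tests)``: the summary mirrors a mean(SD)-per-target
    layout with a whole-graph baseline row (all reactions) and a
    first-neighbours row followed by one row per solution; the tests frame
    carries the one-sided rank-sum p-values with BH adjustment across all
    (solution × target) comparisons.
    """
    rc = reaction_compound_graph(graph)
    targets = _present(rc, target_compounds, "target compound")
    rows: dict[str, Iterable[str]] = {
        "reaction-compound graph": rc.reactions(),
        "first neighbours": neighbour_reactions(rc, input_compounds),
    }
    rows.update(solutions)
    summaries = []
    for name, reactions in rows.items():
        s = reaction_distance_summary(rc, reactions, targets)
        s.insert(0, "set", name)
        summaries.append(s)
    tests = _bh_adjust(_comparison_frame(rc, solutions, input_compounds, targets))
    return pd.concat(summaries, ignore_index=True), tests
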