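"""Enrichment pipeline and reported artefacts.

Runs score → normalise → top-k selection, and summarises the induced
subgraph: connected components, pathways in the solution, overlap
coefficients between solutions, and the classical hypergeometric ORA
baseline (which the diffusion-plus-null machinery contains as a special
case on bipartite compound→pathway graphs).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import diffusion, nullmodel
from .graph import InputSet, LevelledGraph

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Full output of one enrichment run."""

    scores: nullmodel.NormalisedScores
    selected: tuple[str, ...]
    subgraph: nx.Graph
    n_cc: int
    largest_cc: int
    pathway_table: pd.DataFrame
    scores_frame: pd.DataFrame
    params: dict = field(default_factory=dict)


def _ranking_order(scores: nullmodel.NormalisedScores) -> list[str]:
    """Node ids ordered best-first by the deterministic ranking key.

    z statistic: descending z, then descending raw score, then id.
    p statistic: ascending p, then descending raw score, then id (many nodes
    tie at the minimal attainable p).
    Degenerate-null nodes are excluded.
    """
    mask = scores.rankable_mask()
    ids = [n for n, ok in zip(scores.node_ids, mask) if ok]
    raw = {n: scores.raw[i] for i, n in enumerate(scores.node_ids)}
    if scores.statistic == "z":
        stat = {n: scores.z[i] for i, n in enumerate(scores.node_ids)}
        return sorted(ids, key=lambda n: (-stat[n], -raw[n], n))
    stat = {n: scores.p[i] for i, n in enumerate(scores.node_ids)}
    return sorted(ids, key=lambda n: (stat[n], -raw[n], n))


def select_top_k(scores: nullmodel.NormalisedScores, k: int) -> tuple[str, ...]:
    """The k best rankable nodes, deterministic under ties."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = _ranking_order(scores)
    if k > len(order):
        logger.warning("k=%d exceeds the %d rankable nodes; truncating", k, len(order))
        k = len(order)
    return tuple(order[:k])


def cc_summary(subgraph: nx.Graph) -> tuple[int, int]:
    """(number of weak connected components, size of the largest one)."""
    if subgraph.number_of_nodes() == 0:
        return (0, 0)
    if subgraph.is_directed():
        comps = list(nx.weakly_connected_components(subgraph))
    else:
        comps = list(nx.connected_components(subgraph))
    return (len(comps), max(len(c) for c in comps))


def overlap_coefficient(set1: Iterable[str], set2: Iterable[str]) -> float:
    """|G1 ∩ G2| / min(|G1|, |G2|): similarity of two reported node sets."""
    s1, s2 = set(set1), set(set2)
    if not s1 or not s2:
        raise ValueError("overlap coefficient is undefined for empty sets")
    return len(s1 & s2) / min(len(s1), len(s2))


def ora_pathway_test(graph: LevelledGraph, input_set: InputSet, pathway: str) -> float:
    """One-tailed hypergeometric over-representation p-value for one pathway.

    Membership is reachability-based: a compound belongs to the pathway if
    the pathway can be reached from it in the directed view.  With N total
    compounds, K members and n input compounds, p = P(X >= hits) for
    X ~ Hypergeometric(N, K, n).
    """
    if graph.level_of(pathway) != "pathway":
        raise ValueError(f"{pathway!r} is not a pathway node")
    members = graph.pathway_membership()[pathway]
    n_total = len(graph.compounds)
    hits = len(members & input_set.compound_ids)
    return float(stats.hypergeom.sf(hits - 1, n_total, len(members), input_set.n_in))


def _pathway_table(
    graph: LevelledGraph,
    input_set: InputSet,
    selected: Sequence[str],
    scores: nullmodel.NormalisedScores,
) -> pd.DataFrame:
    membership = graph.pathway_membership()
    idx = {n: i for i, n in enumerate(scores.node_ids)}
    rows = []
    for node in selected:
        if graph.level_of(node) != "pathway":
            continue
        members = membership[node]
        stat = scores.values()[idx[node]]
        rows.append(
            {
                "id": node,
                "name": graph.undirected.nodes[node].get("name", ""),
                "statistic": stat,
                "raw_score": scores.raw[idx[node]],
                "n_reachable_compounds": len(members),
                "hits": len(members & input_set.compound_ids),
            }
        )
    return pd.DataFrame(rows, columns=["id", "name", "statistic", "raw_score", "n_reachable_compounds", "hits"])


def _scores_frame(
    graph: LevelledGraph,
    scores: nullmodel.NormalisedScores,
    null: nullmodel.NullMoments | None,
) -> pd.DataFrame:
    df = pd.DataFrame({"id": scores.node_ids, "level": graph.levels, "raw_score": scores.raw})
    if null is not None:
        df["mu"] = null.mu
        df["sigma"] = null.sigma
    df["z"] = scores.z if scores.z is not None else np.nan
    df["p"] = scores.p if scores.p is not None else np.nan
    return df


def enrich(
    graph: LevelledGraph,
    input_set: InputSet,
    method: str = "hd",
    approx: str = "norm",
    k: int = 250,
    damping: float = diffusion.DEFAULT_DAMPING,
    n_perm: int = 10000,
    n_vote: int = 9,
    seed: int = 0,
) -> EnrichmentResult:
    """Full enrichment pipeline.

    ``method`` selects heat diffusion (``hd``) or PageRank (``pr``);
    ``approx`` selects the parametric z-score route (``norm``) or Monte-Carlo
    permutations (``sim``).  In sim mode, ``n_vote`` independent runs of
    ``n_perm`` permutations each report their top k and a strict-majority
    consensus forms the solution, so the reported size may differ from k.
    """
    if method not in ("hd", "pr"):
        raise ValueError(f"unknown method {method!r}")
    if approx not in ("norm", "sim"):
        raise ValueError(f"unknown approx {approx!r}")

    if method == "hd":
        system = diffusion.conductance_system(graph)
        observed = diffusion.heat_diffusion_scores(system, input_set)
        response = diffusion.heat_response_matrix(system)
        normalise_columns = False
        linear_observed = observed
    else:
        observed = diffusion.pagerank_scores(graph, input_set, damping)
        response = diffusion.pagerank_response_matrix(graph, damping)
        normalise_columns = True
        # the analytic null lives on the pre-normalisation linear scale
        linear_observed = diffusion.ScoreVector(
            observed.node_ids,
            response.apply(graph.generation_vector(input_set)[
                [graph.index[c] for c in response.compound_ids]
            ]),
            "pr",
        )

    moments = nullmodel.null_input_moments(len(graph.compounds), input_set.n_in)
    null = nullmodel.analytic_null_moments(response, moments)

    if approx == "norm":
        scores = nullmodel.zscore_normalise(linear_observed, null)
        selected = select_top_k(scores, k)
    else:
        solutions = []
        first_scores = None
        for vote in range(n_vote):
            mc = nullmodel.monte_carlo_pvalues(
                response, graph, input_set.n_in, observed,
                n_perm=n_perm, seed=(seed, vote), normalise_columns=normalise_columns,
            )
            if first_scores is None:
                first_scores = mc
            solutions.append(select_top_k(mc, k))
        consensus = nullmodel.consensus_vote(solutions, n_vote)
        scores = first_scores
        selected = tuple(n for n in _ranking_order(scores) if n in consensus)

    subgraph = graph.induced_subgraph(selected)
    n_cc, largest = cc_summary(subgraph)
    result = EnrichmentResult(
        scores=scores,
        selected=selected,
        subgraph=subgraph,
        n_cc=n_cc,
        largest_cc=largest,
        pathway_table=_pathway_table(graph, input_set, selected, scores),
        scores_frame=_scores_frame(graph, scores, null),
        params={
            "method": method, "approx": approx, "k": k, "damping": damping,
            "n_perm": n_perm, "n_vote": n_vote, "seed": seed, "n_in": input_set.n_in,
        },
    )
    return result
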