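"""Levelled metabolic knowledge graphs.

A knowledge graph in the KEGG style stratifies its nodes into five levels —
compound, reaction, enzyme, module and pathway — with edges linking annotated
entities across levels.  This module loads, validates, writes and synthesises
such graphs, and maps user compound lists onto them.

The graph carries two coupled views: the undirected view used by heat
diffusion, and a directed view with every edge oriented from the lower level
toward the strictly higher one (compound → reaction → enzyme → module →
pathway), used by PageRank and by reachability-based pathway membership.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Levels from bottom to top; edge orientation follows this order.
LEVELS = ("compound", "reaction", "enzyme", "module", "pathway")
LEVEL_RANK = {level: rank for rank, level in enumerate(LEVELS)}

#: Adjacent-level pairs allowed by the working schema, plus the
#: enzyme–pathway shortcut (a pathway can be reachable with no compound
#: members, through enzymes only).
SCHEMA_PAIRS = frozenset(
    {
        ("compound", "reaction"),
        ("reaction", "enzyme"),
        ("enzyme", "module"),
        ("module", "pathway"),
        ("enzyme", "pathway"),
    }
)

_LEVEL_PREFIX = {
    "pathway": "P",
    "module": "M",
    "enzyme": "E",
    "reaction": "R",
    "compound": "C",
}


@dataclass(frozen=True)
class NodeRecord:
    """A single graph node: opaque id, level label and optional display name."""

    id: str
    level: str
    name: str = ""


@dataclass(frozen=True)
class InputSet:
    """A user compound list mapped onto a graph.

    ``compound_ids`` holds the matched, deduplicated compound node ids;
    ``dropped`` the identifiers that could not be matched (unknown or not at
    compound level).
    """

    compound_ids: frozenset[str]
    dropped: tuple[str, ...] = ()

    @property
    def n_in(self) -> int:
        return len(self.compound_ids)

    def sorted_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.compound_ids))


class LevelledGraph:
    """Validated levelled knowledge graph with a fixed node ordering.

    Parameters
    ----------
    graph:
        Undirected :class:`networkx.Graph`; every node must carry a ``level``
        attribute from :data:`LEVELS`.  Self-loops and same-level edges are
        rejected; cross-level edges outside the working schema are accepted
        with a warning.
    node_order:
        Optional explicit node ordering (defaults to graph insertion order).
        All matrix representations downstream use this ordering.
    """

    def __init__(self, graph: nx.Graph, node_order: Sequence[str] | None = None):
        if graph.number_of_nodes() == 0:
            raise ValueError("graph has no nodes")
        self._g = graph
        if node_order is None:
            node_order = list(graph.nodes())
        if set(node_order) != set(graph.nodes()) or len(node_order) != graph.number_of_nodes():
            raise ValueError("node_order must be a permutation of the graph nodes")
        self.node_ids: tuple[str, ...] = tuple(node_order)
        self.index: dict[str, int] = {nid: i for i, nid in enumerate(self.node_ids)}
        self._validate()
        self.levels: tuple[str, ...] = tuple(graph.nodes[n]["level"] for n in self.node_ids)
        self._directed: nx.DiGraph | None = None
        self._membership: dict[str, frozenset[str]] | None = None

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        g = self._g
        off_schema: dict[tuple[str, str], int] = {}
        for n, data in g.nodes(data=True):
            level = data.get("level")
            if level not in LEVEL_RANK:
                raise ValueError(f"node {n!r} has unknown level {level!r}; expected one of {LEVELS}")
        for u, v in g.edges():
            if u == v:
                raise ValueError(f"self-loop on node {u!r} is not allowed")
            lu, lv = g.nodes[u]["level"], g.nodes[v]["level"]
            if lu == lv:
                raise ValueError(f"edge {u!r}–{v!r} joins two {lu!r} nodes; same-level edges are not allowed")
            pair = tuple(sorted((lu, lv), key=LEVEL_RANK.get))
            if pair not in SCHEMA_PAIRS:
                off_schema[pair] = off_schema.get(pair, 0) + 1
        if off_schema:
            desc = ", ".join(f"{a}–{b} (x{n})" for (a, b), n in sorted(off_schema.items()))
            logger.warning("graph contains %d edge(s) outside the adjacent-level schema: %s", sum(off_schema.values()), desc)

    # -- basic accessors ----------------------------------------------------

    @property
    def undirected(self) -> nx.Graph:
        return self._g

    @property
    def directed(self) -> nx.DiGraph:
        """Directed view: every edge oriented toward the strictly higher level."""
        if self._directed is None:
            d = nx.DiGraph()
            d.add_nodes_from((n, self._g.nodes[n]) for n in self.node_ids)
            for u, v in self._g.edges():
                if LEVEL_RANK[self._g.nodes[u]["level"]] < LEVEL_RANK[self._g.nodes[v]["level"]]:
                    d.add_edge(u, v)
                else:
                    d.add_edge(v, u)
            self._directed = d
        return self._directed

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def level_of(self, node_id: str) -> str:
        return self._g.nodes[node_id]["level"]

    def nodes_at(self, level: str) -> tuple[str, ...]:
        if level not in LEVEL_RANK:
            raise ValueError(f"unknown level {level!r}")
        return tuple(n for n, lv in zip(self.node_ids, self.levels) if lv == level)

    @property
    def compounds(self) -> tuple[str, ...]:
        return self.nodes_at("compound")

    @property
    def pathways(self) -> tuple[str, ...]:
        return self.nodes_at("pathway")

    @property
    def reactions(self) -> tuple[str, ...]:
        return self.nodes_at("reaction")

    @property
    def level_counts(self) -> dict[str, int]:
        counts = {level: 0 for level in LEVELS}
        for lv in self.levels:
            counts[lv] += 1
        return counts

    def records(self) -> tuple[NodeRecord, ...]:
        return tuple(
            NodeRecord(n, self._g.nodes[n]["level"], self._g.nodes[n].get("name", ""))
            for n in self.node_ids
        )

    def is_connected(self) -> bool:
        return nx.is_connected(self._g)

    def generation_vector(self, input_set: InputSet) -> np.ndarray:
        """Indicator vector G with G_i = 1 on the input compounds."""
        g = np.zeros(self.n_nodes)
        for cid in input_set.compound_ids:
            g[self.index[cid]] = 1.0
        return g

    def induced_subgraph(self, node_ids: Iterable[str]) -> nx.Graph:
        return self._g.subgraph(list(node_ids)).copy()

    def pathway_membership(self) -> dict[str, frozenset[str]]:
        """Compounds from which each pathway is reachable in the directed view.

        This reachability rule (rather than direct annotation edges) defines
        pathway membership for the ORA baseline and the proportional signal
        scheme; computed once and cached.
        """
        if self._membership is None:
            rev = self.directed.reverse(copy=False)
            compounds = set(self.compounds)
            membership = {}
            for p in self.pathways:
                reach = nx.descendants(rev, p)
                membership[p] = frozenset(reach & compounds)
            self._membership = membership
        return self._membership


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------


def _as_frame(source, columns: Sequence[str], what: str) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing column(s) {missing}; found {list(df.columns)}")
    return df


def load_graph(node_table, edge_table, restrict_to_largest_cc: bool = True) -> LevelledGraph:
    """Build a :class:`LevelledGraph` from node and edge tables.

    ``node_table`` needs columns ``id``/``level`` (``name`` optional);
    ``edge_table`` needs ``source``/``target``.  Tables may be paths to TSV
    files or DataFrames.  Edge endpoints absent from the node table are
    rejected with the offending row.  With ``restrict_to_largest_cc`` only the
    largest connected component is kept, matching a curated single-component
    working graph.
    """
    nodes = _as_frame(node_table, ("id", "level"), "node")
    edges = _as_frame(edge_table, ("source", "target"), "edge")

    if nodes["id"].duplicated().any():
        dup = nodes.loc[nodes["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate node id {dup!r} in node table")

    g = nx.Graph()
    for row in nodes.itertuples(index=False):
        g.add_node(row.id, level=row.level, name=getattr(row, "name", ""))

    known = set(nodes["id"])
    for i, row in enumerate(edges.itertuples(index=False)):
        for endpoint in (row.source, row.target):
            if endpoint not in known:
                raise ValueError(f"edge row {i} ({row.source!r}, {row.target!r}): endpoint {endpoint!r} is not in the node table")
        g.add_edge(row.source, row.target)

    order = list(nodes["id"])
    if restrict_to_largest_cc and g.number_of_nodes() and not nx.is_connected(g):
        comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
        keep = comps[0]
        dropped = g.number_of_nodes() - len(keep)
        logger.info("restricting to largest connected component: dropped %d node(s)", dropped)
        g = g.subgraph(keep).copy()
        order = [n for n in order if n in keep]
    return LevelledGraph(g, node_order=order)


def write_graph(graph: LevelledGraph, node_path, edge_path) -> None:
    """Write node and edge TSV tables (inverse of :func:`load_graph`)."""
    pd.DataFrame(
        {
            "id": graph.node_ids,
            "level": graph.levels,
            "name": [graph.undirected.nodes[n].get("name", "") for n in graph.node_ids],
        }
    ).to_csv(node_path, sep="\t", index=False)
    pd.DataFrame(graph.undirected.edges(), columns=["source", "target"]).to_csv(
        edge_path, sep="\t", index=False
    )


def write_graphml(graph: LevelledGraph, path) -> None:
    """Export to GraphML, preserving the ``level`` (and ``name``) attributes."""
    nx.write_graphml(graph.undirected, path)


def load_graphml(path, restrict_to_largest_cc: bool = True) -> LevelledGraph:
    g = nx.read_graphml(path)
    g = nx.Graph(g)
    order = list(g.nodes())
    if restrict_to_largest_cc and not nx.is_connected(g):
        comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
        g = g.subgraph(comps[0]).copy()
        order = [n for n in order if n in g]
    return LevelledGraph(g, node_order=order)


def read_compound_list(path) -> list[str]:
    """Plain-text compound list: one identifier per line, ``#`` comments allowed."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    return ids


def map_input(graph: LevelledGraph, id_list: Sequence[str]) -> InputSet:
    """Map a user identifier list onto the graph's compound nodes.

    Unmatched or non-compound identifiers are recorded in ``dropped`` and
    logged; an entirely unmatched list is an error (nothing to diffuse).
    """
    if not id_list:
        raise ValueError("input identifier list is empty")
    seen: set[str] = set()
    matched: set[str] = set()
    dropped: list[str] = []
    compounds = set(graph.compounds)
    for ident in id_list:
        if ident in seen:
            continue
        seen.add(ident)
        if ident in compounds:
            matched.add(ident)
        else:
            dropped.append(ident)
    if dropped:
        logger.warning("%d identifier(s) not mapped to graph compounds: %s", len(dropped), dropped)
    if not matched:
        raise ValueError("no input identifier maps to a compound node in the graph")
    return InputSet(frozenset(matched), tuple(dropped))


# ---------------------------------------------------------------------------
# Synthetic graph generation
# ---------------------------------------------------------------------------

#: Mean number of cross-level edges drawn per source node, keyed by
#: (source level, target level).  Sources sit above targets except for the
#: enzyme–pathway shortcut where the pathway draws enzymes directly.
DEFAULT_DENSITY: dict[tuple[str, str], float] = {
    ("reaction", "compound"): 2.5,
    ("enzyme", "reaction"): 3.0,
    ("module", "enzyme"): 3.0,
    ("pathway", "module"): 1.5,
    ("pathway", "enzyme"): 1.0,
}

#: Level sizes of the curated human KEGG working graph, usable as a
#: full-scale generator configuration.
KEGG_SCALE_SIZES: dict[str, int] = {
    "pathway": 288,
    "module": 178,
    "enzyme": 1149,
    "reaction": 4699,
    "compound": 3869,
}


def _coerce_level_sizes(level_sizes) -> dict[str, int]:
    if isinstance(level_sizes, Mapping):
        sizes = {str(k): int(v) for k, v in level_sizes.items()}
    else:
        seq = list(level_sizes)
        if len(seq) != 5:
            raise ValueError("level_sizes sequence must have 5 entries (pathway, module, enzyme, reaction, compound)")
        sizes = dict(zip(("pathway", "module", "enzyme", "reaction", "compound"), map(int, seq)))
    unknown = set(sizes) - set(LEVELS)
    if unknown:
        raise ValueError(f"unknown level(s) in level_sizes: {sorted(unknown)}")
    for level in LEVELS:
        if sizes.get(level, 0) < 1:
            raise ValueError(f"level {level!r} must have at least one node")
    return sizes


def _preferential_edges(
    rng: np.random.Generator,
    n_src: int,
    n_tgt: int,
    rate: float,
    alpha: float,
    tgt_degree: np.ndarray,
) -> list[tuple[int, int]]:
    """Bipartite preferential attachment with staggered target activation.

    Each source draws ``1 + Poisson(rate - 1)`` targets.  Targets become
    eligible on an evenly spaced schedule over the edge sequence and are
    chosen with probability proportional to ``(degree + 1)**alpha``; this
    Yule-type growth yields a heavy-tailed target degree distribution.
    ``tgt_degree`` is updated in place so attachment pressure can be shared
    across level pairs targeting the same level.
    """
    m = 1 + rng.poisson(max(rate - 1.0, 0.0), size=n_src)
    total = int(m.sum())
    order = rng.permutation(n_tgt)
    activation = np.floor(np.arange(n_tgt) * total / max(n_tgt, 1)).astype(int)
    n_active = 0
    edges: list[tuple[int, int]] = []
    e = 0
    for s in range(n_src):
        chosen: set[int] = set()
        for _ in range(int(m[s])):
            while n_active < n_tgt and activation[n_active] <= e:
                n_active += 1
            n_active = max(n_active, 1)
            active = order[:n_active]
            w = (tgt_degree[active] + 1.0) ** alpha
            w /= w.sum()
            t = -1
            for _attempt in range(20):
                cand = int(active[rng.choice(n_active, p=w)])
                if cand not in chosen:
                    t = cand
                    break
            e += 1
            if t < 0:
                continue  # tiny target level saturated for this source
            chosen.add(t)
            tgt_degree[t] += 1.0
            edges.append((s, t))
    return edges


def generate_synthetic_graph(
    level_sizes=KEGG_SCALE_SIZES,
    attachment_exponent: float = 1.0,
    cross_level_density: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> LevelledGraph:
    """Generate a connected 5-level graph emulating the KEGG graph's shape.

    Edges run only between adjacent levels, plus enzyme–pathway shortcuts, so
    that a module or pathway can be reachable with no compound members.
    Degrees are heavy-tailed through preferential attachment within each level
    pair.  Bit-reproducible for a fixed ``seed`` and configuration.
    """
    sizes = _coerce_level_sizes(level_sizes)
    if attachment_exponent <= 0:
        raise ValueError("attachment_exponent must be positive")
    density = dict(DEFAULT_DENSITY)
    if cross_level_density:
        density.update(cross_level_density)
    rng = np.random.default_rng(seed)

    ids = {
        level: [f"{_LEVEL_PREFIX[level]}{i + 1:05d}" for i in range(sizes[level])]
        for level in LEVELS
    }
    g = nx.Graph()
    for level in ("compound", "reaction", "enzyme", "module", "pathway"):
        g.add_nodes_from((n, {"level": level, "name": n}) for n in ids[level])

    degree = {level: np.zeros(sizes[level]) for level in LEVELS}
    for (src_level, tgt_level) in (
        ("reaction", "compound"),
        ("enzyme", "reaction"),
        ("module", "enzyme"),
        ("pathway", "module"),
        ("pathway", "enzyme"),
    ):
        rate = density.get((src_level, tgt_level), 0.0)
        if rate <= 0:
            continue
        pairs = _preferential_edges(
            rng, sizes[src_level], sizes[tgt_level], rate, attachment_exponent, degree[tgt_level]
        )
        for s, t in pairs:
            g.add_edge(ids[src_level][s], ids[tgt_level][t])

    _repair_connectivity(g, rng)
    order = list(itertools.chain.from_iterable(ids[level] for level in ("compound", "reaction", "enzyme", "module", "pathway")))
    graph = LevelledGraph(g, node_order=order)
    if not graph.is_connected():  # pragma: no cover - repair guarantees this
        raise RuntimeError("synthetic graph is disconnected after repair")
    return graph


def _repair_connectivity(g: nx.Graph, rng: np.random.Generator) -> None:
    """Merge secondary components into the largest one with schema edges."""
    partner_level = {
        "compound": "reaction",
        "reaction": "compound",
        "enzyme": "reaction",
        "module": "enzyme",
        "pathway": "module",
    }
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    if len(comps) <= 1:
        return
    main = set(comps[0])
    main_by_level: dict[str, list[str]] = {}
    for n in sorted(main):
        main_by_level.setdefault(g.nodes[n]["level"], []).append(n)
    for comp in comps[1:]:
        u = min(comp)
        lu = g.nodes[u]["level"]
        target_level = partner_level[lu]
        candidates = main_by_level.get(target_level) or next(
            main_by_level[lv] for lv in LEVELS if main_by_level.get(lv)
        )
        w = np.array([g.degree(c) + 1.0 for c in candidates])
        v = candidates[int(rng.choice(len(candidates), p=w / w.sum()))]
        g.add_edge(u, v)
        for n in sorted(comp):
            main.add(n)
            main_by_level.setdefault(g.nodes[n]["level"], []).append(n)


def powerlaw_exponent_mle(degrees: Sequence[int], kmin: int = 2) -> float:
    """Continuous maximum-likelihood estimate of a power-law tail exponent.

    Uses the standard Hill-type estimator with the discrete half-shift,
    ``gamma = 1 + n / sum(log(k / (kmin - 0.5)))`` over degrees ``>= kmin``.
    """
    k = np.asarray(degrees, dtype=float)
    k = k[k >= kmin]
    if k.size < 10:
        raise ValueError("too few observations above kmin to fit a tail exponent")
    return 1.0 + k.size / np.sum(np.log(k / (kmin - 0.5)))


# ---------------------------------------------------------------------------
# Toy graphs
# ---------------------------------------------------------------------------


def bipartite_ora_graph(pathway_sizes: Sequence[int], prefix: str = "pw") -> LevelledGraph:
    """Compound→pathway toy where each compound belongs to exactly one pathway.

    On this family a pathway's stationary temperature equals its hit count, so
    classical over-representation analysis appears as a special case of the
    diffusion-plus-null-model machinery (the null distribution of a pathway's
    temperature is hypergeometric).  ``pathway_sizes`` gives the number of
    member compounds of each pathway (labelled A, B, C, ...).
    """
    if not pathway_sizes or any(s < 1 for s in pathway_sizes):
        raise ValueError("pathway_sizes must be positive")
    g = nx.Graph()
    order: list[str] = []
    n_c = 0
    pathway_ids = []
    for i, size in enumerate(pathway_sizes):
        label = chr(ord("A") + i)
        pid = f"{prefix}_{label}"
        pathway_ids.append((pid, size))
        g.add_node(pid, level="pathway", name=f"pathway {label}")
    for pid, size in pathway_ids:
        for _ in range(size):
            n_c += 1
            cid = f"cpd_{n_c:02d}"
            g.add_node(cid, level="compound", name=cid)
            g.add_edge(cid, pid)
            order.append(cid)
    order.extend(pid for pid, _ in pathway_ids)
    return LevelledGraph(g, node_order=order)
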