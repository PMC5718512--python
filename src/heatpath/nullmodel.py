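"""Null models and score normalisation.

The null hypothesis is an input of ``n_in`` compounds drawn uniformly at
random without replacement from the graph's compound nodes.  The indicator
vector X of such a draw has dependent Bernoulli entries with

    E(X_i)      = p            = n_in / n_compounds
    Var(X_i)    = p (1 - p)
    Cov(X_i,Xj) = -p (1 - p) / (n_compounds - 1)   (i != j)

Because the scores are linear in the input indicator (T = R X), the null
moments of every node follow in closed form:

    mu    = R E(X)
    sigma_i^2 = (R Sigma(X) R^T)_ii

computed row-wise without materialising the covariance.  Observed scores are
normalised either parametrically (z-scores) or empirically via Monte-Carlo
permutations with the corrected tail estimate p = (r + 1) / (n_perm + 1).
"""

from __future__ import annotations

import itertools
import logging
import math
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .diffusion import ResponseMatrix, ScoreVector
from .graph import InputSet, LevelledGraph

logger = logging.getLogger(__name__)

#: Slack used when counting null scores >= observed, so that exact score ties
#: (e.g. integer hit counts reproduced by a float linear solve) are counted as
#: ties rather than split by 1e-15 solver noise.
TIE_TOLERANCE = 1e-9

#: Sigma below this is treated as a degenerate (deterministic) null.
DEGENERATE_SIGMA = 1e-12


@dataclass(frozen=True)
class InputMoments:
    """First and second moments of the without-replacement input indicators."""

    n_compounds: int
    n_in: int

    @property
    def mean(self) -> float:
        return self.n_in / self.n_compounds

    @property
    def var(self) -> float:
        p = self.mean
        return p * (1.0 - p)

    @property
    def cov(self) -> float:
        if self.n_compounds == 1:
            return 0.0
        return -self.var / (self.n_compounds - 1)


def null_input_moments(n_compounds: int, n_in: int) -> InputMoments:
    if not 1 <= n_in <= n_compounds:
        raise ValueError(f"need 1 <= n_in <= n_compounds, got n_in={n_in}, n_compounds={n_compounds}")
    return InputMoments(n_compounds, n_in)


@dataclass
class NullMoments:
    """Per-node null mean and standard deviation of the scores."""

    node_ids: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray

    @property
    def degenerate(self) -> np.ndarray:
        return self.sigma <= DEGENERATE_SIGMA


def analytic_null_moments(response: ResponseMatrix, moments: InputMoments) -> NullMoments:
    """Closed-form null moments of the scores from the response matrix.

    With r the rows of R over compound columns, s1 = sum(r) and s2 = sum(r^2):

        mu_i      = p s1_i
        sigma_i^2 = Var s2_i + Cov (s1_i^2 - s2_i)
    """
    if len(response.compound_ids) != moments.n_compounds:
        raise ValueError(
            f"response has {len(response.compound_ids)} compound columns but moments "
            f"were built for {moments.n_compounds} compounds"
        )
    r = response.matrix
    s1 = r.sum(axis=1)
    s2 = (r * r).sum(axis=1)
    mu = moments.mean * s1
    var = moments.var * s2 + moments.cov * (s1 * s1 - s2)
    sigma = np.sqrt(np.clip(var, 0.0, None))
    return NullMoments(response.node_ids, mu, sigma)


@dataclass
class NormalisedScores:
    """Normalised per-node statistics: z-scores (norm) or empirical p (sim)."""

    node_ids: tuple[str, ...]
    raw: np.ndarray
    statistic: str  # "z" | "p"
    z: np.ndarray | None = None
    p: np.ndarray | None = None
    degenerate: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def values(self) -> np.ndarray:
        return self.z if self.statistic == "z" else self.p

    def rankable_mask(self) -> np.ndarray:
        if self.degenerate is None:
            return np.ones(len(self.node_ids), dtype=bool)
        return ~self.degenerate


def zscore_normalise(scores: ScoreVector, null: NullMoments) -> NormalisedScores:
    """z_i = (T_i - mu_i) / sigma_i; degenerate-null nodes flagged, not inf."""
    if scores.node_ids != null.node_ids:
        raise ValueError("scores and null moments use different node orderings")
    degenerate = null.degenerate
    z = np.full(len(scores.node_ids), np.nan)
    ok = ~degenerate
    z[ok] = (scores.values[ok] - null.mu[ok]) / null.sigma[ok]
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning("%d node(s) have a degenerate null (sigma = 0) and are excluded from ranking", n_deg)
    return NormalisedScores(
        scores.node_ids, scores.values, "z", z=z, degenerate=degenerate,
        meta={"method": scores.method, "approx": "norm"},
    )


# ---------------------------------------------------------------------------
# Monte-Carlo normalisation
# ---------------------------------------------------------------------------


def _null_draw(compounds: tuple[str, ...], n_in: int, seed_key: tuple) -> InputSet:
    rng = np.random.default_rng(seed_key)
    chosen = rng.choice(len(compounds), size=n_in, replace=False)
    return InputSet(frozenset(compounds[i] for i in chosen))


def _as_seed_tuple(seed) -> tuple:
    return tuple(seed) if isinstance(seed, (tuple, list)) else (int(seed),)


def monte_carlo_pvalues(
    scorer: Callable[[InputSet], ScoreVector] | ResponseMatrix,
    graph: LevelledGraph,
    n_in: int,
    observed: ScoreVector,
    n_perm: int = 10000,
    seed=0,
    normalise_columns: bool = False,
) -> NormalisedScores:
    """Empirical p-values p_i = (r_i + 1) / (n_perm + 1).

    ``r_i`` counts permutations whose null score is greater than or equal to
    the observed one (up to :data:`TIE_TOLERANCE`).  ``scorer`` is either a
    scoring callable or a :class:`ResponseMatrix`, in which case all null
    scores are obtained by one matrix product (with per-draw L1 column
    normalisation when ``normalise_columns`` is set, for sum-to-one PageRank).
    Permutation t draws from its own counter-derived RNG stream, so results
    are reproducible and extending ``n_perm`` does not reshuffle earlier
    draws.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    compounds = graph.compounds
    if not 1 <= n_in <= len(compounds):
        raise ValueError("n_in outside [1, number of compounds]")
    base = _as_seed_tuple(seed)
    obs = observed.values
    r = np.zeros(len(obs), dtype=np.int64)
    if isinstance(scorer, ResponseMatrix):
        col_index = {c: j for j, c in enumerate(scorer.compound_ids)}
        batch = 1000
        for start in range(0, n_perm, batch):
            stop = min(start + batch, n_perm)
            x = np.zeros((len(compounds), stop - start))
            for t in range(start, stop):
                draw = _null_draw(compounds, n_in, base + (t,))
                for cid in draw.compound_ids:
                    x[col_index[cid], t - start] = 1.0
            null_scores = scorer.matrix @ x
            if normalise_columns:
                null_scores = null_scores / null_scores.sum(axis=0, keepdims=True)
            r += (null_scores >= obs[:, None] - TIE_TOLERANCE).sum(axis=1)
    else:
        for t in range(n_perm):
            draw = _null_draw(compounds, n_in, base + (t,))
            null_scores = scorer(draw).values
            r += null_scores >= obs - TIE_TOLERANCE
    p = (r + 1.0) / (n_perm + 1.0)
    return NormalisedScores(
        observed.node_ids, obs, "p", p=p,
        meta={"method": observed.method, "approx": "sim", "n_perm": n_perm, "seed": base},
    )


def exhaustive_pvalues(
    scorer: Callable[[InputSet], ScoreVector] | ResponseMatrix,
    graph: LevelledGraph,
    n_in: int,
    observed: ScoreVector,
    max_draws: int = 200_000,
) -> NormalisedScores:
    """Exact permutation p-values by enumerating every possible input draw.

    Feasible only when C(n_compounds, n_in) is small; used to verify that the
    diffusion null reduces to the hypergeometric distribution on
    over-representation toys.  Here p_i = #{draws: null >= observed} / #draws
    (no +1 correction: the enumeration is exhaustive, not sampled).
    """
    compounds = graph.compounds
    n_draws = math.comb(len(compounds), n_in)
    if n_draws > max_draws:
        raise ValueError(f"enumeration of {n_draws} draws exceeds max_draws={max_draws}")
    obs = observed.values
    r = np.zeros(len(obs), dtype=np.int64)
    if isinstance(scorer, ResponseMatrix):
        col_index = {c: j for j, c in enumerate(scorer.compound_ids)}
        for combo in itertools.combinations(compounds, n_in):
            x = np.zeros(len(compounds))
            for cid in combo:
                x[col_index[cid]] = 1.0
            r += scorer.matrix @ x >= obs - TIE_TOLERANCE
    else:
        for combo in itertools.combinations(compounds, n_in):
            null_scores = scorer(InputSet(frozenset(combo))).values
            r += null_scores >= obs - TIE_TOLERANCE
    p = r / n_draws
    return NormalisedScores(
        observed.node_ids, obs, "p", p=p,
        meta={"method": observed.method, "approx": "exhaustive", "n_draws": n_draws},
    )


def sample_null_scores(
    response: ResponseMatrix,
    n_in: int,
    n_perm: int,
    seed=0,
    normalise_columns: bool = False,
) -> np.ndarray:
    """Matrix of null score vectors (nodes x permutations) under the null draw."""
    compounds = response.compound_ids
    base = _as_seed_tuple(seed)
    x = np.zeros((len(compounds), n_perm))
    for t in range(n_perm):
        rng = np.random.default_rng(base + (t,))
        chosen = rng.choice(len(compounds), size=n_in, replace=False)
        x[chosen, t] = 1.0
    scores = response.matrix @ x
    if normalise_columns:
        scores = scores / scores.sum(axis=0, keepdims=True)
    return scores


def consensus_vote(solutions: Sequence[Iterable[str]], n_vote: int | None = None) -> frozenset[str]:
    """Strict-majority consensus over reported node sets.

    A node is kept iff it appears in at least ceil((n_vote + 1) / 2) of the
    ``n_vote`` solutions; with an odd vote count no tie can arise.  The output
    size need not equal the per-run k.
    """
    sets = [frozenset(s) for s in solutions]
    if not sets:
        raise ValueError("no solutions to vote over")
    if n_vote is None:
        n_vote = len(sets)
    if n_vote != len(sets):
        raise ValueError(f"expected {n_vote} solutions, got {len(sets)}")
    threshold = (n_vote + 2) // 2  # ceil((n_vote + 1) / 2)
    counts: dict[str, int] = {}
    for s in sets:
        for node in s:
            counts[node] = counts.get(node, 0) + 1
    return frozenset(n for n, c in counts.items() if c >= threshold)


def hd_scorer(system) -> Callable[[InputSet], ScoreVector]:
    """Heat-diffusion scoring closure over a fixed conductance system."""
    from .diffusion import heat_diffusion_scores

    return lambda input_set: heat_diffusion_scores(system, input_set)


def pr_scorer(graph: LevelledGraph, damping: float = 0.85) -> Callable[[InputSet], ScoreVector]:
    """PageRank scoring closure with fixed damping."""
    from .diffusion import pagerank_scores

    return lambda input_set: pagerank_scores(graph, input_set, damping)
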