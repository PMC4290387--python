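"""Gaussian Bayesian-network structure learning over marks and expression.

The joint distribution of the five mark enrichment levels and the gene
expression level (per gene, averaged across individuals) is modelled as a
Gaussian Bayesian network.  Structure search is greedy hill climbing over
add/delete/reverse edge moves, scoring graphs with the decomposable
Bayesian-Gaussian-equivalent (BGe) marginal likelihood plus a
sparsity-inducing edge prior (per-edge per-direction prior inclusion
probability, default 1%).  A blacklist forbids edges from RNA back into the
marks, encoding the biological direction constraint; it is honoured at
every move.  A BIC-Gaussian score is available as an alternative.

For testing, an exhaustive enumerator finds the global optimum over all
DAGs on up to four nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from math import lgamma, log, pi

import numpy as np
import pandas as pd

from epimarks.constants import MARKS, RNA_NODE


@dataclass
class NetScoreConfig:
    """Score settings: edge prior and the Gaussian score family."""

    edge_prior: float = 0.01
    score: str = "bge"  # "bge" | "bic"
    alpha_mu: float = 1.0
    alpha_w: float | None = None  # defaults to d + 2 at fit time

    def __post_init__(self) -> None:
        if not 0.0 < self.edge_prior < 1.0:
            raise ValueError("edge prior must lie strictly in (0, 1)")
        if self.score not in ("bge", "bic"):
            raise ValueError("score must be 'bge' or 'bic'")


def rna_blacklist(nodes: list[str]) -> set[tuple[str, str]]:
    """Forbid directed edges from RNA into any mark."""
    return {(RNA_NODE, v) for v in nodes if v != RNA_NODE}


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    arr = np.asarray(data, dtype=float)
    return arr, [f"V{i}" for i in range(arr.shape[1])]


class _ScoreCache:
    """Per-node local scores with memoization over parent sets."""

    def __init__(self, data: np.ndarray, nodes: list[str], config: NetScoreConfig):
        self.nodes = nodes
        self.config = config
        self.n, self.d = data.shape
        self.data = data
        mean = data.mean(axis=0)
        centered = data - mean
        self.s_n = centered.T @ centered
        alpha_w = config.alpha_w if config.alpha_w is not None else self.d + 2.0
        self.alpha_w = alpha_w
        self.alpha_mu = config.alpha_mu
        self.t_scale = config.alpha_mu * (alpha_w - self.d - 1) / (config.alpha_mu + 1)
        if self.t_scale <= 0:
            raise ValueError("alpha_w too small for the BGe reference prior")
        # with the prior mean at the sample mean, R = T + S_N
        self.r = self.t_scale * np.eye(self.d) + self.s_n
        self._subset_cache: dict[frozenset, float] = {}
        self._local_cache: dict[tuple[int, frozenset], float] = {}
        self.log_edge_odds = log(config.edge_prior) - log(1.0 - config.edge_prior)

    # -- BGe ---------------------------------------------------------------

    def _log_p_subset(self, subset: frozenset) -> float:
        """log marginal likelihood of the data restricted to a node subset."""
        if not subset:
            return 0.0
        cached = self._subset_cache.get(subset)
        if cached is not None:
            return cached
        idx = sorted(subset)
        l = len(idx)
        n, d = self.n, self.d
        a_w, a_mu = self.alpha_w, self.alpha_mu

        def lgamma_l(a: float) -> float:
            return l * (l - 1) / 4.0 * log(pi) + sum(
                lgamma(a + (1 - j) / 2.0) for j in range(1, l + 1)
            )

        t_sub_logdet = l * log(self.t_scale)
        r_sub = self.r[np.ix_(idx, idx)]
        sign, r_logdet = np.linalg.slogdet(r_sub)
        if sign <= 0:
            raise ValueError("non-positive-definite posterior scatter matrix")
        val = (
            -0.5 * l * n * log(2 * pi)
            + 0.5 * l * (log(a_mu) - log(n + a_mu))
            + lgamma_l((n + a_w - d + l) / 2.0)
            - lgamma_l((a_w - d + l) / 2.0)
            + 0.5 * (a_w - d + l) * t_sub_logdet
            - 0.5 * (n + a_w - d + l) * r_logdet
        )
        self._subset_cache[subset] = val
        return val

    # -- BIC ---------------------------------------------------------------

    def _bic_local(self, node: int, parents: tuple[int, ...]) -> float:
        y = self.data[:, node]
        n = self.n
        if parents:
            x = np.column_stack([np.ones(n), self.data[:, list(parents)]])
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            rss = float(((y - x @ beta) ** 2).sum())
        else:
            rss = float(((y - y.mean()) ** 2).sum())
        rss = max(rss, 1e-300)
        k = len(parents) + 2  # intercept, parents, variance
        return -0.5 * n * (log(2 * pi * rss / n) + 1.0) - 0.5 * k * log(n)

    def local(self, node: int, parents: frozenset) -> float:
        key = (node, parents)
        cached = self._local_cache.get(key)
        if cached is not None:
            return cached
        if self.config.score == "bge":
            fam = frozenset(parents | {node})
            val = self._log_p_subset(fam) - self._log_p_subset(parents)
        else:
            val = self._bic_local(node, tuple(sorted(parents)))
        val += len(parents) * self.log_edge_odds
        self._local_cache[key] = val
        return val


def _validate_dag(parents: dict[int, set[int]], n_nodes: int) -> None:
    color = [0] * n_nodes

    def dfs(v: int) -> None:
        color[v] = 1
        for u in parents[v]:
            if color[u] == 1:
                raise ValueError("graph contains a cycle")
            if color[u] == 0:
                dfs(u)
        color[v] = 2

    for v in range(n_nodes):
        if color[v] == 0:
            dfs(v)


def _edges_to_parents(edges, nodes: list[str]) -> dict[int, set[int]]:
    index = {v: i for i, v in enumerate(nodes)}
    parents: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
    for frm, to in edges:
        parents[index[to]].add(index[frm])
    return parents


def network_score(data, edges, config: NetScoreConfig | None = None) -> float:
    """Total decomposable score of a DAG: node-local scores plus edge prior.

    ``edges`` is an iterable of (from, to) node-name pairs.  Raises on a
    cyclic graph.  Higher is better.
    """
    config = config or NetScoreConfig()
    matrix, nodes = _as_matrix(data)
    parents = _edges_to_parents(edges, nodes)
    _validate_dag(parents, len(nodes))
    cache = _ScoreCache(matrix, nodes, config)
    return sum(cache.local(v, frozenset(ps)) for v, ps in parents.items())


def _reaches(parents: dict[int, set[int]], src: int, dst: int) -> bool:
    """True when dst is an ancestor of src (path dst -> ... -> src)."""
    seen = set()
    stack = [src]
    while stack:
        v = stack.pop()
        if v == dst:
            return True
        for u in parents[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return False


def hill_climb(
    data,
    config: NetScoreConfig | None = None,
    blacklist: set[tuple[str, str]] | None = None,
    restarts: int = 0,
    perturb: int = 2,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], float]:
    """Greedy hill-climbing structure search.

    Starts from the empty graph and repeatedly applies the best of all
    score-improving add/delete/reverse moves until none improves.  Ties are
    broken lexicographically by (move type, source, target), so the search
    is deterministic.  Blacklisted directed edges are never introduced, by
    any move.  Returns (edges, score).

    Greedy search can stall in a local optimum (typically mis-orienting a
    collider); ``restarts`` > 0 re-climbs from seeded random perturbations
    of the best graph (``perturb`` random edge changes each) and keeps the
    best result, at the cost of extra search.
    """
    config = config or NetScoreConfig()
    matrix, nodes = _as_matrix(data)
    if matrix.shape[0] < 50:
        raise ValueError("need at least 50 rows for structure learning")
    cache = _ScoreCache(matrix, nodes, config)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    black = {(index[a], index[b]) for a, b in (blacklist or set()) if a in index and b in index}

    best_edges, best_score = None, -np.inf
    rng = np.random.default_rng(seed)
    start_parents: dict[int, set[int]] = {i: set() for i in range(n)}
    for attempt in range(restarts + 1):
        parents = {i: set(ps) for i, ps in start_parents.items()}
        edges, score = _climb(parents, cache, nodes, black)
        if score > best_score:
            best_edges, best_score = edges, score
        if attempt < restarts:
            if attempt % 2 == 0:
                # perturb the incumbent: escape shallow local optima nearby
                start_parents = _perturb_graph(
                    _edges_to_parents(best_edges, nodes), n, black, perturb, rng
                )
            else:
                # fresh random DAG: escape deep basins entirely
                start_parents = _random_dag(n, black, rng)
    return best_edges, best_score


def _random_dag(n: int, black: set, rng) -> dict[int, set[int]]:
    """Uniform random topological order; each admissible edge w.p. 1/2."""
    order = rng.permutation(n)
    parents: dict[int, set[int]] = {i: set() for i in range(n)}
    for pos in range(1, n):
        to = int(order[pos])
        for prev in order[:pos]:
            frm = int(prev)
            if (frm, to) not in black and rng.random() < 0.5:
                parents[to].add(frm)
    return parents


def _perturb_graph(
    parents: dict[int, set[int]], n: int, black: set, k: int, rng
) -> dict[int, set[int]]:
    """Apply k random valid add/delete/reverse changes to a copy of the graph."""
    parents = {i: set(ps) for i, ps in parents.items()}
    for _ in range(k):
        frm, to = rng.integers(0, n, size=2)
        frm, to = int(frm), int(to)
        if frm == to:
            continue
        if frm in parents[to]:
            if (to, frm) not in black and rng.random() < 0.5 and not _reaches(
                {**parents, to: parents[to] - {frm}}, to, frm
            ):
                parents[to].discard(frm)
                parents[frm].add(to)
            else:
                parents[to].discard(frm)
        elif (frm, to) not in black and not _reaches(parents, frm, to):
            parents[to].add(frm)
    return parents


def _climb(
    parents: dict[int, set[int]],
    cache: _ScoreCache,
    nodes: list[str],
    black: set,
) -> tuple[list[tuple[str, str]], float]:
    n = len(nodes)
    locals_: dict[int, float] = {
        i: cache.local(i, frozenset(parents[i])) for i in range(n)
    }

    def better(delta: float, key: tuple, best) -> bool:
        if delta <= 1e-12:
            return False
        if best is None:
            return True
        if delta > best[0] + 1e-12:
            return True
        # equal-score moves resolved lexicographically (smallest key wins)
        return abs(delta - best[0]) <= 1e-12 and key < best[1]

    while True:
        best = None  # (delta, move_key, apply)
        for frm, to in product(range(n), range(n)):
            if frm == to:
                continue
            name_key = (nodes[frm], nodes[to])
            if frm in parents[to]:
                # delete
                delta = (
                    cache.local(to, frozenset(parents[to] - {frm})) - locals_[to]
                )
                key = ("1-delete",) + name_key
                if better(delta, key, best):
                    best = (delta, key, ("delete", frm, to))
                # reverse
                if (frm, to) not in black and (to, frm) not in black and not _reaches(
                    {**parents, to: parents[to] - {frm}}, to, frm
                ):
                    delta_rev = (
                        cache.local(to, frozenset(parents[to] - {frm}))
                        - locals_[to]
                        + cache.local(frm, frozenset(parents[frm] | {to}))
                        - locals_[frm]
                    )
                    key = ("2-reverse",) + name_key
                    if better(delta_rev, key, best):
                        best = (delta_rev, key, ("reverse", frm, to))
            else:
                # add
                if (frm, to) in black:
                    continue
                if _reaches(parents, frm, to):
                    continue  # would create a cycle
                delta = (
                    cache.local(to, frozenset(parents[to] | {frm})) - locals_[to]
                )
                key = ("0-add",) + name_key
                if better(delta, key, best):
                    best = (delta, key, ("add", frm, to))
        if best is None:
            break
        _, _, (kind, frm, to) = best
        if kind == "add":
            parents[to].add(frm)
        elif kind == "delete":
            parents[to].discard(frm)
        else:
            parents[to].discard(frm)
            parents[frm].add(to)
            locals_[frm] = cache.local(frm, frozenset(parents[frm]))
        locals_[to] = cache.local(to, frozenset(parents[to]))

    edges = [
        (nodes[f], nodes[t]) for t in range(n) for f in sorted(parents[t])
    ]
    edges.sort()
    score = sum(locals_.values())
    return edges, score


def enumerate_best_dag(
    data,
    config: NetScoreConfig | None = None,
    blacklist: set[tuple[str, str]] | None = None,
) -> tuple[list[tuple[str, str]], float]:
    """Global optimum by exhaustive search over all DAGs (<= 4 nodes).

    A test oracle: every directed graph over the nodes is enumerated,
    cyclic ones and blacklist violations discarded, and the best-scoring
    DAG returned (first-in-enumeration tie-break).
    """
    config = config or NetScoreConfig()
    matrix, nodes = _as_matrix(data)
    n = len(nodes)
    if n > 4:
        raise ValueError("exhaustive enumeration is limited to 4 nodes")
    cache = _ScoreCache(matrix, nodes, config)
    index = {v: i for i, v in enumerate(nodes)}
    black = {(index[a], index[b]) for a, b in (blacklist or set()) if a in index and b in index}
    pairs = [(f, t) for f, t in product(range(n), range(n)) if f != t and (f, t) not in black]

    best_edges, best_score = None, -np.inf
    for r in range(len(pairs) + 1):
        for chosen in combinations(pairs, r):
            parents: dict[int, set[int]] = {i: set() for i in range(n)}
            for f, t in chosen:
                parents[t].add(f)
            try:
                _validate_dag(parents, n)
            except ValueError:
                continue
            score = sum(cache.local(v, frozenset(ps)) for v, ps in parents.items())
            if score > best_score:
                best_score = score
                best_edges = sorted((nodes[f], nodes[t]) for f, t in chosen)
    return best_edges, float(best_score)


def mark_rna_network(
    data: pd.DataFrame, config: NetScoreConfig | None = None
) -> tuple[list[tuple[str, str]], float]:
    """Hill-climb the marks+RNA network with the RNA-edge blacklist applied."""
    nodes = [c for c in data.columns]
    missing = [m for m in MARKS if m not in nodes]
    if missing:
        raise ValueError(f"data lacks mark column(s): {missing}")
    if RNA_NODE not in nodes:
        raise ValueError("data lacks the RNA column")
    return hill_climb(data, config, blacklist=rna_blacklist(nodes))
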