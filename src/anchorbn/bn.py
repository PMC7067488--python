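"""Score-based Bayesian-network structure learning.

Decomposable BIC scoring (Gaussian nodes via linear regression on their
parents, multinomial nodes via parent-configuration counts), blacklist/
whitelist constraint handling with directional-anchor helpers, greedy
hill-climbing over single-edge additions/deletions/reversals, and an
exhaustive-search oracle for small node sets.

Scores follow the convention in which the network score is the maximized
log-likelihood minus (d/2) log n per node -- higher is better -- summed
over nodes given their parent sets.  For a Gaussian node with p parents,
d = p + 2 (intercept, p slopes, residual variance); for a multinomial
node with L levels and parent configurations of total cardinality c,
d = (L - 1) * c.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx

from .dataset import Dataset

__all__ = [
    "DAG",
    "ConstraintSet",
    "NetworkScore",
    "bic_local_score",
    "network_score",
    "hill_climb",
    "exhaustive_search",
    "enumerate_dags",
]

#: residual-variance floor for Gaussian nodes (degenerate bootstrap columns)
VAR_FLOOR = 1e-12
#: minimum strict score improvement accepted by hill climbing
HC_TOL = 1e-9


# ---------------------------------------------------------------------------
# DAG and constraints
# ---------------------------------------------------------------------------


@dataclass
class DAG:
    """Directed acyclic graph over named nodes.

    Edges are (from, to) pairs; acyclicity and absence of self/duplicate
    edges are enforced on construction and on every mutation.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.edges = frozenset(self.edges)
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node names")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self edge {a}->{b}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge {a}->{b} references unknown node")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("graph contains a directed cycle")

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(a for a, b in self.edges if b == node))

    def sorted_edges(self) -> list[tuple[str, str]]:
        order = {v: i for i, v in enumerate(self.nodes)}
        return sorted(self.edges, key=lambda e: (order[e[0]], order[e[1]]))

    def with_edge(self, a: str, b: str) -> "DAG":
        return DAG(self.nodes, self.edges | {(a, b)})

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    # -- I/O ------------------------------------------------------------

    def to_edge_csv(self, path: str | Path) -> None:
        lines = ["from,to"] + [f"{a},{b}" for a, b in self.sorted_edges()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_edge_csv(cls, path: str | Path, nodes: tuple[str, ...] | None = None) -> "DAG":
        rows = Path(path).read_text().strip().splitlines()[1:]
        edges = {tuple(r.split(",")) for r in rows if r}
        if nodes is None:
            nodes = tuple(sorted({v for e in edges for v in e}))
        return cls(nodes, edges)

    def to_dot(self) -> str:
        body = "\n".join(f'  "{a}" -> "{b}";' for a, b in self.sorted_edges())
        decls = "\n".join(f'  "{v}";' for v in self.nodes)
        return f"digraph {{\n{decls}\n{body}\n}}\n"


@dataclass
class ConstraintSet:
    """Forbidden (blacklist) and required (whitelist) directed edges.

    Anchor helpers encode the two constraint patterns used with genetic
    instruments: ``add_no_incoming`` forbids every edge into an anchor
    (it can only emit arrows), and ``add_single_outgoing`` pins a score
    node to exactly one edge, into its instrumented variable.
    """

    blacklist: set[tuple[str, str]] = field(default_factory=set)
    whitelist: set[tuple[str, str]] = field(default_factory=set)

    def validate(self, nodes: tuple[str, ...]) -> None:
        if self.whitelist & self.blacklist:
            raise ValueError("whitelist and blacklist overlap")
        DAG(nodes, self.whitelist)  # whitelist alone must be acyclic

    def allows(self, a: str, b: str) -> bool:
        return (a, b) not in self.blacklist

    def add_no_incoming(self, anchor: str, nodes: list[str] | tuple[str, ...]) -> "ConstraintSet":
        """Blacklist u -> anchor for every other node u."""
        for u in nodes:
            if u != anchor:
                self.blacklist.add((u, anchor))
        return self

    def add_single_outgoing(self, score: str, target: str,
                            nodes: list[str] | tuple[str, ...]) -> "ConstraintSet":
        """Whitelist score -> target; blacklist every other edge touching
        the score node (either direction)."""
        self.whitelist.add((score, target))
        for u in nodes:
            if u == score:
                continue
            self.blacklist.add((u, score))
            if u != target:
                self.blacklist.add((score, u))
        return self

    @classmethod
    def no_incoming(cls, anchors: list[str], nodes: list[str] | tuple[str, ...]) -> "ConstraintSet":
        cs = cls()
        for a in anchors:
            cs.add_no_incoming(a, nodes)
        return cs


@dataclass
class NetworkScore:
    total: float
    per_node: dict[str, float]
    n: int


# ---------------------------------------------------------------------------
# BIC scoring
# ---------------------------------------------------------------------------


class BicScorer:
    """Cached decomposable BIC scorer over a fixed data matrix.

    Continuous columns are stored as floats; categorical columns as
    integer codes against their declared level sets (so the parameter
    count is stable even if a bootstrap resample drops a level).
    ``subset`` produces a scorer over a row resample sharing metadata,
    used by the bootstrap loop.
    """

    def __init__(self, data: Dataset, nodes: list[str] | None = None):
        self.nodes = tuple(nodes) if nodes is not None else tuple(data.var_names)
        self.kinds: dict[str, str] = {}
        self.n_levels: dict[str, int] = {}
        self._cols: dict[str, np.ndarray] = {}
        for v in self.nodes:
            kind = data.kinds[v]
            self.kinds[v] = kind
            if kind == "categorical":
                levels = list(data.levels[v])
                codes = np.searchsorted(np.sort(levels),
                                        np.asarray(data.values[v]))
                self._cols[v] = codes.astype(np.int64)
                self.n_levels[v] = len(levels)
            else:
                self._cols[v] = data.column(v)
        self.n = data.n
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def subset(self, idx: np.ndarray) -> "BicScorer":
        new = object.__new__(BicScorer)
        new.nodes = self.nodes
        new.kinds = self.kinds
        new.n_levels = self.n_levels
        new._cols = {v: c[idx] for v, c in self._cols.items()}
        new.n = len(idx)
        new._cache = {}
        return new

    def is_degenerate(self) -> bool:
        """True if any column is constant (no variation to score)."""
        return any(c.min() == c.max() for c in self._cols.values())

    def local_score(self, node: str, parents: tuple[str, ...]) -> float:
        key = (node, tuple(sorted(parents)))
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        if self.n == 0:
            raise ValueError("empty data")
        if self.kinds[node] == "continuous":
            val = self._gaussian_score(node, key[1])
        else:
            val = self._multinomial_score(node, key[1])
        self._cache[key] = val
        return val

    def _gaussian_score(self, node: str, parents: tuple[str, ...]) -> float:
        y = self._cols[node]
        n = self.n
        if parents:
            X = np.column_stack([np.ones(n)] + [self._cols[p] for p in parents])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            rss = resid @ resid
        else:
            resid = y - y.mean()
            rss = resid @ resid
        var = max(rss / n, VAR_FLOOR)
        loglik = -0.5 * n * (np.log(2.0 * np.pi * var) + 1.0)
        d = len(parents) + 2
        return float(loglik - 0.5 * d * np.log(n))

    def _multinomial_score(self, node: str, parents: tuple[str, ...]) -> float:
        y = self._cols[node]
        L = self.n_levels[node]
        n = self.n
        n_cfg = 1
        cfg = np.zeros(n, dtype=np.int64)
        for p in parents:
            if self.kinds[p] != "categorical":
                raise ValueError(
                    f"multinomial node {node!r} has non-categorical parent {p!r}")
            cfg = cfg * self.n_levels[p] + self._cols[p]
            n_cfg *= self.n_levels[p]
        counts = np.bincount(y * n_cfg + cfg, minlength=L * n_cfg)
        counts = counts.reshape(L, n_cfg).astype(float)
        col_tot = counts.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = counts / col_tot
            terms = np.where(counts > 0, counts * np.log(ratio), 0.0)
        loglik = terms.sum()
        d = (L - 1) * n_cfg
        return float(loglik - 0.5 * d * np.log(n))


def bic_local_score(node: str, parents: list[str] | tuple[str, ...],
                    data: Dataset) -> float:
    """Decomposable BIC contribution of one node given its parents."""
    scorer = BicScorer(data)
    return scorer.local_score(node, tuple(parents))


def network_score(dag: DAG, data: Dataset) -> NetworkScore:
    """Total BIC score of a DAG: the exact sum of per-node local scores."""
    if not set(dag.nodes) <= set(data.var_names):
        raise ValueError("DAG nodes must be a subset of dataset variables")
    scorer = BicScorer(data, nodes=list(dag.nodes))
    per_node = {v: scorer.local_score(v, dag.parents(v)) for v in dag.nodes}
    return NetworkScore(total=float(sum(per_node.values())),
                        per_node=per_node, n=data.n)


# ---------------------------------------------------------------------------
# Hill climbing
# ---------------------------------------------------------------------------


def _has_path(children: dict[str, set[str]], src: str, dst: str) -> bool:
    """Directed reachability src ~> dst (DFS)."""
    if src == dst:
        return True
    stack = [src]
    seen = {src}
    while stack:
        v = stack.pop()
        for w in children[v]:
            if w == dst:
                return True
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def _random_start(nodes: tuple[str, ...], constraints: ConstraintSet,
                  rng: np.random.Generator) -> dict[str, set[str]]:
    """Random legal start graph: whitelist edges plus, for each node pair
    visited in random order, an edge with probability 1/2 in a random
    orientation (skipped if it would violate constraints or acyclicity).

    Used by the bootstrap layer so that orientations within a
    score-equivalence class are resolved symmetrically across replicates
    instead of by the deterministic move order.
    """
    parents: dict[str, set[str]] = {v: set() for v in nodes}
    children: dict[str, set[str]] = {v: set() for v in nodes}
    for a, b in constraints.whitelist:
        parents[b].add(a)
        children[a].add(b)
    pairs = list(itertools.combinations(range(len(nodes)), 2))
    rng.shuffle(pairs)
    for i, j in pairs:
        if rng.random() < 0.5:
            continue
        a, b = (nodes[i], nodes[j]) if rng.random() < 0.5 else (nodes[j], nodes[i])
        if (constraints.allows(a, b) and a not in parents[b]
                and b not in parents[a] and not _has_path(children, b, a)):
            parents[b].add(a)
            children[a].add(b)
    return parents


def _hill_climb(scorer: BicScorer, constraints: ConstraintSet,
                max_iter: int | None, tol: float,
                start_parents: dict[str, set[str]] | None = None,
                ) -> tuple[dict[str, set[str]], float]:
    nodes = scorer.nodes
    parents: dict[str, set[str]] = (
        {v: set() for v in nodes} if start_parents is None
        else {v: set(ps) for v, ps in start_parents.items()})
    if start_parents is None:
        for a, b in constraints.whitelist:
            parents[b].add(a)
    children: dict[str, set[str]] = {v: set() for v in nodes}
    for b, ps in parents.items():
        for a in ps:
            children[a].add(b)

    local = {v: scorer.local_score(v, tuple(parents[v])) for v in nodes}
    protected = constraints.whitelist

    iters = 0
    while max_iter is None or iters < max_iter:
        iters += 1
        best_delta = tol
        best_move = None  # (kind, a, b, new scores...)
        # canonical order: from-index, to-index, add < delete < reverse
        for a in nodes:
            for b in nodes:
                if a == b:
                    continue
                present = a in parents[b]
                if not present:
                    # addition a -> b
                    if constraints.allows(a, b) and not _has_path(children, b, a):
                        new_b = scorer.local_score(b, tuple(sorted(parents[b] | {a})))
                        delta = new_b - local[b]
                        if delta > best_delta:
                            best_delta = delta
                            best_move = ("add", a, b, new_b, None)
                else:
                    if (a, b) not in protected:
                        # deletion a -> b
                        new_b = scorer.local_score(b, tuple(sorted(parents[b] - {a})))
                        delta = new_b - local[b]
                        if delta > best_delta:
                            best_delta = delta
                            best_move = ("delete", a, b, new_b, None)
                        # reversal a -> b  =>  b -> a
                        if constraints.allows(b, a):
                            children[a].discard(b)
                            cycle = _has_path(children, a, b)
                            children[a].add(b)
                            if not cycle:
                                new_a = scorer.local_score(a, tuple(sorted(parents[a] | {b})))
                                delta = (new_b - local[b]) + (new_a - local[a])
                                if delta > best_delta:
                                    best_delta = delta
                                    best_move = ("reverse", a, b, new_b, new_a)
        if best_move is None:
            break
        kind, a, b, new_b, new_a = best_move
        if kind == "add":
            parents[b].add(a)
            children[a].add(b)
            local[b] = new_b
        elif kind == "delete":
            parents[b].discard(a)
            children[a].discard(b)
            local[b] = new_b
        else:
            parents[b].discard(a)
            children[a].discard(b)
            parents[a].add(b)
            children[b].add(a)
            local[b] = new_b
            local[a] = new_a
    return parents, float(sum(local.values()))


def hill_climb(data: Dataset, constraints: ConstraintSet | None = None,
               restarts: int = 50, max_iter: int | None = None,
               tol: float = HC_TOL, seed: int = 0,
               nodes: list[str] | None = None) -> DAG:
    """Greedy BIC hill climbing over single-edge moves.

    Starts from the whitelist-only graph and repeatedly applies the best
    strictly improving addition, deletion or reversal that respects
    acyclicity, the blacklist, and whitelist protection.  Ties are broken
    deterministically (smallest from-index, then to-index, then
    add < delete < reverse).

    ``restarts`` re-runs the search from seeded random start graphs and
    keeps the best-scoring local optimum (first found wins ties).  Plain
    greedy search (``restarts=0``) can stall at a covered-edge plateau,
    where a score-neutral reversal must precede an improving deletion;
    random restarts escape these in small networks, so a generous
    nonzero default is used (each climb on a small network costs
    milliseconds).  The result is deterministic given ``seed``.
    """
    scorer = BicScorer(data, nodes=nodes)
    return _hill_climb_scorer(scorer, constraints, restarts=restarts,
                              max_iter=max_iter, tol=tol, seed=seed)


def _hill_climb_scorer(scorer: BicScorer, constraints: ConstraintSet | None = None,
                       restarts: int = 0, max_iter: int | None = None,
                       tol: float = HC_TOL, seed: int = 0,
                       start_rng: np.random.Generator | None = None) -> DAG:
    cs = constraints if constraints is not None else ConstraintSet()
    cs.validate(scorer.nodes)
    start = _random_start(scorer.nodes, cs, start_rng) if start_rng is not None else None
    parents, score = _hill_climb(scorer, cs, max_iter, tol, start_parents=start)
    if restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            start = _random_start(scorer.nodes, cs, rng)
            cand_parents, cand_score = _hill_climb(scorer, cs, max_iter, tol,
                                                   start_parents=start)
            if cand_score > score + tol:
                parents, score = cand_parents, cand_score
    edges = {(a, b) for b, ps in parents.items() for a in ps}
    return DAG(scorer.nodes, edges)


# ---------------------------------------------------------------------------
# Exhaustive search oracle (<= 5 nodes)
# ---------------------------------------------------------------------------


def enumerate_dags(nodes: list[str] | tuple[str, ...],
                   constraints: ConstraintSet | None = None):
    """Yield every constraint-respecting DAG over ``nodes`` as a sorted
    edge tuple, in a deterministic canonical order.

    Each unordered node pair contributes one of {absent, a->b, b->a};
    assignments producing cycles or violating constraints are dropped.
    Intended as a small-graph oracle; limited to 5 nodes.
    """
    nodes = tuple(nodes)
    if len(nodes) > 5:
        raise ValueError("exhaustive enumeration is limited to 5 nodes")
    cs = constraints if constraints is not None else ConstraintSet()
    cs.validate(nodes)
    pairs = list(itertools.combinations(range(len(nodes)), 2))
    for choice in itertools.product(range(3), repeat=len(pairs)):
        edges = []
        ok = True
        for (i, j), c in zip(pairs, choice):
            a, b = nodes[i], nodes[j]
            if c == 1:
                edges.append((a, b))
            elif c == 2:
                edges.append((b, a))
        edge_set = set(edges)
        for e in edge_set:
            if not cs.allows(*e):
                ok = False
                break
        if ok and not cs.whitelist <= edge_set:
            ok = False
        if not ok:
            continue
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edge_set)
        if nx.is_directed_acyclic_graph(g):
            order = {v: i for i, v in enumerate(nodes)}
            yield tuple(sorted(edge_set, key=lambda e: (order[e[0]], order[e[1]])))


def exhaustive_search(data: Dataset, constraints: ConstraintSet | None = None,
                      nodes: list[str] | None = None) -> DAG:
    """Globally optimal DAG by enumeration (oracle; <= 5 nodes).

    Local scores are cached per (node, parent set), so each of the
    enumerated DAGs costs only a lookup-sum.  Ties are broken by the
    canonical enumeration order (first maximizer wins).
    """
    scorer = BicScorer(data, nodes=nodes)
    best_edges = None
    best_score = -np.inf
    for edges in enumerate_dags(scorer.nodes, constraints):
        parents: dict[str, list[str]] = {v: [] for v in scorer.nodes}
        for a, b in edges:
            parents[b].append(a)
        score = sum(scorer.local_score(v, tuple(parents[v])) for v in scorer.nodes)
        if score > best_score:
            best_score = score
            best_edges = edges
    return DAG(scorer.nodes, set(best_edges))
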