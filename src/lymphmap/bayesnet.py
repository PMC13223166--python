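"""Discrete Bayesian-network engine.

DAGs over named discrete variables, BIC scoring, greedy hill-climbing
structure search, maximum-likelihood conditional probability tables (with
optional Laplace smoothing), and exact inference by variable elimination.
A full-joint enumeration routine is kept as a slow independent route for
cross-checking inference, and an exhaustive DAG enumerator (up to 4 nodes)
serves as the oracle for the structure search.

Conventions
-----------
* Data are integer state codes ``0..card-1`` per column; the common case is
  binary involvement indicators.
* BIC is "higher is better": penalised log-likelihood with penalty
  ``(ln n)/2`` per free parameter.  The score decomposes over nodes, and
  local scores are cached during search.
* Hill climbing is steepest-ascent over the operators add / delete /
  reverse with deterministic tie-breaking (operator type order
  add < delete < reverse, then lexicographic by (parent, child) position),
  so a seed fully determines the result.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "Dag",
    "Cpt",
    "bic_score",
    "hill_climb",
    "fit_cpts",
    "posterior_query",
    "joint_distribution",
    "brute_force_posterior",
    "enumerate_dags",
    "DiscreteBayesianNetwork",
]


# ---------------------------------------------------------------------------
# DAG


class Dag:
    """A directed acyclic graph over named variables.

    Edges are ordered (parent, child) pairs.  Every mutation re-checks
    acyclicity; self-loops and duplicate edges are rejected.
    """

    def __init__(self, nodes, edges=()):
        self.nodes: list[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self._parents: dict[str, set[str]] = {v: set() for v in self.nodes}
        self._children: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in edges:
            self.add_edge(u, v)

    # -- structure queries ---------------------------------------------------

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self._parents[node], key=self.nodes.index))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self._children[node], key=self.nodes.index))

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(u, v) for v, ps in self._parents.items() for u in ps}

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._children.get(u, ())

    def has_path(self, src: str, dst: str) -> bool:
        """True if a directed path src -> ... -> dst exists (src != dst)."""
        stack, seen = [src], set()
        while stack:
            x = stack.pop()
            if x == dst:
                return True
            if x in seen:
                continue
            seen.add(x)
            stack.extend(self._children[x])
        return False

    # -- mutation ------------------------------------------------------------

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop {u}->{v}")
        if u not in self._parents or v not in self._parents:
            raise KeyError(f"unknown node in edge {u}->{v}")
        if self.has_edge(u, v):
            raise ValueError(f"duplicate edge {u}->{v}")
        if self.has_path(v, u):
            raise ValueError(f"edge {u}->{v} would create a directed cycle")
        self._parents[v].add(u)
        self._children[u].add(v)

    def remove_edge(self, u: str, v: str) -> None:
        if not self.has_edge(u, v):
            raise ValueError(f"edge {u}->{v} not present")
        self._parents[v].discard(u)
        self._children[u].discard(v)

    def reverse_edge(self, u: str, v: str) -> None:
        self.remove_edge(u, v)
        try:
            self.add_edge(v, u)
        except ValueError:
            self._parents[v].add(u)
            self._children[u].add(v)
            raise

    # -- misc ----------------------------------------------------------------

    def copy(self) -> "Dag":
        d = Dag(self.nodes)
        for v, ps in self._parents.items():
            d._parents[v] = set(ps)
        for u, cs in self._children.items():
            d._children[u] = set(cs)
        return d

    def topological_order(self) -> list[str]:
        """Kahn's algorithm; ties broken by node-list position."""
        indeg = {v: len(self._parents[v]) for v in self.nodes}
        ready = [v for v in self.nodes if indeg[v] == 0]
        order: list[str] = []
        while ready:
            v = min(ready, key=self.nodes.index)
            ready.remove(v)
            order.append(v)
            for c in sorted(self._children[v], key=self.nodes.index):
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != len(self.nodes):
            raise ValueError("graph contains a cycle")
        return order

    def skeleton(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.edges}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Dag)
            and self.nodes == other.nodes
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return f"Dag({len(self.nodes)} nodes, {len(self.edges)} edges)"


# ---------------------------------------------------------------------------
# CPTs


@dataclass
class Cpt:
    """Conditional probability table for one node.

    ``table`` has shape (prod(parent_cards), card): one row per parent-state
    configuration (mixed-radix order, first parent most significant), each
    row a distribution over the node's states.
    """

    node: str
    parents: tuple[str, ...]
    card: int
    parent_cards: tuple[int, ...]
    table: np.ndarray
    alpha: float = 0.0

    def __post_init__(self) -> None:
        q = int(np.prod(self.parent_cards)) if self.parent_cards else 1
        self.table = np.asarray(self.table, dtype=float).reshape(q, self.card)
        rows = self.table.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError(f"CPT rows of {self.node!r} do not sum to 1")

    def row_index(self, parent_states) -> int:
        idx = 0
        for s, c in zip(parent_states, self.parent_cards):
            idx = idx * c + int(s)
        return idx

    def prob(self, state: int, parent_states=()) -> float:
        return float(self.table[self.row_index(parent_states), int(state)])


def _validate_data(data, nodes=None):
    """Coerce data to (X int array, node names, cardinalities)."""
    if isinstance(data, pd.DataFrame):
        names = [str(c) for c in data.columns]
        X = data.to_numpy()
    else:
        X = np.asarray(data)
        names = [f"x{j}" for j in range(X.shape[1])]
    if X.ndim != 2:
        raise ValueError("data must be a 2-D matrix")
    X = X.astype(np.int64, copy=False)
    if X.min(initial=0) < 0:
        raise ValueError("state codes must be non-negative integers")
    if nodes is not None:
        if list(nodes) != names and not isinstance(data, pd.DataFrame):
            names = list(nodes)
        if list(nodes) != names:
            raise ValueError(
                f"data columns {names} do not match network nodes {list(nodes)}"
            )
    cards = np.maximum(X.max(axis=0) + 1, 2).astype(int)
    return X, names, cards


# ---------------------------------------------------------------------------
# BIC scoring


def _local_loglik(X, j, parent_idx, cards):
    """Maximised log-likelihood of column j given its parents (0 ln 0 = 0)."""
    n = X.shape[0]
    r = int(cards[j])
    if parent_idx:
        config = np.zeros(n, dtype=np.int64)
        for p in parent_idx:
            config = config * int(cards[p]) + X[:, p]
        q = int(np.prod([cards[p] for p in parent_idx]))
    else:
        config = np.zeros(n, dtype=np.int64)
        q = 1
    joint = np.bincount(config * r + X[:, j], minlength=q * r).reshape(q, r)
    row_tot = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = joint * (np.log(joint, where=joint > 0, out=np.zeros_like(joint, dtype=float))
                      - np.log(row_tot, where=row_tot > 0, out=np.zeros_like(row_tot, dtype=float)))
    return float(ll.sum())


def _local_bic(X, j, parent_idx, cards, log_n_half):
    q = int(np.prod([cards[p] for p in parent_idx])) if parent_idx else 1
    n_params = (int(cards[j]) - 1) * q
    return _local_loglik(X, j, parent_idx, cards) - log_n_half * n_params


class ScoreCache:
    """Cache of local BIC contributions keyed by (node index, parent set)."""

    def __init__(self, X, cards):
        self.X = X
        self.cards = cards
        self.log_n_half = np.log(X.shape[0]) / 2.0
        self._cache: dict[tuple[int, frozenset[int]], float] = {}

    def local(self, j: int, parent_idx) -> float:
        key = (j, frozenset(parent_idx))
        val = self._cache.get(key)
        if val is None:
            val = _local_bic(self.X, j, tuple(sorted(parent_idx)), self.cards, self.log_n_half)
            self._cache[key] = val
        return val


def bic_score(dag: Dag, data) -> float:
    """BIC score of ``dag`` on ``data`` (higher is better).

    ``score = sum_j [ max log-lik of node j given parents ]
              - (ln n / 2) * sum_j (card_j - 1) * prod(parent cards)``
    """
    X, names, cards = _validate_data(data, dag.nodes)
    if X.shape[0] < 1:
        raise ValueError("need at least one observation")
    idx = {v: i for i, v in enumerate(names)}
    cache = ScoreCache(X, cards)
    return sum(
        cache.local(idx[v], tuple(idx[p] for p in dag.parents(v))) for v in dag.nodes
    )


# ---------------------------------------------------------------------------
# Hill climbing


def _climb(cache: ScoreCache, parents: list[set[int]], max_indegree):
    """Steepest-ascent hill climb from a starting parent structure (in place).

    Returns the total score.  Operators: add, delete, reverse; the single
    best strictly improving operator is applied per step.  Tie-breaking is
    deterministic: add < delete < reverse, then (parent, child) index order.
    """
    k = len(parents)
    children: list[set[int]] = [set() for _ in range(k)]
    for v in range(k):
        for u in parents[v]:
            children[u].add(v)

    def reachable(src, dst):
        stack, seen = [src], set()
        while stack:
            x = stack.pop()
            if x == dst:
                return True
            if x not in seen:
                seen.add(x)
                stack.extend(children[x])
        return False

    local = [cache.local(v, parents[v]) for v in range(k)]
    eps = 1e-10
    while True:
        best = None  # (delta, op_rank, u, v, payload)
        for u in range(k):
            for v in range(k):
                if u == v:
                    continue
                if v in children[u]:
                    # delete u->v
                    d = cache.local(v, parents[v] - {u}) - local[v]
                    cand = (d, 1, u, v)
                    if d > eps and (best is None or _op_better(cand, best)):
                        best = cand
                    # reverse u->v  (becomes v->u)
                    if max_indegree is None or len(parents[u]) < max_indegree:
                        children[u].discard(v)
                        creates = reachable(u, v)
                        children[u].add(v)
                        if not creates:
                            d = (
                                cache.local(v, parents[v] - {u})
                                - local[v]
                                + cache.local(u, parents[u] | {v})
                                - local[u]
                            )
                            cand = (d, 2, u, v)
                            if d > eps and (best is None or _op_better(cand, best)):
                                best = cand
                else:
                    # add u->v
                    if max_indegree is not None and len(parents[v]) >= max_indegree:
                        continue
                    if reachable(v, u):
                        continue
                    d = cache.local(v, parents[v] | {u}) - local[v]
                    cand = (d, 0, u, v)
                    if d > eps and (best is None or _op_better(cand, best)):
                        best = cand
        if best is None:
            break
        _, op, u, v = best
        if op == 0:
            parents[v].add(u)
            children[u].add(v)
            local[v] = cache.local(v, parents[v])
        elif op == 1:
            parents[v].discard(u)
            children[u].discard(v)
            local[v] = cache.local(v, parents[v])
        else:
            parents[v].discard(u)
            children[u].discard(v)
            parents[u].add(v)
            children[v].add(u)
            local[v] = cache.local(v, parents[v])
            local[u] = cache.local(u, parents[u])
    return sum(local)


def _op_better(cand, best):
    """Strict ordering: larger delta wins; ties by op rank then (u, v)."""
    dc, oc, uc, vc = cand
    db, ob, ub, vb = best
    if dc != db:
        return dc > db
    return (oc, uc, vc) < (ob, ub, vb)


def hill_climb(data, restarts: int = 0, seed: int = 0, max_indegree=None) -> Dag:
    """Learn a DAG by greedy BIC hill climbing.

    Starts from the empty graph; with ``restarts > 0`` additionally climbs
    from seeded random starting DAGs and returns the highest-scoring result.
    Deterministic given ``seed``.
    """
    X, names, cards = _validate_data(data)
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 observations and 2 variables")
    cache = ScoreCache(X, cards)

    parents: list[set[int]] = [set() for _ in range(k)]
    best_score = _climb(cache, parents, max_indegree)
    best_parents = [set(p) for p in parents]

    rng = np.random.default_rng(seed)
    p_edge = min(1.0, 2.0 / max(k - 1, 1))
    for _ in range(int(restarts)):
        perm = rng.permutation(k)
        start: list[set[int]] = [set() for _ in range(k)]
        for a in range(k):
            for b in range(a + 1, k):
                if rng.random() < p_edge:
                    u, v = int(perm[a]), int(perm[b])
                    if max_indegree is None or len(start[v]) < max_indegree:
                        start[v].add(u)
        score = _climb(cache, start, max_indegree)
        if score > best_score + 1e-10:
            best_score = score
            best_parents = [set(p) for p in start]

    dag = Dag(names)
    for v in range(k):
        for u in best_parents[v]:
            dag._parents[names[v]].add(names[u])
            dag._children[names[u]].add(names[v])
    return dag


# ---------------------------------------------------------------------------
# Parameter fitting


def fit_cpts(dag: Dag, data, alpha: float = 0.0) -> dict[str, Cpt]:
    """Estimate conditional probability tables.

    Each entry is ``(count + alpha) / (config_total + alpha * card)``;
    ``alpha = 0`` is the pure maximum-likelihood estimate.  Parent
    configurations never observed with ``alpha = 0`` get a uniform vector
    and a logged flag.
    """
    X, names, cards = _validate_data(data, dag.nodes)
    idx = {v: i for i, v in enumerate(names)}
    cpts: dict[str, Cpt] = {}
    for v in dag.nodes:
        j = idx[v]
        parent_names = dag.parents(v)
        pidx = tuple(idx[p] for p in parent_names)
        r = int(cards[j])
        pcards = tuple(int(cards[p]) for p in pidx)
        q = int(np.prod(pcards)) if pcards else 1
        config = np.zeros(X.shape[0], dtype=np.int64)
        for p in pidx:
            config = config * int(cards[p]) + X[:, p]
        joint = np.bincount(config * r + X[:, j], minlength=q * r).reshape(q, r).astype(float)
        tot = joint.sum(axis=1, keepdims=True)
        table = np.empty_like(joint)
        denom = tot + alpha * r
        if alpha > 0:
            table = (joint + alpha) / denom
        else:
            unseen = tot.ravel() == 0
            if unseen.any():
                logger.warning(
                    "node %s: %d parent configuration(s) unseen with alpha=0; "
                    "using uniform rows", v, int(unseen.sum()),
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                table = np.where(tot > 0, joint / np.where(tot > 0, tot, 1.0), 1.0 / r)
        cpts[v] = Cpt(v, parent_names, r, pcards, table, alpha=alpha)
    return cpts


# ---------------------------------------------------------------------------
# Exact inference


class InconsistentEvidenceError(ValueError):
    """Evidence assignment has probability zero under the model."""


def _factor_from_cpt(cpt: Cpt):
    """(vars tuple, array over those vars) with the node as last axis."""
    shape = tuple(cpt.parent_cards) + (cpt.card,)
    return tuple(cpt.parents) + (cpt.node,), cpt.table.reshape(shape)


def _factor_multiply(f1, f2):
    v1, a1 = f1
    v2, a2 = f2
    out_vars = list(v1) + [v for v in v2 if v not in v1]
    a1b = a1.reshape(a1.shape + (1,) * (len(out_vars) - len(v1)))
    shape2 = [a2.shape[v2.index(v)] if v in v2 else 1 for v in out_vars]
    present = [v for v in out_vars if v in v2]
    a2b = np.transpose(a2, [v2.index(v) for v in present]).reshape(shape2)
    return tuple(out_vars), a1b * a2b


def _factor_sum_out(f, var):
    vars_, arr = f
    ax = vars_.index(var)
    return tuple(v for v in vars_ if v != var), arr.sum(axis=ax)


def _factor_condition(f, evidence: dict[str, int]):
    vars_, arr = f
    keep = []
    index = []
    for v in vars_:
        if v in evidence:
            index.append(int(evidence[v]))
        else:
            keep.append(v)
            index.append(slice(None))
    return tuple(keep), arr[tuple(index)]


def posterior_query(dag: Dag, cpts: dict[str, Cpt], target: str, target_state: int,
                    evidence: dict[str, int] | None = None) -> float:
    """Exact posterior ``P(target = target_state | evidence)``.

    Variable elimination with a min-degree ordering.  Raises
    :class:`InconsistentEvidenceError` if the evidence has zero probability.
    """
    evidence = dict(evidence or {})
    if target in evidence:
        raise ValueError(f"target {target!r} appears in the evidence")
    unknown = [v for v in list(evidence) + [target] if v not in dag.nodes]
    if unknown:
        raise KeyError(f"unknown variables {unknown}")

    factors = [_factor_condition(_factor_from_cpt(cpts[v]), evidence) for v in dag.nodes]
    to_eliminate = [v for v in dag.nodes if v != target and v not in evidence]

    # min-degree elimination ordering over the factor graph
    while to_eliminate:
        degree = {}
        for v in to_eliminate:
            neigh = set()
            for vars_, _ in factors:
                if v in vars_:
                    neigh.update(vars_)
            neigh.discard(v)
            degree[v] = len(neigh)
        v = min(to_eliminate, key=lambda x: (degree[x], dag.nodes.index(x)))
        to_eliminate.remove(v)
        involved = [f for f in factors if v in f[0]]
        rest = [f for f in factors if v not in f[0]]
        prod = involved[0]
        for f in involved[1:]:
            prod = _factor_multiply(prod, f)
        rest.append(_factor_sum_out(prod, v))
        factors = rest

    result = ((), np.array(1.0))
    for f in factors:
        result = _factor_multiply(result, f)
    vars_, arr = result
    if vars_ != (target,):
        arr = arr.reshape(-1)  # all remaining vars collapsed; target only
    total = float(arr.sum())
    if total <= 0.0:
        raise InconsistentEvidenceError(
            f"evidence {evidence} has probability zero under the model"
        )
    return float(arr[int(target_state)] / total)


def joint_distribution(dag: Dag, cpts: dict[str, Cpt]) -> tuple[list[str], np.ndarray]:
    """Full joint distribution as an array indexed by the DAG's node order.

    Brute-force product of all CPTs; tractable for the 14 binary zones
    (2^14 states) and used as the independent cross-check for inference.
    """
    vars_order = list(dag.nodes)
    f = ((), np.array(1.0))
    for v in vars_order:
        f = _factor_multiply(f, _factor_from_cpt(cpts[v]))
    got_vars, arr = f
    perm = [got_vars.index(v) for v in vars_order]
    return vars_order, np.transpose(arr, perm)


def brute_force_posterior(dag: Dag, cpts: dict[str, Cpt], target: str, target_state: int,
                          evidence: dict[str, int] | None = None) -> float:
    """Posterior by explicit summation over the full joint (oracle route)."""
    evidence = dict(evidence or {})
    vars_order, joint = joint_distribution(dag, cpts)
    index = [slice(None)] * len(vars_order)
    for v, s in evidence.items():
        index[vars_order.index(v)] = int(s)
    sub = joint[tuple(index)]
    remaining = [v for v in vars_order if v not in evidence]
    t_ax = remaining.index(target)
    other = tuple(i for i in range(sub.ndim) if i != t_ax)
    marg = sub.sum(axis=other) if other else sub
    total = float(marg.sum())
    if total <= 0:
        raise InconsistentEvidenceError(f"evidence {evidence} has probability zero")
    return float(marg[int(target_state)] / total)


# ---------------------------------------------------------------------------
# Exhaustive DAG enumeration (structure-search oracle)


def enumerate_dags(nodes) -> list[Dag]:
    """All labelled DAGs on the given nodes (at most 4: 1, 3, 25, 543 DAGs).

    Enumeration assigns each unordered pair one of {no edge, ->, <-} and
    filters the acyclic results; a combinatorial guard refuses > 4 nodes.
    """
    if isinstance(nodes, int):
        nodes = [f"x{j}" for j in range(nodes)]
    nodes = list(nodes)
    k = len(nodes)
    if k < 1 or k > 4:
        raise ValueError("enumerate_dags supports 1 to 4 nodes (combinatorial guard)")
    pairs = list(itertools.combinations(range(k), 2))
    out: list[Dag] = []
    for choice in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (a, b), c in zip(pairs, choice):
            if c == 1:
                edges.append((nodes[a], nodes[b]))
            elif c == 2:
                edges.append((nodes[b], nodes[a]))
        try:
            out.append(Dag(nodes, edges))
        except ValueError:
            continue
    return out


# ---------------------------------------------------------------------------
# Estimator


class DiscreteBayesianNetwork(BaseEstimator):
    """Discrete Bayesian network learned by BIC hill climbing.

    scikit-learn style estimator: ``fit`` learns structure and parameters
    from a matrix of integer state codes (binary zone indicators in the
    nodal-mapping application); ``query`` answers exact posterior queries
    and ``score`` returns the mean log-likelihood per observation.

    Parameters
    ----------
    restarts : int, default 0
        Number of seeded random restarts for the structure search (the
        empty graph is always one start).
    alpha : float, default 0.0
        Laplace pseudo-count for CPT estimation; 0 is pure MLE.
    max_indegree : int or None
        Optional cap on the number of parents per node.
    random_state : int, default 0
        Seed for the restart perturbations.

    Attributes
    ----------
    dag_ : Dag
        Learned structure.
    cpts_ : dict[str, Cpt]
        Fitted conditional probability tables.
    score_ : float
        BIC score of the learned structure on the training data.
    feature_names_in_ : ndarray of str
    """

    def __init__(self, restarts: int = 0, alpha: float = 0.0,
                 max_indegree=None, random_state: int = 0):
        self.restarts = restarts
        self.alpha = alpha
        self.max_indegree = max_indegree
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray([str(c) for c in X.columns], dtype=object)
        else:
            X = np.asarray(X)
            self.feature_names_in_ = np.asarray(
                [f"x{j}" for j in range(X.shape[1])], dtype=object
            )
            X = pd.DataFrame(X, columns=self.feature_names_in_)
        self.n_features_in_ = len(self.feature_names_in_)
        self.dag_ = hill_climb(
            X, restarts=self.restarts, seed=self.random_state,
            max_indegree=self.max_indegree,
        )
        self.cpts_ = fit_cpts(self.dag_, X, alpha=self.alpha)
        self.score_ = bic_score(self.dag_, X)
        return self

    def query(self, target: str, target_state: int = 1, evidence=None) -> float:
        """Exact posterior probability of ``target = target_state`` given evidence."""
        if not hasattr(self, "dag_"):
            raise ValueError("estimator is not fitted")
        return posterior_query(self.dag_, self.cpts_, target, target_state, evidence)

    def score(self, X, y=None) -> float:
        """Mean log-likelihood per observation under the fitted network."""
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names_in_)]
        Xa, names, cards = _validate_data(X, list(self.feature_names_in_))
        idx = {v: i for i, v in enumerate(names)}
        ll = 0.0
        for v in self.dag_.nodes:
            cpt = self.cpts_[v]
            config = np.zeros(Xa.shape[0], dtype=np.int64)
            for p, c in zip(cpt.parents, cpt.parent_cards):
                config = config * c + Xa[:, idx[p]]
            probs = cpt.table[config, Xa[:, idx[v]]]
            with np.errstate(divide="ignore"):
                ll += np.log(probs).sum()
        return float(ll / Xa.shape[0])
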