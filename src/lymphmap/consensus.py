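"""Bootstrap edge confidence and pairwise co-occurrence probabilities.

These are the two evidence streams the pathway rule combines: the fraction
of bootstrap structure-learning runs in which a directed edge appears (its
"edge strength"), and the fraction of patients in whom two zones are
simultaneously involved (their co-occurrence probability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bayesnet import hill_climb
from .simulate import ZONE_COLS

__all__ = [
    "BootstrapEdgeSummary",
    "CooccurrenceMatrix",
    "bootstrap_edge_strength",
    "cooccurrence_matrix",
    "top_quantile_pairs",
    "BootstrapEdgeConsensus",
]


@dataclass
class BootstrapEdgeSummary:
    """Edge appearance frequencies over bootstrap resamples.

    ``directed_freq[(u, v)]`` is the fraction of resamples whose learned
    DAG contains the edge u -> v; ``undirected_freq[{u, v}]`` counts
    appearance in either orientation, so it always dominates both directed
    frequencies of the pair.
    """

    B: int
    seed: int
    directed_freq: dict[tuple[str, str], float] = field(default_factory=dict)
    undirected_freq: dict[frozenset, float] = field(default_factory=dict)

    def directed(self, u: str, v: str) -> float:
        return self.directed_freq.get((u, v), 0.0)

    def undirected(self, u: str, v: str) -> float:
        return self.undirected_freq.get(frozenset((u, v)), 0.0)


def bootstrap_edge_strength(data: pd.DataFrame, B: int = 200, seed: int = 0,
                            restarts: int = 0, max_indegree=None) -> BootstrapEdgeSummary:
    """Edge strength = appearance fraction over B bootstrap resamples.

    Each iteration resamples the rows with replacement (seeded), learns a
    structure by BIC hill climbing, and records edge presence.  A resample
    with constant columns proceeds normally: a constant variable simply
    attracts no edges.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    data = pd.DataFrame(data)
    n = len(data)
    if n < 2:
        raise ValueError("need at least 2 observations")
    rng = np.random.default_rng(seed)
    X = data.to_numpy()
    cols = [str(c) for c in data.columns]
    dir_counts: dict[tuple[str, str], int] = {}
    und_counts: dict[frozenset, int] = {}
    for _ in range(B):
        idx = rng.integers(0, n, n)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        dag = hill_climb(pd.DataFrame(X[idx], columns=cols), restarts=restarts,
                         seed=sub_seed, max_indegree=max_indegree)
        edges = dag.edges
        for e in edges:
            dir_counts[e] = dir_counts.get(e, 0) + 1
        for pair in {frozenset(e) for e in edges}:
            und_counts[pair] = und_counts.get(pair, 0) + 1
    return BootstrapEdgeSummary(
        B=B,
        seed=seed,
        directed_freq={e: c / B for e, c in dir_counts.items()},
        undirected_freq={p: c / B for p, c in und_counts.items()},
    )


@dataclass
class CooccurrenceMatrix:
    """Symmetric zone-by-zone joint involvement probabilities.

    Diagonal entries are marginal involvement frequencies; off-diagonal
    entry (a, b) is the fraction of patients (of ``denominator``) with both
    zones involved.
    """

    matrix: pd.DataFrame
    denominator: int

    def value(self, a, b) -> float:
        return float(self.matrix.loc[a, b])


def cooccurrence_matrix(cohort: pd.DataFrame,
                        denominator_mode: str = "lnm_patients") -> CooccurrenceMatrix:
    """Pairwise joint involvement probabilities over the 14 zones.

    ``denominator_mode`` selects the reference population: only
    node-positive patients (default) or all patients.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if set(ZONE_COLS) <= set(cohort.columns):
        Z = cohort[ZONE_COLS].to_numpy(dtype=float)
        index = pd.Index(range(1, 15), name="zone")
    else:  # plain binary involvement matrix
        Z = cohort.to_numpy(dtype=float)
        index = pd.Index(cohort.columns, name="zone")
    if denominator_mode == "lnm_patients":
        keep = Z.sum(axis=1) > 0
        Z = Z[keep]
    elif denominator_mode != "all_patients":
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    denom = Z.shape[0]
    if denom == 0:
        raise ValueError("denominator set is empty")
    joint = (Z.T @ Z) / denom
    m = pd.DataFrame(joint, index=index, columns=index)
    return CooccurrenceMatrix(matrix=m, denominator=denom)


def top_quantile_pairs(matrix: CooccurrenceMatrix, q: float = 0.3) -> set[frozenset]:
    """The top-q fraction of zone pairs by co-occurrence probability.

    All C(k, 2) off-diagonal pairs are ranked; the top ``ceil(q * n_pairs)``
    are returned, and ties at the cut value are all included.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    m = matrix.matrix
    labels = list(m.index)
    pairs = [
        (frozenset((labels[i], labels[j])), float(m.iloc[i, j]))
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    k = math.ceil(q * len(pairs))
    ordered = sorted(pairs, key=lambda t: -t[1])
    cut = ordered[k - 1][1]
    return {p for p, v in ordered if v >= cut}


class BootstrapEdgeConsensus(BaseEstimator):
    """Bootstrap consensus over Bayesian-network structures.

    ``fit(X)`` resamples the rows of the binary involvement matrix ``X``
    with replacement ``B`` times, learns a BIC hill-climbing structure on
    each resample, and records per-edge appearance frequencies.

    Attributes
    ----------
    summary_ : BootstrapEdgeSummary
    directed_freq_ : dict[(str, str), float]
    undirected_freq_ : dict[frozenset, float]
    """

    def __init__(self, B: int = 200, restarts: int = 0, max_indegree=None,
                 random_state: int = 0):
        self.B = B
        self.restarts = restarts
        self.max_indegree = max_indegree
        self.random_state = random_state

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray([str(c) for c in X.columns], dtype=object)
        self.n_features_in_ = X.shape[1]
        self.summary_ = bootstrap_edge_strength(
            X, B=self.B, seed=self.random_state,
            restarts=self.restarts, max_indegree=self.max_indegree,
        )
        self.directed_freq_ = self.summary_.directed_freq
        self.undirected_freq_ = self.summary_.undirected_freq
        return self
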