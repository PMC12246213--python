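"""Exact score-based Bayesian-network structure learning on binary data.

Implements the Silander–Myllymäki dynamic program over variable subsets with
BIC scoring, which returns a globally score-maximal DAG:

1. family scores for every (variable, parent set) pair;
2. best parent set within every candidate subset (subset-lattice DP);
3. best-sink DP over variable subsets;
4. reconstruction of a sink order and the attained parent sets.

All four stages are exact; no heuristic search is involved. An exhaustive
enumeration over all DAGs (feasible to 4 variables) is provided as an
independent oracle.

Counting is done once per dataset: rows are packed into integers and a single
``bincount`` yields the full joint contingency table, from which the count
table of every variable subset follows by marginalizing one variable at a
time. Family log-likelihoods then reduce to differences of ``sum N log N``
statistics, so the whole score table is assembled with array arithmetic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, product

import networkx as nx
import numpy as np
from scipy.special import xlogy

from .cohort import CohortMatrix, CohortValidationError, zero_variance_variables

#: Hard guard on network size; the subset DP is O(n * 2^n).
MAX_VARIABLES = 20


class StructureLearningError(ValueError):
    pass


@dataclass(frozen=True)
class DirectedAcyclicGraph:
    """A DAG as a parent-set map; node order fixes all tie-breaking."""

    nodes: tuple[str, ...]
    parents: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self,
            "parents",
            {v: frozenset(self.parents.get(v, frozenset())) for v in self.nodes},
        )
        known = set(self.nodes)
        for v, ps in self.parents.items():
            if v in ps:
                raise StructureLearningError(f"self-loop at {v}")
            if not ps <= known:
                raise StructureLearningError(f"unknown parents for {v}: {ps - known}")
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[str]:
        order, placed = [], set()
        remaining = set(self.nodes)
        while remaining:
            ready = sorted(v for v in remaining if self.parents[v] <= placed)
            if not ready:
                raise StructureLearningError("graph contains a cycle")
            order.extend(ready)
            placed.update(ready)
            remaining.difference_update(ready)
        return order

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted((p, v) for v in self.nodes for p in self.parents[v])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def to_json(self) -> str:
        return json.dumps(
            {v: sorted(self.parents[v]) for v in self.nodes}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "DirectedAcyclicGraph":
        data = json.loads(text)
        return cls(tuple(data.keys()), {v: frozenset(ps) for v, ps in data.items()})


def moralize(dag: DirectedAcyclicGraph) -> nx.Graph:
    """Undirect every edge and marry all co-parents of a common child.

    This is the display form used for network figures: the moral graph keeps
    every direct dependency visible without asserting edge orientation.
    """
    g = nx.Graph()
    g.add_nodes_from(dag.nodes)
    for v in dag.nodes:
        ps = sorted(dag.parents[v])
        for p in ps:
            g.add_edge(p, v)
        for a, b in combinations(ps, 2):
            g.add_edge(a, b)
    return g


# -- packed counting -------------------------------------------------------

def _pack_rows(values: np.ndarray) -> np.ndarray:
    """Encode each 0/1 row as an integer (bit i = column i)."""
    n_vars = values.shape[1]
    weights = (1 << np.arange(n_vars)).astype(np.int64)
    return values.astype(np.int64) @ weights


def _subset_nlogn(joint: np.ndarray, n_vars: int) -> np.ndarray:
    """``s[T] = sum_c N_c ln N_c`` over the count table of every variable
    subset T (bitmask-indexed), via one-variable marginalization from the
    full joint table downward."""
    tables: dict[int, np.ndarray] = {(1 << n_vars) - 1: joint.astype(float)}
    s = np.empty(1 << n_vars)
    full = (1 << n_vars) - 1
    s[full] = float(xlogy(joint, joint).sum())
    for mask in range(full - 1, -1, -1):
        missing = (~mask) & full
        b = (missing & -missing).bit_length() - 1  # lowest missing variable
        sup = mask | (1 << b)
        pos = bin(sup & ((1 << b) - 1)).count("1")  # compact position of b
        tab = tables[sup].reshape(-1, 2, 1 << pos).sum(axis=1).ravel()
        tables[mask] = tab
        s[mask] = float(xlogy(tab, tab).sum())
    return s


@lru_cache(maxsize=8)
def _lattice_index(n_vars: int):
    """Per-popcount-layer index arrays for the subset DPs (cached per n)."""
    masks = np.arange(1 << n_vars)
    pop = np.array([bin(m).count("1") for m in masks])
    layers = []
    for k in range(1, n_vars + 1):
        mk = masks[pop == k]
        bits = np.empty((len(mk), k), dtype=np.int64)
        childs = np.empty((len(mk), k), dtype=np.int64)
        for r, m in enumerate(mk):
            bs = [b for b in range(n_vars) if m >> b & 1]
            bits[r] = bs
            childs[r] = [m ^ (1 << b) for b in bs]
        layers.append((mk, bits, childs))
    return pop, layers


def _family_score_array(packed: np.ndarray, n_vars: int, n_rows: int,
                        max_parents: int | None) -> np.ndarray:
    """scores[v, P] = BIC family score of parent set P (bitmask) for node v;
    -inf where v is in P or |P| exceeds the cap."""
    joint = np.bincount(packed, minlength=1 << n_vars)
    s = _subset_nlogn(joint, n_vars)
    pop, _ = _lattice_index(n_vars)
    penalty = 0.5 * np.log(n_rows) * (2.0 ** pop)
    scores = np.full((n_vars, 1 << n_vars), -np.inf)
    masks = np.arange(1 << n_vars)
    for v in range(n_vars):
        sel = masks[(masks >> v) & 1 == 0]
        ok = sel if max_parents is None else sel[pop[sel] <= max_parents]
        scores[v, ok] = s[ok | (1 << v)] - s[ok] - penalty[ok]
    return scores


def family_bic_score(matrix: CohortMatrix, v: str, parents=()) -> float:
    """BIC score of one (node, parent set) family.

    Maximized multinomial log-likelihood (natural log, 0*log 0 = 0) minus
    ``(ln N / 2) * 2^|parents| * (r - 1)`` with r = 2 states. Parent
    configurations never observed contribute zero likelihood but still count
    in the penalty.
    """
    _require_complete(matrix)
    names = matrix.variable_names
    parents = sorted(set(parents))
    if v in parents:
        raise StructureLearningError(f"{v} cannot be its own parent")
    cols = [names.index(p) for p in parents] + [names.index(v)]
    sub = matrix.values[:, cols]
    packed = _pack_rows(sub)
    counts = np.bincount(packed, minlength=1 << len(cols))
    pair = counts.reshape(2, -1)  # axis 0: v (highest bit), axis 1: parent cfg
    n_pa = pair.sum(axis=0)
    ll = float(xlogy(pair, pair).sum() - xlogy(n_pa, n_pa).sum())
    q = 2 ** len(parents)
    return ll - 0.5 * np.log(matrix.n_patients) * q


def network_score(matrix: CohortMatrix, dag: DirectedAcyclicGraph) -> float:
    """Total BIC score of a DAG: the sum of its family scores."""
    return sum(family_bic_score(matrix, v, dag.parents[v]) for v in dag.nodes)


@dataclass
class FamilyScoreTable:
    """Every family score up to the parent cap, keyed by (node, parent set)."""

    entries: dict[tuple[str, frozenset[str]], float]
    N: int
    max_parents: int | None


def compute_score_table(matrix: CohortMatrix, max_parents: int | None = None
                        ) -> FamilyScoreTable:
    _require_complete(matrix)
    _guard_size(matrix)
    names = matrix.variable_names
    n = len(names)
    scores = _family_score_array(
        _pack_rows(matrix.values), n, matrix.n_patients, max_parents
    )
    entries = {}
    for v in range(n):
        for mask in range(1 << n):
            if np.isfinite(scores[v, mask]):
                ps = frozenset(names[b] for b in range(n) if mask >> b & 1)
                entries[(names[v], ps)] = float(scores[v, mask])
    return FamilyScoreTable(entries, matrix.n_patients, max_parents)


def _require_complete(matrix: CohortMatrix) -> None:
    if not matrix.is_complete:
        raise CohortValidationError(
            "matrix has missing values; impute before structure learning"
        )


def _guard_size(matrix: CohortMatrix) -> None:
    if matrix.n_variables > MAX_VARIABLES:
        raise StructureLearningError(
            f"{matrix.n_variables} variables exceeds the exact-search guard "
            f"({MAX_VARIABLES}); cap max_parents and subset the variables"
        )
    if matrix.n_patients == 0:
        raise StructureLearningError("empty matrix")


def _iter_submasks(mask: int):
    sub = mask
    while True:
        yield sub
        if sub == 0:
            return
        sub = (sub - 1) & mask


def learn_exact(matrix: CohortMatrix, max_parents: int | None = None
                ) -> DirectedAcyclicGraph:
    """Globally BIC-optimal DAG via the exact dynamic program.

    Ties among equal-scoring parent sets are broken toward smaller
    cardinality, then lexicographically by node name; ties among sinks
    lexicographically — the result is deterministic for a given matrix.
    """
    _require_complete(matrix)
    _guard_size(matrix)
    names = matrix.variable_names
    n = len(names)
    if n == 1:
        return DirectedAcyclicGraph((names[0],), {})
    dead = zero_variance_variables(matrix)
    if len(dead) == matrix.n_variables:
        warnings.warn("all variables constant; returning the empty DAG",
                      stacklevel=2)
        return DirectedAcyclicGraph(tuple(names), {})

    scores = _family_score_array(
        _pack_rows(matrix.values), n, matrix.n_patients, max_parents
    )
    _, layers = _lattice_index(n)

    # best parent set score bp[v, C] for candidate sets C (v not in C)
    bp = scores.copy()
    bp[:, 0] = scores[:, 0]
    for mk, bits, childs in layers:
        cand = bp[:, childs].max(axis=2)          # (n, L)
        bp[:, mk] = np.maximum(bp[:, mk], cand)

    # best-network score over each variable subset, via best sink
    best = np.full(1 << n, -np.inf)
    best[0] = 0.0
    for mk, bits, childs in layers:
        cand = best[childs] + bp[bits, childs]    # (L, k)
        best[mk] = cand.max(axis=1)

    # reconstruct: peel sinks from the full set, smallest name first on ties
    parents: dict[str, frozenset[str]] = {}
    W = (1 << n) - 1
    while W:
        target = best[W]
        sink = None
        for b in sorted(range(n), key=lambda b: names[b]):
            if W >> b & 1 and best[W ^ (1 << b)] + bp[b, W ^ (1 << b)] == target:
                sink = b
                break
        assert sink is not None
        C = W ^ (1 << sink)
        parents[names[sink]] = _best_parent_set(scores, bp, names, sink, C)
        W = C
    return DirectedAcyclicGraph(tuple(names), parents)


def _best_parent_set(scores, bp, names, v: int, C: int) -> frozenset[str]:
    """Smallest, lexicographically-first parent set attaining bp[v, C]."""
    target = bp[v, C]
    candidates = [m for m in _iter_submasks(C) if scores[v, m] == target]
    key = lambda m: (bin(m).count("1"),
                     tuple(sorted(names[b] for b in range(len(names))
                                  if m >> b & 1)))
    m = min(candidates, key=key)
    return frozenset(names[b] for b in range(len(names)) if m >> b & 1)


# -- exhaustive oracle -----------------------------------------------------

def enumerate_dags(names: tuple[str, ...]):
    """Yield every DAG over the given nodes (feasible for <= 4 nodes)."""
    n = len(names)
    others = [[frozenset(c) for r in range(n)
               for c in combinations(set(names) - {v}, r)] for v in names]
    for assignment in product(*others):
        try:
            yield DirectedAcyclicGraph(tuple(names),
                                       dict(zip(names, assignment)))
        except StructureLearningError:
            continue


def exhaustive_best_dag(matrix: CohortMatrix
                        ) -> tuple[DirectedAcyclicGraph, float]:
    """Brute-force score maximization over all DAGs; the oracle for
    :func:`learn_exact` at tiny scale."""
    if matrix.n_variables > 4:
        raise StructureLearningError(
            "exhaustive enumeration is limited to 4 variables"
        )
    _require_complete(matrix)
    names = tuple(matrix.variable_names)
    family = {
        (v, ps): family_bic_score(matrix, v, ps)
        for v in names
        for r in range(len(names))
        for ps in (frozenset(c) for c in combinations(set(names) - {v}, r))
    }
    best_dag, best_score = None, -np.inf
    for dag in enumerate_dags(names):
        score = sum(family[(v, dag.parents[v])] for v in names)
        if score > best_score:
            best_dag, best_score = dag, score
    return best_dag, float(best_score)
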