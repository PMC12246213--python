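"""Conditional probability tables and exact inference ("network propagation").

A fitted network is a DAG plus one CPT per node, each row giving
``P(v = 1 | parent configuration)``. Queries are answered exactly: the
reference route enumerates the full joint over all ``2^n`` assignments; an
einsum-based factor-contraction route is kept as an independently coded
check, and the two must agree to machine precision.

Zero-state smoothing adds a pseudocount ``s`` to each of the two outcome
counts of every CPT cell: ``P(v=1|pa) = (n1 + s) / (n0 + n1 + 2 s)``. Two
policies are supported — a fixed value (default 0.01) and ``s = 1/N`` — to
prevent zero-probability states when fitting resampled data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cohort import CohortMatrix, CohortValidationError
from .structure import DirectedAcyclicGraph


class InferenceError(ValueError):
    pass


class ImpossibleEvidenceError(InferenceError):
    """Raised when conditioning on a zero-probability event."""


@dataclass(frozen=True)
class ConditionalProbabilityTable:
    """P(v=1 | parents) with rows indexed by the parent-bit configuration
    (``parent_order[i]`` contributes bit ``i``)."""

    variable: str
    parent_order: tuple[str, ...]
    p1: np.ndarray  # shape (2**len(parent_order),)

    def __post_init__(self):
        p1 = np.asarray(self.p1, dtype=float)
        object.__setattr__(self, "p1", p1)
        if p1.shape != (2 ** len(self.parent_order),):
            raise InferenceError(
                f"CPT for {self.variable} needs one row per parent "
                f"configuration (got {p1.shape})"
            )
        ok = np.isnan(p1) | ((p1 >= 0.0) & (p1 <= 1.0))
        if not ok.all():
            raise InferenceError(f"CPT rows for {self.variable} outside [0,1]")

    @property
    def has_undefined_rows(self) -> bool:
        return bool(np.isnan(self.p1).any())


@dataclass(frozen=True)
class FittedNetwork:
    dag: DirectedAcyclicGraph
    cpts: dict[str, ConditionalProbabilityTable]
    N: int
    smoothing_policy: str = "fixed"
    smoothing_value: float = 0.01

    def __post_init__(self):
        missing = set(self.dag.nodes) - set(self.cpts)
        if missing:
            raise InferenceError(f"no CPT for nodes: {sorted(missing)}")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    def to_json(self) -> str:
        return json.dumps(
            {
                "N": self.N,
                "smoothing": {"policy": self.smoothing_policy,
                              "value": self.smoothing_value},
                "nodes": {
                    v: {
                        "parents": list(self.cpts[v].parent_order),
                        "p1": [None if np.isnan(x) else x
                               for x in self.cpts[v].p1],
                    }
                    for v in self.nodes
                },
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedNetwork":
        data = json.loads(text)
        nodes = tuple(data["nodes"].keys())
        dag = DirectedAcyclicGraph(
            nodes,
            {v: frozenset(d["parents"]) for v, d in data["nodes"].items()},
        )
        cpts = {
            v: ConditionalProbabilityTable(
                v, tuple(d["parents"]),
                np.array([np.nan if x is None else x for x in d["p1"]]),
            )
            for v, d in data["nodes"].items()
        }
        return cls(dag, cpts, int(data["N"]),
                   data["smoothing"]["policy"],
                   float(data["smoothing"]["value"]))


def resolve_smoothing(policy, N: int) -> tuple[str, float]:
    """Map a smoothing spec (number, ``"1/N"`` or ``None``) to (policy, s)."""
    if policy is None:
        return "none", 0.0
    if isinstance(policy, str):
        if policy in ("1/N", "1/n", "korrection", "kn"):
            if N <= 0:
                raise InferenceError("1/N smoothing needs N > 0")
            return "1/N", 1.0 / N
        raise InferenceError(f"unknown smoothing policy {policy!r}")
    s = float(policy)
    if s < 0:
        raise InferenceError("smoothing must be non-negative")
    return ("none", 0.0) if s == 0 else ("fixed", s)


def fit_cpts(dag: DirectedAcyclicGraph, matrix: CohortMatrix,
             smoothing=0.01) -> FittedNetwork:
    """Maximum-likelihood CPTs with additive smoothing.

    With ``s > 0`` an unseen parent configuration yields 0.5 (the symmetric
    prior); with ``s = 0`` it is stored as NaN and any query touching it
    fails loudly.
    """
    if not matrix.is_complete:
        raise CohortValidationError("matrix has missing values; impute first")
    names = matrix.variable_names
    if not set(dag.nodes) <= set(names):
        raise InferenceError("DAG nodes must be matrix variables")
    policy, s = resolve_smoothing(smoothing, matrix.n_patients)
    cpts = {}
    for v in dag.nodes:
        parents = tuple(sorted(dag.parents[v]))
        vcol = matrix.column(v).astype(np.int64)
        cfg = np.zeros(matrix.n_patients, dtype=np.int64)
        for i, p in enumerate(parents):
            cfg |= matrix.column(p).astype(np.int64) << i
        q = 2 ** len(parents)
        n1 = np.bincount(cfg[vcol == 1], minlength=q).astype(float)
        ntot = np.bincount(cfg, minlength=q).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = (n1 + s) / (ntot + 2 * s)
        if s == 0:
            p1[ntot == 0] = np.nan
        cpts[v] = ConditionalProbabilityTable(v, parents, p1)
    return FittedNetwork(dag, cpts, matrix.n_patients, policy, s)


# -- joint / queries -------------------------------------------------------

def joint_probability(fn: FittedNetwork, assignment: Mapping[str, int]) -> float:
    """Chain-rule probability of one full assignment.

    An undefined (unsmoothed, unseen-configuration) CPT row is tolerated
    only when another factor already makes the assignment impossible;
    otherwise it is an error.
    """
    if set(assignment) != set(fn.nodes):
        raise InferenceError("assignment must cover every node exactly")
    factors = []
    for v in fn.nodes:
        cpt = fn.cpts[v]
        cfg = sum(int(assignment[par]) << i
                  for i, par in enumerate(cpt.parent_order))
        row = cpt.p1[cfg]
        factors.append(row if assignment[v] == 1 else 1.0 - row)
    if any(f == 0.0 for f in factors):
        return 0.0
    if any(np.isnan(f) for f in factors):
        raise InferenceError(
            "undefined CPT row on a reachable configuration "
            "(unseen parent configuration, unsmoothed fit)"
        )
    return float(np.prod(factors))


def joint_table(fn: FittedNetwork) -> np.ndarray:
    """Joint over all ``2^n`` assignments; entry index has bit i = node i
    (in ``fn.nodes`` order). The enumeration reference route."""
    nodes = fn.nodes
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    assignments = np.arange(1 << n, dtype=np.int64)
    joint = np.ones(1 << n)
    touches_undefined = np.zeros(1 << n, dtype=bool)
    for v in nodes:
        cpt = fn.cpts[v]
        cfg = np.zeros(1 << n, dtype=np.int64)
        for i, par in enumerate(cpt.parent_order):
            cfg |= ((assignments >> idx[par]) & 1) << i
        val = (assignments >> idx[v]) & 1
        p1 = cpt.p1[cfg]
        if cpt.has_undefined_rows:
            touches_undefined |= np.isnan(p1)
            p1 = np.nan_to_num(p1, nan=0.5)  # placeholder; must be unreachable
        joint *= np.where(val == 1, p1, 1.0 - p1)
    if joint[touches_undefined].sum() > 0.0:
        raise InferenceError(
            "undefined CPT rows carry probability mass; fit with smoothing > 0"
        )
    return joint


def _check_assignment(fn, mapping, label):
    for v, val in mapping.items():
        if v not in fn.nodes:
            raise InferenceError(f"unknown {label} variable {v!r}")
        if val not in (0, 1):
            raise InferenceError(f"{label} value for {v!r} must be 0 or 1")


def query(fn: FittedNetwork, targets: Mapping[str, int],
          evidence: Mapping[str, int] | None = None,
          method: str = "enumeration") -> float:
    """Exact ``P(targets | evidence)`` by summation over hidden variables."""
    evidence = dict(evidence or {})
    targets = dict(targets)
    if not targets:
        raise InferenceError("empty target assignment")
    _check_assignment(fn, targets, "target")
    _check_assignment(fn, evidence, "evidence")
    if set(targets) & set(evidence):
        raise InferenceError("targets and evidence must be disjoint")
    if method == "enumeration":
        return _query_enumeration(fn, targets, evidence)
    if method == "einsum":
        return _query_einsum(fn, targets, evidence)
    raise InferenceError(f"unknown method {method!r}")


def _query_enumeration(fn, targets, evidence) -> float:
    joint = joint_table(fn)
    idx = {v: i for i, v in enumerate(fn.nodes)}
    assignments = np.arange(len(joint), dtype=np.int64)
    emask = np.ones(len(joint), dtype=bool)
    for v, val in evidence.items():
        emask &= ((assignments >> idx[v]) & 1) == val
    pe = joint[emask].sum()
    if pe == 0.0:
        raise ImpossibleEvidenceError(
            f"evidence {evidence} has probability zero"
        )
    tmask = emask.copy()
    for v, val in targets.items():
        tmask &= ((assignments >> idx[v]) & 1) == val
    return float(joint[tmask].sum() / pe)


def _query_einsum(fn, targets, evidence) -> float:
    """Factor contraction with evidence slicing — the independent route."""
    import string

    letters = dict(zip(fn.nodes, string.ascii_lowercase))
    operands, subscripts = [], []
    for v in fn.nodes:
        cpt = fn.cpts[v]
        if cpt.has_undefined_rows:
            raise InferenceError(
                f"undefined CPT rows for {v}; fit with smoothing > 0"
            )
        k = len(cpt.parent_order)
        fac = np.empty((2,) * (k + 1))
        for cfg in range(2 ** k):
            sel = tuple((cfg >> i) & 1 for i in range(k))
            fac[sel + (1,)] = cpt.p1[cfg]
            fac[sel + (0,)] = 1.0 - cpt.p1[cfg]
        operands.append(fac)
        subscripts.append("".join(letters[p] for p in cpt.parent_order)
                          + letters[v])
    for v, val in evidence.items():
        ind = np.zeros(2)
        ind[val] = 1.0
        operands.append(ind)
        subscripts.append(letters[v])
    tvars = sorted(targets)
    expr = ",".join(subscripts) + "->" + "".join(letters[v] for v in tvars)
    marg = np.einsum(expr, *operands)
    pe = marg.sum()
    if pe == 0.0:
        raise ImpossibleEvidenceError(
            f"evidence {evidence} has probability zero"
        )
    return float(marg[tuple(targets[v] for v in tvars)] / pe)
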