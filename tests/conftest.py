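"""Shared fixtures and generators for the test suite.

All randomness is seeded; synthetic inputs are built in-process, never read
from disk fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from chdnet.cohort import CohortMatrix, VariableSpec
from chdnet.inference import ConditionalProbabilityTable, FittedNetwork
from chdnet.simulate import pcgc_like_scenario
from chdnet.structure import DirectedAcyclicGraph


def make_matrix(values, names=None, ids=None) -> CohortMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    names = names or [f"V{j}" for j in range(m)]
    ids = ids or [f"p{i}" for i in range(n)]
    return CohortMatrix(ids, [VariableSpec(x) for x in names], values)


def random_binary_matrix(rng: np.random.Generator, n_rows: int,
                         n_cols: int) -> CohortMatrix:
    """Random dependent binary data: a random DAG-free logistic mixing so
    columns are correlated but not degenerate."""
    base = rng.uniform(0.2, 0.8, size=n_cols)
    vals = (rng.random((n_rows, n_cols)) < base).astype(float)
    # mix in dependence on a random earlier column
    for j in range(1, n_cols):
        src = rng.integers(0, j)
        flip = rng.random(n_rows) < 0.3
        vals[flip, j] = vals[flip, src]
    return make_matrix(vals)


def random_fitted_network(rng: np.random.Generator, n_nodes: int
                          ) -> FittedNetwork:
    """Random DAG (edges respect index order) with uniform-random CPTs."""
    names = tuple(f"N{i}" for i in range(n_nodes))
    parents = {}
    for i, v in enumerate(names):
        cand = list(names[:i])
        k = rng.integers(0, min(len(cand), 3) + 1)
        parents[v] = frozenset(rng.choice(cand, size=k, replace=False)) \
            if k else frozenset()
    dag = DirectedAcyclicGraph(names, parents)
    cpts = {
        v: ConditionalProbabilityTable(
            v, tuple(sorted(parents[v])),
            rng.uniform(0.05, 0.95, size=2 ** len(parents[v])),
        )
        for v in names
    }
    return FittedNetwork(dag, cpts, N=0, smoothing_policy="none",
                         smoothing_value=0.0)


def brute_force_conditional(fn: FittedNetwork, targets: dict,
                            evidence: dict) -> float:
    """Plain-Python enumeration oracle, independent of the library's
    vectorized joint construction."""
    from itertools import product

    nodes = list(fn.nodes)
    p_evidence = 0.0
    p_joint = 0.0
    for bits in product((0, 1), repeat=len(nodes)):
        asg = dict(zip(nodes, bits))
        p = 1.0
        for v in nodes:
            cpt = fn.cpts[v]
            cfg = 0
            for i, par in enumerate(cpt.parent_order):
                cfg += asg[par] * (2 ** i)
            row = float(cpt.p1[cfg])
            p *= row if asg[v] == 1 else 1.0 - row
        if all(asg[k] == v for k, v in evidence.items()):
            p_evidence += p
            if all(asg[k] == v for k, v in targets.items()):
                p_joint += p
    return p_joint / p_evidence


def skeleton(dag: DirectedAcyclicGraph) -> set[frozenset]:
    return {frozenset((p, v)) for p, v in dag.edges}


def v_structures(dag: DirectedAcyclicGraph) -> set[tuple]:
    """Colliders a -> c <- b with a, b non-adjacent."""
    sk = skeleton(dag)
    out = set()
    for c in dag.nodes:
        ps = sorted(dag.parents[c])
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                if frozenset((ps[i], ps[j])) not in sk:
                    out.add((ps[i], c, ps[j]))
    return out


@pytest.fixture(scope="session")
def scenario():
    return pcgc_like_scenario()
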