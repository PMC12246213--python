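"""Synthetic cohorts with the statistical structure of a CHD surgical study.

The generator owns a ground-truth Bayesian network (DAG + CPTs) over binary
genotype / phenotype / surgical / outcome flags, calibrated so that exact
enumeration of its joint reproduces the anchored cohort summaries: a 10.6%
damaging-genotype prevalence split over two pathway flags, deterministic
phenotype nesting (HLHS within LVO), and planted absolute/relative risk
ratios in the 1.4–4.0 range. Cohorts are drawn by seeded ancestral sampling;
missingness is injected completely at random (MCAR). The same network
doubles as an exact oracle — enumeration-based true risk ratios — for every
recovery and calibration test downstream.

A second generator emits phenotype-code (Fyler-style) matrices with
category-specific and shared codes for classifier tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import fsolve

from .cohort import CohortMatrix, VariableSpec
from .inference import (
    ConditionalProbabilityTable,
    FittedNetwork,
    ImpossibleEvidenceError,
    joint_table,
    query,
)
from .structure import DirectedAcyclicGraph

MISSING_RATE_CAP = 0.10


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GroundTruthNetwork:
    """The generative DAG+CPT model; also the exact oracle for risk ratios."""

    variables: tuple[VariableSpec, ...]
    network: FittedNetwork

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def enumerated_marginal(self, name: str) -> float:
        return query(self.network, {name: 1})


@dataclass(frozen=True)
class ScenarioConfig:
    n_patients: int = 2253
    seed: int = 0
    missing_rate: float = 0.05
    scenario: str = "pcgc_like"

    def __post_init__(self):
        if self.n_patients < 0:
            raise SimulationError("n_patients must be >= 0")
        if not 0.0 <= self.missing_rate <= MISSING_RATE_CAP:
            raise SimulationError(
                f"missing_rate {self.missing_rate} outside [0, "
                f"{MISSING_RATE_CAP}]"
            )


# -- calibrated scenario ---------------------------------------------------

def _load_preset(name: str) -> dict:
    path = resources.files("chdnet.presets").joinpath(f"{name}.yaml")
    return yaml.safe_load(path.read_text())


def _solve_outcome_cpt(weights: np.ndarray, marginal: float, rr_chrm: float,
                       rr_cilia: float, c_stat: float) -> np.ndarray:
    """Solve the multiplicative outcome CPT against exact enumeration.

    ``weights`` is the joint P(CHRMdGV, CILIAdGV, STAT45) over 8 parent
    configurations (bit order chrm, cilia, stat). Returns P(out=1 | cfg)
    with cfg bit order (CHRMdGV, CILIAdGV, STAT45), such that the enumerated
    marginal and both genotype-contrast relative risk ratios equal their
    anchors.
    """
    cfg = np.arange(8)
    chrm, cilia, stat = cfg & 1, (cfg >> 1) & 1, (cfg >> 2) & 1

    def cpt(x):
        base, a, b = np.exp(x)
        return np.clip(base * a**chrm * b**cilia * c_stat**stat, 0.0, 1.0)

    def residuals(x):
        p = cpt(x)
        m = float(weights @ p)
        w1 = weights * (chrm == 1)
        w0 = weights * (chrm == 0)
        rrc = float(w1 @ p) / w1.sum() / (float(w0 @ p) / w0.sum())
        u1 = weights * (cilia == 1)
        u0 = weights * (cilia == 0)
        rrl = float(u1 @ p) / u1.sum() / (float(u0 @ p) / u0.sum())
        return [m - marginal, rrc - rr_chrm, rrl - rr_cilia]

    x0 = np.log([marginal / 2.0, rr_chrm, rr_cilia])
    x, info, ier, msg = fsolve(residuals, x0, full_output=True)
    if ier != 1 or np.max(np.abs(residuals(x))) > 1e-10:
        raise SimulationError(f"outcome CPT calibration failed: {msg}")
    return cpt(x)


def _anchored_child_cpt(marginal: float, absolute_rr: float,
                        parent_prev: float) -> np.ndarray:
    """Closed-form CPT for a child with one root parent, anchored by its
    marginal and the absolute risk ratio P(v|parent=1)/P(v)."""
    p1 = absolute_rr * marginal
    p0 = (marginal - p1 * parent_prev) / (1.0 - parent_prev)
    if not (0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0):
        raise SimulationError(
            f"anchors (marginal={marginal}, rr={absolute_rr}) are infeasible"
        )
    return np.array([p0, p1])


@lru_cache(maxsize=4)
def pcgc_like_scenario(preset: str = "pcgc_like") -> GroundTruthNetwork:
    """Ground-truth network calibrated to the anchored cohort summaries.

    Variables: CHRMdGV, CILIAdGV (damaging-genotype pathway flags), LVO,
    HLHS, HTX (CHD phenotype categories; HLHS deterministically implies
    LVO), ECA (extracardiac anomaly), STAT45 (highest surgical-risk
    category), and the post-operative outcomes MORT, ARREST, VENT7.
    """
    cfg = _load_preset(preset)
    specs: list[VariableSpec] = []
    parents: dict[str, frozenset[str]] = {}
    cpts: dict[str, ConditionalProbabilityTable] = {}

    for name, rc in cfg["roots"].items():
        specs.append(VariableSpec(name, rc["role"], "damaging-genotype flag"))
        parents[name] = frozenset()
        cpts[name] = ConditionalProbabilityTable(
            name, (), np.array([rc["prevalence"]])
        )
    root_prev = {n: rc["prevalence"] for n, rc in cfg["roots"].items()}

    for name, ac in cfg["anchored_children"].items():
        par = ac["parent"]
        specs.append(VariableSpec(name, ac["role"]))
        parents[name] = frozenset([par])
        cpts[name] = ConditionalProbabilityTable(
            name, (par,),
            _anchored_child_cpt(ac["marginal"], ac["absolute_rr"],
                                root_prev[par]),
        )

    hl = cfg["hlhs"]
    specs.append(VariableSpec("HLHS", hl["role"], "subset of LVO"))
    hp = sorted(hl["parents"])  # CPT parent order is sorted, bit i = hp[i]
    parents["HLHS"] = frozenset(hp)
    rows = np.zeros(4)
    for c in range(4):
        vals = {hp[i]: (c >> i) & 1 for i in range(2)}
        if vals["LVO"] == 0:
            rows[c] = hl["p_given"]["lvo0"]
        elif vals["CHRMdGV"] == 0:
            rows[c] = hl["p_given"]["lvo1_chrm0"]
        else:
            rows[c] = hl["p_given"]["lvo1_chrm1"]
    cpts["HLHS"] = ConditionalProbabilityTable("HLHS", tuple(hp), rows)

    st = cfg["stat45"]
    specs.append(VariableSpec("STAT45", st["role"], "STAT category 4 or 5"))
    sp = sorted(st["parents"])
    parents["STAT45"] = frozenset(sp)
    rows = np.zeros(4)
    for c in range(4):
        vals = {sp[i]: (c >> i) & 1 for i in range(2)}
        if vals["HLHS"] and vals["HTX"]:
            rows[c] = st["p_given"]["both"]
        elif vals["HLHS"]:
            rows[c] = st["p_given"]["hlhs"]
        elif vals["HTX"]:
            rows[c] = st["p_given"]["htx"]
        else:
            rows[c] = st["p_given"]["base"]
    cpts["STAT45"] = ConditionalProbabilityTable("STAT45", tuple(sp), rows)

    # parent-configuration weights P(CHRMdGV, CILIAdGV, STAT45) for outcome
    # calibration, from the upstream network
    up_nodes = tuple(v.name for v in specs)
    upstream = FittedNetwork(
        DirectedAcyclicGraph(up_nodes, {k: parents[k] for k in up_nodes}),
        {k: cpts[k] for k in up_nodes}, N=0, smoothing_policy="exact",
        smoothing_value=0.0,
    )
    jt = joint_table(upstream)
    idx = {v: i for i, v in enumerate(up_nodes)}
    asg = np.arange(len(jt))
    weights = np.zeros(8)
    key = (((asg >> idx["CHRMdGV"]) & 1)
           | (((asg >> idx["CILIAdGV"]) & 1) << 1)
           | (((asg >> idx["STAT45"]) & 1) << 2))
    np.add.at(weights, key, jt)

    out_parents = ("CHRMdGV", "CILIAdGV", "STAT45")
    for name, oc in cfg["outcomes"].items():
        specs.append(VariableSpec(name, oc["role"]))
        parents[name] = frozenset(out_parents)
        p_cfg = _solve_outcome_cpt(
            weights, oc["marginal"], oc["relative_rr_chrm"],
            oc["relative_rr_cilia"], oc["stat_multiplier"],
        )
        cpts[name] = ConditionalProbabilityTable(name, out_parents, p_cfg)

    names = tuple(v.name for v in specs)
    dag = DirectedAcyclicGraph(names, parents)
    fn = FittedNetwork(dag, cpts, N=0, smoothing_policy="exact",
                       smoothing_value=0.0)
    return GroundTruthNetwork(tuple(specs), fn)


# -- sampling --------------------------------------------------------------

def sample_cohort(gtn: GroundTruthNetwork, n: int, seed: int) -> CohortMatrix:
    """Ancestral sampling of n i.i.d. patients, seed-deterministic.

    Nodes are sampled in a fixed topological order (independent of variable
    declaration order); output columns follow the scenario's variable order.
    """
    if n < 0:
        raise SimulationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    fn = gtn.network
    names = list(gtn.variable_names)
    data = {}
    for v in fn.dag.topological_order():
        cpt = fn.cpts[v]
        cfg = np.zeros(n, dtype=np.int64)
        for i, p in enumerate(cpt.parent_order):
            cfg |= data[p] << i
        data[v] = (rng.random(n) < cpt.p1[cfg]).astype(np.int64)
    values = np.column_stack([data[v] for v in names]).astype(float) \
        if n else np.empty((0, len(names)))
    return CohortMatrix(
        patient_ids=[f"P{i:06d}" for i in range(n)],
        variables=list(gtn.variables),
        values=values,
    )


def inject_missingness(matrix: CohortMatrix, rate: float, seed: int,
                       override_cap: bool = False) -> CohortMatrix:
    """Set each cell missing independently with the given probability
    (missing completely at random)."""
    if rate < 0:
        raise SimulationError("rate must be >= 0")
    if rate > MISSING_RATE_CAP and not override_cap:
        raise SimulationError(
            f"rate {rate} exceeds the cap {MISSING_RATE_CAP}; "
            "pass override_cap=True to exceed it"
        )
    if rate == 0:
        return matrix
    rng = np.random.default_rng(seed)
    mask = rng.random(matrix.values.shape) < rate
    values = matrix.values.copy()
    values[mask] = np.nan
    return CohortMatrix(list(matrix.patient_ids), list(matrix.variables),
                        values, missing_cap=max(matrix.missing_cap, 1.0))


def simulate_cohort(config: ScenarioConfig) -> CohortMatrix:
    """Sample a cohort per the scenario config, with MCAR missingness."""
    gtn = pcgc_like_scenario(config.scenario)
    cohort = sample_cohort(gtn, config.n_patients, config.seed)
    if config.missing_rate > 0:
        cohort = inject_missingness(cohort, config.missing_rate,
                                    seed=config.seed + 1)
    return cohort


# -- exact risk-ratio oracles ---------------------------------------------

def true_absolute_rr(gtn: GroundTruthNetwork, target: tuple[str, int],
                     condition: tuple[str, int]) -> float:
    """P(target | condition) / P(target), by exact CPT enumeration."""
    tv, tval = target
    cv, cval = condition
    try:
        if tv == cv:
            # self-conditioning: P(T|T) is 1 (or 0), ratio collapses to 1/P(T)
            if query(gtn.network, {cv: cval}) == 0.0:
                raise SimulationError(f"undefined ratio: P({cv}={cval}) = 0")
            num = 1.0 if tval == cval else 0.0
        else:
            num = query(gtn.network, {tv: tval}, {cv: cval})
    except ImpossibleEvidenceError as e:
        raise SimulationError(f"undefined ratio: {e}") from e
    den = query(gtn.network, {tv: tval})
    if den == 0.0:
        raise SimulationError(f"undefined ratio: P({tv}={tval}) = 0")
    return num / den


def true_relative_rr(gtn: GroundTruthNetwork, targets: dict[str, int],
                     factor: str) -> float:
    """P(targets | factor=1) / P(targets | factor=0), by exact enumeration."""
    if factor in targets:
        raise SimulationError("factor must not be among the targets")
    try:
        num = query(gtn.network, targets, {factor: 1})
        den = query(gtn.network, targets, {factor: 0})
    except ImpossibleEvidenceError as e:
        raise SimulationError(f"undefined ratio: {e}") from e
    if den == 0.0:
        raise SimulationError("undefined ratio: zero denominator probability")
    return num / den


# -- Fyler-code scenario ---------------------------------------------------

CATEGORIES = ("LVO", "HTX", "AVC", "CTD", "OTH")


@dataclass(frozen=True)
class FylerScenario:
    """Emission model for phenotype-code matrices.

    Each patient draws a category from ``priors`` and then emits each code
    independently with that category's Bernoulli probability. Category-
    specific codes fire at ``p_specific`` in their own category and at
    ``p_specific * mixing`` elsewhere; shared low-information codes (the
    pulmonary-stenosis / septal-defect analogue) fire everywhere.
    """

    categories: tuple[str, ...] = CATEGORIES
    priors: tuple[float, ...] = (0.287, 0.097, 0.028, 0.415, 0.173)
    n_specific: int = 4
    n_shared: int = 6
    p_specific: float = 0.75
    p_shared: float = 0.30
    mixing: float = 0.05

    def __post_init__(self):
        if len(self.priors) != len(self.categories):
            raise SimulationError("one prior per category required")
        if abs(sum(self.priors) - 1.0) > 1e-9:
            raise SimulationError("priors must sum to 1")

    @property
    def codes(self) -> tuple[str, ...]:
        spec = [f"FC_{cat}_{i}" for cat in self.categories
                for i in range(self.n_specific)]
        shared = [f"FC_SHARED_{i}" for i in range(self.n_shared)]
        return tuple(spec + shared)

    def emission_matrix(self) -> np.ndarray:
        """(n_categories, n_codes) Bernoulli emission probabilities."""
        k = len(self.categories)
        em = np.zeros((k, len(self.codes)))
        for ci in range(k):
            for cj in range(k):
                block = slice(cj * self.n_specific, (cj + 1) * self.n_specific)
                em[ci, block] = (self.p_specific if ci == cj
                                 else self.p_specific * self.mixing)
        em[:, k * self.n_specific:] = self.p_shared
        return em


def separable_fyler_scenario() -> FylerScenario:
    """One perfectly informative code per category, no crosstalk."""
    return FylerScenario(n_specific=1, n_shared=0, p_specific=1.0,
                         mixing=0.0)


def generate_fyler_cohort(fs: FylerScenario, n: int, seed: int
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Sample a binary code matrix plus true category labels."""
    rng = np.random.default_rng(seed)
    cats = rng.choice(len(fs.categories), size=n, p=np.asarray(fs.priors))
    em = fs.emission_matrix()
    codes = (rng.random((n, em.shape[1])) < em[cats]).astype(np.int64)
    ids = pd.Index([f"P{i:06d}" for i in range(n)], name="patient_id")
    frame = pd.DataFrame(codes, index=ids, columns=list(fs.codes))
    labels = pd.Series([fs.categories[c] for c in cats], index=ids,
                       name="category")
    return frame, labels
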