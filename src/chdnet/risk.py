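"""Network-propagated risk ratios with bootstrap confidence intervals.

Two ratios summarize risk in a fitted network:

* absolute RR — ``P(target | condition) / P(target)``: enrichment of a
  target state among carriers of a condition relative to the whole cohort;
* relative RR — ``P(targets | factor=1) / P(targets | factor=0)``: the
  change in (possibly joint) outcome probability between patients with and
  without a factor, with the network marginalizing everything else.

Uncertainty comes from a nonparametric bootstrap that resamples patients
with replacement and, by default, re-learns the network structure and
refits smoothed CPTs inside every replicate, so the intervals carry
structural as well as parametric uncertainty. Two interval summaries are
supported: the empirical (5th, 95th) replicate percentiles around the
median, and mean +/- t(0.975, B-1) * replicate SD. Replicates whose
resample leaves the conditioning event with zero probability are recorded
as undefined and excluded, with their count always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortMatrix, CohortValidationError
from .inference import FittedNetwork, ImpossibleEvidenceError, InferenceError, \
    fit_cpts, query
from .structure import DirectedAcyclicGraph, learn_exact


class RiskEstimationError(ValueError):
    pass


@dataclass(frozen=True)
class RiskQuery:
    """A target/condition specification.

    ``kind="absolute"``: single-variable target versus the cohort baseline,
    conditioning on ``factor = factor_value``.
    ``kind="relative"``: joint target assignment contrasted between
    ``factor = 1`` and ``factor = 0``.
    """

    kind: str
    targets: dict[str, int]
    factor: str
    factor_value: int = 1

    def __post_init__(self):
        if self.kind not in ("absolute", "relative"):
            raise RiskEstimationError(f"unknown query kind {self.kind!r}")
        if not self.targets:
            raise RiskEstimationError("empty target assignment")
        if self.factor in self.targets:
            raise RiskEstimationError(
                "factor must be distinct from the target variables"
            )
        if self.kind == "absolute" and len(self.targets) != 1:
            raise RiskEstimationError(
                "absolute RR takes a single target variable"
            )

    @property
    def variables(self) -> set[str]:
        return set(self.targets) | {self.factor}

    def label(self) -> str:
        t = ",".join(f"{k}={v}" for k, v in sorted(self.targets.items()))
        if self.kind == "absolute":
            return f"absRR({t}|{self.factor}={self.factor_value})"
        return f"relRR({t}|{self.factor})"


@dataclass
class RiskEstimate:
    query: RiskQuery
    point: float
    ci_low: float
    ci_high: float
    summary_method: str
    B: int
    n_undefined: int
    seed: int | None
    replicates: np.ndarray | None = field(default=None, repr=False)


# -- point estimates on a fitted network -----------------------------------

def absolute_rr(fn: FittedNetwork, target, condition) -> float:
    """``P(target | condition) / P(target)`` via exact queries.

    ``target`` and ``condition`` are variable names (implying value 1) or
    ``(name, value)`` pairs.
    """
    tv, tval = _as_pair(target)
    cv, cval = _as_pair(condition)
    try:
        if tv == cv:
            # self-conditioning: P(T|T) is 1 (or 0), so the ratio is 1/P(T)
            if query(fn, {cv: cval}) == 0.0:
                raise RiskEstimationError(
                    f"undefined ratio: P({cv}={cval}) = 0")
            num = 1.0 if tval == cval else 0.0
        else:
            num = query(fn, {tv: tval}, {cv: cval})
    except ImpossibleEvidenceError as e:
        raise RiskEstimationError(f"undefined ratio: {e}") from e
    den = query(fn, {tv: tval})
    if den == 0.0:
        raise RiskEstimationError(f"undefined ratio: P({tv}={tval}) = 0")
    return num / den


def relative_rr(fn: FittedNetwork, targets: dict[str, int], factor: str
                ) -> float:
    """``P(targets | factor=1) / P(targets | factor=0)``."""
    if factor in targets:
        raise RiskEstimationError("factor must not be among the targets")
    try:
        num = query(fn, targets, {factor: 1})
        den = query(fn, targets, {factor: 0})
    except ImpossibleEvidenceError as e:
        raise RiskEstimationError(f"undefined ratio: {e}") from e
    if den == 0.0:
        raise RiskEstimationError("undefined ratio: zero denominator")
    return num / den


def evaluate_risk_query(fn: FittedNetwork, rq: RiskQuery) -> float:
    if rq.kind == "absolute":
        (tv, tval), = rq.targets.items()
        return absolute_rr(fn, (tv, tval), (rq.factor, rq.factor_value))
    return relative_rr(fn, rq.targets, rq.factor)


def _as_pair(spec) -> tuple[str, int]:
    if isinstance(spec, str):
        return spec, 1
    name, val = spec
    return name, int(val)


# -- bootstrap -------------------------------------------------------------

def bootstrap_risk(
    matrix: CohortMatrix,
    variables: list[str],
    rq: RiskQuery,
    B: int = 1000,
    seed: int = 0,
    summary: str = "percentile_median",
    smoothing=0.01,
    relearn_structure: bool = True,
    resample: bool = True,
    max_parents: int | None = None,
    percentiles: tuple[float, float] = (5.0, 95.0),
    keep_replicates: bool = False,
) -> RiskEstimate:
    """Bootstrap a risk ratio with per-replicate structure re-learning.

    Each replicate resamples the patients with replacement, re-learns the
    network over ``variables`` (unless ``relearn_structure`` is off, an
    ablation that freezes the full-data structure), refits CPTs with
    smoothing, and evaluates the query. The default summary reports the
    replicate median with the empirical ``percentiles`` as the interval;
    ``summary="t_mean"`` reports mean +/- t(0.975, B-1) * SD of the
    replicates.
    """
    if B < 1:
        raise RiskEstimationError("B must be >= 1")
    if summary not in ("percentile_median", "t_mean"):
        raise RiskEstimationError(f"unknown summary {summary!r}")
    if not rq.variables <= set(variables):
        raise RiskEstimationError(
            f"variables must include the query variables {sorted(rq.variables)}"
        )
    sub = matrix.subset(variables)
    if not sub.is_complete:
        raise CohortValidationError("matrix has missing values; impute first")
    n = sub.n_patients
    rng = np.random.default_rng(seed)
    fixed_dag: DirectedAcyclicGraph | None = None
    if not relearn_structure:
        fixed_dag = learn_exact(sub, max_parents=max_parents)

    reps = np.full(B, np.nan)
    for b in range(B):
        idx = rng.integers(0, n, n) if resample else np.arange(n)
        boot = sub.take_patients(idx)
        try:
            dag = fixed_dag if fixed_dag is not None else learn_exact(
                boot, max_parents=max_parents)
            fn = fit_cpts(dag, boot, smoothing=smoothing)
            reps[b] = evaluate_risk_query(fn, rq)
        except (RiskEstimationError, InferenceError):
            continue  # undefined replicate; counted below

    defined = reps[~np.isnan(reps)]
    n_undef = int(B - len(defined))
    if len(defined) == 0:
        raise RiskEstimationError(
            f"all {B} bootstrap replicates were undefined for {rq.label()}"
        )
    if summary == "percentile_median":
        point = float(np.median(defined))
        lo, hi = np.percentile(defined, percentiles)
    else:
        point = float(defined.mean())
        if len(defined) > 1:
            half = stats.t.ppf(0.975, df=len(defined) - 1) * defined.std(ddof=1)
        else:
            half = 0.0
        lo, hi = point - half, point + half
    return RiskEstimate(
        query=rq, point=point, ci_low=float(lo), ci_high=float(hi),
        summary_method=summary, B=B, n_undefined=n_undef, seed=seed,
        replicates=reps if keep_replicates else None,
    )


def point_risk(matrix: CohortMatrix, variables: list[str], rq: RiskQuery,
               smoothing=0.0, max_parents: int | None = None) -> float:
    """Single-fit (no resampling) risk ratio on the full matrix."""
    sub = matrix.subset(variables)
    dag = learn_exact(sub, max_parents=max_parents)
    fn = fit_cpts(dag, sub, smoothing=smoothing)
    return evaluate_risk_query(fn, rq)


# -- feature selection -----------------------------------------------------

def screen_features(
    matrix: CohortMatrix,
    candidates: list[str],
    targets: list[str],
    B: int = 1000,
    seed: int = 0,
    threshold: float = 1.0,
    smoothing=0.01,
) -> pd.DataFrame:
    """Conditional-dependency screen over (candidate, target) pairs.

    For each pair, the conditional probability of the target given the
    candidate is taken as the median over B resampled networks, divided by
    the target's baseline to give an absolute RR; pairs with RR >= threshold
    are selected for downstream network construction.
    """
    if set(candidates) & set(targets):
        raise RiskEstimationError("candidates and targets must be disjoint")
    rows = []
    for ci, cand in enumerate(candidates):
        for ti, targ in enumerate(targets):
            rq = RiskQuery("absolute", {targ: 1}, cand)
            est = bootstrap_risk(
                matrix, [cand, targ], rq, B=B,
                seed=seed + 1000 * ci + ti, smoothing=smoothing,
                summary="percentile_median",
            )
            rows.append({
                "candidate": cand, "target": targ, "absolute_rr": est.point,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
                "n_undefined": est.n_undefined,
                "selected": est.point >= threshold,
            })
    return pd.DataFrame(rows)


# -- enrichment table ------------------------------------------------------

def pathway_enrichment_table(
    matrix: CohortMatrix,
    pathway_flags: list[str],
    phenotype_flags: list[str],
    B: int = 1000,
    seed: int = 0,
    smoothing=0.01,
) -> pd.DataFrame:
    """Absolute RRs of each phenotype given each gene-pathway flag.

    One row per (pathway, phenotype): the bootstrap mean with a
    t-distribution 95% interval, plus the pathway carrier count. Cells with
    no carrier/phenotype co-occurrence are left absent (NaN point), matching
    the dash convention of printed enrichment tables.
    """
    rows = []
    for pi, path in enumerate(pathway_flags):
        carriers = matrix.column(path) == 1.0
        n_path = int(carriers.sum())
        for hi, pheno in enumerate(phenotype_flags):
            co = int((matrix.column(pheno)[carriers] == 1.0).sum())
            if co == 0:
                rows.append({
                    "pathway": path, "phenotype": pheno, "n_pathway": n_path,
                    "n_cooccur": 0, "point": np.nan, "ci_low": np.nan,
                    "ci_high": np.nan, "n_undefined": 0,
                })
                continue
            rq = RiskQuery("absolute", {pheno: 1}, path)
            est = bootstrap_risk(
                matrix, [path, pheno], rq, B=B,
                seed=seed + 100 * pi + hi, smoothing=smoothing,
                summary="t_mean",
            )
            rows.append({
                "pathway": path, "phenotype": pheno, "n_pathway": n_path,
                "n_cooccur": co, "point": est.point, "ci_low": est.ci_low,
                "ci_high": est.ci_high, "n_undefined": est.n_undefined,
            })
    return pd.DataFrame(rows)


def format_enrichment_table(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy enrichment table into printable pathway x phenotype
    cells ``point (lo, hi)`` with dashes for absent cells."""
    def cell(r):
        if np.isnan(r["point"]):
            return "-"
        return f"{r['point']:.2f} ({r['ci_low']:.2f}, {r['ci_high']:.2f})"

    wide = table.assign(cell=table.apply(cell, axis=1)).pivot(
        index="pathway", columns="phenotype", values="cell")
    counts = table.groupby("pathway")["n_pathway"].first()
    wide.insert(0, "n", counts)
    return wide


# -- report I/O ------------------------------------------------------------

REPORT_COLUMNS = [
    "kind", "targets", "factor", "point", "ci_low", "ci_high",
    "summary_method", "B", "n_undefined_replicates", "seed",
]


def estimates_to_frame(estimates: list[RiskEstimate]) -> pd.DataFrame:
    rows = [
        {
            "kind": e.query.kind,
            "targets": ",".join(f"{k}={v}" for k, v in
                                sorted(e.query.targets.items())),
            "factor": e.query.factor,
            "point": e.point,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "summary_method": e.summary_method,
            "B": e.B,
            "n_undefined_replicates": e.n_undefined,
            "seed": e.seed,
        }
        for e in estimates
    ]
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return frame.sort_values(["kind", "targets", "factor"],
                             kind="stable").reset_index(drop=True)


def write_report(estimates: list[RiskEstimate], path) -> None:
    """TSV risk report with deterministic (lexicographic) row order."""
    estimates_to_frame(estimates).to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
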