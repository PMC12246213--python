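"""Binary cohort matrices: data model, I/O, validation, screening, imputation.

The substrate of every downstream stage is a patients x variables matrix of
presence/absence flags (damaging-genotype indicators per gene pathway, CHD
phenotype-category flags, extracardiac-anomaly flag, surgical risk-category
flags, and post-operative outcome flags) with a small amount of missingness.

Internally values are stored as a float ndarray with 0.0 / 1.0 / NaN; NaN
encodes a missing observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VARIABLE_ROLES = frozenset(
    {"genotype", "cardiac_phenotype", "extracardiac", "surgical", "outcome"}
)

#: Per-variable missing-fraction cap applied at load (cohort-construction rule).
DEFAULT_MISSING_CAP = 0.10


class CohortValidationError(ValueError):
    """Raised when a cohort matrix violates its structural invariants."""


@dataclass(frozen=True)
class VariableSpec:
    """A named binary variable and its clinical role."""

    name: str
    role: str = "outcome"
    description: str = ""

    def __post_init__(self) -> None:
        if self.role not in VARIABLE_ROLES:
            raise CohortValidationError(
                f"unknown role {self.role!r} for variable {self.name!r}; "
                f"expected one of {sorted(VARIABLE_ROLES)}"
            )


@dataclass
class CohortMatrix:
    """Patients x binary variables with optional missingness.

    Parameters
    ----------
    patient_ids
        Unique patient identifiers, one per row.
    variables
        One :class:`VariableSpec` per column; names must be unique.
    values
        Float array of shape ``(n_patients, n_variables)`` with entries in
        ``{0.0, 1.0, nan}``.
    imputed
        True once missing cells have been filled by :func:`knn_impute`.
    """

    patient_ids: list[str]
    variables: list[VariableSpec]
    values: np.ndarray
    imputed: bool = False
    missing_cap: float = DEFAULT_MISSING_CAP

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CohortValidationError("values must be a 2-D array")
        n, m = self.values.shape
        if n != len(self.patient_ids):
            raise CohortValidationError(
                f"{len(self.patient_ids)} patient ids but {n} rows"
            )
        if m != len(self.variables):
            raise CohortValidationError(
                f"{len(self.variables)} variable specs but {m} columns"
            )
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise CohortValidationError("duplicate patient ids")
        names = self.variable_names
        if len(set(names)) != len(names):
            raise CohortValidationError("duplicate variable names")
        finite = self.values[~np.isnan(self.values)]
        if not np.all((finite == 0.0) | (finite == 1.0)):
            raise CohortValidationError("cells must be 0, 1 or missing")

    # -- accessors ---------------------------------------------------------
    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variable_names.index(name)]

    def missing_fraction(self) -> pd.Series:
        """Per-variable fraction of missing cells."""
        if self.n_patients == 0:
            return pd.Series(0.0, index=self.variable_names)
        frac = np.isnan(self.values).mean(axis=0)
        return pd.Series(frac, index=self.variable_names)

    def check_missing_cap(self, cap: float | None = None) -> None:
        cap = self.missing_cap if cap is None else cap
        frac = self.missing_fraction()
        bad = frac[frac > cap]
        if len(bad):
            raise CohortValidationError(
                "missing fraction exceeds cap "
                f"{cap:.2f} for: {', '.join(f'{k}={v:.3f}' for k, v in bad.items())}"
            )

    def subset(self, names: Sequence[str]) -> "CohortMatrix":
        """Column subset preserving patient order."""
        idx = [self.variable_names.index(n) for n in names]
        return CohortMatrix(
            patient_ids=list(self.patient_ids),
            variables=[self.variables[i] for i in idx],
            values=self.values[:, idx].copy(),
            imputed=self.imputed,
            missing_cap=self.missing_cap,
        )

    def take_patients(self, row_idx: np.ndarray, ids: Sequence[str] | None = None
                      ) -> "CohortMatrix":
        """Row subset / resample; ids default to suffixed originals."""
        row_idx = np.asarray(row_idx, dtype=int)
        if ids is None:
            ids = [f"{self.patient_ids[i]}#{j}" for j, i in enumerate(row_idx)]
        return CohortMatrix(
            patient_ids=list(ids),
            variables=list(self.variables),
            values=self.values[row_idx].copy(),
            imputed=self.imputed,
            missing_cap=self.missing_cap,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.patient_ids, name="patient_id"),
            columns=self.variable_names,
        )


# -- I/O -------------------------------------------------------------------

def read_cohort_matrix(
    path,
    sep: str = "\t",
    missing_token: str = "NA",
    roles: dict[str, str] | None = None,
    missing_cap: float = DEFAULT_MISSING_CAP,
    enforce_cap: bool = True,
) -> CohortMatrix:
    """Read a cohort matrix from delimited text.

    First column is the patient identifier, header row carries variable
    names, cells are 0 / 1 / ``missing_token`` (empty cells also count as
    missing).
    """
    df = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False,
        na_values=[missing_token, ""],
    )
    if df.shape[1] == 0:
        raise CohortValidationError(f"no header in {path}")
    if df.shape[1] < 2:
        raise CohortValidationError(
            f"{path}: need an ID column plus at least one variable column"
        )
    id_col = df.columns[0]
    patient_ids = df[id_col].astype(str).tolist()
    if len(set(patient_ids)) != len(patient_ids):
        raise CohortValidationError(f"duplicate patient ids in {path}")
    body = df.drop(columns=[id_col])
    values = np.full(body.shape, np.nan)
    for j, col in enumerate(body.columns):
        raw = body[col]
        for i, cell in enumerate(raw):
            if pd.isna(cell):
                continue
            cell = str(cell).strip()
            if cell in ("0", "1"):
                values[i, j] = float(cell)
            elif cell in ("0.0", "1.0"):
                values[i, j] = float(cell)
            else:
                raise CohortValidationError(
                    f"non-binary cell {cell!r} at row {patient_ids[i]!r}, "
                    f"column {col!r}"
                )
    roles = roles or {}
    variables = [
        VariableSpec(name=c, role=roles.get(c, "outcome")) for c in body.columns
    ]
    matrix = CohortMatrix(patient_ids, variables, values, missing_cap=missing_cap)
    if enforce_cap:
        matrix.check_missing_cap()
    return matrix


def write_cohort_matrix(matrix: CohortMatrix, path, sep: str = "\t",
                        missing_token: str = "NA") -> None:
    """Write a matrix in the dialect :func:`read_cohort_matrix` accepts."""
    df = matrix.to_frame()
    out = df.map(lambda v: missing_token if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep=sep)


def read_roles_sidecar(path, sep: str = "\t") -> dict[str, str]:
    """Read an optional (name, role[, description]) sidecar table."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# -- summaries -------------------------------------------------------------

def variable_frequencies(matrix: CohortMatrix) -> pd.DataFrame:
    """Baseline P(v=1) per variable over non-missing entries.

    Returns a frame with columns ``frequency`` and ``n_observed``.
    """
    obs = ~np.isnan(matrix.values)
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        dead = [n for n, c in zip(matrix.variable_names, n_obs) if c == 0]
        raise CohortValidationError(f"all-missing variable(s): {dead}")
    freq = np.nansum(matrix.values, axis=0) / n_obs
    return pd.DataFrame(
        {"frequency": freq, "n_observed": n_obs.astype(int)},
        index=matrix.variable_names,
    )


@dataclass
class CorrelationReport:
    """All pairwise phi coefficients plus the pairs flagged as collinear."""

    phi: pd.DataFrame
    n_pairs: pd.DataFrame
    flagged: list[tuple[str, str, float]]
    undefined: list[tuple[str, str]] = field(default_factory=list)
    threshold: float = 0.9


def _phi_from_counts(x: np.ndarray, y: np.ndarray) -> float:
    """Phi (Pearson on 0/1) over pairwise-complete observations; nan if a
    margin is degenerate."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return np.nan
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return np.nan
    return float(np.corrcoef(xs, ys)[0, 1])


def collinearity_screen(matrix: CohortMatrix, threshold: float = 0.9
                        ) -> CorrelationReport:
    """Screen variable pairs for collinearity via the phi coefficient.

    Highly correlated variables can distort structure learning and risk
    estimation, so pairs with ``|phi| > threshold`` are flagged for manual
    exclusion. Zero-variance variables make phi undefined; such pairs are
    reported in ``undefined`` rather than silently assigned 0.
    """
    names = matrix.variable_names
    m = matrix.n_variables
    if m < 2:
        raise CohortValidationError("need at least two variables to screen")
    phi = np.eye(m)
    npairs = np.zeros((m, m), dtype=int)
    flagged: list[tuple[str, str, float]] = []
    undefined: list[tuple[str, str]] = []
    for i in range(m):
        npairs[i, i] = int((~np.isnan(matrix.values[:, i])).sum())
        for j in range(i + 1, m):
            ok = ~np.isnan(matrix.values[:, i]) & ~np.isnan(matrix.values[:, j])
            npairs[i, j] = npairs[j, i] = int(ok.sum())
            r = _phi_from_counts(matrix.values[:, i], matrix.values[:, j])
            phi[i, j] = phi[j, i] = r
            if np.isnan(r):
                undefined.append((names[i], names[j]))
            elif abs(r) > threshold:
                flagged.append((names[i], names[j], r))
    return CorrelationReport(
        phi=pd.DataFrame(phi, index=names, columns=names),
        n_pairs=pd.DataFrame(npairs, index=names, columns=names),
        flagged=flagged,
        undefined=undefined,
        threshold=threshold,
    )


def zero_variance_variables(matrix: CohortMatrix) -> list[str]:
    """Variables constant over their observed entries (excluded from
    network stages)."""
    out = []
    for j, name in enumerate(matrix.variable_names):
        col = matrix.values[:, j]
        obs = col[~np.isnan(col)]
        if len(obs) == 0 or obs.min() == obs.max():
            out.append(name)
    return out


# -- KNN imputation --------------------------------------------------------

def knn_impute(matrix: CohortMatrix, k: int = 10) -> CohortMatrix:
    """Fill missing cells by majority vote of the k nearest patients.

    Distance is the Hamming mismatch rate over mutually observed variables
    (normalized by overlap size). Ties in distance are broken by patient
    order, even votes fall back to the variable's marginal mode — both rules
    make the result deterministic. Observed cells are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if matrix.is_complete:
        return replace(matrix, values=matrix.values.copy(), imputed=True)
    V = matrix.values
    n = matrix.n_patients
    obs = ~np.isnan(V)
    if np.any(obs.sum(axis=1) == 0):
        bad = [matrix.patient_ids[i] for i in np.where(obs.sum(axis=1) == 0)[0]]
        raise CohortValidationError(f"patients with all entries missing: {bad}")

    # marginal mode per variable, used for even-vote ties
    freq = np.nansum(V, axis=0) / obs.sum(axis=0)
    mode = (freq >= 0.5).astype(float)

    X = np.nan_to_num(V, nan=0.0)
    # pairwise mismatches over mutual overlap: |x - y| summed where both seen
    overlap = obs.astype(float) @ obs.astype(float).T
    agree = (X * obs) @ (X * obs).T + ((1 - X) * obs) @ ((1 - X) * obs).T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - agree / overlap
    np.fill_diagonal(dist, np.inf)
    dist[overlap == 0] = np.inf

    out = V.copy()
    rows, cols = np.where(~obs)
    for i, j in zip(rows, cols):
        donors = np.where(obs[:, j] & np.isfinite(dist[i]))[0]
        if len(donors) == 0:
            out[i, j] = mode[j]
            continue
        if len(donors) < k:
            warnings.warn(
                f"only {len(donors)} usable neighbors (<k={k}) for patient "
                f"{matrix.patient_ids[i]!r}, variable "
                f"{matrix.variable_names[j]!r}; using all of them",
                stacklevel=2,
            )
            chosen = donors
        else:
            # stable sort => distance ties broken by patient order
            order = donors[np.argsort(dist[i, donors], kind="stable")]
            chosen = order[:k]
        votes = V[chosen, j]
        ones = votes.sum()
        if 2 * ones > len(chosen):
            out[i, j] = 1.0
        elif 2 * ones < len(chosen):
            out[i, j] = 0.0
        else:
            out[i, j] = mode[j]
    return replace(matrix, values=out, imputed=True)
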