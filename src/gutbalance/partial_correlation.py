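"""Covariate-adjusted partial Spearman correlations.

The screen used for lung-function / CPET associations: rank-transform the
feature, the parameter and each continuous covariate (average ranks for
ties; binary and one-hot dummy columns pass through unranked), then read
the partial correlation off the precision matrix of the rank-correlation
matrix, ``rho_xy.Z = -P_xy / sqrt(P_xx P_yy)``.  Significance uses
``t = rho * sqrt((n - 2 - q) / (1 - rho^2))`` on ``n - 2 - q`` degrees of
freedom, two-sided, with q adjusting covariate columns.

No multiple-testing correction is applied in this screen — reported rows
are filtered on the raw p-value (and optionally a minimum |rho|), matching
the convention for this analysis; the paired differential-abundance module
is the one that applies FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import AbundanceTable, ClinicalTable, PairedDesign, TableError


@dataclass
class PartialCorrelationResult:
    feature_id: str
    parameter_name: str
    rho_partial: float
    p_value: float
    n_used: int
    covariates: list[str] = field(default_factory=list)
    undefined: bool = False

    def __post_init__(self) -> None:
        if not self.undefined:
            assert abs(self.rho_partial) <= 1.0 + 1e-9


def _is_binary(col: np.ndarray) -> bool:
    vals = np.unique(col[~np.isnan(col)])
    return vals.size <= 2 and np.all(np.isin(vals, (0.0, 1.0)))


def _rank_columns(m: np.ndarray) -> np.ndarray:
    """Average-rank each column; binary/dummy columns pass through."""
    out = np.empty_like(m, dtype=float)
    for j in range(m.shape[1]):
        col = m[:, j]
        out[:, j] = col if _is_binary(col) else stats.rankdata(col)
    return out


def partial_spearman(x, y, Z=None, x_name: str = "x",
                     y_name: str = "y",
                     covariate_names: list[str] | None = None) -> PartialCorrelationResult:
    """Partial Spearman correlation of x and y given covariate matrix Z.

    With no covariates this reduces exactly to the ordinary Spearman rho.
    Rows with any missing value are dropped (complete cases); at least
    q + 3 complete cases are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z is None or (hasattr(Z, "size") and np.asarray(Z).size == 0):
        z = np.empty((x.size, 0))
    else:
        z = np.asarray(Z, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    names = covariate_names or [f"z{j}" for j in range(z.shape[1])]
    data = np.column_stack([x, y, z])
    complete = ~np.isnan(data).any(axis=1)
    data = data[complete]
    n, q = data.shape[0], z.shape[1]
    if n < q + 3:
        raise ValueError(f"need >= {q + 3} complete cases, got {n}")
    ranked = _rank_columns(data)
    sds = ranked.std(axis=0)
    if sds[0] == 0 or sds[1] == 0:
        return PartialCorrelationResult(x_name, y_name, np.nan, np.nan, n,
                                        list(names), undefined=True)
    corr = np.corrcoef(ranked, rowvar=False)
    # x and y in exact monotone (anti)agreement: partial rho is +/-1
    if abs(corr[0, 1]) >= 1.0 - 1e-12:
        return PartialCorrelationResult(x_name, y_name,
                                        float(np.sign(corr[0, 1])), 0.0,
                                        n, list(names))
    if np.linalg.cond(corr) > 1e10:
        collinear = _collinear_columns(ranked, [x_name, y_name, *names])
        raise ValueError(f"singular rank-correlation matrix; collinear "
                         f"columns: {collinear}")
    prec = np.linalg.inv(corr)
    rho = float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 2 - q
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho ** 2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(x_name, y_name, rho, p, n, list(names))


def _collinear_columns(ranked: np.ndarray, names: list[str]) -> list[str]:
    corr = np.corrcoef(ranked, rowvar=False)
    hits = set()
    k = corr.shape[0]
    for i in range(k):
        for j in range(i + 1, k):
            if abs(corr[i, j]) > 1 - 1e-10:
                hits.update((names[i], names[j]))
    return sorted(hits)


def one_hot_covariates(clinical_rows: pd.DataFrame,
                       covariates: list[str]) -> pd.DataFrame:
    """Numeric covariate design: binary columns pass through, categorical
    columns become one-hot dummies with the first level dropped."""
    pieces = []
    for cov in covariates:
        if cov not in clinical_rows.columns:
            raise TableError(f"unknown covariate {cov!r}")
        col = clinical_rows[cov]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True).astype(float)
            pieces.append(dummies)
        else:
            pieces.append(col.astype(float).to_frame())
    if not pieces:
        return pd.DataFrame(index=clinical_rows.index)
    return pd.concat(pieces, axis=1)


def _clinical_rows_for(index: pd.Index, clinical: ClinicalTable) -> pd.DataFrame:
    """Align clinical rows to a feature-matrix index of sample or patient ids."""
    if set(index) <= set(clinical.data.index):
        return clinical.data.loc[index]
    patients = set(clinical.data["patient_id"])
    if set(index) <= patients:
        per_patient = clinical.data.groupby("patient_id").first()
        return per_patient.loc[index]
    raise TableError("feature-matrix index matches neither sample ids nor patient ids")


def correlation_screen(features, clinical: ClinicalTable,
                       parameters: list[str], covariates: list[str],
                       p_max: float = 0.05,
                       min_abs_rho: float = 0.0) -> pd.DataFrame:
    """All feature x parameter partial Spearman correlations, filtered.

    ``features`` is an :class:`AbundanceTable` or a DataFrame (e.g. the
    post-pre change table) indexed by sample or patient ids.  Each cell is
    computed on its own pairwise-complete cases.  Rows reported satisfy
    ``p < p_max`` and ``|rho| > min_abs_rho`` (use 0.65 for the fungal
    profile, 0 for bacteria).
    """
    if isinstance(features, AbundanceTable):
        fdf = features.values
    else:
        fdf = features
    for p in parameters:
        if p not in clinical.data.columns:
            raise TableError(f"unknown parameter {p!r}")
        if clinical.data[p].isna().all():
            raise TableError(f"parameter {p!r} entirely missing")
    rows = _clinical_rows_for(fdf.index, clinical)
    zdf = one_hot_covariates(rows, covariates)
    z = zdf.to_numpy(dtype=float)
    records = []
    for param in parameters:
        yv = rows[param].to_numpy(dtype=float)
        for feat in fdf.columns:
            xv = fdf[feat].to_numpy(dtype=float)
            try:
                res = partial_spearman(xv, yv, z, x_name=feat, y_name=param,
                                       covariate_names=list(zdf.columns))
            except ValueError:
                continue
            if res.undefined:
                continue
            if res.p_value < p_max and abs(res.rho_partial) > min_abs_rho:
                records.append({
                    "feature_id": feat, "parameter": param,
                    "rho_partial": res.rho_partial, "p_value": res.p_value,
                    "n_used": res.n_used,
                })
    out = pd.DataFrame(records,
                       columns=["feature_id", "parameter", "rho_partial",
                                "p_value", "n_used"])
    return out.sort_values(["parameter", "p_value"]).reset_index(drop=True)


def change_table(table: AbundanceTable, pairs: PairedDesign) -> pd.DataFrame:
    """Per-patient log2((post + eps)/(pre + eps)) change matrix."""
    eps = table.pseudo_fraction()
    pre = table.subset_samples(pairs.pre_samples).matrix()
    post = table.subset_samples(pairs.post_samples).matrix()
    changes = np.log2((post + eps) / (pre + eps))
    return pd.DataFrame(changes, index=pairs.patient_ids,
                        columns=table.feature_ids)
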