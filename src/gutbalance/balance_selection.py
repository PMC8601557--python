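"""Log-contrast microbial balances and cross-validated forward selection.

A balance contrasts the mean log abundances of two disjoint feature sets:

    B(X+, X-) = (1/k+) sum_{i in I+} log X_i  -  (1/k-) sum_{j in I-} log X_j

(the ``proportional`` form; ``normalized`` multiplies by
``sqrt(k+ k- / (k+ + k-))``, the isometric-log-ratio scaling).  Because the
two means subtract, B is invariant to the closure constant of the
composition.

:class:`BalanceSelector` is the model object: given a table and a response
it runs selbal-style forward selection — start from the best single pair,
then repeatedly add the one feature (to either side) that most improves the
fit, producing a sequence of balances with C = 2..C_max components.
Repeated k-fold cross-validation scores each C on held-out samples; the
optimal size C_opt is the smallest C within one standard error of the best
mean score; the global balance is refit on all samples at C_opt.  Component
and whole-balance frequencies across the CV fits measure robustness.
Fit criteria: squared Pearson correlation of B with a continuous response,
or AUC of B as a ranking score for a dichotomous one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import AbundanceTable, TableError, phylum_of


@dataclass
class Balance:
    """A fitted log-contrast: the sets I+/I- and the per-sample values B."""

    plus_set: tuple[str, ...]
    minus_set: tuple[str, ...]
    normalization: str = "proportional"
    values: pd.Series | None = None

    def __post_init__(self) -> None:
        if set(self.plus_set) & set(self.minus_set):
            raise ValueError("I+ and I- overlap")
        if not self.plus_set or not self.minus_set:
            raise ValueError("I+ and I- must both be non-empty")
        if self.normalization not in ("proportional", "normalized"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def k_plus(self) -> int:
        return len(self.plus_set)

    @property
    def k_minus(self) -> int:
        return len(self.minus_set)

    @property
    def n_components(self) -> int:
        return self.k_plus + self.k_minus

    def key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Canonical identity for frequency tallies (order-free sets)."""
        return (tuple(sorted(self.plus_set)), tuple(sorted(self.minus_set)))


def _log_matrix(table: AbundanceTable) -> pd.DataFrame:
    eps = table.pseudo_fraction()
    return np.log(table.values + eps)


def compute_balance(table: AbundanceTable, plus_set, minus_set,
                    normalization: str = "proportional") -> Balance:
    """Evaluate a balance on every sample of a table.

    Zeros are replaced by the table-wide pseudo-fraction (half the smallest
    nonzero value) before the log, the same constant everywhere so balances
    stay comparable across operations.
    """
    plus = tuple(plus_set)
    minus = tuple(minus_set)
    bal = Balance(plus, minus, normalization)
    missing = (set(plus) | set(minus)) - set(table.feature_ids)
    if missing:
        raise TableError(f"features absent from table: {sorted(missing)[:5]}")
    logx = _log_matrix(table)
    b = logx[list(plus)].mean(axis=1) - logx[list(minus)].mean(axis=1)
    if normalization == "normalized":
        kp, km = len(plus), len(minus)
        b = b * np.sqrt(kp * km / (kp + km))
    bal.values = b
    return bal


# ---------------------------------------------------------------------------
# fit criteria


def _pearson_sq(bmat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of each column of bmat with y."""
    bc = bmat - bmat.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((bc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, bc.T @ yc / denom, 0.0)
    return r ** 2


def _auc_columns(bmat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """AUC of each column of bmat as a score for binary y (rank-sum form)."""
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        return np.full(bmat.shape[1], np.nan)
    ranks = stats.rankdata(bmat, axis=0)
    rank_sum_pos = ranks[y == 1].sum(axis=0)
    return (rank_sum_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _criterion(bmat: np.ndarray, y: np.ndarray, kind: str) -> np.ndarray:
    return _pearson_sq(bmat, y) if kind == "continuous" else _auc_columns(bmat, y)


# ---------------------------------------------------------------------------
# forward selection


def _forward_path(logx: np.ndarray, y: np.ndarray, feature_ids: list[str],
                  c_max: int, kind: str) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Greedy sequence of (plus indices, minus indices) for C = 2..c_max.

    Ties in the fit criterion break on the lexicographically smallest
    feature id, plus side before minus, so the path is deterministic.
    """
    n, d = logx.shape
    order = np.argsort(np.asarray(feature_ids))

    # C = 2: best ordered pair (i plus, j minus)
    best_score, best_pair = -np.inf, None
    for i in order:
        bmat = logx[:, [i]] - logx  # column j: balance ({i},{j})
        scores = _criterion(bmat, y, kind)
        scores[i] = -np.inf
        for j in order:
            if scores[j] > best_score + 1e-12:
                best_score, best_pair = scores[j], (i, j)
    if best_pair is None:
        raise ValueError("no valid starting pair (single-class response?)")
    plus, minus = [best_pair[0]], [best_pair[1]]
    path = [(tuple(plus), tuple(minus))]

    sum_plus = logx[:, plus[0]].copy()
    sum_minus = logx[:, minus[0]].copy()
    while len(plus) + len(minus) < min(c_max, d):
        used = set(plus) | set(minus)
        cand = np.array([j for j in order if j not in used])
        kp, km = len(plus), len(minus)
        b_plus = (sum_plus[:, None] + logx[:, cand]) / (kp + 1) - (sum_minus / km)[:, None]
        b_minus = (sum_plus / kp)[:, None] - (sum_minus[:, None] + logx[:, cand]) / (km + 1)
        s_plus = _criterion(b_plus, y, kind)
        s_minus = _criterion(b_minus, y, kind)
        # candidates are in lexicographic order; strict > keeps the first
        best = (-np.inf, None, None)
        for side, scores in (("plus", s_plus), ("minus", s_minus)):
            k = int(np.nanargmax(scores)) if not np.all(np.isnan(scores)) else None
            if k is not None and scores[k] > best[0] + 1e-12:
                best = (scores[k], side, cand[k])
        if best[1] is None:
            break
        _, side, j = best
        if side == "plus":
            plus.append(int(j))
            sum_plus += logx[:, int(j)]
        else:
            minus.append(int(j))
            sum_minus += logx[:, int(j)]
        path.append((tuple(plus), tuple(minus)))
    return path


def _balance_values(logx: np.ndarray, plus, minus) -> np.ndarray:
    return logx[:, list(plus)].mean(axis=1) - logx[:, list(minus)].mean(axis=1)


# ---------------------------------------------------------------------------
# model / results objects


@dataclass
class FitStatistic:
    kind: str
    value: float                 # Pearson r (continuous) or AUC (dichotomous)
    p_value: float | None = None
    accuracy: float | None = None
    threshold: float | None = None


def evaluate_balance(balance: Balance, response, kind: str) -> FitStatistic:
    """Association of a computed balance with a response.

    continuous -> Pearson r with two-sided p; dichotomous -> AUC of B as a
    ranking score plus accuracy at the Youden-optimal threshold.
    """
    if balance.values is None:
        raise ValueError("balance has no values; compute it on a table first")
    b = np.asarray(balance.values, dtype=float)
    y = np.asarray(response, dtype=float)
    if y.size != b.size:
        raise ValueError("response length does not match balance values")
    if kind == "continuous":
        r, p = stats.pearsonr(b, y)
        return FitStatistic(kind=kind, value=float(r), p_value=float(p))
    if kind == "dichotomous":
        classes = np.unique(y)
        if not np.all(np.isin(classes, (0.0, 1.0))) or classes.size != 2:
            raise ValueError("dichotomous response must contain both 0 and 1")
        auc = float(_auc_columns(b[:, None], y)[0])
        thr, acc = _youden(b, y)
        return FitStatistic(kind=kind, value=auc, accuracy=acc, threshold=thr)
    raise ValueError(f"unknown response kind {kind!r}")


def _youden(b: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing sensitivity + specificity - 1; returns accuracy."""
    cuts = np.unique(b)
    mids = np.concatenate([[cuts[0] - 1], (cuts[:-1] + cuts[1:]) / 2, [cuts[-1] + 1]])
    n1, n0 = y.sum(), (1 - y).sum()
    best_j, best_thr, best_acc = -np.inf, mids[0], 0.0
    for thr in mids:
        pred = (b > thr).astype(float)
        tp = float(((pred == 1) & (y == 1)).sum())
        tn = float(((pred == 0) & (y == 0)).sum())
        j = tp / n1 + tn / n0 - 1.0
        if j > best_j + 1e-12:
            best_j, best_thr = j, float(thr)
            best_acc = (tp + tn) / y.size
    return best_thr, best_acc


class BalanceSelector:
    """selbal-style balance-selection model.

    Parameters
    ----------
    table:
        Closed abundance table; restrict its features beforehand (e.g. to
        the significantly changed ones) to mirror the intended screen.
    response:
        Per-sample response aligned with ``samples`` (a name resolved
        against a clinical table via :meth:`from_clinical`, or a vector).
    kind:
        ``continuous`` (squared-Pearson fit) or ``dichotomous`` (AUC fit).
    """

    def __init__(self, table: AbundanceTable, response, kind: str = "continuous",
                 log_response: bool = False):
        if kind not in ("continuous", "dichotomous"):
            raise ValueError(f"unknown response kind {kind!r}")
        y = np.asarray(response, dtype=float)
        if y.size != table.n_samples:
            raise ValueError("response length does not match table samples")
        if np.isnan(y).any():
            raise ValueError("response contains missing values; drop those samples")
        if kind == "dichotomous":
            if np.unique(y).size < 2:
                raise ValueError("dichotomous response has a single class")
            if log_response:
                raise ValueError("log_response applies to continuous responses")
        else:
            if np.unique(y).size < 2:
                raise ValueError("constant response (zero variance)")
            if log_response:
                if (y <= 0).any():
                    raise ValueError("log_response needs positive responses")
                y = np.log(y)
        self.table = table
        self.response = y
        self.kind = kind
        self._logx = _log_matrix(table).to_numpy()

    @classmethod
    def from_clinical(cls, table: AbundanceTable, clinical, response_name: str,
                      kind: str = "continuous", log_response: bool = False,
                      censoring: str | None = None) -> "BalanceSelector":
        """Build from a clinical table, aligning on the abundance sample ids.

        Survival times are treated as a continuous response (optionally
        log-transformed); a censoring column, if named, is ignored with a
        warning — the model correlates, it does not model censoring.
        """
        if censoring is not None:
            warnings.warn("censoring indicators are ignored; OS is treated "
                          "as a continuous response")
        y = clinical.column(response_name).reindex(table.sample_ids)
        keep = y.notna()
        if not keep.all():
            table = table.subset_samples(list(y.index[keep]))
            y = y[keep]
        return cls(table, y.to_numpy(dtype=float), kind=kind,
                   log_response=log_response)

    def fit(self, C_max: int = 20, n_folds: int = 5, n_repeats: int = 10,
            seed: int | None = None) -> "BalanceSelectionResults":
        """Run the cross-validated forward selection and global refit."""
        if C_max < 2:
            raise ValueError("C_max must be >= 2")
        y = self.response
        logx = self._logx
        n, d = logx.shape
        c_cap = min(C_max, d)
        feature_ids = self.table.feature_ids
        rng = np.random.default_rng(seed)

        # -- cross-validation: per repeat, pool held-out balance values ----
        cv_paths: list[list[tuple[tuple[int, ...], tuple[int, ...]]]] = []
        per_repeat_scores = np.full((n_repeats, c_cap - 1), np.nan)
        for rep in range(n_repeats):
            fold_of = np.repeat(np.arange(n_folds), int(np.ceil(n / n_folds)))[:n]
            fold_of = fold_of[rng.permutation(n)]
            held_b = np.full((n, c_cap - 1), np.nan)
            for f in range(n_folds):
                test = fold_of == f
                if test.sum() == 0 or (~test).sum() < 3:
                    continue
                if self.kind == "dichotomous" and np.unique(y[~test]).size < 2:
                    continue  # single-class training fold is unusable
                path = _forward_path(logx[~test], y[~test], feature_ids,
                                     c_cap, self.kind)
                cv_paths.append(path)
                for ci, (plus, minus) in enumerate(path):
                    held_b[test, ci] = _balance_values(logx[test], plus, minus)
            for ci in range(c_cap - 1):
                mask = ~np.isnan(held_b[:, ci])
                if mask.sum() >= 3 and np.unique(y[mask]).size >= 2:
                    per_repeat_scores[rep, ci] = _criterion(
                        held_b[mask, ci][:, None], y[mask], self.kind)[0]

        cv_mean = np.nanmean(per_repeat_scores, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cv_se = np.nanstd(per_repeat_scores, axis=0, ddof=1) / np.sqrt(
                np.sum(~np.isnan(per_repeat_scores), axis=0).clip(min=1))

        # 1-SE rule: smallest C within one SE of the best mean score
        best = int(np.nanargmax(cv_mean))
        cutoff = cv_mean[best] - cv_se[best]
        c_opt_idx = next(i for i in range(c_cap - 1)
                         if not np.isnan(cv_mean[i]) and cv_mean[i] >= cutoff)
        c_opt = c_opt_idx + 2

        # -- global refit on all samples ----------------------------------
        full_path = _forward_path(logx, y, feature_ids, c_cap, self.kind)
        plus_idx, minus_idx = full_path[c_opt_idx]
        global_balance = compute_balance(
            self.table,
            [feature_ids[i] for i in plus_idx],
            [feature_ids[j] for j in minus_idx],
        )
        # orient so the balance associates positively with the response
        # (I+ holds the taxa whose dominance predicts higher response)
        trial = evaluate_balance(global_balance, y, self.kind)
        flip_point = 0.0 if self.kind == "continuous" else 0.5
        if trial.value < flip_point:
            global_balance = compute_balance(
                self.table,
                [feature_ids[j] for j in minus_idx],
                [feature_ids[i] for i in plus_idx],
            )

        # -- robustness frequencies across CV fits at C_opt ---------------
        comp_counts: dict[str, int] = {}
        bal_counts: dict[tuple, int] = {}
        n_fits = 0
        for path in cv_paths:
            if len(path) < c_opt_idx + 1:
                continue
            plus, minus = path[c_opt_idx]
            n_fits += 1
            names = ([feature_ids[i] for i in plus], [feature_ids[j] for j in minus])
            for fid in names[0] + names[1]:
                comp_counts[fid] = comp_counts.get(fid, 0) + 1
            key = (tuple(sorted(names[0])), tuple(sorted(names[1])))
            bal_counts[key] = bal_counts.get(key, 0) + 1
        denom = max(n_fits, 1)
        component_frequency = {f: c / denom for f, c in comp_counts.items()}
        balance_frequency = {k: c / denom for k, c in bal_counts.items()}

        cv_by_c = {c + 2: (float(cv_mean[c]), float(cv_se[c]))
                   for c in range(c_cap - 1)}
        in_sample = evaluate_balance(global_balance, y, self.kind)
        return BalanceSelectionResults(
            model=self, C_opt=c_opt, global_balance=global_balance,
            cv_score_by_C=cv_by_c,
            cv_score_at_C_opt=float(cv_mean[c_opt_idx]),
            component_frequency=component_frequency,
            balance_frequency=balance_frequency,
            fit=in_sample, n_folds=n_folds, n_repeats=n_repeats,
        )


@dataclass
class BalanceSelectionResults:
    """Fitted balance-selection results: C_opt, the global balance, CV curve,
    robustness frequencies, and the in-sample association statistic."""

    model: BalanceSelector
    C_opt: int
    global_balance: Balance
    cv_score_by_C: dict[int, tuple[float, float]]
    cv_score_at_C_opt: float
    component_frequency: dict[str, float]
    balance_frequency: dict[tuple, float]
    fit: FitStatistic
    n_folds: int
    n_repeats: int

    def __post_init__(self) -> None:
        assert self.C_opt >= 2
        assert self.global_balance.n_components == self.C_opt

    def summary(self) -> str:
        lines = ["Balance selection results",
                 "=" * 60,
                 f"response kind: {self.model.kind}   "
                 f"CV: {self.n_folds} folds x {self.n_repeats} repeats",
                 f"C_opt = {self.C_opt} (1-SE rule)",
                 f"held-out fit at C_opt: {self.cv_score_at_C_opt:.3f}"]
        if self.model.kind == "continuous":
            lines.append(f"global balance: in-sample Pearson r = "
                         f"{self.fit.value:.3f} (P = {self.fit.p_value:.2g})")
        else:
            lines.append(f"global balance: AUC = {self.fit.value:.3f}, "
                         f"accuracy = {self.fit.accuracy:.3f} (Youden)")
        lines.append("I+ : " + ", ".join(self.global_balance.plus_set))
        lines.append("I- : " + ", ".join(self.global_balance.minus_set))
        lines.append("component inclusion frequencies:")
        top = sorted(self.component_frequency.items(), key=lambda kv: -kv[1])
        for fid, freq in top[:10]:
            lines.append(f"  {freq:5.2f}  {fid}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# phylum-level log ratios


def phylum_ratio(table: AbundanceTable, numerator, denominator) -> pd.Series:
    """Per-sample log of (summed numerator-phylum abundance + eps) over
    (summed denominator-phylum abundance + eps).

    Phylum names are parsed from the pipe-separated lineage labels.  The
    Firmicutes/Bacteroidetes ratio is ``phylum_ratio(t, {"Firmicutes"},
    {"Bacteroidetes"})``.
    """
    num_set, den_set = set(numerator), set(denominator)
    groups: dict[str, list[str]] = {"num": [], "den": []}
    for fid in table.feature_ids:
        ph = phylum_of(fid)
        if ph in num_set:
            groups["num"].append(fid)
        elif ph in den_set:
            groups["den"].append(fid)
    for side, phyla in (("num", num_set), ("den", den_set)):
        if not groups[side]:
            raise TableError(f"no features from phyla {sorted(phyla)} in table")
    eps = table.pseudo_fraction()
    num = table.values[groups["num"]].sum(axis=1)
    den = table.values[groups["den"]].sum(axis=1)
    if (den == 0).any():
        warnings.warn("denominator phyla absent in some samples; pseudo-fraction applied")
    return np.log((num + eps) / (den + eps)).rename("phylum_log_ratio")
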