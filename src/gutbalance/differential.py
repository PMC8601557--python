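"""Paired differential abundance: prevalence filter, Wilcoxon signed-rank
with Benjamini-Hochberg FDR, fold-change ranking, and the aerobe/anaerobe
aggregate comparison with the matched-pairs effect size r = |Z| / sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import AbundanceTable, OxygenAnnotation, PairedDesign, TableError

RESULT_COLUMNS = ("feature_id", "W", "p_value", "q_value", "direction",
                  "log2_fold_change", "prevalence", "untestable")


def prevalence_filter(table: AbundanceTable, min_prevalence: float = 0.10) -> AbundanceTable:
    """Keep features detected (nonzero) in at least ``min_prevalence`` of all
    samples, pre and post pooled.  The boundary is inclusive: a feature seen
    in exactly 10% of samples survives a 0.10 threshold."""
    if not 0.0 < min_prevalence <= 1.0:
        raise ValueError("min_prevalence must be in (0, 1]")
    x = table.matrix()
    n = x.shape[0]
    counts = (x > 0).sum(axis=0)
    # compare counts, not ratios, so the boundary is exact in floating point
    keep = counts >= min_prevalence * n - 1e-9
    if not keep.any():
        raise TableError("no feature passes the prevalence filter")
    kept = [f for f, k in zip(table.feature_ids, keep) if k]
    return table.subset_features(kept)


def _wilcoxon_paired(diff: np.ndarray) -> tuple[float, float, float]:
    """(W, two-sided p, Z) for one vector of paired differences.

    Exact distribution when n <= 25 with no ties among |differences|;
    normal approximation with continuity and tie correction otherwise.
    Zero differences are dropped (Wilcoxon's original treatment).
    """
    d = diff[diff != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, 0.0
    abs_d = np.abs(d)
    has_ties = np.unique(abs_d).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    if method == "approx":
        z = float(res.zstatistic)
    else:
        # normal-approximation Z for the effect size, tie-corrected
        ranks = stats.rankdata(abs_d)
        w_plus = ranks[d > 0].sum()
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(abs_d, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
        z = (w_plus - mu) / np.sqrt(var) if var > 0 else 0.0
    return float(res.statistic), float(res.pvalue), float(z)


def paired_wilcoxon(table: AbundanceTable, pairs: PairedDesign,
                    min_pairs: int = 5) -> pd.DataFrame:
    """Per-feature paired (post - pre) Wilcoxon signed-rank tests with BH FDR.

    Returns one row per feature with columns ``RESULT_COLUMNS``.  Features
    whose differences are all zero get p = 1 and ``untestable=True`` (they
    still enter the BH correction as tested hypotheses don't — untestable
    features are excluded from the BH family).
    """
    if pairs.n_pairs < min_pairs:
        raise ValueError(f"need >= {min_pairs} pairs, got {pairs.n_pairs}")
    pre = table.subset_samples(pairs.pre_samples).matrix()
    post = table.subset_samples(pairs.post_samples).matrix()
    eps = table.pseudo_fraction()
    x_all = table.matrix()
    prevalence = (x_all > 0).mean(axis=0)

    rows = []
    for j, fid in enumerate(table.feature_ids):
        diff = post[:, j] - pre[:, j]
        untestable = bool((diff == 0).all())
        if untestable:
            w, p, z = 0.0, 1.0, 0.0
        else:
            w, p, z = _wilcoxon_paired(diff)
        med = np.median(diff)
        direction = "up_post" if med > 0 else "down_post"
        lfc = float(np.log2((post[:, j].mean() + eps) / (pre[:, j].mean() + eps)))
        rows.append({
            "feature_id": fid, "W": w, "p_value": p, "q_value": np.nan,
            "direction": direction, "log2_fold_change": lfc,
            "prevalence": float(prevalence[j]), "untestable": untestable,
        })
    out = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    testable = ~out["untestable"]
    if testable.any():
        out.loc[testable, "q_value"] = bh_adjust(out.loc[testable, "p_value"].to_numpy())
    out.loc[~testable, "q_value"] = 1.0
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(p_values, method="fdr_bh")[1]


def significant_features(results: pd.DataFrame, alpha: float = 0.05,
                         use_fdr: bool = True) -> list[str]:
    """Feature ids significant at ``alpha``.

    ``use_fdr=True`` thresholds the BH q-value (the default reading);
    ``use_fdr=False`` thresholds the raw p-value.
    """
    col = "q_value" if use_fdr else "p_value"
    mask = (results[col] < alpha) & ~results["untestable"]
    return results.loc[mask, "feature_id"].tolist()


def fold_change_rank(results: pd.DataFrame, alpha: float = 0.05,
                     use_fdr: bool = True) -> pd.DataFrame:
    """Significant features ordered by log2 fold-change, descending."""
    if results.empty:
        raise ValueError("empty differential results")
    keep = significant_features(results, alpha=alpha, use_fdr=use_fdr)
    sub = results[results["feature_id"].isin(keep)]
    return sub.sort_values(["log2_fold_change", "feature_id"],
                           ascending=[False, True]).reset_index(drop=True)


@dataclass
class EffectSize:
    """Matched-pairs rank-biserial-style effect size r = |Z| / sqrt(n_pairs)."""

    r: float
    p_value: float
    n_pairs: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.r


def aggregate_class_test(table: AbundanceTable, pairs: PairedDesign,
                         annotation: OxygenAnnotation, cls: str) -> EffectSize:
    """Paired test on the summed relative abundance of one oxygen class.

    Sums the relative abundances of all features annotated ``cls`` per
    sample, runs the paired Wilcoxon on the sums, and reports the effect
    size r = |Z|/sqrt(n_pairs).  Subgroup variants (e.g. recurrent-only)
    are obtained by subsetting ``pairs`` first.
    """
    feats = annotation.features_of(table, cls)
    if not feats:
        raise TableError(f"no feature annotated as {cls!r}")
    if pairs.n_pairs < 5:
        raise ValueError("need >= 5 pairs")
    sub = table.subset_features(feats)
    pre = sub.subset_samples(pairs.pre_samples).matrix().sum(axis=1)
    post = sub.subset_samples(pairs.post_samples).matrix().sum(axis=1)
    diff = post - pre
    if (diff == 0).all():
        return EffectSize(r=0.0, p_value=1.0, n_pairs=pairs.n_pairs)
    _, p, z = _wilcoxon_paired(diff)
    r = abs(z) / np.sqrt(pairs.n_pairs)
    return EffectSize(r=float(r), p_value=p, n_pairs=pairs.n_pairs)
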