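import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutbalance.differential import (
    EffectSize, aggregate_class_test, bh_adjust, fold_change_rank,
    paired_wilcoxon, prevalence_filter, significant_features,
    _wilcoxon_paired,
)
from gutbalance.io_tables import OxygenAnnotation, PairedDesign, TableError
from conftest import make_table


def _pairs(n):
    return PairedDesign([(f"P{i}", f"P{i}_pre", f"P{i}_post")
                         for i in range(n)])


def _paired_table(pre, post):
    pre, post = np.asarray(pre, float), np.asarray(post, float)
    n = pre.shape[0]
    ids = [f"P{i}_pre" for i in range(n)] + [f"P{i}_post" for i in range(n)]
    return make_table(np.vstack([pre, post]), sample_ids=ids), _pairs(n)


def test_prevalence_filter_boundary_inclusive():
    x = np.zeros((30, 3))
    x[:, 0] = 0.5                     # everywhere
    x[:3, 1] = 0.3                    # 3/30 = exactly 10%
    x[:2, 2] = 0.2                    # 2/30 < 10%
    t = make_table(x + 0.0)
    kept = prevalence_filter(t, 0.10)
    assert kept.feature_ids == ["f0", "f1"]


def test_prevalence_filter_rejects_zero_threshold(uniform4_table):
    with pytest.raises(ValueError):
        prevalence_filter(uniform4_table, 0.0)


def test_prevalence_filter_no_survivor_errors():
    t = make_table(np.vstack([np.eye(10), np.zeros((0, 10))]) + 0.0)
    with pytest.raises(TableError):
        prevalence_filter(t, 1.0)


def test_exact_p_for_five_positive_differences():
    # all 5 differences positive: two-sided exact p = 2/2^5 = 0.0625
    pre = np.tile([0.2, 0.8], (5, 1))
    post = np.column_stack([0.2 + np.array([1, 2, 3, 4, 5]) * 0.01,
                            0.8 - np.array([1, 2, 3, 4, 5]) * 0.01])
    t, pairs = _paired_table(pre, post)
    res = paired_wilcoxon(t, pairs)
    assert res.loc[0, "p_value"] == pytest.approx(0.0625)
    assert res.loc[0, "direction"] == "up_post"


def test_all_zero_differences_flagged_untestable():
    pre = np.tile([0.3, 0.3, 0.4], (6, 1))
    post = pre.copy()
    post[:, 2] = [0.41, 0.39, 0.42, 0.38, 0.43, 0.37]
    post[:, 1] = 1 - post[:, 0] - post[:, 2]
    t, pairs = _paired_table(pre, post)
    res = paired_wilcoxon(t, pairs)
    row = res[res.feature_id == "f0"].iloc[0]
    assert row.untestable and row.p_value == 1.0


def test_bh_stepup_hand_example():
    q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=30))
def test_bh_is_monotone_in_p(ps):
    p = np.array(ps)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(q >= p - 1e-12)


def test_fold_change_values_and_ranking():
    # a tiny fourth feature keeps the table-wide pseudo-fraction negligible
    pre = np.tile([0.2, 0.4, 0.4 - 1e-6, 1e-6], (8, 1))
    post = np.column_stack([
        0.4 + np.linspace(-0.01, 0.01, 8),
        0.2 - np.linspace(-0.01, 0.01, 8),
        np.full(8, 0.4 - 1e-6),
        np.full(8, 1e-6),
    ])
    t, pairs = _paired_table(pre, post)
    res = paired_wilcoxon(t, pairs)
    lfc = res.set_index("feature_id")["log2_fold_change"]
    assert lfc["f0"] == pytest.approx(1.0, abs=0.05)   # doubled
    assert lfc["f2"] == pytest.approx(0.0, abs=0.05)   # unchanged
    ranked = fold_change_rank(res, alpha=0.05, use_fdr=False)
    assert list(ranked.feature_id)[0] == "f0"
    assert np.all(np.diff(ranked.log2_fold_change) <= 1e-12)


def test_fold_change_finite_for_absent_pre_feature():
    pre = np.tile([0.5, 0.5, 0.0], (6, 1))
    post = np.tile([0.45, 0.45, 0.10], (6, 1)) + np.random.default_rng(0).normal(
        0, 1e-3, (6, 3))
    post = np.abs(post)
    t, pairs = _paired_table(pre, post)
    res = paired_wilcoxon(t, pairs)
    assert np.isfinite(res.log2_fold_change).all()
    assert res.set_index("feature_id").loc["f2", "log2_fold_change"] > 0


def test_effect_size_matches_hand_formula():
    # n=15 strictly positive differences, no ties:
    # W+ = 120, mu = 60, var = 15*16*31/24 = 310
    # Z = 60/sqrt(310) = 3.4078 -> r = Z/sqrt(15) = 0.87989
    d = np.arange(1, 16, dtype=float)
    _, p, z = _wilcoxon_paired(d)
    assert abs(z) == pytest.approx(60 / np.sqrt(310), rel=1e-6)
    classes = OxygenAnnotation({"f0": "anaerobe"})
    pre = np.column_stack([0.2 + 0.01 * d, 0.8 - 0.01 * d])
    post = np.column_stack([0.2 + 0.02 * d, 0.8 - 0.02 * d])
    t, pairs = _paired_table(pre, post)
    es = aggregate_class_test(t, pairs, classes, "anaerobe")
    assert es.n_pairs == 15
    assert es.r == pytest.approx(0.87989, abs=1e-4)


def test_aggregate_of_all_features_is_degenerate():
    classes = OxygenAnnotation({"f0": "anaerobe", "f1": "anaerobe"})
    pre = np.tile([0.4, 0.6], (6, 1))
    post = np.tile([0.7, 0.3], (6, 1))
    t, pairs = _paired_table(pre, post)
    es = aggregate_class_test(t, pairs, classes, "anaerobe")
    assert es.p_value == 1.0 and es.r == 0.0  # sums are 1.0 everywhere


def test_aggregate_missing_class_errors():
    pre = np.tile([0.4, 0.6], (6, 1))
    t, pairs = _paired_table(pre, pre * 0.99 + 0.005)
    with pytest.raises(TableError):
        aggregate_class_test(t, pairs, OxygenAnnotation({"f0": "aerobe"}),
                             "anaerobe")


def test_planted_decrease_detected_in_aggregate():
    """Anaerobe-summed abundance drops when all anaerobes are planted with
    negative effects; detected in most seeds at n=50 pairs."""
    from gutbalance.synthetic import SyntheticSpec, generate
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        spec = SyntheticSpec(n_patients=50, n_features=30,
                             differential_features={i: -1.5 for i in range(5)},
                             seed=seed)
        ds = generate(spec)
        feats = ds.abundance.feature_ids
        ann = OxygenAnnotation({feats[i].split("s__")[1]: ("anaerobe" if i < 5
                                                           else "aerobe")
                                for i in range(30)})
        es = aggregate_class_test(ds.abundance, ds.pairs, ann, "anaerobe")
        if es.p_value < 0.05:
            hits += 1
    assert hits >= 0.95 * n_seeds


def test_sample_order_equivariance(demo_dataset):
    t = demo_dataset.abundance
    pairs = demo_dataset.pairs
    res1 = paired_wilcoxon(prevalence_filter(t, 0.1), pairs)
    shuffled = t.subset_samples(list(reversed(t.sample_ids)))
    res2 = paired_wilcoxon(prevalence_filter(shuffled, 0.1), pairs)
    pd.testing.assert_frame_equal(res1, res2)


def test_significant_features_raw_vs_fdr(demo_dataset):
    res = paired_wilcoxon(prevalence_filter(demo_dataset.abundance, 0.1),
                          demo_dataset.pairs)
    raw = set(significant_features(res, use_fdr=False))
    fdr = set(significant_features(res, use_fdr=True))
    assert fdr <= raw
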