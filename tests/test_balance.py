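from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from gutbalance.balance_selection import (
    Balance, BalanceSelector, _criterion, compute_balance, evaluate_balance,
    phylum_ratio,
)
from gutbalance.io_tables import AbundanceTable, TableError
from gutbalance.synthetic import (
    BalanceTruth, SyntheticSpec, feature_names, generate,
)
from conftest import make_table


def _two_part_table():
    # singleton sets on (0.8, 0.2); a tiny third part keeps eps negligible
    return make_table(np.tile([0.8 - 1e-9, 0.2, 1e-9], (4, 1)))


def test_singleton_balance_is_log_ratio():
    t = _two_part_table()
    b = compute_balance(t, ["f0"], ["f1"])
    assert np.allclose(b.values, np.log(4), atol=1e-6)


def test_normalized_mode_applies_ilr_scaling():
    t = _two_part_table()
    b = compute_balance(t, ["f0"], ["f1"], normalization="normalized")
    assert np.allclose(b.values, np.sqrt(0.5) * np.log(4), atol=1e-6)


def test_equal_parts_balance_is_zero():
    t = make_table(np.tile([0.4, 0.4, 0.2], (3, 1)))
    b = compute_balance(t, ["f0"], ["f1"])
    assert np.allclose(b.values, 0.0)


def test_balance_invariant_to_closure_constant():
    rng = np.random.default_rng(0)
    x = rng.dirichlet(np.ones(6), size=10)
    t1 = make_table(x)
    t2 = AbundanceTable(t1.values * 7.0)  # unclosed scaling
    b1 = compute_balance(t1, ["f0", "f2"], ["f3"])
    b2 = compute_balance(t2, ["f0", "f2"], ["f3"])
    assert np.allclose(b1.values, b2.values, atol=1e-12)


def test_swapping_sides_negates_balance():
    rng = np.random.default_rng(1)
    t = make_table(rng.dirichlet(np.ones(5), size=8))
    a = compute_balance(t, ["f0", "f1"], ["f2", "f3"])
    b = compute_balance(t, ["f2", "f3"], ["f0", "f1"])
    assert np.allclose(a.values, -b.values, atol=1e-12)


def test_overlapping_or_empty_sets_rejected():
    t = make_table(np.tile([0.5, 0.3, 0.2], (3, 1)))
    with pytest.raises(ValueError):
        Balance(("f0",), ("f0",))
    with pytest.raises(ValueError):
        Balance(("f0",), ())
    with pytest.raises(TableError):
        compute_balance(t, ["f0"], ["missing"])


# ---------------------------------------------------------------------------
# evaluation


def test_evaluate_continuous_extremes():
    rng = np.random.default_rng(2)
    t = make_table(rng.dirichlet(np.ones(4), size=12))
    b = compute_balance(t, ["f0"], ["f1"])
    y = b.values.to_numpy()
    assert evaluate_balance(b, y, "continuous").value == pytest.approx(1.0)
    assert evaluate_balance(b, -y, "continuous").value == pytest.approx(-1.0)


def test_evaluate_dichotomous_separable_and_null():
    rng = np.random.default_rng(3)
    t = make_table(rng.dirichlet(np.ones(4), size=400))
    b = compute_balance(t, ["f0"], ["f1"])
    bv = b.values.to_numpy()
    sep = (bv > np.median(bv)).astype(float)
    fit = evaluate_balance(b, sep, "dichotomous")
    assert fit.value > 0.99 and fit.accuracy > 0.99
    null = rng.binomial(1, 0.5, size=400).astype(float)
    assert abs(evaluate_balance(b, null, "dichotomous").value - 0.5) < 0.1


def test_evaluate_kind_mismatch_errors():
    t = make_table(np.random.default_rng(4).dirichlet(np.ones(4), size=6))
    b = compute_balance(t, ["f0"], ["f1"])
    with pytest.raises(ValueError):
        evaluate_balance(b, np.array([0, 1, 2, 0, 1, 2.0]), "dichotomous")


# ---------------------------------------------------------------------------
# forward selection


def _exhaustive_best_pair(logx, y, kind):
    d = logx.shape[1]
    best = -np.inf
    for i, j in permutations(range(d), 2):
        s = _criterion((logx[:, i] - logx[:, j])[:, None], y, kind)[0]
        best = max(best, s)
    return best


@pytest.mark.parametrize("kind", ["continuous", "dichotomous"])
def test_forward_start_matches_exhaustive_pair_search(kind):
    rng = np.random.default_rng(5)
    n, d = 40, 10
    t = make_table(rng.dirichlet(np.ones(d), size=n))
    logx = np.log(t.matrix() + t.pseudo_fraction())
    if kind == "continuous":
        y = logx[:, 0] - logx[:, 3] + 0.5 * rng.normal(size=n)
    else:
        y = (logx[:, 0] - logx[:, 3] + rng.normal(size=n) > 0).astype(float)
    model = BalanceSelector(t, y, kind=kind)
    res = model.fit(C_max=2, n_folds=4, n_repeats=2, seed=0)
    pair_score = _criterion(
        res.global_balance.values.to_numpy()[:, None], y, kind)[0]
    assert pair_score == pytest.approx(
        _exhaustive_best_pair(logx, y, kind), abs=1e-10)


def test_planted_balance_recovered_single_seed():
    spec = SyntheticSpec(
        n_patients=50, n_features=15,
        balance_truth=BalanceTruth(plus=(0,), minus=(1,), beta=3.0, sigma=0.3),
        seed=6,
    )
    ds = generate(spec)
    post = ds.abundance.subset_samples(ds.pairs.post_samples)
    vo2 = ds.clinical.data.loc[ds.pairs.post_samples, "VO2"].to_numpy()
    res = BalanceSelector(post, vo2).fit(C_max=8, n_folds=5, n_repeats=5,
                                         seed=7)
    feats = ds.abundance.feature_ids
    members = set(res.global_balance.plus_set) | set(res.global_balance.minus_set)
    assert {feats[0], feats[1]} <= members
    assert res.component_frequency.get(feats[0], 0) >= 0.9
    assert res.component_frequency.get(feats[1], 0) >= 0.9


def test_heldout_fit_below_insample_on_noise():
    rng = np.random.default_rng(8)
    t = make_table(rng.dirichlet(np.ones(12), size=40))
    y = rng.normal(size=40)
    res = BalanceSelector(t, y).fit(C_max=6, n_folds=5, n_repeats=4, seed=9)
    in_sample = res.fit.value ** 2
    assert res.cv_score_at_C_opt <= in_sample + 1e-9


def test_invalid_inputs_rejected():
    rng = np.random.default_rng(10)
    t = make_table(rng.dirichlet(np.ones(5), size=12))
    with pytest.raises(ValueError):
        BalanceSelector(t, np.ones(12))                      # constant response
    with pytest.raises(ValueError):
        BalanceSelector(t, np.ones(12), kind="dichotomous")  # single class
    with pytest.raises(ValueError):
        BalanceSelector(t, rng.normal(size=12)).fit(C_max=1)


def test_results_invariants(demo_dataset):
    ds = demo_dataset
    post = ds.abundance.subset_samples(ds.pairs.post_samples)
    vo2 = ds.clinical.data.loc[ds.pairs.post_samples, "VO2"].to_numpy()
    res = BalanceSelector(post, vo2).fit(C_max=5, n_folds=5, n_repeats=3,
                                         seed=11)
    assert 2 <= res.C_opt <= 5
    assert res.global_balance.n_components == res.C_opt
    assert all(0 <= v <= 1 for v in res.component_frequency.values())
    assert all(0 <= v <= 1 for v in res.balance_frequency.values())
    assert "C_opt" in res.summary()


# ---------------------------------------------------------------------------
# phylum ratios


def test_phylum_ratio_values_and_errors():
    names = feature_names(4)  # cycles Firmicutes, Bacteroidetes, Proteo, Actino
    # tiny Proteobacteria value keeps the pseudo-fraction negligible
    vals = pd.DataFrame(
        [[0.25, 0.25, 1e-9, 0.5 - 1e-9],
         [0.40, 0.20, 1e-9, 0.4 - 1e-9]],
        index=["s1", "s2"], columns=names)
    t = AbundanceTable(vals)
    fb = phylum_ratio(t, {"Firmicutes"}, {"Bacteroidetes"})
    assert fb["s1"] == pytest.approx(0.0, abs=1e-6)
    assert fb["s2"] == pytest.approx(np.log(2), abs=1e-6)
    with pytest.raises(TableError):
        phylum_ratio(t, {"Euryarchaeota"}, {"Firmicutes"})


def test_phylum_ratio_survives_zero_denominator():
    names = feature_names(4)
    vals = pd.DataFrame([[0.5, 0.0, 0.25, 0.25]], index=["s1"], columns=names)
    t = AbundanceTable(vals)
    with pytest.warns(UserWarning):
        r = phylum_ratio(t, {"Firmicutes"}, {"Bacteroidetes"})
    assert np.isfinite(r).all()
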