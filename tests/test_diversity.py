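from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from gutbalance.diversity import (
    alpha_diversity, bray_curtis, pcoa, permanova, _pseudo_f,
)
from gutbalance.io_tables import TableError
from conftest import make_table


def test_shannon_simpson_closed_forms(uniform4_table):
    sh = alpha_diversity(uniform4_table, "shannon")
    si = alpha_diversity(uniform4_table, "simpson")
    assert np.allclose(sh, np.log(4))
    assert np.allclose(si, 0.75)


def test_single_feature_sample_has_zero_diversity():
    t = make_table([[1.0, 0, 0, 0]])
    assert alpha_diversity(t, "shannon").iloc[0] == 0.0
    assert alpha_diversity(t, "simpson").iloc[0] == 0.0


def test_chao1_classic_formula():
    # 10 observed species: 4 singletons, 2 doubletons, 4 abundant;
    # counts sum to the pseudo-count depth so rounding is exact
    counts = [1, 1, 1, 1, 2, 2, 2498, 2498, 2498, 2498]
    t = make_table([np.array(counts) / 10_000])
    # chao1 = 10 + 4^2 / (2*2) = 14
    assert alpha_diversity(t, "chao1").iloc[0] == 14.0
    # F2 == 0 branch: 2 singletons -> S_obs + F1(F1-1)/2
    counts2 = [1, 1, 4999, 4999]
    t2 = make_table([np.array(counts2) / 10_000])
    assert alpha_diversity(t2, "chao1").iloc[0] == 4 + 2 * 1 / 2


def test_alpha_rejects_zero_sample():
    t = make_table([[0.5, 0.5], [0.0, 0.0]])
    with pytest.raises(TableError):
        alpha_diversity(t, "shannon")


def test_shannon_maximal_for_uniform_composition():
    rng = np.random.default_rng(0)
    comps = rng.dirichlet(np.ones(6), size=50)
    t = make_table(np.vstack([comps, np.full((1, 6), 1 / 6)]))
    sh = alpha_diversity(t, "shannon")
    assert sh.iloc[-1] == pytest.approx(np.log(6))
    assert (sh.iloc[:-1] <= sh.iloc[-1] + 1e-12).all()


def test_bray_curtis_worked_examples():
    t = make_table([[0.5, 0.5, 0.0],
                    [0.25, 0.25, 0.5],
                    [0.5, 0.5, 0.0],
                    [0.0, 0.0, 1.0]])
    dm = bray_curtis(t)
    assert dm[0, 1] == pytest.approx(0.5)      # hand evaluation
    assert dm[0, 2] == pytest.approx(0.0)      # identical samples
    assert dm[0, 3] == pytest.approx(1.0)      # disjoint supports
    d = dm.data
    assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)
    assert d.min() >= 0 and d.max() <= 1


def test_pcoa_three_equidistant_points():
    t = make_table(np.eye(3))
    dm = bray_curtis(t)           # all pairwise distances 1
    res = pcoa(dm, k=3)
    w = res.eigenvalues
    assert w[0] == pytest.approx(w[1], rel=1e-9)
    assert abs(w[2]) < 1e-10
    # embedded coordinates reproduce the distances
    from scipy.spatial.distance import pdist, squareform
    rec = squareform(pdist(res.coordinates.to_numpy()))
    assert np.allclose(rec, dm.data, atol=1e-8)


def test_pcoa_collinear_configuration_is_rank_one():
    x = np.array([0.0, 1.0, 2.0, 3.5])
    d = np.abs(x[:, None] - x[None, :])
    from skbio import DistanceMatrix
    res = pcoa(DistanceMatrix(d, ids=list("abcd")), k=3)
    w = res.eigenvalues
    assert w[0] > 0
    assert np.all(np.abs(w[1:]) < 1e-9 * w[0])


def test_pcoa_duplicate_samples_collocate():
    t = make_table([[0.5, 0.5], [0.5, 0.5], [0.1, 0.9]])
    res = pcoa(bray_curtis(t), k=1)
    c = res.coordinates.to_numpy()
    assert np.allclose(c[0], c[1], atol=1e-10)


def test_pcoa_matches_skbio_on_random_data(demo_dataset):
    dm = bray_curtis(demo_dataset.abundance)
    ours = pcoa(dm, k=3)
    ref = skbio_pcoa(dm, method="eigh", number_of_dimensions=3)
    # same eigenvalues; coordinates equal up to per-axis sign
    assert np.allclose(ours.eigenvalues[:3], ref.eigvals.to_numpy()[:3],
                       atol=1e-8)
    for j in range(3):
        a = ours.coordinates.iloc[:, j].to_numpy()
        b = ref.samples.iloc[:, j].to_numpy()
        assert np.allclose(a, b, atol=1e-6) or np.allclose(a, -b, atol=1e-6)


def _exhaustive_permanova(d, labels):
    """Brute-force: F and R2 for the observed labeling, and the exhaustive
    p over all distinct binary labelings with the same group sizes."""
    n = len(labels)
    codes = np.asarray(labels)
    d2 = d ** 2
    f_obs, r2_obs = _pseudo_f(d2, codes, 2)
    n1 = int(codes.sum())
    fs = []
    for ones in combinations(range(n), n1):
        lab = np.zeros(n, dtype=int)
        lab[list(ones)] = 1
        fs.append(_pseudo_f(d2, lab, 2)[0])
    fs = np.array(fs)
    p = np.mean(fs >= f_obs - 1e-12)
    return f_obs, r2_obs, p


def test_permanova_matches_exhaustive_oracle_two_clusters():
    # 3+3 perfect clusters: within-distance 0, between-distance 1
    d = np.ones((6, 6))
    d[:3, :3] = 0
    d[3:, 3:] = 0
    np.fill_diagonal(d, 0)
    labels = np.array([0, 0, 0, 1, 1, 1])
    f_obs, r2_obs, p_exh = _exhaustive_permanova(d, labels)
    # partition oracle: SS_total = 9/6, SS_within = 0
    assert r2_obs == pytest.approx(1.0)
    assert p_exh == pytest.approx(2 / 20)  # only the two perfect labelings
    from skbio import DistanceMatrix
    res = permanova(DistanceMatrix(d, ids=list("abcdef")), labels,
                    n_permutations=999, seed=0)
    assert res.R2 == pytest.approx(r2_obs)
    assert abs(res.p_value - p_exh) < 0.04


def test_permanova_matches_skbio_statistic(demo_dataset):
    dm = bray_curtis(demo_dataset.abundance)
    tp = demo_dataset.clinical.column("timepoint").reindex(list(dm.ids))
    ours = permanova(dm, tp, n_permutations=99, seed=1)
    ref = skbio_permanova(dm, tp.to_numpy(), permutations=99)
    assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-10)


def test_permanova_invariant_to_relabeling(demo_dataset):
    dm = bray_curtis(demo_dataset.abundance)
    tp = demo_dataset.clinical.column("timepoint").reindex(list(dm.ids))
    a = permanova(dm, tp, n_permutations=99, seed=5)
    swapped = tp.map({"pre": "B", "post": "A"})
    b = permanova(dm, swapped, n_permutations=99, seed=5)
    assert a.pseudo_F == pytest.approx(b.pseudo_F)
    assert a.R2 == pytest.approx(b.R2)


def test_permanova_strata_restricts_swaps(demo_dataset):
    dm = bray_curtis(demo_dataset.abundance)
    tp = demo_dataset.clinical.column("timepoint").reindex(list(dm.ids))
    pat = demo_dataset.clinical.column("patient_id").reindex(list(dm.ids))
    res = permanova(dm, tp, n_permutations=199, seed=2, strata=pat)
    assert res.p_value >= 1 / 200


@pytest.mark.parametrize("labels,err", [
    (np.zeros(6, dtype=int), "2 groups"),
], ids=["single-group"])
def test_permanova_input_validation(labels, err):
    d = np.ones((6, 6))
    np.fill_diagonal(d, 0)
    from skbio import DistanceMatrix
    with pytest.raises(ValueError, match=err):
        permanova(DistanceMatrix(d, ids=list("abcdef")), labels,
                  n_permutations=99, seed=0)


def test_permanova_rejects_too_few_permutations():
    d = np.ones((4, 4)); np.fill_diagonal(d, 0)
    from skbio import DistanceMatrix
    with pytest.raises(ValueError):
        permanova(DistanceMatrix(d, ids=list("abcd")), [0, 0, 1, 1],
                  n_permutations=50, seed=0)
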