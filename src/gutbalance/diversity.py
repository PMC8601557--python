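"""Alpha diversity, Bray-Curtis beta diversity, PCoA and PERMANOVA.

Alpha indices operate on relative abundances (Chao1 via pseudo-counts, see
:func:`alpha_diversity`).  PERMANOVA partitions the squared-distance sum of
squares between and within groups and assesses the pseudo-F against seeded
label permutations, optionally restricted within strata (e.g. within
patient for a paired pre/post design).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io_tables import AbundanceTable, TableError

logger = logging.getLogger(__name__)

ALPHA_INDICES = ("shannon", "simpson", "chao1")


def alpha_diversity(table: AbundanceTable, index: str,
                    library_size: int = 10_000) -> pd.Series:
    """Per-sample alpha diversity.

    shannon = -sum p_i ln p_i; simpson = 1 - sum p_i^2 (Gini-Simpson, the
    bounded [0,1] form); chao1 = S_obs + F1^2/(2 F2) (or the bias-corrected
    S_obs + F1(F1-1)/2 when F2 == 0), computed on pseudo-counts obtained by
    scaling relative abundances by ``library_size`` and rounding — richness
    from relative data is inherently approximate.
    """
    if index not in ALPHA_INDICES:
        raise ValueError(f"unknown alpha index {index!r}")
    x = table.matrix()
    if (x.sum(axis=1) <= 0).any():
        raise TableError("all-zero sample")
    p = x / x.sum(axis=1, keepdims=True)
    if index == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        vals = -terms.sum(axis=1)
    elif index == "simpson":
        vals = 1.0 - (p ** 2).sum(axis=1)
    else:  # chao1
        logger.info("chao1 from relative abundances uses pseudo-counts "
                    "(library size %d); treat as approximate richness", library_size)
        counts = np.rint(p * library_size).astype(int)
        vals = np.array([_chao1(row) for row in counts], dtype=float)
    return pd.Series(vals, index=table.sample_ids, name=index)


def _chao1(counts: np.ndarray) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: d(x,y) = 1 - 2 sum min(x,y) / sum (x+y)."""
    condensed = pdist(table.matrix(), metric="braycurtis")
    dm = squareform(condensed)
    np.fill_diagonal(dm, 0.0)
    return DistanceMatrix(dm, ids=table.sample_ids)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame      # samples x axes, descending eigenvalue
    eigenvalues: np.ndarray        # all eigenvalues incl. negative ones
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, k: int = 2) -> PCoAResult:
    """Classical scaling (Torgerson) of the double-centred squared distances.

    Eigenvalues are reported in full, negatives included; coordinates use
    the top-k positive eigenvalues (truncated with a warning if fewer than
    k are positive).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = dm.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    n_pos = int((w > 1e-10).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(f"only {n_pos} positive eigenvalues; returning {k_eff} axes")
    coords = v[:, :k_eff] * np.sqrt(w[:k_eff])
    pos_sum = w[w > 0].sum()
    prop = np.where(w > 0, w / pos_sum, 0.0) if pos_sum > 0 else np.zeros_like(w)
    frame = pd.DataFrame(coords, index=list(dm.ids),
                         columns=[f"PC{i + 1}" for i in range(k_eff)])
    return PCoAResult(coordinates=frame, eigenvalues=w, proportion_explained=prop)


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int

    def __post_init__(self) -> None:
        # R2 may dip below 0 for anti-clustered groupings of a
        # non-Euclidean (e.g. Bray-Curtis) distance matrix
        assert self.R2 <= 1.0
        assert self.p_value >= 1.0 / (self.n_permutations + 1) - 1e-12

    def summary(self) -> str:
        return (f"PERMANOVA: pseudo-F = {self.pseudo_F:.4f}, "
                f"R2 = {100 * self.R2:.1f}%, P = {self.p_value:.4g} "
                f"({self.n_permutations} permutations, n = {self.n_samples}, "
                f"{self.n_groups} groups)")


def _ss_partition(d2: np.ndarray, codes: np.ndarray,
                  n_groups: int) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size >= 2:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total, ss_within = _ss_partition(d2, codes, n_groups)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0 or df_within <= 0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return float(f), float(r2)


def permanova(dm: DistanceMatrix, grouping, n_permutations: int = 999,
              seed: int | None = None, strata=None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``grouping`` is a sequence or Series of labels aligned with ``dm.ids``
    (a Series is reindexed by id).  ``strata``, if given, restricts label
    permutations to within each stratum (e.g. patient id for paired
    designs); default is free permutation.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    labels = _aligned(grouping, dm)
    codes, uniques = pd.factorize(labels)
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    d2 = dm.data ** 2
    f_obs, r2 = _pseudo_f(d2, codes, n_groups)

    rng = np.random.default_rng(seed)
    strata_codes = None
    if strata is not None:
        strata_codes = pd.factorize(_aligned(strata, dm))[0]
    exceed = 0
    for _ in range(n_permutations):
        perm = _permute(codes, rng, strata_codes)
        f_perm, _ = _pseudo_f(d2, perm, n_groups)
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(pseudo_F=f_obs, R2=r2, p_value=p,
                           n_permutations=n_permutations,
                           n_samples=len(codes), n_groups=n_groups)


def _aligned(values, dm: DistanceMatrix) -> np.ndarray:
    if isinstance(values, pd.Series):
        return values.reindex(list(dm.ids)).to_numpy()
    arr = np.asarray(values)
    if arr.shape[0] != len(dm.ids):
        raise ValueError("grouping length does not match distance matrix")
    return arr


def _permute(codes: np.ndarray, rng: np.random.Generator,
             strata_codes: np.ndarray | None) -> np.ndarray:
    if strata_codes is None:
        return rng.permutation(codes)
    out = codes.copy()
    for s in np.unique(strata_codes):
        idx = np.flatnonzero(strata_codes == s)
        out[idx] = codes[idx][rng.permutation(idx.size)]
    return out
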