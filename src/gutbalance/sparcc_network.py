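"""SparCC basis-correlation inference and differential co-abundance networks.

SparCC estimates correlations of unobserved absolute ("basis") abundances
from compositions.  The observable is the variation matrix
``t_ij = Var(log(x_i / x_j))``; under the sparsity assumption that most
basis correlations vanish, the basis variances ``w_i^2`` solve the linear
system obtained by summing ``t_ij = w_i^2 + w_j^2 - 2 r_ij w_i w_j`` over
partners, after which ``r_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j)``.
Strongly correlated pairs violate the sparsity assumption and are excluded
iteratively before re-solving.  Zero handling follows the method's own
resampling design: each inference iteration draws fractions from a
Dirichlet posterior over pseudo-counts, and the final correlation is the
element-wise mean over iterations.  Significance is a permutation pseudo
p-value with the add-one rule, so it is never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import AbundanceTable

MIN_PERMUTATIONS = 19
VARIANCE_FLOOR = 1e-10


@dataclass
class CorrelationNetwork:
    """Feature x feature basis-correlation estimates with optional pseudo-p."""

    feature_ids: list[str]
    rho: pd.DataFrame
    pseudo_p: pd.DataFrame | None = None
    n_iterations: int = 20
    n_permutations: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        r = self.rho.to_numpy()
        assert np.all(np.abs(r) <= 1.0 + 1e-9)
        assert np.allclose(r, r.T, atol=1e-9)

    @property
    def significant(self) -> pd.DataFrame:
        """Boolean mask pseudo_p < alpha, diagonal excluded."""
        if self.pseudo_p is None:
            raise ValueError("pseudo p-values not computed yet")
        mask = self.pseudo_p.to_numpy() < self.alpha
        np.fill_diagonal(mask, False)
        return pd.DataFrame(mask, index=self.feature_ids, columns=self.feature_ids)


def variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """t_ij = Var(log(x_i/x_j)) across samples, via the log covariance."""
    logx = np.log(fractions)
    cov = np.cov(logx, rowvar=False, ddof=1)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _solve_basis_variances(t: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Solve the basis-variance system restricted to active (non-excluded)
    pairs; negative solutions are clipped to a small positive floor."""
    m = active.astype(float)
    m += np.diag(active.sum(axis=1).astype(float))
    rhs = (active * t).sum(axis=1)
    try:
        w2 = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError:
        w2 = np.linalg.lstsq(m, rhs, rcond=None)[0]
    if (w2 <= 0).any():
        warnings.warn("negative basis variance solved; clipped to floor")
        w2 = np.clip(w2, VARIANCE_FLOOR, None)
    return w2


def _basis_correlations(t: np.ndarray, exclusion_threshold: float,
                        exclusion_rounds: int) -> np.ndarray:
    d = t.shape[0]
    active = ~np.eye(d, dtype=bool)
    excluded = np.zeros((d, d), dtype=bool)
    rho = np.zeros((d, d))
    for _ in range(exclusion_rounds + 1):
        w2 = _solve_basis_variances(t, active)
        w = np.sqrt(w2)
        denom = 2.0 * np.outer(w, w)
        rho = (w2[:, None] + w2[None, :] - t) / denom
        np.fill_diagonal(rho, 1.0)
        rho = np.clip(rho, -1.0, 1.0)
        # exclude the single strongest still-active pair above threshold
        cand = np.abs(rho).copy()
        cand[~active | excluded] = -np.inf
        np.fill_diagonal(cand, -np.inf)
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] < exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        active[i, j] = active[j, i] = False
        # a component must keep >= 2 active partners for a solvable row
        for k in (i, j):
            if active[k].sum() < 2:
                active[k, :] = active[:, k] = False
                active[k, k] = False
                excluded[k, :] = excluded[:, k] = True
    return rho


def _dirichlet_fractions(fractions: np.ndarray, depth: int,
                         rng: np.random.Generator) -> np.ndarray:
    """One Dirichlet-posterior draw per sample from pseudo-counts
    (fraction * depth, +1 prior)."""
    alpha = fractions * depth + 1.0
    g = rng.standard_gamma(alpha)
    return g / g.sum(axis=1, keepdims=True)


def _sparcc_rho(fractions: np.ndarray, n_iterations: int, depth: int,
                exclusion_threshold: float, exclusion_rounds: int,
                rng: np.random.Generator) -> np.ndarray:
    d = fractions.shape[1]
    acc = np.zeros((d, d))
    for _ in range(n_iterations):
        f = _dirichlet_fractions(fractions, depth, rng)
        t = variation_matrix(f)
        acc += _basis_correlations(t, exclusion_threshold, exclusion_rounds)
    rho = acc / n_iterations
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def sparcc(table: AbundanceTable, n_iterations: int = 20,
           exclusion_threshold: float = 0.1, exclusion_rounds: int = 10,
           depth: int = 10_000, seed: int | None = None) -> CorrelationNetwork:
    """Estimate the basis-correlation network of a compositional table.

    The estimate is the mean over ``n_iterations`` inference iterations,
    each on a fresh Dirichlet-posterior resample of the compositions
    (pseudo-count depth ``depth``).  Needs >= 4 features; below that the
    basis-variance system is degenerate.
    """
    if table.n_features < 4:
        raise ValueError("SparCC needs at least 4 features")
    fractions = table.close().matrix()
    dup = _duplicate_columns(fractions)
    if dup:
        warnings.warn(f"perfectly dependent feature columns detected: {dup[:3]}")
    rng = np.random.default_rng(seed)
    rho = _sparcc_rho(fractions, n_iterations, depth,
                      exclusion_threshold, exclusion_rounds, rng)
    frame = pd.DataFrame(rho, index=table.feature_ids, columns=table.feature_ids)
    return CorrelationNetwork(feature_ids=table.feature_ids, rho=frame,
                              n_iterations=n_iterations)


def _duplicate_columns(x: np.ndarray) -> list[int]:
    _, first_idx, counts = np.unique(np.round(x, 12), axis=1,
                                     return_index=True, return_counts=True)
    return sorted(int(i) for i, c in zip(first_idx, counts) if c > 1)


def sparcc_pseudo_p(table: AbundanceTable, network: CorrelationNetwork,
                    n_permutations: int = 100, seed: int | None = None,
                    exclusion_threshold: float = 0.1, exclusion_rounds: int = 10,
                    depth: int = 10_000) -> CorrelationNetwork:
    """Two-sided permutation pseudo p-values for an estimated network.

    Each permutation shuffles every feature's values across samples
    independently (destroying all between-feature dependence), re-runs the
    full SparCC estimate, and counts ``|rho_perm| >= |rho_obs|``;
    ``pseudo_p = (1 + exceedances) / (1 + n_permutations)``.
    """
    if n_permutations < MIN_PERMUTATIONS:
        raise ValueError(f"need >= {MIN_PERMUTATIONS} permutations for alpha=0.05")
    fractions = table.close().matrix()
    n, d = fractions.shape
    rho_obs = np.abs(network.rho.to_numpy())
    rng = np.random.default_rng(seed)
    exceed = np.zeros((d, d))
    for _ in range(n_permutations):
        shuffled = np.empty_like(fractions)
        for j in range(d):
            shuffled[:, j] = fractions[rng.permutation(n), j]
        shuffled /= shuffled.sum(axis=1, keepdims=True)
        rho_perm = _sparcc_rho(shuffled, network.n_iterations, depth,
                               exclusion_threshold, exclusion_rounds, rng)
        exceed += np.abs(rho_perm) >= rho_obs
    p = (1.0 + exceed) / (1.0 + n_permutations)
    np.fill_diagonal(p, 1.0)
    frame = pd.DataFrame(p, index=network.feature_ids, columns=network.feature_ids)
    return CorrelationNetwork(feature_ids=network.feature_ids, rho=network.rho,
                              pseudo_p=frame, n_iterations=network.n_iterations,
                              n_permutations=n_permutations, alpha=network.alpha)


@dataclass
class SignFlipEdge:
    """A feature pair whose significant correlation changes sign post-surgery."""

    feature_a: str
    feature_b: str
    rho_pre: float
    rho_post: float

    @property
    def flip(self) -> str:
        return "pos_to_neg" if self.rho_pre > 0 else "neg_to_pos"


@dataclass
class SignFlipResult:
    edges: list[SignFlipEdge]
    n_pos_to_neg: int
    n_neg_to_pos: int


def sign_flip_edges(net_pre: CorrelationNetwork, net_post: CorrelationNetwork,
                    restrict_to=None) -> SignFlipResult:
    """Edges significant in BOTH condition networks with opposite rho signs.

    ``restrict_to`` limits both endpoints to a feature subset (typically
    the differentially abundant features).
    """
    if net_pre.feature_ids != net_post.feature_ids:
        raise ValueError("pre and post networks have different feature sets")
    feats = net_pre.feature_ids
    keep = set(feats) if restrict_to is None else set(restrict_to) & set(feats)
    if restrict_to is not None and len(keep) < len(set(restrict_to)):
        missing = set(restrict_to) - set(feats)
        if missing:
            raise ValueError(f"restrict_to features absent from networks: "
                             f"{sorted(missing)[:5]}")
    sig_pre = net_pre.significant.to_numpy()
    sig_post = net_post.significant.to_numpy()
    r_pre = net_pre.rho.to_numpy()
    r_post = net_post.rho.to_numpy()
    edges: list[SignFlipEdge] = []
    idx = {f: i for i, f in enumerate(feats)}
    chosen = sorted(keep)
    for a_pos, fa in enumerate(chosen):
        for fb in chosen[a_pos + 1:]:
            i, j = idx[fa], idx[fb]
            if not (sig_pre[i, j] and sig_post[i, j]):
                continue
            if np.sign(r_pre[i, j]) * np.sign(r_post[i, j]) < 0:
                edges.append(SignFlipEdge(fa, fb, float(r_pre[i, j]),
                                          float(r_post[i, j])))
    n_p2n = sum(1 for e in edges if e.flip == "pos_to_neg")
    n_n2p = len(edges) - n_p2n
    return SignFlipResult(edges=edges, n_pos_to_neg=n_p2n, n_neg_to_pos=n_n2p)


def degree_ranking(edges: list[SignFlipEdge]) -> list[tuple[str, int]]:
    """Features ranked by incident flip-edge count, descending; ties broken
    lexicographically."""
    counts: dict[str, int] = {}
    for e in edges:
        counts[e.feature_a] = counts.get(e.feature_a, 0) + 1
        counts[e.feature_b] = counts.get(e.feature_b, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
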