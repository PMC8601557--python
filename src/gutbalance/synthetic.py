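"""Synthetic paired compositional datasets with known ground truth.

The generator emulates the structure of a paired (pre/post surgery) gut
metagenome study: ~15 patients, a few hundred species-level features,
log-normal basis abundances with per-timepoint correlation structure,
planted pre/post abundance shifts, and clinical outcomes driven by a
planted microbial balance plus covariate confounding.  Every downstream
stage therefore has a ground-truth recovery test.

Basis abundances are log-normal (not Dirichlet) because the co-abundance
inference downstream assumes exactly that generative model; recovery tests
stay fair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_tables import (
    AbundanceTable,
    ClinicalTable,
    PairedDesign,
    TableError,
    build_pairs,
)

_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria",
          "Euryarchaeota")

LN2 = float(np.log(2.0))


@dataclass
class BalanceTruth:
    """The planted log-contrast driving the simulated outcomes."""

    plus: tuple[int, ...]        # feature indices of I+
    minus: tuple[int, ...]       # feature indices of I-
    beta: float = 3.0            # outcome units per unit balance
    sigma: float = 1.0           # residual sd of the continuous outcome
    link: str = "identity"       # identity | logistic | log

    def __post_init__(self) -> None:
        if set(self.plus) & set(self.minus):
            raise ValueError("balance truth: I+ and I- overlap")
        if self.link not in ("identity", "logistic", "log"):
            raise ValueError(f"unknown link {self.link!r}")


@dataclass
class CovariateModel:
    copd_prevalence: float = 0.4
    cancer_type_probs: tuple[float, ...] = (0.3, 0.5, 0.2)  # I / II / IIIA
    gamma_copd: float = 0.0          # confounding weight on outcomes
    gamma_cancer: tuple[float, ...] = (0.0, 0.0, 0.0)


@dataclass
class SyntheticSpec:
    """Full description of one simulated study; reproducible from ``seed``."""

    n_patients: int = 15
    n_features: int = 200
    log_basis_mean: np.ndarray | None = None
    log_sd: np.ndarray | None = None
    basis_correlation_pre: np.ndarray | None = None
    basis_correlation_post: np.ndarray | None = None
    #: feature index -> log2 effect applied to the post log-mean
    differential_features: dict[int, float] = field(default_factory=dict)
    balance_truth: BalanceTruth | None = None
    covariates: CovariateModel = field(default_factory=CovariateModel)
    vo2_intercept: float = 20.0       # ml/kg/min scale baseline
    os_scale: float = 36.0            # months
    seed: int = 0

    def resolved(self) -> "SyntheticSpec":
        """Fill derived defaults (means, sds, identity correlations)."""
        d = self.n_features
        rng = np.random.default_rng(self.seed ^ 0x5EED)
        mean = self.log_basis_mean
        if mean is None:
            # broad log-abundance spectrum; abundance rank independent of index
            mean = rng.normal(0.0, 2.0, size=d)
        sd = self.log_sd if self.log_sd is not None else np.full(d, 1.0)
        cpre = self.basis_correlation_pre
        cpost = self.basis_correlation_post
        if cpre is None:
            cpre = np.eye(d)
        if cpost is None:
            cpost = cpre.copy()
        for name, c in (("pre", cpre), ("post", cpost)):
            _check_correlation(c, d, name)
        return replace(
            self,
            log_basis_mean=np.asarray(mean, float),
            log_sd=np.asarray(sd, float),
            basis_correlation_pre=np.asarray(cpre, float),
            basis_correlation_post=np.asarray(cpost, float),
        )


def _check_correlation(c: np.ndarray, d: int, name: str) -> None:
    c = np.asarray(c)
    if c.shape != (d, d):
        raise ValueError(f"{name} correlation matrix has wrong shape {c.shape}")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError(f"{name} correlation matrix not symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-10):
        raise ValueError(f"{name} correlation matrix diagonal != 1")
    w = np.linalg.eigvalsh(c)
    if w.min() < -1e-8:
        raise ValueError(f"{name} correlation matrix not positive semidefinite "
                         f"(min eigenvalue {w.min():.3g})")


@dataclass
class SyntheticDataset:
    abundance: AbundanceTable
    clinical: ClinicalTable
    pairs: PairedDesign
    truth: SyntheticSpec
    #: unobserved absolute ("basis") log abundances, for recovery scoring
    log_basis_pre: np.ndarray | None = None
    log_basis_post: np.ndarray | None = None


def feature_names(n_features: int) -> list[str]:
    """Deterministic lineage-style feature ids cycling through major phyla."""
    names = []
    for i in range(n_features):
        phylum = _PHYLA[i % len(_PHYLA)]
        names.append(
            f"k__Bacteria|p__{phylum}|g__Genus{i:03d}|s__Species_{i:03d}"
        )
    return names


def nearest_psd_correlation(c: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project to the nearest PSD matrix (eigenvalue clipping) and rescale
    to unit diagonal.  Deterministic; the standard repair."""
    c = np.asarray(c, float)
    c = (c + c.T) / 2.0
    w, v = np.linalg.eigh(c)
    w = np.clip(w, eig_floor, None)
    fixed = (v * w) @ v.T
    dd = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(dd, dd)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


def plant_sign_flip(spec: SyntheticSpec, feature_a: int, feature_b: int,
                    rho: float) -> SyntheticSpec:
    """Plant a correlation that flips sign after surgery: +rho pre, -rho post.

    Both matrices are PSD-projected after the edit, so neighbouring entries
    may move slightly.
    """
    if feature_a == feature_b:
        raise ValueError("cannot plant a sign flip on a feature with itself")
    if abs(rho) > 0.9:
        raise ValueError("|rho| must be <= 0.9 to leave room for PSD projection")
    spec = spec.resolved()
    cpre = spec.basis_correlation_pre.copy()
    cpost = spec.basis_correlation_post.copy()
    for c, val in ((cpre, rho), (cpost, -rho)):
        c[feature_a, feature_b] = val
        c[feature_b, feature_a] = val
    return replace(
        spec,
        basis_correlation_pre=nearest_psd_correlation(cpre),
        basis_correlation_post=nearest_psd_correlation(cpost),
    )


def _balance_values(comp: np.ndarray, plus: tuple[int, ...],
                    minus: tuple[int, ...]) -> np.ndarray:
    """Proportional balance on closed compositions with zero replacement."""
    nz = comp[comp > 0]
    eps = nz.min() / 2.0 if nz.size else 1e-12
    logx = np.log(comp + eps)
    return logx[:, list(plus)].mean(axis=1) - logx[:, list(minus)].mean(axis=1)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one paired dataset from the spec; byte-reproducible from seed."""
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_patients, spec.n_features
    names = feature_names(d)
    sd = spec.log_sd

    def draw(corr: np.ndarray, mean: np.ndarray) -> np.ndarray:
        cov = corr * np.outer(sd, sd)
        # eigen-decomposition draw: stable for barely-PSD matrices
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        z = rng.standard_normal((n, d))
        return mean + z @ (v * np.sqrt(w)).T

    post_mean = spec.log_basis_mean.copy()
    for idx, delta_log2 in spec.differential_features.items():
        post_mean[idx] += delta_log2 * LN2

    log_pre = draw(spec.basis_correlation_pre, spec.log_basis_mean)
    log_post = draw(spec.basis_correlation_post, post_mean)

    comp_pre = _close_rows(np.exp(log_pre))
    comp_post = _close_rows(np.exp(log_post))

    patients = [f"P{i + 1:02d}" for i in range(n)]
    sample_ids = [f"{p}_pre" for p in patients] + [f"{p}_post" for p in patients]
    values = pd.DataFrame(
        np.vstack([comp_pre, comp_post]), index=sample_ids, columns=names
    )
    abundance = AbundanceTable(values, unit_scale="fraction")

    clinical = _simulate_clinical(spec, rng, patients, comp_post)
    pairs = build_pairs(clinical, abundance)
    return SyntheticDataset(abundance, clinical, pairs, spec,
                            log_basis_pre=log_pre, log_basis_post=log_post)


def _close_rows(x: np.ndarray) -> np.ndarray:
    return x / x.sum(axis=1, keepdims=True)


def _simulate_clinical(spec: SyntheticSpec, rng: np.random.Generator,
                       patients: list[str], comp_post: np.ndarray) -> ClinicalTable:
    n = len(patients)
    cov = spec.covariates
    copd = rng.binomial(1, cov.copd_prevalence, size=n)
    probs = np.asarray(cov.cancer_type_probs, float)
    probs = probs / probs.sum()
    cancer_idx = rng.choice(len(probs), size=n, p=probs)
    cancer_labels = np.array(["I", "II", "IIIA"])[cancer_idx]
    gamma_c = np.asarray(cov.gamma_cancer, float)

    confound = cov.gamma_copd * copd + gamma_c[cancer_idx]

    if spec.balance_truth is not None:
        bt = spec.balance_truth
        b = _balance_values(comp_post, bt.plus, bt.minus)
        lin = bt.beta * (b - b.mean()) + confound
        vo2 = spec.vo2_intercept + lin + rng.normal(0.0, bt.sigma, size=n)
        recurrence = rng.binomial(1, _sigmoid(lin)).astype(int)
        os_months = spec.os_scale * np.exp(
            0.1 * lin + rng.normal(0.0, 0.1 * max(bt.sigma, 1e-12), size=n)
        )
    else:
        vo2 = spec.vo2_intercept + confound + rng.normal(0.0, 1.0, size=n)
        recurrence = rng.binomial(1, _sigmoid(confound)).astype(int)
        os_months = spec.os_scale * np.exp(rng.normal(0.0, 0.2, size=n))

    # remaining CPET / lung-function parameters: covariate effect + noise
    extra = {}
    for name, base, sdev in (
        ("FEV1%", 85.0, 12.0), ("TLC%", 100.0, 10.0), ("RV%", 110.0, 20.0),
        ("sGaw%", 90.0, 15.0), ("Watt", 110.0, 25.0), ("VE", 60.0, 12.0),
        ("O2/HR", 12.0, 2.0), ("VE/VCO2", 32.0, 4.0), ("VE/VO2", 35.0, 5.0),
    ):
        extra[name] = base - 5.0 * copd + rng.normal(0.0, sdev, size=n)

    rows = []
    for tp in ("pre", "post"):
        for i, p in enumerate(patients):
            row = {
                "sample_id": f"{p}_{tp}",
                "patient_id": p,
                "timepoint": tp,
                "COPD": int(copd[i]),
                "cancer_type": cancer_labels[i],
                "recurrence": int(recurrence[i]),
                "OS": float(os_months[i]),
                "VO2": float(vo2[i]),
            }
            for name in extra:
                row[name] = float(extra[name][i])
            rows.append(row)
    df = pd.DataFrame(rows).set_index("sample_id")
    return ClinicalTable(df)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def default_study_spec(seed: int = 0, n_patients: int = 15,
                       n_features: int = 200) -> SyntheticSpec:
    """The demo study: planted differential taxa, one sign-flip edge, and a
    2-vs-3-taxon balance driving VO2, recurrence and OS.

    Mirrors the target study's scale (15 paired patients, tens to hundreds
    of species) and effect architecture: ~1/6 of taxa shifted strongly
    after surgery (4-8-fold, the size needed for paired detection at 15
    patients), the down-shifted taxa forming a collectively decreasing
    anaerobe class, one co-abundance edge flipping sign, and small
    balances of 2-7 taxa predicting outcomes.
    """
    differential = {0: 2.5, 1: 2.0, 4: 2.0, 6: 3.0, 8: 2.5,
                    2: -2.5, 3: -2.0, 5: -2.0, 7: -3.0, 9: -2.5}
    spec = SyntheticSpec(
        n_patients=n_patients,
        n_features=n_features,
        differential_features=differential,
        balance_truth=BalanceTruth(plus=(0, 1), minus=(2, 3), beta=3.0, sigma=1.0),
        covariates=CovariateModel(gamma_copd=-1.0, gamma_cancer=(0.0, -0.5, -1.0)),
        seed=seed,
    )
    return plant_sign_flip(spec, 0, 2, 0.8)
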