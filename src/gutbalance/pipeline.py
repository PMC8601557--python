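"""End-to-end orchestration: simulate or ingest, then run diversity,
differential abundance, co-abundance networks, correlation screens and
balance selection from a single seeded configuration.

Every stage is a pure function of (inputs, config, seed); per-stage seeds
are derived deterministically from the top-level seed by hashing the stage
name, so stages can be rerun independently yet reproducibly.  Each stage
writes one TSV into the output directory; a manifest records the config,
seed, package version and per-stage wall time (the manifest is the one
file allowed to differ between otherwise identical reruns).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_tables import (
    AbundanceTable, ClinicalTable, OxygenAnnotation, PairedDesign,
    build_pairs, read_abundance_table, read_annotation, read_clinical,
    write_abundance_table, write_clinical,
)
from . import diversity as div
from . import differential as diff
from . import sparcc_network as net
from . import partial_correlation as pcorr
from .balance_selection import BalanceSelector
from .synthetic import SyntheticDataset, default_study_spec, generate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one analysis run; a seed is mandatory."""

    seed: int
    abundance_path: str | None = None
    clinical_path: str | None = None
    annotation_path: str | None = None
    simulate: bool = False
    n_patients: int = 15
    n_features: int = 60
    min_prevalence: float = 0.10
    alpha: float = 0.05
    use_fdr: bool = True
    pseudo_p_alpha: float = 0.05
    min_abs_rho_fungi: float = 0.65
    permanova_permutations: int = 999
    sparcc_iterations: int = 20
    sparcc_permutations: int = 100
    C_max: int = 20
    n_folds: int = 5
    n_repeats: int = 10
    parameters: list[str] = field(default_factory=lambda: ["VO2", "Watt", "VE"])
    covariates: list[str] = field(default_factory=lambda: ["COPD", "cancer_type"])

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        if not 0 < self.min_prevalence <= 1:
            raise ValueError("min_prevalence out of range")
        for name in ("alpha", "pseudo_p_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} out of range")
        if not self.simulate and self.abundance_path is None:
            raise ValueError("either simulate=true or input paths required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must name a seed")
        return cls(**raw)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stage-name hashing), < 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _load_inputs(config: RunConfig, out: Path):
    if config.simulate:
        spec = default_study_spec(seed=stage_seed(config.seed, "simulate"),
                                  n_patients=config.n_patients,
                                  n_features=config.n_features)
        ds = generate(spec)
        write_abundance_table(ds.abundance, out / "abundance.tsv")
        write_clinical(ds.clinical, out / "clinical.tsv")
        annotation = _synthetic_annotation(ds)
        with open(out / "truth.json", "w") as fh:
            json.dump(_truth_dict(ds), fh, indent=1, sort_keys=True)
        return ds.abundance, ds.clinical, ds.pairs, annotation
    table = read_abundance_table(config.abundance_path, layout="taxa_merged")
    clinical = read_clinical(config.clinical_path)
    pairs = build_pairs(clinical, table)
    annotation = (read_annotation(config.annotation_path)
                  if config.annotation_path else None)
    return table, clinical, pairs, annotation


def _synthetic_annotation(ds: SyntheticDataset) -> OxygenAnnotation:
    """Deterministic synthetic oxygen labels: the planted-decrease taxa are
    anaerobes, planted increases aerobes; most other species stay
    unannotated (as in real oxygen-tolerance maps), with every seventh
    labelled to give each class unshifted members."""
    classes = {}
    diffs = ds.truth.differential_features
    for i, fid in enumerate(ds.abundance.feature_ids):
        if i in diffs:
            classes[fid] = "anaerobe" if diffs[i] < 0 else "aerobe"
        elif i % 7 == 0:
            classes[fid] = "anaerobe" if (i // 7) % 2 else "aerobe"
        else:
            classes[fid] = "unknown"
    return OxygenAnnotation(classes)


def _truth_dict(ds: SyntheticDataset) -> dict:
    t = ds.truth
    feats = ds.abundance.feature_ids
    return {
        "differential_features": {feats[i]: d
                                  for i, d in t.differential_features.items()},
        "balance_plus": [feats[i] for i in t.balance_truth.plus],
        "balance_minus": [feats[i] for i in t.balance_truth.minus],
        "beta": t.balance_truth.beta,
        "sigma": t.balance_truth.sigma,
        "seed": t.seed,
    }


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage in dependency order; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "seed": config.seed,
                      "version": __version__, "stages": {}}

    def timed(name):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self_inner
            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                manifest["stages"][name] = {"seconds": round(dt, 3),
                                            "ok": exc_type is None}
                if exc_type is not None:
                    logger.error("stage %s failed: %s", name, exc)
        return _T()

    with timed("load"):
        table, clinical, pairs, annotation = _load_inputs(config, out)

    with timed("diversity"):
        alpha = pd.DataFrame({idx: div.alpha_diversity(table, idx)
                              for idx in div.ALPHA_INDICES})
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t",
                     index_label="sample_id")
        dm = div.bray_curtis(table)
        timepoint = clinical.column("timepoint").reindex(table.sample_ids)
        perm = div.permanova(dm, timepoint,
                             n_permutations=config.permanova_permutations,
                             seed=stage_seed(config.seed, "permanova"))
        pd.DataFrame([{"pseudo_F": perm.pseudo_F, "R2": perm.R2,
                       "p_value": perm.p_value,
                       "n_permutations": perm.n_permutations}]).to_csv(
            out / "permanova.tsv", sep="\t", index=False)

    with timed("differential"):
        filtered = diff.prevalence_filter(table, config.min_prevalence)
        da = diff.paired_wilcoxon(filtered, pairs)
        da.to_csv(out / "differential.tsv", sep="\t", index=False)
        sig = diff.significant_features(da, alpha=config.alpha,
                                        use_fdr=config.use_fdr)
        # figure-style stages (networks, correlation heatmaps) follow the
        # raw-p convention; tabulated counts follow the FDR setting
        sig_raw = diff.significant_features(da, alpha=config.alpha,
                                            use_fdr=False)
        if annotation is not None:
            rows = []
            for cls in ("aerobe", "anaerobe"):
                try:
                    es = diff.aggregate_class_test(filtered, pairs, annotation, cls)
                    rows.append({"class": cls, "r": es.r,
                                 "p_value": es.p_value, "n_pairs": es.n_pairs})
                except Exception as exc:  # class may be absent
                    logger.warning("aggregate test for %s skipped: %s", cls, exc)
            pd.DataFrame(rows, columns=["class", "r", "p_value", "n_pairs"]
                         ).to_csv(out / "oxygen_class.tsv", sep="\t",
                                  index=False)

    with timed("network"):
        pre = filtered.subset_samples(pairs.pre_samples)
        post = filtered.subset_samples(pairs.post_samples)
        nseed = stage_seed(config.seed, "network")
        net_pre = net.sparcc(pre, n_iterations=config.sparcc_iterations,
                             seed=nseed)
        net_pre = net.sparcc_pseudo_p(pre, net_pre,
                                      n_permutations=config.sparcc_permutations,
                                      seed=nseed + 1)
        net_post = net.sparcc(post, n_iterations=config.sparcc_iterations,
                              seed=nseed + 2)
        net_post = net.sparcc_pseudo_p(post, net_post,
                                       n_permutations=config.sparcc_permutations,
                                       seed=nseed + 3)
        net_pre.rho.to_csv(out / "sparcc_rho_pre.tsv", sep="\t")
        net_post.rho.to_csv(out / "sparcc_rho_post.tsv", sep="\t")
        flips = net.sign_flip_edges(net_pre, net_post,
                                    restrict_to=sig_raw if sig_raw else None)
        pd.DataFrame([{"feature_a": e.feature_a, "feature_b": e.feature_b,
                       "rho_pre": e.rho_pre, "rho_post": e.rho_post,
                       "flip": e.flip} for e in flips.edges],
                     columns=["feature_a", "feature_b", "rho_pre",
                              "rho_post", "flip"]).to_csv(
            out / "sign_flips.tsv", sep="\t", index=False)

    with timed("correlations"):
        post_sig = (filtered.subset_features(sig_raw).subset_samples(pairs.post_samples)
                    if sig_raw else filtered.subset_samples(pairs.post_samples))
        screen = pcorr.correlation_screen(post_sig.values, clinical,
                                          parameters=config.parameters,
                                          covariates=config.covariates,
                                          p_max=config.alpha)
        screen.to_csv(out / "correlations.tsv", sep="\t", index=False)

    with timed("balances"):
        bal_feats = sig
        if len(bal_feats) < 2:
            logger.warning("too few FDR-significant features; falling back "
                           "to raw p < alpha for balance selection")
            bal_feats = diff.significant_features(da, alpha=config.alpha,
                                                  use_fdr=False)
        rows = []
        if len(bal_feats) >= 2:
            post_tab = filtered.subset_features(bal_feats).subset_samples(
                pairs.post_samples)
            bseed = stage_seed(config.seed, "balance")
            for resp, kind, logr in (("VO2", "continuous", False),
                                     ("recurrence", "dichotomous", False),
                                     ("OS", "continuous", True)):
                try:
                    model = BalanceSelector.from_clinical(
                        post_tab, clinical, resp, kind=kind, log_response=logr)
                    res = model.fit(C_max=config.C_max, n_folds=config.n_folds,
                                    n_repeats=config.n_repeats, seed=bseed)
                except ValueError as exc:
                    logger.warning("balance for %s skipped: %s", resp, exc)
                    continue
                rows.append({
                    "response": resp, "kind": kind, "C_opt": res.C_opt,
                    "fit": res.fit.value, "cv_fit": res.cv_score_at_C_opt,
                    "accuracy": res.fit.accuracy,
                    "plus": ";".join(res.global_balance.plus_set),
                    "minus": ";".join(res.global_balance.minus_set),
                })
        pd.DataFrame(rows, columns=["response", "kind", "C_opt", "fit",
                                    "cv_fit", "accuracy", "plus", "minus"]
                     ).to_csv(out / "balances.tsv", sep="\t", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def report(out_dir: str | Path) -> str:
    """Markdown summary of a result bundle; missing stages are flagged."""
    out = Path(out_dir)
    lines = ["# gutbalance run summary", ""]
    found = False

    def read(name):
        p = out / name
        if not p.exists():
            return None
        try:
            return pd.read_csv(p, sep="\t")
        except pd.errors.EmptyDataError:
            return None

    perm = read("permanova.tsv")
    if perm is not None:
        found = True
        r = perm.iloc[0]
        lines += ["## Beta diversity",
                  f"PERMANOVA pre vs post: pseudo-F = {r.pseudo_F:.3f}, "
                  f"R2 = {100 * r.R2:.1f}%, P = {r.p_value:.4g}", ""]
    da = read("differential.tsv")
    if da is not None:
        found = True
        sig = da[(da.q_value < 0.05) & ~da.untestable]
        up = (sig.direction == "up_post").sum()
        lines += ["## Differential abundance",
                  f"{len(sig)} significant features (q < 0.05): "
                  f"{up} up after surgery, {len(sig) - up} down", ""]
    ox = read("oxygen_class.tsv")
    if ox is not None and len(ox):
        found = True
        lines.append("## Oxygen-class aggregate shifts")
        for _, r in ox.iterrows():
            lines.append(f"- {r['class']}: r = {100 * r.r:.1f}%, "
                         f"P = {r.p_value:.3g} ({int(r.n_pairs)} pairs)")
        lines.append("")
    fl = read("sign_flips.tsv")
    if fl is not None:
        found = True
        p2n = (fl.flip == "pos_to_neg").sum() if len(fl) else 0
        n2p = (fl.flip == "neg_to_pos").sum() if len(fl) else 0
        lines += ["## Co-abundance sign flips",
                  f"{n2p} edges changed negative->positive, "
                  f"{p2n} positive->negative", ""]
    sc = read("correlations.tsv")
    if sc is not None:
        found = True
        lines += ["## CPET / lung-function correlations",
                  f"{len(sc)} feature-parameter pairs pass the screen"]
        for _, r in sc.head(5).iterrows():
            lines.append(f"- {r.feature_id} vs {r.parameter}: "
                         f"rho = {r.rho_partial:.2f}, P = {r.p_value:.3g}")
        lines.append("")
    ba = read("balances.tsv")
    if ba is not None:
        found = True
        lines.append("## Balance selection")
        if len(ba) == 0:
            lines.append("no balances fitted (too few significant features)")
        for _, r in ba.iterrows():
            stat = "r" if r.kind == "continuous" else "AUC"
            lines.append(f"- {r.response}: C_opt = {int(r.C_opt)}, "
                         f"{stat} = {r.fit:.2f} (CV {r.cv_fit:.2f}); "
                         f"I+ = {r.plus}; I- = {r.minus}")
        lines.append("")
    if not found:
        lines.append("no stages completed")
    return "\n".join(lines)
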