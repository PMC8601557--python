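"""Figure helpers: correlation heatmaps with significance stars and PCoA
ordination plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_heatmap(screen: pd.DataFrame, ax=None):
    """Heatmap of a long-format correlation screen (feature_id, parameter,
    rho_partial, p_value), cells annotated with significance stars."""
    wide_r = screen.pivot(index="feature_id", columns="parameter",
                          values="rho_partial")
    wide_p = screen.pivot(index="feature_id", columns="parameter",
                          values="p_value")
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + wide_r.shape[1],
                                      1 + 0.4 * wide_r.shape[0]))
    im = ax.imshow(wide_r.to_numpy(dtype=float), cmap="RdBu_r",
                   vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(wide_r.shape[1]), wide_r.columns, rotation=45,
                  ha="right")
    ax.set_yticks(range(wide_r.shape[0]),
                  [f.split("s__")[-1] for f in wide_r.index])
    for i in range(wide_r.shape[0]):
        for j in range(wide_r.shape[1]):
            p = wide_p.iloc[i, j]
            if np.isfinite(p):
                ax.text(j, i, significance_stars(float(p)),
                        ha="center", va="center", fontsize=8)
    ax.figure.colorbar(im, ax=ax, label="partial Spearman rho")
    return ax


def pcoa_plot(result, grouping, ax=None):
    """Scatter of the first two PCoA axes coloured by a grouping aligned
    with the coordinate index."""
    coords = result.coordinates
    if coords.shape[1] < 2:
        raise ValueError("need at least two ordination axes")
    labels = pd.Series(np.asarray(grouping), index=coords.index) \
        if not isinstance(grouping, pd.Series) else grouping.reindex(coords.index)
    if ax is None:
        _, ax = plt.subplots()
    for lab, grp in coords.groupby(labels):
        ax.scatter(grp.iloc[:, 0], grp.iloc[:, 1], label=str(lab), alpha=0.8)
    prop = result.proportion_explained
    ax.set_xlabel(f"PC1 ({100 * prop[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * prop[1]:.1f}%)")
    ax.legend(title="group")
    return ax
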