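"""Plot helpers for derived-trait trajectories and association results."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import sex_stratified_smoother


def plot_age_trends(age, value, sex, ax=None, span: float = 0.75,
                    trait_name: str = "", colors=("#1b9e77", "#d95f02")):
    """Sex-stratified local-regression curves of a trait against age.

    Draws one locally weighted regression line per sex with a shaded
    pointwise 95% confidence band, the standard way of showing how a
    derived glycosylation trait drifts across the lifespan in each sex.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    curves = sex_stratified_smoother(age, value, sex, span=span)
    for color, (label, df) in zip(colors, sorted(curves.items())):
        ax.fill_between(df["age"], df["lo"], df["hi"], alpha=0.25,
                        color="gray", linewidth=0)
        ax.plot(df["age"], df["fit"], color=color, label=label)
    ax.set_xlabel("age (years)")
    ax.set_ylabel(f"{trait_name} (% area)" if trait_name else "% area")
    ax.legend(title="sex", frameon=False)
    return ax


def plot_correlation_heatmap(meta_table: pd.DataFrame, alpha: float = 0.01,
                             ax=None):
    """Signed heat map of BH-significant meta effects (glycan x phenotype).

    Non-significant cells (adjusted p above ``alpha``) are masked, matching
    the usual presentation of covariate-adjusted glycan-phenotype
    correlation screens.
    """
    import matplotlib.pyplot as plt

    pivot = meta_table.pivot(index="glycan", columns="trait", values="effect")
    mask = meta_table.pivot(index="glycan", columns="trait",
                            values="p_adjusted") > alpha
    data = pivot.mask(mask)
    if ax is None:
        _, ax = plt.subplots(figsize=(0.5 * len(pivot.columns) + 2,
                                      0.3 * len(pivot) + 1.5))
    vmax = np.nanmax(np.abs(data.to_numpy())) if np.isfinite(data.to_numpy()).any() else 1.0
    im = ax.imshow(data.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(len(data.columns)), data.columns, rotation=90)
    ax.set_yticks(range(len(data.index)), data.index)
    ax.figure.colorbar(im, ax=ax, label="meta effect")
    return ax
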