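"""Optional figures (requires matplotlib; install the ``plots`` extra).

Headless-safe: figures are returned, never shown; callers decide whether to
save them. The numeric CSV outputs remain the authoritative results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _mpl():
    try:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib "
                          "(pip install heterowheat[plots])") from exc
    return plt


def heterosis_density(records: pd.DataFrame, traits: list[str], *,
                      kind: str = "mid_parent"):
    """Density-style histograms of per-hybrid heterosis, one panel per trait,
    with the mean +- SD marked."""
    plt = _mpl()
    col = {"mid_parent": "het_mp", "best_parent": "het_bp"}[kind]
    fig, axes = plt.subplots(1, len(traits), figsize=(3 * len(traits), 3),
                             squeeze=False)
    for ax, trait in zip(axes[0], traits):
        het = records.loc[(records["trait"] == trait)
                          & (~records["undefined"]), col].dropna()
        ax.hist(het, bins=20, density=True, alpha=0.6)
        ax.axvline(0, color="k", lw=0.8, ls="--")
        m, s = het.mean(), het.std(ddof=1)
        ax.errorbar([m], [0], xerr=[[s], [s]], fmt="o", color="k")
        ax.set_title(f"{trait} ({kind.replace('_', '-')})")
        ax.set_xlabel("heterosis (%)")
    fig.tight_layout()
    return fig


def ancova_scatter(wide: pd.DataFrame, response: str, covariate: str, *,
                   group_col: str = "group"):
    """Scatter of response vs covariate with per-group regression lines."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4, 4))
    for group, marker, color in (("line", "^", "tab:blue"),
                                 ("hybrid", "o", "tab:red")):
        sub = wide[wide[group_col] == group].dropna(
            subset=[response, covariate])
        ax.scatter(sub[covariate], sub[response], marker=marker, s=18,
                   color=color, alpha=0.7, label=group)
        if len(sub) >= 3:
            slope, intercept = np.polyfit(sub[covariate], sub[response], 1)
            xs = np.linspace(sub[covariate].min(), sub[covariate].max(), 50)
            ax.plot(xs, slope * xs + intercept, color=color, lw=1.2)
    ax.set_xlabel(covariate)
    ax.set_ylabel(response)
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig
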