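"""Optional diagnostic figures: occurrence bar chart and Williams plot."""

from __future__ import annotations

import pandas as pd

from .validation import ADResult


def occurrence_bar(occurrence: pd.Series, path=None, ax=None):
    """Bar chart of per-descriptor selection occurrence (%) with its mean."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    occ = occurrence.sort_values(ascending=False)
    ax.bar(occ.index, occ.to_numpy(), color="#33557f")
    ax.axhline(occurrence.mean(), color="crimson", ls="--", label="mean occurrence")
    ax.set_ylabel("occurrence / %")
    ax.tick_params(axis="x", rotation=60)
    ax.legend()
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax


def williams_plot(ad: ADResult, path=None, ax=None):
    """Leverage vs standardized residual with the h* and residual warning limits."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 4.5))
    markers = {"train": ("o", "royalblue"), "query": ("D", "hotpink")}
    for label, grp in ad.table.groupby("set"):
        marker, color = markers.get(label, ("s", "gray"))
        ax.scatter(grp["h"], grp["std_residual"], marker=marker, color=color,
                   label=label, edgecolor="k", lw=0.4)
    ax.axvline(ad.h_star, color="crimson", ls="--", label="h*")
    for s in (-ad.residual_limit, ad.residual_limit):
        ax.axhline(s, color="gray", ls=":")
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend()
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
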