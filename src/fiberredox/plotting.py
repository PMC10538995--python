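"""Quick-look plots for per-fiber redox tables and capillary panels."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_redox_by_type", "plot_section_overview"]

_TYPE_ORDER = ("I", "IIa", "IIx")


def plot_redox_by_type(table: pd.DataFrame, outcome: str = "redox_ratio",
                       ax=None):
    """Strip plot of a per-fiber outcome by fiber type with type means.

    ``table`` is the frame from :func:`fiberredox.quantify_section`; dots are
    individual fibers, horizontal bars the per-type means (ratio computed per
    fiber first, then averaged).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    sub = table[table.included & table.type.isin(_TYPE_ORDER)]
    rng = np.random.default_rng(0)
    for i, t in enumerate(_TYPE_ORDER):
        vals = sub.loc[sub.type == t, outcome].dropna()
        if len(vals) == 0:
            continue
        x = i + rng.uniform(-0.15, 0.15, len(vals))
        ax.plot(x, vals, "o", ms=3, alpha=0.6)
        ax.hlines(vals.mean(), i - 0.25, i + 0.25, color="k", lw=2)
    ax.set_xticks(range(len(_TYPE_ORDER)), [f"MHC {t}" for t in _TYPE_ORDER])
    ax.set_ylabel(outcome.replace("_", " "))
    return ax


def plot_section_overview(images: dict, truth=None, ax=None):
    """Show the Fp channel with fiber outlines and planted capillaries."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(images["Fp"].pixels, cmap="magma")
    if truth is not None:
        for poly in truth.polygons.values():
            x, y = poly.exterior.xy
            ax.plot(x, y, "w-", lw=0.5, alpha=0.7)
        if len(truth.capillaries):
            ax.plot(truth.capillaries[:, 0], truth.capillaries[:, 1], "c.",
                    ms=3)
    ax.set_axis_off()
    return ax
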