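"""Basic association plot helper (optional; requires matplotlib)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def manhattan(res: pd.DataFrame, ax=None, threshold: float | None = None):
    """Minimal Manhattan plot of -log10 p by cumulative genome position."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    for i, (chrom, grp) in enumerate(res.groupby("chrom", sort=True)):
        ax.scatter(grp["pos"] + offset, -np.log10(grp["p"]), s=4,
                   color="C0" if i % 2 == 0 else "C1", label=None)
        offset += grp["pos"].max() + 1
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", lw=0.8, ls="--")
    ax.set_xlabel("cumulative position (bp)")
    ax.set_ylabel(r"$-\log_{10} p$")
    return ax
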