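"""Simple Manhattan and QQ plots from scan output (matplotlib, lazy import)."""

from __future__ import annotations

import numpy as np

from .scan import GENOME_WIDE_ALPHA, manhattan_data, qq_data

__all__ = ["plot_manhattan", "plot_qq"]


def plot_manhattan(rows, ax=None, alpha=GENOME_WIDE_ALPHA):
    """Manhattan plot of F-test p-values; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3.5))
    md = manhattan_data(rows)
    for i, (chrom, sub) in enumerate(md.groupby("chrom", sort=False)):
        ax.scatter(sub["x"], sub["neglog10p"], s=8,
                   color=f"C{i % 2}", label=f"chr {chrom}")
    ax.axhline(-np.log10(alpha), color="red", ls="--", lw=0.8)
    ax.set_xlabel("cumulative position (bp)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.legend(fontsize=8, frameon=False)
    return ax


def plot_qq(p_values, ax=None):
    """QQ plot of p-values with the genomic inflation factor in the title."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    expected, observed, lam = qq_data(p_values)
    ax.scatter(expected, observed, s=8, color="C0")
    lim = max(expected.max(), observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    ax.set_title(rf"$\lambda_{{GC}} = {lam:.3f}$", fontsize=10)
    return ax
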