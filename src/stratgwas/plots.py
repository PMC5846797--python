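"""Manhattan and QQ plots for difference / joint test P-values."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["manhattan", "qq"]


def manhattan(
    tests: pd.DataFrame,
    p_col: str = "p_joint",
    out: str | Path | None = None,
    alpha: float = 5e-8,
    highlight: pd.DataFrame | None = None,
    highlight_window: int = 500_000,
):
    """Manhattan plot of -log10 P by genomic position.

    ``highlight`` (columns chr, pos) marks known regions (+/- window) in a
    second colour.
    """
    fig, ax = plt.subplots(figsize=(10, 3.2))
    offset, ticks = 0, []
    for chrom, grp in tests.groupby(tests["chr"].astype(str), sort=False):
        x = grp["pos"].to_numpy() + offset
        logp = -np.log10(np.clip(grp[p_col].to_numpy(), 1e-320, 1.0))
        known = np.zeros(len(grp), dtype=bool)
        if highlight is not None:
            hp = highlight[highlight["chr"].astype(str) == chrom]["pos"].to_numpy()
            for p in hp:
                known |= np.abs(grp["pos"].to_numpy() - p) <= highlight_window
        ax.scatter(x[~known], logp[~known], s=4, c="grey")
        ax.scatter(x[known], logp[known], s=4, c="tab:blue")
        ticks.append((chrom, offset + grp["pos"].median()))
        offset += grp["pos"].max() + 1
    ax.axhline(-np.log10(alpha), color="red", lw=0.8, ls="--")
    ax.set_xticks([t for _, t in ticks], [c for c, _ in ticks])
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} P$")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def qq(
    tests: pd.DataFrame,
    p_col: str = "p_joint",
    out: str | Path | None = None,
    exclude: pd.DataFrame | None = None,
    exclude_window: int = 500_000,
):
    """QQ plot of observed vs expected -log10 P, optionally with a second
    series after exclusion of known regions (+/- window)."""
    fig, ax = plt.subplots(figsize=(3.6, 3.6))

    def series(p, color, label):
        p = np.sort(np.clip(p, 1e-320, 1.0))
        exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))
        ax.scatter(exp[::-1], -np.log10(p)[::-1], s=4, c=color, label=label)

    series(tests[p_col].to_numpy(), "black", "all variants")
    if exclude is not None:
        keep = np.ones(len(tests), dtype=bool)
        chrom = tests["chr"].astype(str).to_numpy()
        pos = tests["pos"].to_numpy()
        for row in exclude.itertuples():
            keep &= ~((chrom == str(row.chr)) & (np.abs(pos - row.pos) <= exclude_window))
        series(tests.loc[keep, p_col].to_numpy(), "red", "known loci excluded")
        ax.legend(fontsize=7)
    lim = ax.get_xlim()[1]
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10} P$")
    ax.set_ylabel(r"observed $-\log_{10} P$")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
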