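"""Optional convenience plots of sweep output (histogram panels per grid cell)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_histogram_grid(directory: str | Path, filename: str = "histograms.png") -> Path:
    """Plot the per-cell donation/aspiration histograms from ``histograms.csv``.

    One panel per (l, h) grid cell, donation and aspiration frequencies
    side by side with across-replication error bars.  Returns the path
    of the written PNG.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    directory = Path(directory)
    df = pd.read_csv(directory / "histograms.csv")
    ls = sorted(df["l"].unique())
    hs = sorted(df["h"].unique())
    fig, axes = plt.subplots(len(ls), len(hs), figsize=(3 * len(hs), 2.2 * len(ls)),
                             sharex=True, sharey=True, squeeze=False)
    width = 0.4
    for i, l in enumerate(ls):
        for j, h in enumerate(hs):
            ax = axes[i][j]
            for quantity, color, off in (("aspiration", "tab:red", -width / 2),
                                         ("donation", "tab:blue", width / 2)):
                sub = df[(df.l == l) & (df.h == h) & (df.quantity == quantity)]
                ax.bar(sub["bin"] + off, sub["freq_mean"], width=width,
                       yerr=sub["freq_sd"], color=color, label=quantity,
                       error_kw=dict(lw=0.8))
            ax.set_title(f"l={l:g}, h={h:g}", fontsize=8)
            ax.set_xticks(range(0, 11, 2))
    axes[0][0].legend(fontsize=7)
    fig.supxlabel("bin n:  n/10 ≤ value < (n+1)/10")
    fig.supylabel("frequency")
    fig.tight_layout()
    out = directory / filename
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
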