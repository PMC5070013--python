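"""Minimal figure helpers (group boxplots, metagene profiles).

Matplotlib is imported lazily so headless pipelines pay nothing for it.
"""

from __future__ import annotations

import pandas as pd


def volume_boxplot(measurements: pd.DataFrame, path, group_col: str = "group") -> None:
    """Boxplot of percent nuclear volume per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(measurements[group_col].unique())
    data = [measurements.loc[measurements[group_col] == g, "percent"] for g in groups]
    fig, ax = plt.subplots(figsize=(1.2 + len(groups), 4))
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel("percent nuclear volume (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def metagene_plot(profiles, path) -> None:
    """Line plot of metagene profiles (TSS left, TTS right)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for prof in profiles:
        ax.plot(prof.values, label=f"{prof.label} (n={prof.n_genes})")
        ax.axvline(prof.flank_bins, color="grey", lw=0.5)
        ax.axvline(prof.flank_bins + prof.body_bins, color="grey", lw=0.5)
    ax.set_xlabel("flank | scaled gene body | flank")
    ax.set_ylabel("mean z-score")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
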