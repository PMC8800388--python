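"""Figures: per-species BTI box plots and the cross-regime scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["boxplot_bti", "scatter_regimes"]


def boxplot_bti(
    bti_table: pd.DataFrame,
    cutoff: float,
    regime: str,
    out_path: str | Path,
    letters: dict[str, str] | None = None,
) -> Path:
    """Box plot of BTI by species at one cutoff/regime (letter-annotated)."""
    sub = bti_table[
        (bti_table["cutoff"] == cutoff) & (bti_table["regime"] == regime)
    ].dropna(subset=["bti_days"])
    species = sorted(sub["species"].unique())
    data = [sub.loc[sub["species"] == sp, "bti_days"].to_numpy()
            for sp in species]
    fig, ax = plt.subplots(figsize=(1.2 * len(species) + 2, 4))
    ax.boxplot(data, tick_labels=species, showmeans=True)
    if letters:
        for i, sp in enumerate(species, start=1):
            top = data[i - 1].max() if len(data[i - 1]) else 0
            ax.annotate(letters.get(sp, ""), (i, top), xytext=(0, 6),
                        textcoords="offset points", ha="center")
    ax.set_ylabel(f"BTI at {cutoff:g}% cutoff (days)")
    ax.set_title(f"{regime}")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    out = Path(out_path)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def scatter_regimes(
    bti_table: pd.DataFrame,
    cutoff: float,
    out_path: str | Path,
    r: float | None = None,
) -> Path:
    """Scatter of SHP vs FHP BTI, paired by (species, colony)."""
    sub = bti_table[bti_table["cutoff"] == cutoff]
    piv = sub.pivot_table(
        index=["species", "colony"], columns="regime",
        values="bti_days", aggfunc="first",
    ).dropna()
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for sp, grp in piv.groupby(level="species"):
        ax.scatter(grp["FHP"], grp["SHP"], label=sp, s=24)
    ax.set_xlabel(f"FHP BTI{cutoff:g} (days)")
    ax.set_ylabel(f"SHP BTI{cutoff:g} (days)")
    title = f"BTI{cutoff:g} across regimes"
    if r is not None:
        title += f" (Pearson r = {r:.2f})"
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    out = Path(out_path)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
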