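"""Simple matplotlib renderings of the pipeline's matrix outputs.

These are convenience plots (PDP heatmap, terminal-profile stacked bars,
per-index boxplots); the TSV matrices are the authoritative outputs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .degradome import order_by_total  # noqa: E402
from .physchem import TerminalProfile  # noqa: E402

# residue colouring by chemical class (polar / neutral / basic / acidic /
# hydrophobic), the usual logo convention
_CLASS_COLORS = {
    **dict.fromkeys("GSTYC", "tab:green"),
    **dict.fromkeys("QN", "tab:purple"),
    **dict.fromkeys("KRH", "tab:blue"),
    **dict.fromkeys("DE", "tab:red"),
    **dict.fromkeys("AVLIPWFM", "black"),
}


def pdp_heatmap(matrix: pd.DataFrame, path: str | Path, max_rows: int = 100) -> None:
    """Heatmap of a PDP matrix, rows ordered by total peptide count."""
    mat = order_by_total(matrix).head(max_rows)
    fig, ax = plt.subplots(figsize=(6, max(2, 0.08 * len(mat))))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(mat.columns)), mat.columns)
    ax.set_yticks([])
    ax.set_xlabel("relative position in precursor (%)")
    ax.set_ylabel(f"{len(mat)} precursors")
    fig.colorbar(im, ax=ax, label="peptide starts")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def terminal_logo(profile: TerminalProfile, path: str | Path) -> None:
    """Stacked-bar sequence-logo sketch of a terminal profile.

    Bar heights are residue frequencies scaled by the position's
    information content, coloured by chemical class.
    """
    pfm, info = profile.pfm, profile.information
    fig, ax = plt.subplots(figsize=(1.2 * len(pfm) + 1, 3))
    for pos in pfm.index:
        bottom = 0.0
        row = pfm.loc[pos].sort_values()
        for res, freq in row.items():
            h = freq * info[pos]
            if h <= 0:
                continue
            ax.bar(pos, h, bottom=bottom, color=_CLASS_COLORS.get(res, "grey"),
                   width=0.8)
            if h > 0.15:
                ax.text(pos, bottom + h / 2, res, ha="center", va="center",
                        fontsize=8, color="white")
            bottom += h
    ax.set_xticks(list(pfm.index))
    ax.set_xlabel(f"position from {profile.terminus}-terminus")
    ax.set_ylabel("bits")
    ax.set_ylim(0, np.log2(20))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def index_boxplots(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame, index_ids,
    labels: tuple[str, str], path: str | Path,
) -> None:
    """Side-by-side boxplots of per-peptide descriptor values per index."""
    index_ids = [i for i in index_ids if i in matrix_a.columns]
    fig, axes = plt.subplots(1, max(1, len(index_ids)),
                             figsize=(2.2 * max(1, len(index_ids)), 3))
    axes = np.atleast_1d(axes)
    for ax, idx in zip(axes, index_ids):
        ax.boxplot([matrix_a[idx], matrix_b[idx]], tick_labels=list(labels),
                   showfliers=False)
        ax.set_title(idx, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
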