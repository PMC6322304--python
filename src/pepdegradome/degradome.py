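"""Protein degradation pattern (PDP) matrices.

A PDP summarises where along a precursor the observed peptides begin: the
protein is split into ``n`` equal relative-length windows (10 by default,
i.e. 10% of the precursor each) and peptide start positions are counted per
window. The coarse window deliberately absorbs peptide ladders — families of
near-identical peptides trimmed by a few residues — so patterns compare
digestion hotspots, not individual cleavage events.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FilteredPeptidome
from .io import ProteomeMap


def window_bounds(protein_length: int, n_windows: int) -> list[tuple[int, int]]:
    """1-based inclusive bounds of the relative-position windows.

    Window i covers residues floor((i-1)·L/n)+1 .. floor(i·L/n); bounds are
    floor-based so widths differ by at most one residue and the windows tile
    1..L exactly. Short proteins (L < n) yield some empty windows.
    """
    if protein_length < 1:
        raise ValueError("protein length must be >= 1")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    return [
        ((i - 1) * protein_length // n_windows + 1, i * protein_length // n_windows)
        for i in range(1, n_windows + 1)
    ]


def pdp_row(
    protein_length: int, start_positions, n_windows: int = 10
) -> np.ndarray:
    """Count peptide starts per relative-position window of one precursor."""
    bounds = window_bounds(protein_length, n_windows)
    highs = np.array([hi for _lo, hi in bounds])
    starts = np.asarray(list(start_positions), dtype=int)
    counts = np.zeros(n_windows, dtype=int)
    if starts.size == 0:
        return counts
    if starts.min() < 1 or starts.max() > protein_length:
        raise ValueError(
            f"start positions must lie in 1..{protein_length}"
        )
    # first window whose upper bound reaches the start; empty windows have
    # hi < lo and can never capture a start
    idx = np.searchsorted(highs, starts, side="left")
    np.add.at(counts, idx, 1)
    return counts


def pdp_matrix(
    filtered: FilteredPeptidome,
    proteome: ProteomeMap,
    compartment: str,
    condition: str,
    n_windows: int = 10,
) -> pd.DataFrame:
    """Precursor × window matrix of peptide start counts.

    One row per precursor with at least one mapped peptide; a peptide with
    several match sites contributes one count per site. Columns are labelled
    by the window's upper relative bound in percent ("10" … "100").
    """
    table = filtered.table(compartment, condition)
    starts_by_protein: dict[str, list[int]] = {}
    for _, row in table.iterrows():
        if row.get("unmapped", False):
            continue
        matches = row.get("matches") or []
        if not matches and not pd.isna(row.get("start")):
            matches = [(row["proteins"][0], int(row["start"]), int(row["end"]))]
        for pid, s, _e in matches:
            starts_by_protein.setdefault(pid, []).append(int(s))
    cols = [str(round(100 * i / n_windows)) for i in range(1, n_windows + 1)]
    rows = {}
    for pid in sorted(starts_by_protein):
        rows[pid] = pdp_row(len(proteome[pid]), starts_by_protein[pid], n_windows)
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=cols, dtype=int)
    mat.index.name = "protein_id"
    return mat


def pdp_similarity(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Cosine similarity of per-precursor degradation patterns.

    Rows are normalised to unit sum first so the comparison is of pattern
    shape, not peptide yield. Returns the per-protein similarities over the
    shared precursors and their median. The choice of cosine is this
    package's own — the comparison is reported as such.
    """
    shared = sorted(set(matrix_a.index) & set(matrix_b.index))
    if not shared:
        raise ValueError("no shared precursors between the two PDP matrices")
    sims = {}
    for pid in shared:
        a = matrix_a.loc[pid].to_numpy(dtype=float)
        b = matrix_b.loc[pid].to_numpy(dtype=float)
        if a.sum() == 0 or b.sum() == 0:
            continue
        a, b = a / a.sum(), b / b.sum()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        sims[pid] = float(a @ b / denom)
    series = pd.Series(sims, name="cosine_similarity")
    return series, float(series.median())


def order_by_total(matrix: pd.DataFrame) -> pd.DataFrame:
    """Cosmetic row ordering for heatmaps: total start count, descending."""
    return matrix.loc[matrix.sum(axis=1).sort_values(ascending=False).index]
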