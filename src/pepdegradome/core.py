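"""Peptide-to-precursor mapping, replicate filtering and set algebra.

This module turns a raw peptide identification table into the filtered
per-(compartment, condition) peptidomes that every downstream analysis
consumes, and implements the comparisons run on them: Venn partitions
between conditions, new-precursor accounting for treatment-unique peptides,
intensity fold changes and correlation, and the positional classifiers
(C-terminal peptides, small precursor proteins).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProteomeMap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


def find_matches(peptide: str, proteome: ProteomeMap) -> list[tuple[str, int, int]]:
    """All exact-substring occurrences of ``peptide``, as (id, start, end) 1-based."""
    hits: list[tuple[str, int, int]] = []
    for pid, seq in proteome.items():
        pos = seq.find(peptide)
        while pos != -1:
            hits.append((pid, pos + 1, pos + len(peptide)))
            pos = seq.find(peptide, pos + 1)
    return hits


def locate_peptides(
    df: pd.DataFrame,
    proteome: ProteomeMap,
    only_missing: bool = False,
) -> pd.DataFrame:
    """Assign precursor coordinates by exact substring search.

    Every match is recorded in a ``matches`` column; ``proteins``/``start``/
    ``end`` carry the first match. Peptides with more than one match site are
    flagged ``ambiguous``; peptides with none are flagged ``unmapped`` (kept,
    but excluded from coordinate-based analyses downstream).
    """
    df = df.copy()
    if "matches" not in df.columns:
        df["matches"] = [[] for _ in range(len(df))]
    cache: dict[str, list[tuple[str, int, int]]] = {}
    for i in range(len(df)):
        if only_missing and not pd.isna(df["start"].iat[i]) and df["proteins"].iat[i]:
            pid = df["proteins"].iat[i][0]
            df.at[df.index[i], "matches"] = [
                (pid, int(df["start"].iat[i]), int(df["end"].iat[i]))
            ]
            continue
        seq = df["sequence"].iat[i]
        if seq not in cache:
            cache[seq] = find_matches(seq, proteome)
        hits = cache[seq]
        idx = df.index[i]
        df.at[idx, "matches"] = hits
        if not hits:
            df.at[idx, "unmapped"] = True
            df.at[idx, "start"] = np.nan
            df.at[idx, "end"] = np.nan
            df.at[idx, "proteins"] = []
            continue
        df.at[idx, "unmapped"] = False
        df.at[idx, "ambiguous"] = len(hits) > 1
        df.at[idx, "proteins"] = sorted({h[0] for h in hits})
        df.at[idx, "start"] = hits[0][1]
        df.at[idx, "end"] = hits[0][2]
    df["start"] = df["start"].astype("Int64")
    df["end"] = df["end"].astype("Int64")
    return df


# ---------------------------------------------------------------------------
# replicate filter
# ---------------------------------------------------------------------------


@dataclass
class FilteredPeptidome:
    """Per (compartment, condition) peptide tables after the replicate filter.

    Each group's table has one row per distinct peptide sequence; duplicate
    identifications are merged (repeat evidence unioned, intensities averaged
    per repeat).
    """

    groups: dict[tuple[str, str], pd.DataFrame]
    min_repeats: int
    counts: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)

    def sequences(self, compartment: str, condition: str) -> set[str]:
        g = self.groups.get((compartment, condition))
        return set() if g is None else set(g["sequence"])

    def table(self, compartment: str, condition: str) -> pd.DataFrame:
        return self.groups.get(
            (compartment, condition),
            pd.DataFrame(columns=["sequence"]),
        )

    def precursors(self, compartment: str, condition: str) -> set[str]:
        g = self.groups.get((compartment, condition))
        if g is None or g.empty:
            return set()
        return set().union(*g["proteins"])


def intensity_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("intensity_")]


def _merge_duplicates(group: pd.DataFrame) -> pd.DataFrame:
    """One row per peptide sequence: union repeats, mean intensities."""
    if group["sequence"].is_unique:
        return group.reset_index(drop=True)
    icols = intensity_columns(group)
    first = group.drop_duplicates("sequence", keep="first").set_index("sequence")
    gb = group.groupby("sequence", sort=False)
    first["repeats"] = gb["repeats"].agg(lambda s: frozenset().union(*s))
    if icols:
        first[icols] = gb[icols].mean()
    return first.reset_index()


def replicate_filter(
    df: pd.DataFrame,
    min_repeats: int = 2,
    n_repeats_design: int | None = None,
) -> FilteredPeptidome:
    """Keep peptides identified in at least ``min_repeats`` biological repeats.

    The filter is applied within each (compartment, condition) group; a
    peptide "identified in a condition" is one passing the filter there.
    """
    if n_repeats_design is None:
        all_reps = set().union(*df["repeats"]) if len(df) else set()
        n_repeats_design = len(all_reps)
    if n_repeats_design and min_repeats > n_repeats_design:
        raise ValueError(
            f"min_repeats={min_repeats} exceeds the {n_repeats_design}-repeat design"
        )
    groups: dict[tuple[str, str], pd.DataFrame] = {}
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for key, sub in df.groupby(["compartment", "condition"], sort=True):
        merged = _merge_duplicates(sub)
        passed = merged.loc[merged["repeats"].map(len) >= min_repeats]
        groups[key] = passed.reset_index(drop=True)
        counts[key] = {"input_rows": len(sub), "distinct": len(merged),
                       "retained": len(passed)}
        logger.info("replicate filter %s: %s", key, counts[key])
    return FilteredPeptidome(groups, min_repeats, counts)


# ---------------------------------------------------------------------------
# set algebra
# ---------------------------------------------------------------------------


@dataclass
class VennSummary:
    unique_a: int
    shared: int
    unique_b: int
    unique_a_sequences: set[str]
    shared_sequences: set[str]
    unique_b_sequences: set[str]
    percent_shared: float | None = None
    percent_shared_sd: float | None = None

    @property
    def union_size(self) -> int:
        return self.unique_a + self.shared + self.unique_b


def venn_counts(set_a: set[str], set_b: set[str]) -> VennSummary:
    """Two-set Venn partition; unique_a + shared + unique_b == |A ∪ B|."""
    shared = set_a & set_b
    ua = set_a - set_b
    ub = set_b - set_a
    union = len(set_a | set_b)
    return VennSummary(
        len(ua), len(shared), len(ub), ua, shared, ub,
        percent_shared=(100.0 * len(shared) / union) if union else None,
    )


def percent_shared_by_repeat(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[float, float]:
    """Mean ± SD of the shared-peptide percentage recomputed per repeat.

    For each biological repeat r, the peptide sets are restricted to members
    identified in r and the shared fraction of the union recomputed; the
    dispersion across repeats is the reported SD.
    """
    reps = sorted(
        set().union(*table_a["repeats"]) | set().union(*table_b["repeats"])
    )
    fracs = []
    for r in reps:
        sa = set(table_a.loc[table_a["repeats"].map(lambda s: r in s), "sequence"])
        sb = set(table_b.loc[table_b["repeats"].map(lambda s: r in s), "sequence"])
        union = sa | sb
        if union:
            fracs.append(100.0 * len(sa & sb) / len(union))
    if not fracs:
        return math.nan, math.nan
    return float(np.mean(fracs)), float(np.std(fracs, ddof=1)) if len(fracs) > 1 else 0.0


def new_precursor_fraction(
    unique_sequences: set[str],
    unique_table: pd.DataFrame,
    reference_table: pd.DataFrame,
) -> tuple[int, float | None]:
    """Among treatment-unique peptides, how many come from precursors with no
    peptide at all in the reference (control) set.

    Returns (count, fraction of the unique set); fraction is None when the
    unique set is empty. A peptide matching several precursors counts as
    new-precursor only if none of them is seen in the reference set.
    """
    if not unique_sequences:
        return 0, None
    ref_precursors: set[str] = set()
    if len(reference_table):
        ref_precursors = set().union(*reference_table["proteins"])
    sub = unique_table.loc[unique_table["sequence"].isin(unique_sequences)]
    count = 0
    for prots in sub["proteins"]:
        if prots and not (set(prots) & ref_precursors):
            count += 1
    return count, count / len(unique_sequences)


# ---------------------------------------------------------------------------
# positional classifiers
# ---------------------------------------------------------------------------


def is_cterminal(start: int, protein_length: int, window_aa: int) -> bool:
    """C-terminal peptide: start within ``window_aa`` residues of the C-terminus.

    Equivalent to start >= L - window + 1; a protein shorter than the window
    makes every start qualify.
    """
    return start >= protein_length - window_aa + 1


def classify_cterminal(
    row: pd.Series, proteome: ProteomeMap, window_aa: int = 50
) -> bool:
    """True iff any of the record's match sites is C-terminal."""
    matches = row.get("matches") or []
    if not matches:
        if row.get("unmapped", False) or pd.isna(row.get("start")):
            raise ValueError(f"peptide {row['sequence']!r} is unmapped")
        matches = [(row["proteins"][0], int(row["start"]), int(row["end"]))]
    return any(
        is_cterminal(s, len(proteome[pid]), window_aa) for pid, s, _e in matches
    )


def cterminal_fraction(
    table: pd.DataFrame, proteome: ProteomeMap, window_aa: int = 50
) -> float:
    """Fraction of mapped peptides classified C-terminal."""
    mapped = table.loc[~table["unmapped"]]
    if mapped.empty:
        return math.nan
    flags = mapped.apply(classify_cterminal, axis=1, proteome=proteome,
                         window_aa=window_aa)
    return float(flags.mean())


def small_protein_flags(proteome: ProteomeMap, threshold_aa: int = 200) -> set[str]:
    """Ids of proteins strictly shorter than ``threshold_aa`` residues."""
    return {pid for pid, L in proteome.lengths.items() if L < threshold_aa}


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------


def fold_change_table(
    filtered: FilteredPeptidome,
    compartment: str,
    cond_from: str = "control",
    cond_to: str = "treated",
    min_quantified: int | None = None,
) -> pd.DataFrame:
    """Per-peptide log2 fold change between two conditions of one compartment.

    Status per peptide: ``ok`` (quantified in >= min repeats of both
    conditions), ``present_only_from`` / ``present_only_to`` (one-sided),
    ``not_quantified`` (no usable intensities). One-sided and unquantified
    peptides carry NaN log2fc and are excluded from correlations.
    """
    if min_quantified is None:
        min_quantified = filtered.min_repeats
    ta = filtered.table(compartment, cond_from)
    tb = filtered.table(compartment, cond_to)

    def side(t: pd.DataFrame) -> pd.DataFrame:
        icols = intensity_columns(t)
        if not len(t) or not icols:
            return pd.DataFrame(columns=["mean", "n"])
        vals = t[icols].astype(float)
        return pd.DataFrame(
            {
                "mean": vals.mean(axis=1).to_numpy(),
                "n": vals.notna().sum(axis=1).to_numpy(),
            },
            index=pd.Index(t["sequence"].to_numpy(), name="sequence"),
        )

    a, b = side(ta), side(tb)
    seqs = sorted(set(ta["sequence"]) | set(tb["sequence"]))
    out = pd.DataFrame(index=pd.Index(seqs, name="sequence"))
    out["mean_from"] = a["mean"].reindex(seqs)
    out["n_from"] = a["n"].reindex(seqs).fillna(0).astype(int)
    out["mean_to"] = b["mean"].reindex(seqs)
    out["n_to"] = b["n"].reindex(seqs).fillna(0).astype(int)

    ok = (
        (out["n_from"] >= min_quantified) & (out["n_to"] >= min_quantified)
        & (out["mean_from"] > 0) & (out["mean_to"] > 0)
    )
    out["log2fc"] = np.where(ok, np.log2(out["mean_to"] / out["mean_from"]), np.nan)
    status = np.select(
        [
            ok,
            (out["n_from"] == 0) & (out["n_to"] == 0),
            (out["n_to"] < min_quantified) & (out["n_from"] >= min_quantified),
            (out["n_from"] < min_quantified) & (out["n_to"] >= min_quantified),
        ],
        ["ok", "not_quantified", "present_only_from", "present_only_to"],
        default="not_quantified",
    )
    out["status"] = status
    return out.reset_index()


def log2_fold_change(mean_from: float, mean_to: float) -> float:
    """log2 of the intensity ratio to/from (means over observed repeats)."""
    if not (mean_from > 0 and mean_to > 0):
        raise ValueError("fold change requires positive mean intensities")
    return math.log2(mean_to / mean_from)


def intensity_correlation(
    fc: pd.DataFrame, log_transform: bool = True
) -> tuple[float, float, int]:
    """Pearson correlation of per-peptide intensities between two conditions.

    Uses peptides quantified in both conditions (status ``ok``); intensities
    are log10 means unless ``log_transform`` is False. Returns (r, p, n);
    fewer than 3 common peptides is an error.
    """
    sub = fc.loc[fc["status"] == "ok"]
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >=3 peptides quantified in both conditions, got {n}")
    x, y = sub["mean_from"].to_numpy(), sub["mean_to"].to_numpy()
    if log_transform:
        x, y = np.log10(x), np.log10(y)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n
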