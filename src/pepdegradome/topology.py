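"""Peptide localisation relative to predicted membrane topology.

Each mapped peptide is assigned the topology class (inside / outside /
TMhelix) covering the strict majority of its residues on the precursor;
exact ties are "mixed" and precursors without topology records give
"unannotated". Compartment × location over-representation is then tested
with two-sided Fisher exact tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import TOPOLOGY_LABELS, TopologyMap

logger = logging.getLogger(__name__)

LOCATION_LABELS = TOPOLOGY_LABELS + ("mixed", "unannotated")


@dataclass
class PeptideLocation:
    sequence: str
    location: str
    overlap: dict[str, int]  # residues per topology label (+ "none" for gaps)


def classify_location(
    protein_id: str, start: int, end: int, topology: TopologyMap, sequence: str = ""
) -> PeptideLocation:
    """Majority-overlap topology class of one peptide span."""
    length = end - start + 1
    segs = topology.get(protein_id)
    if not segs:
        return PeptideLocation(sequence, "unannotated", {})
    overlap = dict.fromkeys(TOPOLOGY_LABELS, 0)
    for seg in segs:
        ov = min(end, seg.end) - max(start, seg.start) + 1
        if ov > 0:
            overlap[seg.label] += ov
    covered = sum(overlap.values())
    if covered == 0:
        return PeptideLocation(sequence, "unannotated", overlap)
    overlap["none"] = length - covered
    best = max(TOPOLOGY_LABELS, key=lambda lab: overlap[lab])
    # strict majority of the peptide's residues, gaps included
    location = best if 2 * overlap[best] > length else "mixed"
    return PeptideLocation(sequence, location, overlap)


def locate_table(table: pd.DataFrame, topology: TopologyMap) -> pd.DataFrame:
    """Per-peptide location labels for a mapped peptide table.

    Uses each peptide's primary match site (ambiguous peptides are labelled
    by their first site, consistent with once-per-peptide set algebra).
    """
    rows = []
    for _, row in table.iterrows():
        if row.get("unmapped", False) or pd.isna(row.get("start")):
            rows.append({"sequence": row["sequence"], "location": "unannotated"})
            continue
        pid = row["proteins"][0]
        loc = classify_location(
            pid, int(row["start"]), int(row["end"]), topology, row["sequence"]
        )
        rows.append({"sequence": row["sequence"], "location": loc.location,
                     "protein_id": pid})
    return pd.DataFrame(rows)


def location_enrichment(
    cell_locations: pd.DataFrame, secretome_locations: pd.DataFrame
) -> pd.DataFrame:
    """Compartment × location Fisher tests for the inside and outside classes.

    For each label, a 2×2 table (compartment × is-label) over peptides with a
    definite single-class location; mixed and unannotated peptides are
    excluded from the margins (their counts are reported alongside). A zero
    margin yields p = 1 with a warning. Odds ratios are oriented so values
    > 1 mean over-representation in the cell peptidome.
    """
    def counts(locs: pd.DataFrame) -> pd.Series:
        return locs["location"].value_counts()

    cc, sc = counts(cell_locations), counts(secretome_locations)
    definite = list(TOPOLOGY_LABELS)
    n_cell = int(sum(cc.get(lab, 0) for lab in definite))
    n_sec = int(sum(sc.get(lab, 0) for lab in definite))
    rows = []
    for lab in ("inside", "outside"):
        a = int(cc.get(lab, 0))
        b = n_cell - a
        c = int(sc.get(lab, 0))
        d = n_sec - c
        if min(a + c, b + d, a + b, c + d) == 0:
            logger.warning("location_enrichment: zero margin for %s", lab)
            odds, p = float("nan"), 1.0
        else:
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({
            "location": lab,
            "cell_in": a, "cell_out": b,
            "secretome_in": c, "secretome_out": d,
            "odds_ratio_cell": odds, "p": p,
            "overrepresented_in": (
                "cell" if (a / n_cell if n_cell else 0) > (c / n_sec if n_sec else 0)
                else "secretome"
            ),
            "n_excluded_cell": int(cc.sum()) - n_cell,
            "n_excluded_secretome": int(sc.sum()) - n_sec,
        })
    return pd.DataFrame(rows).set_index("location")
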