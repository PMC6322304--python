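"""Readers and writers for the external formats the pipeline consumes.

Formats handled here:

* proteome FASTA (via Bio.SeqIO);
* tab-separated peptide identification tables (MaxQuant ``peptides.txt``-like);
* the ``aaindex1`` flat file of per-residue amino-acid property scales;
* TMHMM-2.0-style long-format membrane topology records;
* the YAML run configuration.

Everything downstream of this module operates on the validated in-memory
objects returned here, never on raw files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the 20 standard residues, alphabetical (used for frequency vectors)
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: aaindex1 I-line residue order: row one then row two
AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"
#: residues tolerated in input sequences beyond the standard 20
AA_EXTRA = "XU"

_AA20_SET = frozenset(AA20)
_VALID_SET = frozenset(AA20 + AA_EXTRA)


def is_standard(sequence: str) -> bool:
    """True iff the sequence uses only the 20 standard residues."""
    return bool(sequence) and set(sequence) <= _AA20_SET


# ---------------------------------------------------------------------------
# proteome FASTA
# ---------------------------------------------------------------------------


@dataclass
class ProteomeMap:
    """Protein id -> amino-acid sequence, uppercase.

    Ids are taken verbatim from the FASTA header up to the first whitespace.
    """

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for pid, seq in self.entries.items():
            if not seq:
                raise ValueError(f"empty sequence for protein {pid!r}")
            bad = set(seq) - _VALID_SET
            if bad:
                raise ValueError(
                    f"protein {pid!r} contains invalid residues {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {pid: len(seq) for pid, seq in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pid: str) -> bool:
        return pid in self.entries

    def __getitem__(self, pid: str) -> str:
        return self.entries[pid]

    def items(self):
        return self.entries.items()


def read_fasta(path: str | Path) -> ProteomeMap:
    """Read a proteome FASTA; duplicate ids or empty sequences are errors."""
    entries: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in entries:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for protein {pid!r} in {path}")
        entries[pid] = seq
    return ProteomeMap(entries)


def write_fasta(proteome: ProteomeMap, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in proteome.entries.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# peptide tables
# ---------------------------------------------------------------------------

#: columns every peptide table carries after validation
PEPTIDE_COLUMNS = [
    "sequence",
    "proteins",
    "start",
    "end",
    "condition",
    "compartment",
    "repeats",
    "unmapped",
    "ambiguous",
    "nonstandard",
]

CONDITIONS = ("control", "treated")
COMPARTMENTS = ("cell", "secretome")


def _parse_repeats(value) -> frozenset[int]:
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (set, list, tuple)):
        return frozenset(int(v) for v in value)
    s = str(value).strip()
    if not s:
        return frozenset()
    return frozenset(int(tok) for tok in s.replace(",", ";").split(";") if tok)


def read_peptide_table(
    path: str | Path,
    proteome: ProteomeMap | None = None,
) -> pd.DataFrame:
    """Read a TSV peptide identification table.

    Required columns: ``sequence``, ``condition``, ``compartment``,
    ``repeats`` (``;``-separated biological-repeat indices). Optional:
    ``proteins`` (``;``-separated ids), ``start``, ``end`` and any number of
    ``intensity_*`` columns. Rows whose coordinates fall outside their
    precursor are rejected (logged); rows naming unknown proteins are kept
    but flagged ``unmapped``. Rows lacking coordinates are mapped by exact
    substring search when a proteome is supplied.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    required = {"sequence", "condition", "compartment", "repeats"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"peptide table {path} missing columns {sorted(missing)}")

    df = raw.copy()
    df["sequence"] = df["sequence"].str.upper()
    bad_cond = set(df["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown condition labels {sorted(bad_cond)}")
    bad_comp = set(df["compartment"].unique()) - set(COMPARTMENTS)
    if bad_comp:
        raise ValueError(f"unknown compartment labels {sorted(bad_comp)}")

    df["repeats"] = df["repeats"].map(_parse_repeats)
    if (df["repeats"].map(len) == 0).any():
        raise ValueError("rows with empty repeat evidence")
    if "proteins" in df.columns:
        df["proteins"] = (
            df["proteins"].fillna("").map(lambda s: [t for t in str(s).split(";") if t])
        )
    else:
        df["proteins"] = [[] for _ in range(len(df))]
    for col in ("start", "end"):
        if col not in df.columns:
            df[col] = np.nan

    df["nonstandard"] = ~df["sequence"].map(is_standard)
    df["unmapped"] = df["proteins"].map(len) == 0
    df["ambiguous"] = False

    if proteome is not None:
        keep = np.ones(len(df), dtype=bool)
        for i, row in enumerate(df.itertuples(index=False)):
            pids = row.proteins
            known = [p for p in pids if p in proteome]
            if pids and not known:
                df.iat[i, df.columns.get_loc("unmapped")] = True
                logger.warning("row %d: unknown protein id(s) %s", i, pids)
                continue
            if known and not np.isnan(row.start):
                pid = known[0]
                s, e = int(row.start), int(row.end)
                L = len(proteome[pid])
                if not (1 <= s <= e <= L) or e - s + 1 != len(row.sequence):
                    logger.warning(
                        "row %d rejected: coordinates %d-%d invalid on %s (len %d)",
                        i, s, e, pid, L,
                    )
                    keep[i] = False
        df = df.loc[keep].reset_index(drop=True)
        if df["start"].isna().any():
            from .core import locate_peptides  # deferred: avoids import cycle

            df = locate_peptides(df, proteome, only_missing=True)

    df["start"] = df["start"].astype("Int64")
    df["end"] = df["end"].astype("Int64")
    return df


def write_peptide_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a peptide table as TSV (round-trips through read_peptide_table)."""
    out = df.copy()
    out["repeats"] = out["repeats"].map(
        lambda s: ";".join(str(i) for i in sorted(s))
    )
    out["proteins"] = out["proteins"].map(lambda p: ";".join(p))
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# aaindex1
# ---------------------------------------------------------------------------


class AAindexTable:
    """Per-residue property scales parsed from an aaindex1 flat file.

    ``values`` is a DataFrame indexed by index id with one column per
    standard residue (alphabetical order); missing ("NA") entries are NaN.
    """

    def __init__(self, values: pd.DataFrame, descriptions: dict[str, str]):
        self.values = values[list(AA20)]
        self.descriptions = descriptions

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def complete(self) -> pd.Series:
        """True per index iff all 20 standard residues have values."""
        return ~self.values.isna().any(axis=1)

    def complete_table(self) -> pd.DataFrame:
        return self.values.loc[self.complete]

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, index_id: str) -> bool:
        return index_id in self.values.index

    def __getitem__(self, index_id: str) -> pd.Series:
        return self.values.loc[index_id]

    def subset(self, ids: Iterable[str]) -> "AAindexTable":
        ids = [i for i in ids]
        return AAindexTable(
            self.values.loc[ids].copy(),
            {i: self.descriptions.get(i, "") for i in ids},
        )


def _parse_i_block(index_id: str, lines: list[str]) -> dict[str, float]:
    fields: list[str] = []
    for ln in lines:
        fields.extend(ln.split())
    if len(fields) != 20:
        raise ValueError(
            f"aaindex entry {index_id}: I-block has {len(fields)} fields, expected 20"
        )
    out: dict[str, float] = {}
    for residue, tok in zip(AAINDEX_ORDER, fields):
        if tok.upper() == "NA":
            out[residue] = np.nan
        else:
            try:
                out[residue] = float(tok)
            except ValueError as exc:
                raise ValueError(
                    f"aaindex entry {index_id}: bad I-block field {tok!r}"
                ) from exc
    return out


def read_aaindex1(path: str | Path) -> AAindexTable:
    """Parse an aaindex1 flat file (H/D/I blocks; entries end with ``//``)."""
    rows: dict[str, dict[str, float]] = {}
    descriptions: dict[str, str] = {}
    index_id: str | None = None
    description = ""
    i_lines: list[str] = []
    in_i = False

    def flush() -> None:
        nonlocal index_id, description, i_lines, in_i
        if index_id is not None:
            if not i_lines:
                raise ValueError(f"aaindex entry {index_id}: missing I-block")
            rows[index_id] = _parse_i_block(index_id, i_lines)
            descriptions[index_id] = description.strip()
        index_id, description, i_lines, in_i = None, "", [], False

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("//"):
                flush()
            elif line.startswith("H "):
                index_id = line[2:].strip()
                in_i = False
            elif line.startswith("D "):
                description = line[2:].strip()
                in_i = False
            elif line.startswith("I "):
                in_i = True
            elif line.startswith(" ") and in_i:
                i_lines.append(line)
            else:
                in_i = False
    flush()
    if not rows:
        raise ValueError(f"no aaindex entries parsed from {path}")
    values = pd.DataFrame.from_dict(rows, orient="index")
    return AAindexTable(values, descriptions)


def write_aaindex1(table: AAindexTable, path: str | Path) -> None:
    """Minimal aaindex1 writer (H/D/I blocks); round-trips read_aaindex1."""
    with open(path, "w") as fh:
        for idx in table.ids:
            vals = table.values.loc[idx]
            fh.write(f"H {idx}\n")
            fh.write(f"D {table.descriptions.get(idx, '')}\n")
            fh.write("I    A/L     R/K     N/M     D/F     C/P     "
                     "Q/S     E/T     G/W     H/Y     I/V\n")
            for half in (AAINDEX_ORDER[:10], AAINDEX_ORDER[10:]):
                toks = []
                for r in half:
                    v = vals[r]
                    toks.append("NA" if pd.isna(v) else repr(float(v)))
                fh.write("    " + "   ".join(toks) + "\n")
            fh.write("//\n")


def bundled_aaindex_path() -> Path:
    """Path of the miniature aaindex1 file shipped with the package.

    It holds the published KLEP840101 (net charge) and KYTJ820101
    (Kyte-Doolittle hydropathy) scales plus synthetic entries; full-scale
    screens expect a user-supplied aaindex1 file.
    """
    return Path(__file__).parent / "data" / "aaindex1_mini_synthetic.txt"


# ---------------------------------------------------------------------------
# membrane topology
# ---------------------------------------------------------------------------

TOPOLOGY_LABELS = ("inside", "outside", "TMhelix")


class TopoSegment(NamedTuple):
    label: str
    start: int
    end: int


TopologyMap = dict[str, list[TopoSegment]]


def read_topology(path: str | Path) -> TopologyMap:
    """Read TMHMM-2.0-style long-format records.

    Each non-comment line: ``<protein_id> <method> <label> <start> <end>``
    with label one of inside/outside/TMhelix. Segments per protein are
    sorted; overlaps are an error. An empty file yields an empty map.
    """
    segments: dict[str, list[TopoSegment]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(toks)}")
            pid, _method, label, start, end = toks[:5]
            if label not in TOPOLOGY_LABELS:
                raise ValueError(f"{path}:{lineno}: unknown topology label {label!r}")
            s, e = int(start), int(end)
            if not (1 <= s <= e):
                raise ValueError(f"{path}:{lineno}: bad span {s}-{e}")
            segments.setdefault(pid, []).append(TopoSegment(label, s, e))
    for pid, segs in segments.items():
        segs.sort(key=lambda t: (t.start, t.end))
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping topology segments for {pid}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
    return segments


def write_topology(topology: TopologyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, segs in topology.items():
            for seg in segs:
                fh.write(f"{pid}\tTMHMM2.0\t{seg.label}\t{seg.start}\t{seg.end}\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Fixed analysis constants.

    Defaults are the study conditions the pipeline reproduces: the
    two-repeat identification filter, the 50-residue C-terminal window, ten
    relative-length degradation windows, five-residue terminal profiles, the
    1e-5 / 1e-15 / 1e-25 significance tiers, six property clusters, the
    200-residue small-protein cutoff, predictor thresholds 0.5/0.5/0 and the
    log2FC>1 up-regulation rule.
    """

    min_repeats: int = 2
    cterm_window_aa: int = 50
    n_pdp_windows: int = 10
    terminal_k: int = 5
    p_tiers: tuple[float, float, float] = (1e-5, 1e-15, 1e-25)
    n_clusters: int = 6
    small_protein_aa: int = 200
    amp_thresholds: dict[str, float] = field(
        default_factory=lambda: {"camp": 0.5, "iamppred": 0.5, "adam": 0.0}
    )
    upregulated_log2fc: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_repeats < 1:
            raise ValueError("min_repeats must be >= 1")
        for name in ("cterm_window_aa", "n_pdp_windows", "terminal_k",
                     "n_clusters", "small_protein_aa"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        tiers = tuple(self.p_tiers)
        if list(tiers) != sorted(tiers, reverse=True) or len(set(tiers)) != len(tiers):
            raise ValueError("p_tiers must be strictly decreasing")
        if any(t <= 0 for t in tiers):
            raise ValueError("p_tiers must be positive")
        self.p_tiers = tiers

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["p_tiers"] = list(self.p_tiers)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
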