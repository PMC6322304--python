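"""In-silico proteolysis simulator with ground truth.

Generates a random proteome (optionally with membrane-topology
architectures) and endogenous peptide tables carrying the statistical
structure the analyses assume: peptide ladders, C-terminal start bias,
compartment-specific hydrophobicity and topology sampling biases, a
treatment condition with an increased proteolysis rate and new precursor
proteins, per-repeat Bernoulli detection and log-normal XIC intensities.
Every emitted peptide row is paired with a ground-truth record, so each
pipeline stage can be tested closed-loop without real MS data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (
    AA20,
    AAindexTable,
    ProteomeMap,
    TopologyMap,
    TopoSegment,
    bundled_aaindex_path,
    read_aaindex1,
)
from .topology import classify_location

#: background residue frequencies, roughly a plant proteome composition
DEFAULT_RESIDUE_FREQS = {
    "A": 0.077, "C": 0.016, "D": 0.053, "E": 0.065, "F": 0.040,
    "G": 0.068, "H": 0.023, "I": 0.053, "K": 0.060, "L": 0.093,
    "M": 0.024, "N": 0.044, "P": 0.048, "Q": 0.036, "R": 0.052,
    "S": 0.083, "T": 0.052, "V": 0.067, "W": 0.012, "Y": 0.034,
}

COMPARTMENTS = ("cell", "secretome")


@dataclass
class SimulationConfig:
    """Parameters of one simulated two-compartment, two-condition study.

    Defaults emulate the study design the pipeline targets: 1,000 precursor
    proteins, 2,000 peptides per compartment of mean length 15, three
    biological repeats, a treated condition adding ~5.5% (cell) / ~2.3%
    (secretome) extra peptides of which 27% come from new precursors, a
    hydrophobicity sampling bias in the secretome and an inside-region bias
    in the cell peptidome.
    """

    # proteome
    n_proteins: int = 1000
    length_logmu: float = 5.4
    length_logsigma: float = 0.45
    min_length: int = 60
    residue_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_FREQS)
    )
    tm_fraction: float = 0.3
    helix_length: int = 21
    loop_mean: int = 40

    # peptide sampling
    peptides_per_compartment: int = 2000
    length_mean: float = 15.0
    length_sd: float = 4.0
    min_pep_length: int = 7
    max_pep_length: int = 40
    cterm_bias: float = 2.0
    cterm_window: int = 50
    hydro_delta: dict[str, float] = field(
        default_factory=lambda: {"cell": 0.0, "secretome": 0.5}
    )
    topo_beta: dict[str, float] = field(
        default_factory=lambda: {"cell": 3.0, "secretome": 1.0}
    )
    hydropathy_index_id: str = "KYTJ820101"

    # treatment
    treatment_extra_fraction: dict[str, float] = field(
        default_factory=lambda: {"cell": 0.055, "secretome": 0.023}
    )
    new_precursor_fraction: float = 0.27
    new_precursor_pool: float = 0.05
    effect_fraction: float = 0.2
    effect_log2fc_mean: float = 1.0
    effect_log2fc_sd: float = 0.25

    # ladders
    ladder_p: float = 0.3
    ladder_trim_max: int = 3
    ladder_intensity_penalty: float = 0.75

    # replicates / intensities
    n_repeats: int = 3
    detection_p: float = 0.9
    intensity_logmu: float = 13.8
    intensity_logsigma: float = 1.0
    repeat_sigma: float = 0.25

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for p in (self.detection_p, self.tm_fraction, self.ladder_p,
                  self.new_precursor_fraction, self.new_precursor_pool,
                  self.effect_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.length_logsigma <= 0 or self.length_sd <= 0:
            raise ValueError("distribution scales must be positive")
        if self.min_pep_length < 1 or self.max_pep_length < self.min_pep_length:
            raise ValueError("invalid peptide length bounds")
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory")
        total = sum(self.residue_freqs.get(r, 0.0) for r in AA20)
        if not math.isclose(total, 1.0, abs_tol=0.05):
            raise ValueError("residue_freqs must roughly sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# proteome generation
# ---------------------------------------------------------------------------


def generate_proteome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ProteomeMap, TopologyMap]:
    """Random proteome plus synthetic membrane-topology architectures.

    A ``tm_fraction`` of proteins receive an alternating
    inside/TMhelix/outside segment layout covering their full length; the
    rest carry no topology record. Deterministic given config.rng_seed.
    """
    if config.n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    residues = np.array(list(AA20))
    probs = np.array([config.residue_freqs.get(r, 0.0) for r in AA20])
    probs = probs / probs.sum()
    lengths = np.maximum(
        config.min_length,
        np.round(rng.lognormal(config.length_logmu, config.length_logsigma,
                               config.n_proteins)).astype(int),
    )
    width = len(str(config.n_proteins))
    entries: dict[str, str] = {}
    topology: TopologyMap = {}
    has_tm = rng.random(config.n_proteins) < config.tm_fraction
    for i, L in enumerate(lengths):
        pid = f"SYNP{i + 1:0{width}d}"
        entries[pid] = "".join(rng.choice(residues, size=L, p=probs))
        if has_tm[i]:
            topology[pid] = _membrane_architecture(int(L), config, rng)
    return ProteomeMap(entries), topology


def _membrane_architecture(
    L: int, config: SimulationConfig, rng: np.random.Generator
) -> list[TopoSegment]:
    """Alternating loop/helix segments tiling residues 1..L."""
    side = "inside" if rng.random() < 0.5 else "outside"
    segs: list[TopoSegment] = []
    pos = 1
    while pos <= L:
        loop_len = max(5, int(rng.poisson(config.loop_mean)))
        end = min(L, pos + loop_len - 1)
        segs.append(TopoSegment(side, pos, end))
        pos = end + 1
        if pos > L:
            break
        end = min(L, pos + config.helix_length - 1)
        segs.append(TopoSegment("TMhelix", pos, end))
        pos = end + 1
        side = "outside" if side == "inside" else "inside"
    return segs


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------


class _PositionIndex:
    """Flattened per-residue arrays over the proteome for weighted sampling."""

    def __init__(self, proteome: ProteomeMap, topology: TopologyMap,
                 hydropathy: pd.Series, window: int):
        self.pids = sorted(proteome.entries)
        seqs = [proteome[p] for p in self.pids]
        self.lengths = np.array([len(s) for s in seqs])
        self.offsets = np.concatenate(([0], np.cumsum(self.lengths)))
        self.protein_of = np.repeat(np.arange(len(self.pids)), self.lengths)
        self.pos1 = np.concatenate([np.arange(1, L + 1) for L in self.lengths])
        self.len_of_pos = self.lengths[self.protein_of]
        scale = hydropathy.to_dict()
        hyd = np.concatenate([
            np.array([scale.get(ch, 0.0) for ch in s]) for s in seqs
        ])
        # forward-looking mean hydropathy over the next `window` residues,
        # clipped at each protein's C-terminus
        fwd = np.empty_like(hyd)
        for i, s in enumerate(seqs):
            a, b = self.offsets[i], self.offsets[i + 1]
            c = np.concatenate(([0.0], np.cumsum(hyd[a:b])))
            L = b - a
            hi = np.minimum(np.arange(L) + window, L)
            fwd[a:b] = (c[hi] - c[np.arange(L)]) / (hi - np.arange(L))
        self.fwd_hydro = fwd
        inside = np.zeros(self.offsets[-1], dtype=bool)
        for i, pid in enumerate(self.pids):
            for seg in topology.get(pid, []):
                if seg.label == "inside":
                    a = self.offsets[i]
                    inside[a + seg.start - 1:a + seg.end] = True
        self.inside = inside

    def sequence_at(self, proteome: ProteomeMap, flat: int, plen: int):
        i = int(self.protein_of[flat])
        pid = self.pids[i]
        L = int(self.lengths[i])
        start = int(self.pos1[flat])
        end = min(L, start + plen - 1)
        if end - start + 1 < plen:
            start = max(1, end - plen + 1)
        return pid, start, end, proteome[pid][start - 1:end]


def _start_weights(
    index: _PositionIndex, config: SimulationConfig, compartment: str,
    allowed_protein_mask: np.ndarray,
) -> np.ndarray:
    feasible = index.pos1 <= index.len_of_pos - config.min_pep_length + 1
    w = feasible.astype(float)
    cterm = index.pos1 >= index.len_of_pos - config.cterm_window + 1
    w *= np.where(cterm, config.cterm_bias, 1.0)
    delta = config.hydro_delta.get(compartment, 0.0)
    if delta:
        h = index.fwd_hydro
        hz = (h - h.mean()) / (h.std() or 1.0)
        w *= np.exp(delta * hz)
    beta = config.topo_beta.get(compartment, 1.0)
    if beta != 1.0 and index.inside.any():
        w *= np.where(index.inside, beta, 1.0)
    w *= allowed_protein_mask[index.protein_of]
    total = w.sum()
    if total <= 0:
        raise ValueError("no feasible start positions under the given biases")
    return w / total


def simulate_digestion(
    proteome: ProteomeMap,
    topology: TopologyMap,
    config: SimulationConfig,
    aaindex: AAindexTable | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the endogenous peptide tables of a two-condition study.

    Returns (peptide_table, truth). The peptide table has one row per
    (peptide event, condition) that was detected in at least one repeat,
    in the same layout ``io.read_peptide_table`` produces. The truth table
    has one row per emitted peptide row, keyed by ``event_id`` and
    ``condition``, recording provenance, the injected log2 fold change,
    ladder group and true topology location.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if aaindex is None:
        aaindex = read_aaindex1(bundled_aaindex_path())
    hydropathy = aaindex[config.hydropathy_index_id]
    index = _PositionIndex(proteome, topology, hydropathy,
                           window=int(round(config.length_mean)))

    n_prot = len(index.pids)
    n_new_pool = int(round(config.new_precursor_pool * n_prot))
    new_pool = np.zeros(n_prot, dtype=bool)
    if n_new_pool:
        new_pool[rng.choice(n_prot, size=n_new_pool, replace=False)] = True
    regular_mask = (~new_pool).astype(float)
    newpool_mask = new_pool.astype(float)

    events: list[dict] = []

    def draw_events(compartment: str, n: int, provenance: str,
                    protein_mask: np.ndarray) -> None:
        if n <= 0:
            return
        weights = _start_weights(index, config, compartment, protein_mask)
        flats = rng.choice(index.offsets[-1], size=n, p=weights)
        plens = np.clip(
            np.round(rng.normal(config.length_mean, config.length_sd, n)),
            config.min_pep_length, config.max_pep_length,
        ).astype(int)
        for flat, plen in zip(flats, plens):
            pid, start, end, seq = index.sequence_at(proteome, int(flat), int(plen))
            events.append({
                "event_id": len(events), "compartment": compartment,
                "protein": pid, "start": start, "end": end, "sequence": seq,
                "provenance": provenance, "ladder_group": len(events),
            })

    for compartment in COMPARTMENTS:
        n_shared = config.peptides_per_compartment
        draw_events(compartment, n_shared, "shared", regular_mask)
        n_extra = int(round(
            config.treatment_extra_fraction.get(compartment, 0.0) * n_shared
        ))
        n_newprec = int(round(config.new_precursor_fraction * n_extra))
        if n_newprec and not new_pool.any():
            n_newprec = 0
        draw_events(compartment, n_extra - n_newprec, "treated_extra",
                    regular_mask)
        draw_events(compartment, n_newprec, "treated_newprec", newpool_mask)

    # ladders: trimmed children inheriting the parent's condition membership
    parents = list(events)
    for ev in parents:
        if rng.random() >= config.ladder_p:
            continue
        trim = int(rng.integers(1, config.ladder_trim_max + 1))
        if ev["end"] - ev["start"] + 1 - trim < config.min_pep_length:
            continue
        from_n = rng.random() < 0.5
        s = ev["start"] + trim if from_n else ev["start"]
        e = ev["end"] if from_n else ev["end"] - trim
        child = dict(ev)
        child.update({
            "event_id": len(events), "start": s, "end": e,
            "sequence": proteome[ev["protein"]][s - 1:e],
            "ladder_group": ev["ladder_group"], "_parent_trim": trim,
        })
        events.append(child)

    # intensities, effects, per-repeat detection
    icols = [f"intensity_{r}" for r in range(1, config.n_repeats + 1)]
    pep_rows: list[dict] = []
    truth_rows: list[dict] = []
    for ev in events:
        base = rng.lognormal(config.intensity_logmu, config.intensity_logsigma)
        base *= config.ladder_intensity_penalty ** ev.get("_parent_trim", 0)
        if ev["provenance"] == "shared":
            fc = (rng.normal(config.effect_log2fc_mean, config.effect_log2fc_sd)
                  if rng.random() < config.effect_fraction else 0.0)
            conditions = ("control", "treated")
        else:
            fc = math.nan
            conditions = ("treated",)
        loc = classify_location(ev["protein"], ev["start"], ev["end"], topology)
        for condition in conditions:
            mean = base * (2.0 ** fc if condition == "treated" and fc == fc else 1.0)
            detected = rng.random(config.n_repeats) < config.detection_p
            if not detected.any():
                continue
            noise = rng.normal(0.0, config.repeat_sigma, config.n_repeats)
            row = {
                "sequence": ev["sequence"],
                "proteins": [ev["protein"]],
                "start": ev["start"], "end": ev["end"],
                "condition": condition, "compartment": ev["compartment"],
                "repeats": frozenset(
                    int(r + 1) for r in np.flatnonzero(detected)
                ),
                "unmapped": False, "ambiguous": False,
                "nonstandard": False,
                "matches": [(ev["protein"], ev["start"], ev["end"])],
            }
            for r in range(config.n_repeats):
                row[icols[r]] = mean * math.exp(noise[r]) if detected[r] else np.nan
            pep_rows.append(row)
            truth_rows.append({
                "event_id": ev["event_id"], "condition": condition,
                "compartment": ev["compartment"], "sequence": ev["sequence"],
                "protein": ev["protein"], "start": ev["start"], "end": ev["end"],
                "provenance": ev["provenance"], "true_log2fc": fc,
                "ladder_group": ev["ladder_group"],
                "true_location": loc.location,
            })

    peptides = pd.DataFrame(pep_rows)
    peptides["start"] = peptides["start"].astype("Int64")
    peptides["end"] = peptides["end"].astype("Int64")
    truth = pd.DataFrame(truth_rows)
    return peptides, truth


# ---------------------------------------------------------------------------
# synthetic AAindex families and predictor scores
# ---------------------------------------------------------------------------


def synthetic_aaindex(
    rng: np.random.Generator,
    n_families: int = 3,
    per_family: int = 20,
    noise_sd: float = 0.15,
    include_hydrophobicity_refs: bool = True,
    base_table: AAindexTable | None = None,
) -> tuple[AAindexTable, pd.Series]:
    """AAindex-like scale collection with known family structure.

    Family 0 is hydrophobicity: noisy rescalings of the Kyte–Doolittle
    hydropathy scale (and, when requested, entries named after the published
    reference hydrophobicity scales so cluster labelling works on synthetic
    screens). Remaining families are built from independent latent residue
    factors. Returns the table and the true family label per index id.
    """
    if base_table is None:
        base_table = read_aaindex1(bundled_aaindex_path())
    kd = base_table["KYTJ820101"].to_numpy(dtype=float)
    kd = (kd - kd.mean()) / kd.std()
    factors = [kd] + [rng.normal(0, 1, 20) for _ in range(n_families - 1)]
    rows: dict[str, np.ndarray] = {}
    labels: dict[str, int] = {}
    from .physchem import HYDROPHOBICITY_REFERENCE_IDS

    if include_hydrophobicity_refs:
        for ref in HYDROPHOBICITY_REFERENCE_IDS:
            rows[ref] = kd * rng.uniform(0.7, 1.3) + rng.normal(0, noise_sd, 20)
            labels[ref] = 0
    for fam, factor in enumerate(factors):
        for j in range(per_family):
            name = f"SYNF{fam}{j:03d}"
            rows[name] = (factor * rng.uniform(0.5, 1.5)
                          + rng.normal(0, noise_sd, 20))
            labels[name] = fam
    values = pd.DataFrame.from_dict(rows, orient="index")
    values.columns = list(AA20)
    table = AAindexTable(
        values, {k: f"synthetic family {v}" for k, v in labels.items()}
    )
    return table, pd.Series(labels, name="family")


def simulate_amp_scores(
    sequences,
    rng: np.random.Generator,
    aaindex: AAindexTable | None = None,
    steepness: float = 2.5,
    offset: float = 1.2,
    noise_sd: float = 0.4,
) -> pd.DataFrame:
    """Synthetic CAMP/iAMPpred/ADAM score tables for a peptide set.

    The latent antimicrobial propensity combines net charge and hydropathy
    (the two axes real AMP predictors weight most), z-scored over the set;
    the three predictor scores are independently noisy readouts of it, so
    the consensus rate lands at a few percent under default biases.
    """
    if aaindex is None:
        aaindex = read_aaindex1(bundled_aaindex_path())
    from .physchem import property_matrix

    seqs = sorted(set(sequences))
    sub = aaindex.subset(["KLEP840101", "KYTJ820101"])
    props = property_matrix(seqs, sub)
    z = (props - props.mean()) / props.std()
    latent = (1.2 * z["KLEP840101"] + 1.0 * z["KYTJ820101"]).to_numpy()
    latent = (latent - latent.mean()) / latent.std()

    def sigmoid(v):
        return 1.0 / (1.0 + np.exp(-v))

    n = len(seqs)
    camp = sigmoid(steepness * (latent - offset) + rng.normal(0, noise_sd, n))
    iamp = sigmoid(steepness * (latent - offset) + rng.normal(0, noise_sd, n))
    adam = latent - offset + rng.normal(0, noise_sd, n)
    out = pd.DataFrame(
        {"camp": camp, "iamppred": iamp, "adam": adam},
        index=pd.Index(props.index, name="peptide"),
    )
    return out


# ---------------------------------------------------------------------------
# truth recovery
# ---------------------------------------------------------------------------


def truth_recovery_report(
    truth: pd.DataFrame,
    fold_changes: pd.DataFrame | None = None,
    venn=None,
    compartment: str = "cell",
) -> dict:
    """Compare pipeline outputs against the simulator's ground truth.

    ``fold_changes``: the per-peptide log2FC table of one compartment;
    recovered values are matched to injected ones by sequence (sequences
    emitted more than once are dropped as ambiguous). ``venn`` is the
    control-vs-treated VennSummary of the same compartment.
    """
    report: dict = {"compartment": compartment}
    tsub = truth.loc[truth["compartment"] == compartment]
    if fold_changes is not None and len(fold_changes):
        shared = tsub.loc[
            (tsub["provenance"] == "shared") & (tsub["condition"] == "treated")
        ][["sequence", "true_log2fc"]]
        shared = shared.drop_duplicates("sequence", keep=False)
        rec = fold_changes.loc[fold_changes["status"] == "ok",
                               ["sequence", "log2fc"]]
        joined = rec.merge(shared, on="sequence")
        if len(joined):
            err = joined["log2fc"] - joined["true_log2fc"]
            report["log2fc_n"] = int(len(joined))
            report["log2fc_bias"] = float(err.mean())
            report["log2fc_rmse"] = float(np.sqrt((err ** 2).mean()))
    if venn is not None:
        treated_seqs = set(tsub.loc[tsub["condition"] == "treated", "sequence"])
        control_seqs = set(tsub.loc[tsub["condition"] == "control", "sequence"])
        report["true_treated_unique"] = len(treated_seqs - control_seqs)
        report["measured_treated_unique"] = venn.unique_b
        report["true_shared"] = len(treated_seqs & control_seqs)
        report["measured_shared"] = venn.shared
    return report
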