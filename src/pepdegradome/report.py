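"""End-to-end pipeline orchestration and the reproducibility manifest.

``analyze`` runs every analysis stage on one validated input bundle
(peptide table, proteome, optional topology / AAindex / predictor scores)
and returns a :class:`PipelineResults`. ``run_synthetic`` generates the
inputs with the simulator first and attaches ground truth.
``write_bundle`` serialises all stage outputs as TSV plus a JSON manifest
with checksums, the configuration snapshot and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import amp as amp_mod
from . import core, degradome, physchem, topology as topo_mod
from .io import (
    AAindexTable,
    ProteomeMap,
    RunConfig,
    TopologyMap,
    bundled_aaindex_path,
    read_aaindex1,
    write_fasta,
    write_peptide_table,
    write_topology,
)
from .simulate import (
    SimulationConfig,
    generate_proteome,
    simulate_amp_scores,
    simulate_digestion,
    synthetic_aaindex,
    truth_recovery_report,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResults:
    config: RunConfig
    filtered: core.FilteredPeptidome
    venns: dict[str, core.VennSummary] = field(default_factory=dict)
    new_precursors: dict[str, tuple[int, float | None]] = field(default_factory=dict)
    fold_changes: dict[str, pd.DataFrame] = field(default_factory=dict)
    correlations: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    cterm_fractions: dict[str, float] = field(default_factory=dict)
    small_proteins: set[str] = field(default_factory=set)
    pdp: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    pdp_similarity: dict[str, tuple[pd.Series, float]] = field(default_factory=dict)
    aaf: dict[str, pd.Series] = field(default_factory=dict)
    aaf_comparison: pd.DataFrame | None = None
    background: list[str] = field(default_factory=list)
    terminal_profiles: dict[tuple[str, str], physchem.TerminalProfile] = field(
        default_factory=dict
    )
    screen: pd.DataFrame | None = None
    clustering: physchem.IndexClustering | None = None
    cluster_enrichment: pd.DataFrame | None = None
    hydrophobicity_cluster: int | None = None
    locations: dict[str, pd.DataFrame] = field(default_factory=dict)
    location_enrichment: pd.DataFrame | None = None
    amp_calls: dict[str, pd.DataFrame] = field(default_factory=dict)
    amp_rates: dict[str, float] = field(default_factory=dict)
    candidates: dict[str, pd.DataFrame] = field(default_factory=dict)
    truth: pd.DataFrame | None = None
    truth_report: dict = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise StageError(name, exc) from exc
        return wrapped
    return deco


@_stage("core")
def _run_core(results: PipelineResults, peptides: pd.DataFrame,
              proteome: ProteomeMap, cfg: RunConfig) -> None:
    filtered = results.filtered
    for compartment in ("cell", "secretome"):
        ctrl = filtered.sequences(compartment, "control")
        trt = filtered.sequences(compartment, "treated")
        if not (ctrl or trt):
            continue
        venn = core.venn_counts(ctrl, trt)
        ta = filtered.table(compartment, "control")
        tb = filtered.table(compartment, "treated")
        if len(ta) and len(tb):
            venn.percent_shared, venn.percent_shared_sd = (
                core.percent_shared_by_repeat(ta, tb)
            )
        results.venns[compartment] = venn
        results.new_precursors[compartment] = core.new_precursor_fraction(
            venn.unique_b_sequences, tb, ta
        )
        fc = core.fold_change_table(filtered, compartment)
        results.fold_changes[compartment] = fc
        try:
            results.correlations[compartment] = core.intensity_correlation(fc)
        except ValueError as exc:
            logger.warning("correlation skipped for %s: %s", compartment, exc)
        both = pd.concat([ta, tb], ignore_index=True)
        results.cterm_fractions[compartment] = core.cterminal_fraction(
            both, proteome, cfg.cterm_window_aa
        )
    results.small_proteins = core.small_protein_flags(
        proteome, cfg.small_protein_aa
    )


@_stage("pdp")
def _run_pdp(results: PipelineResults, proteome: ProteomeMap,
             cfg: RunConfig) -> None:
    for (compartment, condition) in results.filtered.groups:
        mat = degradome.pdp_matrix(
            results.filtered, proteome, compartment, condition, cfg.n_pdp_windows
        )
        if len(mat):
            results.pdp[(compartment, condition)] = mat
    for compartment in ("cell", "secretome"):
        a = results.pdp.get((compartment, "control"))
        b = results.pdp.get((compartment, "treated"))
        if a is not None and b is not None and set(a.index) & set(b.index):
            results.pdp_similarity[compartment] = degradome.pdp_similarity(a, b)


@_stage("physchem")
def _run_physchem(results: PipelineResults, peptides: pd.DataFrame,
                  proteome: ProteomeMap, aaindex: AAindexTable,
                  cfg: RunConfig, rng: np.random.Generator,
                  background_n: int | None) -> None:
    filtered = results.filtered
    cell = sorted(filtered.sequences("cell", "control")
                  | filtered.sequences("cell", "treated"))
    sec = sorted(filtered.sequences("secretome", "control")
                 | filtered.sequences("secretome", "treated"))
    if cell:
        results.aaf["cell"] = physchem.aa_frequencies(cell)
    if sec:
        results.aaf["secretome"] = physchem.aa_frequencies(sec)
    mapped = peptides.loc[~peptides["unmapped"]]
    if len(mapped):
        n_bg = background_n or max(200, min(2000, len(mapped)))
        results.background = physchem.background_peptides(
            proteome, mapped, n_bg, rng
        )
        results.aaf["background"] = physchem.aa_frequencies(results.background)
    if cell and sec:
        results.aaf_comparison = physchem.compare_aaf(cell, sec)
        for compartment, peps in (("cell", cell), ("secretome", sec)):
            for terminus in ("N", "C"):
                results.terminal_profiles[(compartment, terminus)] = (
                    physchem.terminal_profile(peps, terminus, cfg.terminal_k)
                )
        results.screen = physchem.property_screen(
            cell, sec, aaindex, cfg.p_tiers, label_a="cell", label_b="secretome"
        )
        n_complete = int(aaindex.complete.sum())
        if n_complete >= cfg.n_clusters:
            pm = physchem.property_matrix(sorted(set(cell) | set(sec)), aaindex)
            try:
                results.clustering = physchem.cluster_indexes(pm, cfg.n_clusters)
            except ValueError as exc:
                logger.warning("index clustering skipped: %s", exc)
        if results.clustering is not None and results.screen is not None:
            sig = set(results.screen.index[results.screen["tier"] != "ns"])
            results.cluster_enrichment = physchem.cluster_enrichment(
                results.clustering, sig
            )
            results.hydrophobicity_cluster = (
                physchem.identify_hydrophobicity_cluster(results.clustering)
            )


@_stage("topology")
def _run_topology(results: PipelineResults, topology: TopologyMap) -> None:
    filtered = results.filtered
    for compartment in ("cell", "secretome"):
        tabs = [filtered.table(compartment, cond) for cond in ("control", "treated")]
        tabs = [t for t in tabs if len(t)]
        if not tabs:
            continue
        merged = pd.concat(tabs, ignore_index=True).drop_duplicates("sequence")
        results.locations[compartment] = topo_mod.locate_table(merged, topology)
    if "cell" in results.locations and "secretome" in results.locations:
        results.location_enrichment = topo_mod.location_enrichment(
            results.locations["cell"], results.locations["secretome"]
        )


@_stage("amp")
def _run_amp(results: PipelineResults, amp_scores: dict[str, pd.DataFrame],
             cfg: RunConfig) -> None:
    for compartment, scores in amp_scores.items():
        calls = amp_mod.consensus_amp(scores, cfg.amp_thresholds)
        results.amp_calls[compartment] = calls
        results.amp_rates[compartment] = amp_mod.amp_rate(calls)
        fc = results.fold_changes.get(compartment)
        results.candidates[compartment] = amp_mod.prioritize_candidates(
            calls, fc, compartment, cfg.upregulated_log2fc
        )


def analyze(
    peptides: pd.DataFrame,
    proteome: ProteomeMap,
    config: RunConfig | None = None,
    topology: TopologyMap | None = None,
    aaindex: AAindexTable | None = None,
    amp_scores: dict[str, pd.DataFrame] | None = None,
    background_n: int | None = None,
    rng: np.random.Generator | None = None,
) -> PipelineResults:
    """Run every analysis stage on one validated input bundle."""
    cfg = config or RunConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    if aaindex is None:
        aaindex = read_aaindex1(bundled_aaindex_path())
    try:
        filtered = core.replicate_filter(peptides, cfg.min_repeats)
    except Exception as exc:  # noqa: BLE001
        raise StageError("filter", exc) from exc
    results = PipelineResults(cfg, filtered)
    results.stage_counts["filter"] = {
        f"{c}/{d}": v for (c, d), v in filtered.counts.items()
    }
    _run_core(results, peptides, proteome, cfg)
    _run_pdp(results, proteome, cfg)
    _run_physchem(results, peptides, proteome, aaindex, cfg, rng, background_n)
    if topology:
        _run_topology(results, topology)
    else:
        logger.warning("no topology records; localization stage skipped")
    if amp_scores:
        _run_amp(results, amp_scores, cfg)
    return results


def run_synthetic(
    config: RunConfig | None = None,
    sim_config: SimulationConfig | None = None,
    with_amp: bool = True,
    with_synthetic_aaindex: bool = True,
) -> tuple[PipelineResults, dict]:
    """Simulate a full study and analyse it; returns (results, inputs).

    ``inputs`` carries the generated proteome, topology, peptide table,
    truth and score tables so they can be written out or inspected. With
    ``with_synthetic_aaindex`` the property screen runs over a synthetic
    index collection with known family structure (the bundled miniature
    aaindex file alone is too small to cluster).
    """
    cfg = config or RunConfig()
    sim = sim_config or SimulationConfig(rng_seed=cfg.rng_seed)
    rng = np.random.default_rng(sim.rng_seed)
    proteome, topo = generate_proteome(sim, rng)
    peptides, truth = simulate_digestion(proteome, topo, sim, rng=rng)
    if with_synthetic_aaindex:
        aaindex, _families = synthetic_aaindex(rng, n_families=6, per_family=15)
    else:
        aaindex = read_aaindex1(bundled_aaindex_path())
    amp_scores = None
    if with_amp:
        amp_scores = {}
        for compartment in ("cell", "secretome"):
            seqs = peptides.loc[
                peptides["compartment"] == compartment, "sequence"
            ].unique()
            amp_scores[compartment] = simulate_amp_scores(seqs, rng)
    results = analyze(
        peptides, proteome, cfg, topology=topo, aaindex=aaindex,
        amp_scores=amp_scores, rng=rng,
    )
    results.truth = truth
    for compartment in ("cell", "secretome"):
        results.truth_report[compartment] = truth_recovery_report(
            truth,
            results.fold_changes.get(compartment),
            results.venns.get(compartment),
            compartment,
        )
    inputs = {
        "proteome": proteome, "topology": topo, "peptides": peptides,
        "truth": truth, "amp_scores": amp_scores, "sim_config": sim,
    }
    return results, inputs


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def summary_tables(results: PipelineResults) -> dict[str, pd.DataFrame]:
    """Flat summary tables of the headline quantities."""
    venn_rows = []
    for compartment, v in results.venns.items():
        npc, frac = results.new_precursors.get(compartment, (0, None))
        corr = results.correlations.get(compartment)
        venn_rows.append({
            "compartment": compartment,
            "control_unique": v.unique_a, "shared": v.shared,
            "treated_unique": v.unique_b,
            "percent_shared": v.percent_shared,
            "percent_shared_sd": v.percent_shared_sd,
            "new_precursor_count": npc,
            "new_precursor_fraction": frac,
            "pearson_r": corr[0] if corr else np.nan,
            "pearson_p": corr[1] if corr else np.nan,
            "cterm_fraction": results.cterm_fractions.get(compartment, np.nan),
        })
    out = {"venn_summary": pd.DataFrame(venn_rows)}
    if results.pdp_similarity:
        out["pdp_similarity"] = pd.DataFrame([
            {"compartment": comp, "median_cosine": med, "n_proteins": len(per)}
            for comp, (per, med) in results.pdp_similarity.items()
        ])
    if results.screen is not None:
        tiers = results.screen["tier"].value_counts()
        out["screen_tiers"] = pd.DataFrame([{
            "n_indexes": len(results.screen),
            "n_sig": int((results.screen["tier"] != "ns").sum()),
            "n_sigAA": int(results.screen["tier"].isin(["sigAA", "top"]).sum()),
            "n_top": int(tiers.get("top", 0)),
        }])
    if results.amp_rates:
        out["amp_rates"] = pd.DataFrame([
            {"compartment": c, "amp_rate": r} for c, r in results.amp_rates.items()
        ])
    return out


def write_bundle(
    results: PipelineResults,
    out_dir: str | Path,
    inputs: dict | None = None,
) -> Path:
    """Write all stage outputs as TSV plus a JSON run manifest.

    Returns the manifest path. Deterministic stages re-run with the same
    seed and config reproduce these files byte-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        written.append(path)

    if inputs:
        write_fasta(inputs["proteome"], out / "proteome.fasta")
        written.append(out / "proteome.fasta")
        if inputs.get("topology"):
            write_topology(inputs["topology"], out / "topology.tsv")
            written.append(out / "topology.tsv")
        pep = inputs["peptides"].drop(columns=["matches"], errors="ignore")
        write_peptide_table(pep, out / "peptides.tsv")
        written.append(out / "peptides.tsv")
        if inputs.get("truth") is not None:
            save(inputs["truth"], "truth.tsv", index=False)
        for compartment, scores in (inputs.get("amp_scores") or {}).items():
            save(scores, f"amp_scores_{compartment}.tsv")

    for (compartment, condition), table in results.filtered.groups.items():
        t = table.drop(columns=["matches"], errors="ignore").copy()
        t["repeats"] = t["repeats"].map(
            lambda s: ";".join(str(i) for i in sorted(s))
        )
        t["proteins"] = t["proteins"].map(";".join)
        save(t, f"filtered_{compartment}_{condition}.tsv", index=False)
    for name, df in summary_tables(results).items():
        save(df, f"{name}.tsv", index=False)
    for compartment, fc in results.fold_changes.items():
        save(fc, f"fold_change_{compartment}.tsv", index=False)
    for (compartment, condition), mat in results.pdp.items():
        save(mat, f"pdp_{compartment}_{condition}.tsv")
    if results.aaf_comparison is not None:
        save(results.aaf_comparison, "aaf_comparison.tsv")
    for (compartment, terminus), prof in results.terminal_profiles.items():
        save(prof.pfm, f"terminal_profile_{compartment}_{terminus}.tsv")
    if results.screen is not None:
        save(results.screen, "screen_results.tsv")
    if results.clustering is not None:
        save(results.clustering.labels.to_frame(), "clusters.tsv")
    if results.cluster_enrichment is not None:
        save(results.cluster_enrichment, "cluster_enrichment.tsv")
    for compartment, locs in results.locations.items():
        save(locs, f"peptide_locations_{compartment}.tsv", index=False)
    if results.location_enrichment is not None:
        save(results.location_enrichment, "location_enrichment.tsv")
    for compartment, cand in results.candidates.items():
        save(cand, f"candidates_ranked_{compartment}.tsv")

    manifest = {
        "package_version": __version__,
        "config": results.config.to_dict(),
        "sim_config": (
            inputs["sim_config"].to_dict()
            if inputs and "sim_config" in inputs else None
        ),
        "seed": results.config.rng_seed,
        "stage_counts": results.stage_counts,
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
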