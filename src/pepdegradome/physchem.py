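"""Amino-acid composition, terminal profiles and AAindex property screening.

The physicochemical characterisation of a peptide set proceeds in layers:

* pooled amino-acid frequencies (AAF) and their comparison between sets;
* background peptides drawn from precursor regions never observed by MS,
  as the composition null;
* position-frequency matrices of the first/last ``k`` residues (terminal
  profiles, the data behind sequence logos);
* per-peptide mean AAindex descriptors, a two-group Mann–Whitney screen
  over all complete indexes with tiered significance levels, Ward
  clustering of the index profiles and Fisher enrichment of clusters among
  the significant indexes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .io import AA20, AAindexTable, ProteomeMap, is_standard

logger = logging.getLogger(__name__)

#: published hydrophobicity scales used to label the hydrophobicity cluster
#: (partition-coefficient / hydropathy / transfer-energy style entries)
HYDROPHOBICITY_REFERENCE_IDS = (
    "KYTJ820101",  # Kyte-Doolittle hydropathy
    "GARJ730101",  # partition coefficient
    "JOND750101",  # hydrophobicity
    "NOZY710101",  # transfer energy, organic solvent/water
    "GUYH850101",  # partition energy
)


# ---------------------------------------------------------------------------
# amino-acid frequencies
# ---------------------------------------------------------------------------


def aa_frequencies(peptides) -> pd.Series:
    """Pooled residue frequencies over a peptide set.

    Residues outside the 20-letter alphabet are excluded from both numerator
    and denominator. The returned Series (indexed by residue) sums to 1 and
    carries the total residue count in ``attrs['total']``.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("empty peptide set")
    counts = residue_counts(peptides)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no standard residues in peptide set")
    freqs = counts / total
    freqs.attrs["total"] = total
    return freqs


def residue_counts(peptides) -> pd.Series:
    """Counts of the 20 standard residues pooled over a peptide set."""
    counter = dict.fromkeys(AA20, 0)
    for pep in peptides:
        for ch in pep:
            if ch in counter:
                counter[ch] += 1
    return pd.Series(counter, name="count")


def compare_aaf(peptides_a, peptides_b, alpha: float = 0.05) -> pd.DataFrame:
    """Per-residue composition comparison between two peptide sets.

    For each residue a 2×2 Fisher exact test (this residue vs all others,
    set A vs set B), Benjamini–Hochberg corrected across the 20 residues.
    "No significant difference" between sets means zero residues at
    q < alpha.
    """
    ca, cb = residue_counts(peptides_a), residue_counts(peptides_b)
    ta, tb = ca.sum(), cb.sum()
    rows = []
    for res in AA20:
        table = [[ca[res], ta - ca[res]], [cb[res], tb - cb[res]]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({
            "residue": res,
            "count_a": int(ca[res]), "count_b": int(cb[res]),
            "freq_a": ca[res] / ta if ta else np.nan,
            "freq_b": cb[res] / tb if tb else np.nan,
            "odds_ratio": odds, "p": p,
        })
    out = pd.DataFrame(rows).set_index("residue")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    return out


# ---------------------------------------------------------------------------
# background peptides
# ---------------------------------------------------------------------------


def background_peptides(
    proteome: ProteomeMap,
    observed: pd.DataFrame,
    n: int,
    rng: np.random.Generator,
    max_redraws: int = 200,
) -> list[str]:
    """Sample peptides from precursor regions not covered by observed peptides.

    Observed spans (all match sites) are masked; lengths are drawn with
    replacement from the observed length distribution and placed uniformly
    over valid start positions inside contiguous unmasked runs. A sampled
    span never touches a masked residue.
    """
    masks: dict[str, np.ndarray] = {
        pid: np.zeros(L, dtype=bool) for pid, L in proteome.lengths.items()
    }
    lengths: list[int] = []
    for _, row in observed.iterrows():
        if row.get("unmapped", False):
            continue
        lengths.append(len(row["sequence"]))
        matches = row.get("matches") or []
        if not matches and not pd.isna(row.get("start")):
            matches = [(row["proteins"][0], int(row["start"]), int(row["end"]))]
        for pid, s, e in matches:
            if pid in masks:
                masks[pid][s - 1:e] = True
    if not lengths:
        raise ValueError("no mapped observed peptides to define a length distribution")

    # contiguous unmasked runs as (protein, run_start0, run_len)
    runs: list[tuple[str, int, int]] = []
    for pid, mask in masks.items():
        free = ~mask
        edges = np.flatnonzero(np.diff(np.concatenate(([0], free.view(np.int8), [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            runs.append((pid, int(a), int(b - a)))
    if not runs:
        raise ValueError("all precursor residues are covered by observed peptides")
    run_lens = np.array([r[2] for r in runs])

    out: list[str] = []
    lengths_arr = np.array(lengths)
    attempts = 0
    while len(out) < n:
        if attempts > max_redraws * n:
            raise RuntimeError(
                "could not place background peptides: unmasked runs too short"
            )
        attempts += 1
        plen = int(rng.choice(lengths_arr))
        n_starts = run_lens - plen + 1
        valid = n_starts > 0
        if not valid.any():
            continue
        weights = np.where(valid, n_starts, 0).astype(float)
        ridx = int(rng.choice(len(runs), p=weights / weights.sum()))
        pid, a, rl = runs[ridx]
        off = int(rng.integers(0, rl - plen + 1))
        out.append(proteome[pid][a + off:a + off + plen])
    return out


# ---------------------------------------------------------------------------
# terminal profiles
# ---------------------------------------------------------------------------


@dataclass
class TerminalProfile:
    """Position-frequency matrix of the first/last k residues of a peptide set.

    ``pfm`` has ``k`` rows (position 1 = the terminal residue, counting
    inward) and 20 residue columns, each row summing to 1 over contributing
    peptides. ``information`` is log2(20) minus the Shannon entropy per
    position, in bits.
    """

    terminus: str
    pfm: pd.DataFrame
    information: pd.Series
    n_used: int
    n_skipped: int


def terminal_profile(peptides, terminus: str, k: int = 5) -> TerminalProfile:
    if terminus not in ("N", "C"):
        raise ValueError("terminus must be 'N' or 'C'")
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.zeros((k, len(AA20)), dtype=float)
    col = {r: j for j, r in enumerate(AA20)}
    n_used = n_skipped = 0
    for pep in peptides:
        if len(pep) < k:
            n_skipped += 1
            continue
        n_used += 1
        window = pep[:k] if terminus == "N" else pep[::-1][:k]
        for i, ch in enumerate(window):
            if ch in col:
                counts[i, col[ch]] += 1
    if n_used == 0:
        raise ValueError(f"no peptides of length >= {k}")
    if n_skipped:
        logger.info("terminal_profile: skipped %d peptides shorter than %d",
                    n_skipped, k)
    row_tot = counts.sum(axis=1, keepdims=True)
    pfm = counts / row_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pfm > 0, pfm * np.log2(pfm), 0.0)
    info = math.log2(20) + plogp.sum(axis=1)
    return TerminalProfile(
        terminus,
        pd.DataFrame(pfm, index=range(1, k + 1), columns=list(AA20)),
        pd.Series(info, index=range(1, k + 1), name="bits"),
        n_used, n_skipped,
    )


# ---------------------------------------------------------------------------
# AAindex descriptors
# ---------------------------------------------------------------------------


def peptide_property(peptide: str, index_values: pd.Series) -> float:
    """Mean per-residue value of one AAindex scale over a peptide."""
    if index_values.isna().any():
        raise ValueError("index is incomplete (missing residue values)")
    if not is_standard(peptide):
        raise ValueError(f"peptide {peptide!r} contains non-standard residues")
    return float(np.mean([index_values[ch] for ch in peptide]))


def property_matrix(peptides, aaindex: AAindexTable) -> pd.DataFrame:
    """Peptide × index matrix of mean descriptors (complete indexes only).

    Peptides with non-standard residues are dropped. Vectorised as
    composition (peptide × residue fractions) @ values (residue × index).
    """
    peptides = [p for p in peptides if is_standard(p)]
    if not peptides:
        raise ValueError("no standard-alphabet peptides")
    values = aaindex.complete_table()  # index × residue
    col = {r: j for j, r in enumerate(AA20)}
    comp = np.zeros((len(peptides), len(AA20)))
    for i, pep in enumerate(peptides):
        for ch in pep:
            comp[i, col[ch]] += 1
        comp[i] /= len(pep)
    mat = comp @ values[list(AA20)].to_numpy().T
    return pd.DataFrame(mat, index=pd.Index(peptides, name="peptide"),
                        columns=values.index)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def mannwhitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney by permutation enumeration.

    Enumerates all C(n1+n2, n1) group labelings of the pooled sample;
    the two-sided p is the probability of a U statistic at least as far
    from its null mean n1·n2/2 as observed. Valid with ties.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    count = total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return float(u_obs), count / total


def mannwhitney(x, y, exact_max: int = 8) -> tuple[float, float]:
    """Two-sided Mann–Whitney U.

    Exact permutation enumeration when both groups have at most
    ``exact_max`` observations, tie-corrected normal approximation
    otherwise. Returns (U of the first sample, two-sided p).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    if len(x) <= exact_max and len(y) <= exact_max:
        return mannwhitney_exact(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


TIER_LABELS = ("ns", "sig", "sigAA", "top")


def assign_tier(p: float, tiers: tuple[float, float, float]) -> str:
    """Tier by raw p: sig (< tiers[0]), sigAA (< tiers[1]), top (< tiers[2])."""
    t_sig, t_sigaa, t_top = tiers
    if p < t_top:
        return "top"
    if p < t_sigaa:
        return "sigAA"
    if p < t_sig:
        return "sig"
    return "ns"


def property_screen(
    peptides_a,
    peptides_b,
    aaindex: AAindexTable,
    tiers: tuple[float, float, float] = (1e-5, 1e-15, 1e-25),
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Mann–Whitney screen of every complete AAindex scale between two sets.

    Per index: per-peptide mean descriptors in each set, two-sided test,
    direction (which set scores higher, by mean), raw-p tier and BH q.
    """
    ma = property_matrix(peptides_a, aaindex)
    mb = property_matrix(peptides_b, aaindex)
    if len(ma) < 2 or len(mb) < 2:
        raise ValueError("need at least 2 usable peptides per set")
    rows = []
    for idx in ma.columns:
        a, b = ma[idx].to_numpy(), mb[idx].to_numpy()
        u, p = mannwhitney(a, b)
        rows.append({
            "index_id": idx,
            "U": u, "p": p,
            "direction": label_a if a.mean() > b.mean() else label_b,
            "mean_a": a.mean(), "mean_b": b.mean(),
            "tier": assign_tier(p, tiers),
        })
    out = pd.DataFrame(rows).set_index("index_id")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# index clustering and enrichment
# ---------------------------------------------------------------------------


@dataclass
class IndexClustering:
    """Ward clustering of AAindex profiles over a peptide set."""

    labels: pd.Series  # index_id -> cluster 1..n
    linkage_matrix: np.ndarray
    excluded: list[str]  # zero-variance indexes left out

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def cluster_indexes(prop_matrix: pd.DataFrame, n_clusters: int = 6) -> IndexClustering:
    """Ward hierarchical clustering of indexes by their z-scored profiles.

    Each index's vector of per-peptide descriptors is z-scored across
    peptides; Ward linkage on Euclidean distances; tree cut to
    ``n_clusters``. Indexes constant over the peptides carry no profile and
    are excluded with a warning. Input column order does not matter: columns
    are sorted lexically first.
    """
    cols = sorted(prop_matrix.columns)
    mat = prop_matrix[cols].to_numpy(dtype=float)
    sd = mat.std(axis=0)
    excluded = [c for c, s in zip(cols, sd) if s == 0]
    if excluded:
        logger.warning("cluster_indexes: excluding constant indexes %s", excluded)
    keep = [i for i, c in enumerate(cols) if c not in set(excluded)]
    cols = [cols[i] for i in keep]
    if len(cols) < n_clusters:
        raise ValueError(
            f"need at least {n_clusters} varying indexes, have {len(cols)}"
        )
    z = (mat[:, keep] - mat[:, keep].mean(axis=0)) / mat[:, keep].std(axis=0)
    lk = linkage(z.T, method="ward")
    labels = fcluster(lk, t=n_clusters, criterion="maxclust")
    return IndexClustering(
        pd.Series(labels, index=pd.Index(cols, name="index_id"), name="cluster"),
        lk,
        excluded,
    )


def cluster_enrichment(
    clustering: IndexClustering, significant_ids
) -> pd.DataFrame:
    """Fisher enrichment of each cluster within the significant index set.

    Per cluster, a 2×2 (in-cluster × significant) two-sided Fisher exact
    test over the clustered index universe, BH-corrected across clusters.
    """
    universe = set(clustering.labels.index)
    sig = set(significant_ids) & universe
    rows = []
    for c in range(1, clustering.n_clusters + 1):
        members = set(clustering.members(c))
        a = len(members & sig)
        b = len(members - sig)
        c2 = len(sig - members)
        d = len(universe - members - sig)
        odds, p = stats.fisher_exact([[a, b], [c2, d]], alternative="two-sided")
        rows.append({
            "cluster": c, "n_members": len(members),
            "n_significant": a, "odds_ratio": odds, "p": p,
        })
    out = pd.DataFrame(rows).set_index("cluster")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def identify_hydrophobicity_cluster(
    clustering: IndexClustering,
    reference_ids=HYDROPHOBICITY_REFERENCE_IDS,
) -> int | None:
    """Cluster holding the majority of the reference hydrophobicity scales.

    Returns None when none of the reference scales was clustered.
    """
    present = [r for r in reference_ids if r in clustering.labels.index]
    if not present:
        return None
    return int(clustering.labels[present].mode().iloc[0])
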