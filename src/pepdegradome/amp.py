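"""Consensus antimicrobial-peptide (AMP) triage.

Scores from three external sequence-based predictors (CAMP and iAMPpred
probabilities, ADAM's real-valued SVM score) are combined by conjunction:
a peptide is a consensus AMP candidate when every predictor calls it
(probability >= 0.5 for CAMP/iAMPpred, score strictly > 0 for ADAM).
Candidates are then prioritised by consensus, predicted-probability product
and abundance change upon treatment.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

PREDICTORS = ("camp", "iamppred", "adam")
DEFAULT_THRESHOLDS = {"camp": 0.5, "iamppred": 0.5, "adam": 0.0}


def read_score_table(path: str | Path, predictor: str) -> pd.Series:
    """Read one predictor's TSV (columns: peptide, score) as a Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns peptide, score")
    s = pd.Series(
        df.iloc[:, 1].to_numpy(float),
        index=df.iloc[:, 0].astype(str).str.upper(),
        name=predictor,
    )
    return s[~s.index.duplicated()]


def load_amp_scores(
    camp: str | Path | pd.Series,
    iamppred: str | Path | pd.Series,
    adam: str | Path | pd.Series,
) -> pd.DataFrame:
    """Assemble the per-peptide score table; probabilities validated to [0,1]."""
    cols = {}
    for name, src in zip(PREDICTORS, (camp, iamppred, adam)):
        cols[name] = src if isinstance(src, pd.Series) else read_score_table(src, name)
    scores = pd.DataFrame(cols)
    scores.index.name = "peptide"
    for name in ("camp", "iamppred"):
        vals = scores[name].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{name} probabilities outside [0, 1]")
    return scores


def consensus_amp(
    scores: pd.DataFrame, thresholds: dict[str, float] | None = None
) -> pd.DataFrame:
    """Per-predictor calls and the consensus conjunction.

    Probability predictors call at score >= threshold; ADAM calls strictly
    above its zero threshold. Peptides missing any score have an
    undetermined consensus (NaN), reported separately from true/false.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    for name in ("camp", "iamppred"):
        vals = scores[name].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{name} probabilities outside [0, 1]")
    calls = scores.copy()
    calls["camp_call"] = scores["camp"] >= th["camp"]
    calls["iamppred_call"] = scores["iamppred"] >= th["iamppred"]
    calls["adam_call"] = scores["adam"] > th["adam"]
    complete = scores[list(PREDICTORS)].notna().all(axis=1)
    conj = calls["camp_call"] & calls["iamppred_call"] & calls["adam_call"]
    calls["complete"] = complete
    calls["consensus"] = conj.where(complete, other=pd.NA)
    return calls


def amp_rate(calls: pd.DataFrame, universe=None) -> float:
    """Fraction of consensus AMP candidates among fully scored peptides."""
    sub = calls
    if universe is not None:
        sub = calls.loc[calls.index.intersection(set(universe))]
    complete = sub.loc[sub["complete"]]
    if complete.empty:
        raise ValueError("no peptides with complete predictor scores")
    return float((complete["consensus"] == True).sum() / len(complete))  # noqa: E712


def prioritize_candidates(
    calls: pd.DataFrame,
    fold_changes: pd.DataFrame | None = None,
    compartment: str | None = None,
    upregulated_log2fc: float = 1.0,
    exclude=None,
) -> pd.DataFrame:
    """Rank AMP candidates for follow-up.

    Order: consensus first, then the CAMP × iAMPpred probability product,
    then log2 fold change. ``exclude`` is an optional user-supplied peptide
    blacklist (e.g. predictor-reported unreliable calls). Peptides with
    log2FC above ``upregulated_log2fc`` are flagged up-regulated.
    """
    out = calls.copy()
    if exclude:
        out = out.loc[~out.index.isin(set(exclude))]
    out["prob_product"] = out["camp"] * out["iamppred"]
    if fold_changes is not None and len(fold_changes):
        fc = fold_changes.set_index("sequence")["log2fc"]
        out["log2fc"] = out.index.map(fc)
    else:
        out["log2fc"] = np.nan
    out["upregulated"] = out["log2fc"] > upregulated_log2fc
    if compartment is not None:
        out["compartment"] = compartment
    consensus_rank = out["consensus"].map({True: 1, False: 0}).fillna(0)
    out = out.assign(_c=consensus_rank).sort_values(
        by=["_c", "prob_product", "log2fc"],
        ascending=[False, False, False],
        na_position="last",
        kind="mergesort",
    ).drop(columns="_c")
    return out
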