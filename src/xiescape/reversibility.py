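"""Washout reversibility of Xist-induced escapee silencing.

After Dox washout the fold recovery of a gene is its washout allelic ratio
divided by its untreated allelic ratio. A gene is reversible when it recovers
at least 50% of untreated escape AND reaches an allelic ratio above 0.1 after
washout; partially irreversible when recovery lies in [10%, 50%) with a
washout ratio above 0.1; irreversible otherwise. A zero (or missing)
untreated ratio leaves the call undefined.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import condition_label

CLASSES = ["reversible", "partially_irreversible", "irreversible", "undefined"]


def compute_fold_recovery(untreated_ratio: float, washout_ratio: float) -> float:
    """washout ratio / untreated ratio; NaN when the denominator is zero."""
    if untreated_ratio < 0 or washout_ratio < 0:
        raise ValueError("allelic ratios must be non-negative")
    if untreated_ratio == 0:
        return float("nan")
    return washout_ratio / untreated_ratio


def _classify(fold_recovery: float, washout_ratio: float,
              reversible_min: float, partial_min: float,
              min_washout_ratio: float) -> str:
    if not np.isfinite(fold_recovery):
        return "undefined"
    if fold_recovery >= reversible_min and washout_ratio > min_washout_ratio:
        return "reversible"
    if fold_recovery >= partial_min and washout_ratio > min_washout_ratio:
        return "partially_irreversible"
    return "irreversible"


def classify_reversibility(
    condition_means: pd.DataFrame,
    sheet: pd.DataFrame,
    genes=None,
    untreated_condition: str = "untreated",
    reversible_min_recovery: float = 0.5,
    partial_min_recovery: float = 0.1,
    min_washout_ratio: float = 0.1,
) -> pd.DataFrame:
    """Three-way reversibility call per gene and induction duration.

    One washout condition per (dox_days, washout_days) pair in the sheet is
    compared against the untreated condition mean. Returns gene_id,
    induction_days, washout_days, fold_recovery, washout_ratio, class.
    """
    washouts = (
        sheet[(sheet["washout_days"] > 0) & ~sheet["auxin"]]
        [["dox_days", "washout_days"]].drop_duplicates()
        .sort_values(["dox_days", "washout_days"])
    )
    if washouts.empty:
        raise ConfigurationError("sample sheet declares no washout condition")
    means = condition_means.set_index(["gene_id", "condition_label"])["mean_ratio"]
    if genes is None:
        genes = condition_means["gene_id"].drop_duplicates().tolist()

    rows = []
    for spec in washouts.itertuples(index=False):
        label = condition_label(spec.dox_days, spec.washout_days, False)
        for gene_id in genes:
            untreated = means.get((gene_id, untreated_condition), np.nan)
            washout = means.get((gene_id, label), np.nan)
            if not np.isfinite(untreated) or not np.isfinite(washout):
                recovery, cls = np.nan, "undefined"
            else:
                recovery = compute_fold_recovery(float(untreated), float(washout))
                cls = _classify(recovery, float(washout),
                                reversible_min_recovery, partial_min_recovery,
                                min_washout_ratio)
            rows.append((gene_id, spec.dox_days, spec.washout_days,
                         recovery, washout, cls))
    return pd.DataFrame(rows, columns=[
        "gene_id", "induction_days", "washout_days", "fold_recovery",
        "washout_ratio", "class",
    ])


def summarize_reversibility(calls: pd.DataFrame) -> dict:
    """Class counts per induction duration (the stacked-histogram tallies)."""
    out = {}
    for duration, sub in calls.groupby("induction_days"):
        counts = sub["class"].value_counts().to_dict()
        out[f"dox{int(duration)}d"] = {
            cls: int(counts.get(cls, 0)) for cls in CLASSES
        }
    return out
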