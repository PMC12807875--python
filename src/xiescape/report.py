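"""Run summaries and export matrices assembled from stage outputs."""

from __future__ import annotations

import json
import platform
from typing import Any

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .groups import summarize_groups
from .reversibility import summarize_reversibility


def heatmap_matrix(condition_means: pd.DataFrame,
                   annotation: pd.DataFrame | None = None,
                   genes=None, conditions=None) -> pd.DataFrame:
    """Genes x conditions matrix of mean allelic ratios.

    Rows are ordered by genomic position when an annotation is supplied
    (heat-map convention), otherwise by first appearance.
    """
    matrix = condition_means.pivot(index="gene_id", columns="condition_label",
                                   values="mean_ratio")
    if genes is not None:
        matrix = matrix.loc[[g for g in genes if g in matrix.index]]
    if conditions is not None:
        matrix = matrix[[c for c in conditions if c in matrix.columns]]
    if annotation is not None:
        starts = annotation.set_index("gene_id")["start"]
        order = matrix.index.to_series().map(starts).sort_values(kind="stable")
        matrix = matrix.loc[order.index]
    return matrix


def summarize_run(stages: dict[str, Any], thresholds: dict | None = None,
                  seed: int | None = None) -> dict:
    """Deterministic tallies over the pipeline's stage outputs.

    Every count is a direct recount of the corresponding stage table, so the
    summary always reconciles with the TSVs it describes.
    """
    summary: dict[str, Any] = {
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": seed,
        "thresholds": thresholds or {},
    }
    if "escape_calls" in stages:
        calls = stages["escape_calls"]
        summary["escape_status_counts"] = (
            calls["status"].value_counts().astype(int).to_dict()
        )
    if "categories" in stages:
        cats = stages["categories"]
        summary["category_counts"] = (
            cats["category"].value_counts().astype(int).to_dict()
        )
    if "silencing" in stages:
        sil = stages["silencing"]
        summary["silenced_by_dox_counts"] = {
            condition: int(sub["silenced_by_dox"].sum())
            for condition, sub in sil.groupby("condition")
        }
    if "kinetics" in stages:
        fits = stages["kinetics"]
        reliable = fits[fits["selected_model"] != "unreliable"]
        summary["kinetics"] = {
            "n_fitted": int(len(fits)),
            "n_reliable": int(len(reliable)),
            "n_residual_escape": int(reliable["residual_escape"].sum()),
            "median_half_life_days": (
                float(reliable["half_life_days"].median())
                if len(reliable) else None
            ),
        }
    if "groups" in stages:
        summary["groups"] = summarize_groups(stages["groups"])
    if "reversibility" in stages:
        summary["reversibility_counts"] = summarize_reversibility(
            stages["reversibility"]
        )
    return summary


def require_stages(stages: dict[str, Any], names: list[str]) -> None:
    missing = [name for name in names if name not in stages]
    if missing:
        raise ConfigurationError(f"missing stage output(s): {missing}")


def write_summary(summary: dict, path) -> None:
    with open(path, "wt", encoding="utf-8") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")
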