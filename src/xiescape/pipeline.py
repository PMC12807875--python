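"""End-to-end orchestration of the analysis stages.

``run_pipeline`` chains ratio computation, low-expression filtering, escape
calling, meta-classification, per-timepoint imbalance tests with silencing
calls, decay-kinetics fitting, gene grouping and (when the design includes
washout arms) reversibility classification. Each stage consumes only the
validated outputs of earlier stages, mirroring how the stages are exposed on
the command line.
"""

from __future__ import annotations

from typing import Any

import pandas as pd

from . import escape, groups, imbalance, kinetics, ratios, reversibility
from .config import default_config


def run_pipeline(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    study_matrix: pd.DataFrame | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Run every applicable stage; returns a dict of stage outputs."""
    cfg = config or default_config()
    out: dict[str, Any] = {}

    ratio_table = ratios.compute_allelic_ratios(counts, sheet)
    kept, filter_table = ratios.filter_low_expression(
        ratio_table, cfg["filters"]["min_mean_allelic_count"]
    )
    out["ratios"] = ratio_table
    out["filter"] = filter_table
    cond = ratios.aggregate_conditions(ratio_table, sheet)
    out["condition_means"] = cond

    calls = escape.call_escape(
        ratio_table, sheet,
        rule=cfg["escape"]["rule"],
        ratio_threshold=cfg["escape"]["ratio_threshold"],
        high_ratio_threshold=cfg["escape"]["high_ratio_threshold"],
        fraction_threshold=cfg["escape"]["fraction_threshold"],
        untreated_condition=cfg["escape"]["untreated_condition"],
        xist_gene=cfg["escape"]["xist_gene"],
        min_mean_allelic_count=cfg["filters"]["min_mean_allelic_count"],
    )
    out["escape_calls"] = calls
    escapees = calls.loc[calls["status"] == "escapee", "gene_id"].tolist()

    if study_matrix is not None:
        categories = escape.classify_meta(
            study_matrix,
            min_studies_detected=cfg["meta"]["min_studies_detected"],
            constitutive_fraction=cfg["meta"]["constitutive_fraction"],
            genes=calls["gene_id"].tolist(),
        )
        out["categories"] = escape.annotate_clone_specific(calls, categories)

    # imbalance tests: untreated vs each Dox timepoint (no washout, no auxin)
    untreated = cfg["escape"]["untreated_condition"]
    dox_conditions = (
        sheet[(sheet["dox_days"] > 0) & (sheet["washout_days"] == 0)
              & ~sheet["auxin"]]["condition_label"].drop_duplicates().tolist()
    )
    escapee_ratios = ratio_table[ratio_table["gene_id"].isin(set(escapees))]
    tests, silencing = [], []
    for condition in dox_conditions:
        model = imbalance.AllelicImbalanceModel(
            escapee_ratios, sheet, (untreated, condition)
        )
        adjusted = model.fit().adjusted(cfg["imbalance"]["adjust_method"])
        tests.append(adjusted)
        sil = imbalance.call_silencing(
            adjusted, cond,
            alpha=cfg["imbalance"]["alpha"],
            reduction_threshold=cfg["imbalance"]["reduction_threshold"],
        )
        sil.insert(1, "condition", condition)
        silencing.append(sil)
    if tests:
        out["imbalance"] = pd.concat(tests, ignore_index=True)
        out["silencing"] = pd.concat(silencing, ignore_index=True)

    fits = kinetics.fit_trajectories(
        ratio_table, sheet, genes=escapees,
        use_condition_means=cfg["kinetics"]["use_condition_means"],
        r2_threshold=cfg["kinetics"]["r2_threshold"],
        residual_b_threshold=cfg["kinetics"]["residual_b_threshold"],
        k_bounds=tuple(cfg["kinetics"]["k_bounds"]),
        b_bounds=tuple(cfg["kinetics"]["b_bounds"]),
        a_bounds=tuple(cfg["kinetics"]["a_bounds"]),
        k_starts=tuple(cfg["kinetics"]["k_starts"]),
    )
    out["kinetics"] = fits.table

    if annotation is not None:
        grouped = groups.partition_gene_groups(
            escapees, annotation, window=cfg["groups"]["window_bp"]
        )
        out["groups"] = grouped
        if seed is not None:
            out["neighbor_similarity"] = kinetics.neighbor_similarity_test(
                fits.table, annotation,
                window=cfg["kinetics"]["neighbor_window_bp"],
                n_permutations=cfg["kinetics"]["n_permutations"],
                seed=seed,
                max_half_life=cfg["kinetics"]["neighbor_max_half_life_days"],
            )

    has_washout = bool(((sheet["washout_days"] > 0) & ~sheet["auxin"]).any())
    if has_washout:
        out["reversibility"] = reversibility.classify_reversibility(
            cond, sheet, genes=escapees,
            untreated_condition=untreated,
            reversible_min_recovery=cfg["reversibility"]["reversible_min_recovery"],
            partial_min_recovery=cfg["reversibility"]["partial_min_recovery"],
            min_washout_ratio=cfg["reversibility"]["min_washout_ratio"],
        )
    return out
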