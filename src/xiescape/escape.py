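"""Escape calling and cross-study meta-classification.

A gene escapes X inactivation when it keeps expressing from the inactive X:
operationally, an allelic ratio strictly above 0.1 in the untreated state.
Ratios above 0.8 indicate strain-specific expression or mapping artefacts and
are excluded, as is Xist itself (expressed *from* the Xi by construction).

The meta-classifier places escapees into cross-study categories from a
gene x study call matrix: constitutive (detected in >= 3 studies, escaping in
more than half of them), facultative (escaping somewhere, but not
constitutive), silenced (detected, never escaping). Genes escaping in the
local dataset with no literature escape call are clone-specific.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError

STATUSES = [
    "escapee", "silenced", "excluded_high_ratio", "excluded_xist",
    "excluded_low_expression", "not_informative",
]
CATEGORIES = ["constitutive", "facultative", "clone_specific", "silenced",
              "unclassified"]


def call_escape(
    ratios: pd.DataFrame,
    sheet: pd.DataFrame,
    rule: str = "all_replicates",
    ratio_threshold: float = 0.1,
    high_ratio_threshold: float = 0.8,
    fraction_threshold: float = 0.5,
    untreated_condition: str = "untreated",
    xist_gene: str = "Xist",
    min_mean_allelic_count: float = 10.0,
) -> pd.DataFrame:
    """Call escape status per gene from untreated-condition ratios.

    ``rule`` is either ``all_replicates`` (clone-style calling: the ratio must
    exceed the threshold in every untreated replicate) or ``fraction``
    (population-style calling: in at least ``fraction_threshold`` of samples).
    Status precedence: excluded_xist > excluded_high_ratio >
    excluded_low_expression > escapee/silenced; genes with no defined
    untreated ratio are not_informative. ``basis_ratio`` is the mean defined
    untreated ratio.
    """
    if rule not in ("all_replicates", "fraction"):
        raise ConfigurationError(f"unknown escape-calling rule: {rule!r}")
    condition = sheet.set_index("sample_id")["condition_label"]
    if untreated_condition not in set(condition):
        raise ConfigurationError(
            f"untreated condition {untreated_condition!r} absent from sheet"
        )
    work = ratios.copy()
    work["condition_label"] = work["sample_id"].map(condition)
    untreated = work[work["condition_label"] == untreated_condition]

    mean_count = work.groupby("gene_id", sort=False)["total"].mean()

    rows = []
    for gene_id, sub in untreated.groupby("gene_id", sort=False):
        defined = sub[sub["defined"]]
        basis = defined["ratio"].mean() if len(defined) else np.nan
        if gene_id == xist_gene:
            status = "excluded_xist"
        elif len(defined) and basis > high_ratio_threshold:
            status = "excluded_high_ratio"
        elif mean_count.loc[gene_id] < min_mean_allelic_count:
            status = "excluded_low_expression"
        elif not len(defined):
            status = "not_informative"
        else:
            above = defined["ratio"] > ratio_threshold
            if rule == "all_replicates":
                escapes = bool(above.all())
            else:
                escapes = above.mean() >= fraction_threshold
            status = "escapee" if escapes else "silenced"
        rows.append((gene_id, status, basis))
    return pd.DataFrame(rows, columns=["gene_id", "status", "basis_ratio"])


def classify_meta(
    matrix: pd.DataFrame,
    min_studies_detected: int = 3,
    constitutive_fraction: float = 0.5,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Cross-study escape categories from a gene x study call matrix.

    A gene is detected in a study when the call is escaping or silenced.
    Constitutive requires detection in >= ``min_studies_detected`` studies and
    escape in strictly more than ``constitutive_fraction`` of the detecting
    studies (a tie at exactly the fraction is facultative). Genes absent from
    the matrix (or never detected) are unclassified.
    """
    per_gene = (
        matrix.assign(
            detected=matrix["call"] != "not_detected",
            escaping=matrix["call"] == "escaping",
        )
        .groupby("gene_id", sort=False)[["detected", "escaping"]]
        .sum()
    )
    rows = []
    for gene_id, row in per_gene.iterrows():
        detected, escaping = int(row["detected"]), int(row["escaping"])
        if detected == 0:
            category = "unclassified"
        elif (
            detected >= min_studies_detected
            and escaping / detected > constitutive_fraction
        ):
            category = "constitutive"
        elif escaping >= 1:
            category = "facultative"
        else:
            category = "silenced"
        rows.append((gene_id, category))
    out = pd.DataFrame(rows, columns=["gene_id", "category"])
    if genes is not None:
        extra = [g for g in genes if g not in set(out["gene_id"])]
        out = pd.concat(
            [out, pd.DataFrame({"gene_id": extra, "category": "unclassified"})],
            ignore_index=True,
        )
    return out


def annotate_clone_specific(
    calls: pd.DataFrame, categories: pd.DataFrame
) -> pd.DataFrame:
    """Mark local escapees with no literature escape call as clone-specific.

    Genes escaping in the local dataset but unclassified or silenced in the
    meta matrix become clone_specific; every other category is kept.
    """
    local_escapees = set(calls.loc[calls["status"] == "escapee", "gene_id"])
    out = categories.copy()
    flip = out["gene_id"].isin(local_escapees) & out["category"].isin(
        ["unclassified", "silenced"]
    )
    out.loc[flip, "category"] = "clone_specific"
    return out
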