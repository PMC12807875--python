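"""Allelic ratios (Xi fraction), expression filtering and CPM fold changes.

The central quantity is the allelic ratio (d-score) of a gene in a sample,

    r = Xi / (Xi + Xa),

the fraction of haplotype-assigned reads coming from the inactive X. The
sample sheet declares which haplotype is inactive; a ratio is undefined (NaN,
``defined == False``) when a gene has zero allelic coverage in a sample —
never silently zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError


def compute_allelic_ratios(counts: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-(gene, sample) Xi fraction.

    Returns columns gene_id, sample_id, xi_count, xa_count, total, ratio,
    defined. ``ratio`` is NaN where total == 0.
    """
    unknown = set(counts["sample_id"]) - set(sheet["sample_id"])
    if unknown:
        raise IntegrityError(
            f"samples present in counts but not in sample sheet: {sorted(unknown)}"
        )
    xi_hap = sheet.set_index("sample_id")["xi_haplotype"]
    hap = counts["sample_id"].map(xi_hap)
    xi = np.where(hap == "hap1", counts["count_hap1"], counts["count_hap2"])
    xa = np.where(hap == "hap1", counts["count_hap2"], counts["count_hap1"])
    total = xi + xa
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total > 0, xi / np.where(total > 0, total, 1), np.nan)
    return pd.DataFrame({
        "gene_id": counts["gene_id"],
        "sample_id": counts["sample_id"],
        "xi_count": xi.astype(np.int64),
        "xa_count": xa.astype(np.int64),
        "total": total.astype(np.int64),
        "ratio": ratio,
        "defined": total > 0,
    })


def filter_low_expression(
    ratios: pd.DataFrame, min_mean_allelic_count: float = 10.0
) -> tuple[list[str], pd.DataFrame]:
    """Exclude lowly expressed genes.

    A gene is kept when its mean allelic count (xi + xa, averaged over all
    samples of the analysis set) is >= ``min_mean_allelic_count``; genes with
    a mean strictly below the threshold are excluded. Returns the kept gene
    ids (input order) and a table of all genes with their mean count and
    ``filter_flag`` ("pass" / "low_expression").
    """
    if ratios.empty:
        warnings.warn("filter_low_expression: empty input", stacklevel=2)
        return [], pd.DataFrame(
            columns=["gene_id", "mean_allelic_count", "filter_flag"]
        )
    means = ratios.groupby("gene_id", sort=False)["total"].mean()
    table = means.rename("mean_allelic_count").reset_index()
    table["filter_flag"] = np.where(
        table["mean_allelic_count"] >= min_mean_allelic_count,
        "pass", "low_expression",
    )
    kept = table.loc[table["filter_flag"] == "pass", "gene_id"].tolist()
    return kept, table


def aggregate_conditions(ratios: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Average replicate ratios per (gene, condition).

    The mean is the unweighted mean of the *defined* per-replicate ratios
    (matching per-replicate averaging rather than count pooling); conditions
    where no replicate has coverage emit no row. ``mean_allelic_count``
    averages xi + xa over all replicates of the condition.
    """
    condition = sheet.set_index("sample_id")["condition_label"]
    work = ratios.copy()
    work["condition_label"] = work["sample_id"].map(condition)
    defined = work[work["defined"]]
    grouped = defined.groupby(["gene_id", "condition_label"], sort=False)
    out = grouped.agg(
        mean_ratio=("ratio", "mean"),
        n_replicates=("ratio", "size"),
    ).reset_index()
    counts = (
        work.groupby(["gene_id", "condition_label"], sort=False)["total"]
        .mean().rename("mean_allelic_count").reset_index()
    )
    return out.merge(counts, on=["gene_id", "condition_label"], how="left")


def expression_fold_change(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    reference_condition: str = "untreated",
    library_sizes: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Library-size normalised CPM and fold change vs a reference condition.

    cpm = 1e6 * (hap1 + hap2) / library size. By default the library size is
    the total haplotype-assigned count of the sample; externally measured
    totals (e.g. full library sizes) may be supplied instead. The fold change
    divides each sample's CPM by the gene's mean CPM across the reference
    condition's samples.
    """
    condition = sheet.set_index("sample_id")["condition_label"]
    if reference_condition not in set(condition):
        raise ConfigurationError(
            f"reference condition {reference_condition!r} absent from sample sheet"
        )
    total = counts["count_hap1"] + counts["count_hap2"]
    if library_sizes is None:
        libsize = total.groupby(counts["sample_id"]).transform("sum")
    else:
        sizes = pd.Series(library_sizes, dtype=float)
        missing = set(counts["sample_id"]) - set(sizes.index)
        if missing:
            raise ConfigurationError(f"no library size for samples {sorted(missing)}")
        libsize = counts["sample_id"].map(sizes)
    out = pd.DataFrame({
        "gene_id": counts["gene_id"],
        "sample_id": counts["sample_id"],
        "cpm": 1e6 * total / libsize,
    })
    out["condition_label"] = out["sample_id"].map(condition)
    ref_mean = (
        out[out["condition_label"] == reference_condition]
        .groupby("gene_id")["cpm"].mean()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fold_change"] = out["cpm"] / out["gene_id"].map(ref_mean)
    return out.drop(columns="condition_label")
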