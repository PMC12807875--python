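"""Partition escapees into local gene groups by 100-kb start chaining.

Genes are sorted by start position (stable sort; ties keep input order) and
chained left to right: a gene joins the current group while its start is
within the window of the previous gene's start, and a new group begins
whenever the gap exceeds the window. Distances are start-to-start on the
left-most coordinate, strand-agnostic; "within" is inclusive (<= window).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def partition_gene_groups(
    genes, annotation: pd.DataFrame, window: int = 100_000
) -> pd.DataFrame:
    """Chain genes into groups; returns group_id, gene_id, chromosome, start,
    group_size. Genes missing from the annotation are skipped with a warning.
    Chromosomes are partitioned independently (chains never cross them).
    """
    genes = list(genes)
    known = annotation.set_index("gene_id")
    missing = [g for g in genes if g not in known.index]
    if missing:
        warnings.warn(
            f"partition_gene_groups: {len(missing)} unannotated gene(s) "
            f"skipped: {missing[:5]}", stacklevel=2
        )
    kept = [g for g in genes if g in known.index]
    table = pd.DataFrame({
        "gene_id": kept,
        "chromosome": known.loc[kept, "chromosome"].to_numpy(),
        "start": known.loc[kept, "start"].to_numpy(dtype=np.int64),
    })
    table = table.sort_values(["chromosome", "start"], kind="stable")

    group_ids = []
    group_id = 0
    prev_chrom, prev_start = None, None
    for rec in table.itertuples(index=False):
        if prev_chrom != rec.chromosome or rec.start - prev_start > window:
            group_id += 1
        group_ids.append(group_id)
        prev_chrom, prev_start = rec.chromosome, rec.start
    table["group_id"] = group_ids
    sizes = table.groupby("group_id")["gene_id"].transform("size")
    table["group_size"] = sizes
    return table[["group_id", "gene_id", "chromosome", "start",
                  "group_size"]].reset_index(drop=True)


def summarize_groups(groups: pd.DataFrame) -> dict:
    """Counts of multi-gene groups (>= 3 members) and singles/pairs."""
    if groups.empty:
        return {"n_groups": 0, "n_groups_ge3": 0, "n_singles_or_pairs": 0,
                "min_size": 0, "max_size": 0}
    sizes = groups.groupby("group_id")["gene_id"].size()
    return {
        "n_groups": int(len(sizes)),
        "n_groups_ge3": int((sizes >= 3).sum()),
        "n_singles_or_pairs": int((sizes <= 2).sum()),
        "min_size": int(sizes.min()),
        "max_size": int(sizes.max()),
    }
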