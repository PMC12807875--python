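"""Readers and writers for the tabular formats the pipeline consumes.

All tables are tab-separated UTF-8 text with a header line; lines starting
with ``#`` are comments. Genomic coordinates are held internally in the
1-based closed convention of GTF; BED input (0-based half-open) is converted
at the boundary.

In-memory containers are plain :class:`pandas.DataFrame` objects with
validated column sets:

``AllelicCountTable``
    gene_id, sample_id, count_hap1, count_hap2, chromosome
``SampleSheet``
    sample_id, dox_days, washout_days, auxin, replicate, xi_haplotype,
    condition_label (always re-derived, never free-typed)
``GeneAnnotation``
    gene_id, chromosome, start, end, strand
``StudyMatrix``
    gene_id, study_id, call in {escaping, silenced, not_detected}
"""

from __future__ import annotations

import re
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

COUNT_COLUMNS = ["gene_id", "sample_id", "count_hap1", "count_hap2"]
SHEET_COLUMNS = [
    "sample_id", "dox_days", "washout_days", "auxin", "replicate",
    "xi_haplotype",
]
ANNOTATION_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand"]
STUDY_CALLS = {"escaping", "silenced", "not_detected"}
HAPLOTYPES = {"hap1", "hap2"}

_WIDE_SUFFIX = re.compile(r"^(?P<sample>.+)_(?P<hap>hap[12])$")


# ---------------------------------------------------------------------------
# generic helpers

def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.ParserError as exc:  # malformed row geometry
        raise FormatError(f"{path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def _to_count(series: pd.Series, name: str) -> pd.Series:
    values = pd.to_numeric(series, errors="coerce")
    if values.isna().any():
        bad = series[values.isna()].iloc[0]
        raise IntegrityError(f"column {name!r}: non-numeric count {bad!r}")
    if (values < 0).any():
        bad = values[values < 0].iloc[0]
        raise IntegrityError(f"column {name!r}: negative count {bad}")
    if (values % 1 != 0).any():
        bad = values[values % 1 != 0].iloc[0]
        raise IntegrityError(f"column {name!r}: non-integer count {bad}")
    return values.astype(np.int64)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# condition labels

def _fmt_days(days: float) -> str:
    return str(int(days)) if float(days) == int(days) else str(float(days))


def condition_label(dox_days: float, washout_days: float = 0.0,
                    auxin: bool = False) -> str:
    """Deterministic condition label from the treatment design.

    ``untreated`` when nothing was applied; otherwise the Dox duration,
    washout duration and auxin flag are encoded in a fixed order, e.g.
    ``dox14d_wo7d`` or ``dox3d_aux``.
    """
    parts = []
    if float(dox_days) > 0:
        parts.append(f"dox{_fmt_days(dox_days)}d")
    if float(washout_days) > 0:
        parts.append(f"wo{_fmt_days(washout_days)}d")
    if bool(auxin):
        parts.append("aux")
    return "_".join(parts) if parts else "untreated"


# ---------------------------------------------------------------------------
# allelic count tables

def validate_allelic_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an allelic count table (long layout)."""
    _require_columns(df, COUNT_COLUMNS, "allelic count table")
    out = df.copy()
    if "chromosome" not in out.columns:
        out["chromosome"] = "X"
    out["count_hap1"] = _to_count(out["count_hap1"], "count_hap1")
    out["count_hap2"] = _to_count(out["count_hap2"], "count_hap2")
    duplicated = out.duplicated(subset=["gene_id", "sample_id"])
    if duplicated.any():
        pair = out.loc[duplicated, ["gene_id", "sample_id"]].iloc[0]
        raise IntegrityError(
            f"duplicate (gene, sample) pair: ({pair.gene_id}, {pair.sample_id})"
        )
    return out[COUNT_COLUMNS + ["chromosome"]].reset_index(drop=True)


def _wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    id_cols = [c for c in ("gene_id", "chromosome") if c in df.columns]
    if "gene_id" not in id_cols:
        raise FormatError("wide count table: missing required column(s) ['gene_id']")
    pairs: dict[str, dict[str, str]] = {}
    for col in df.columns:
        if col in id_cols:
            continue
        match = _WIDE_SUFFIX.match(col)
        if match is None:
            raise FormatError(
                f"wide count table: column {col!r} is not <sample>_hap1/2"
            )
        pairs.setdefault(match["sample"], {})[match["hap"]] = col
    rows = []
    for sample, haps in pairs.items():
        if set(haps) != HAPLOTYPES:
            raise FormatError(
                f"wide count table: sample {sample!r} lacks one haplotype column"
            )
        block = df[id_cols].copy()
        block["sample_id"] = sample
        block["count_hap1"] = df[haps["hap1"]].values
        block["count_hap2"] = df[haps["hap2"]].values
        rows.append(block)
    long_df = pd.concat(rows, ignore_index=True)
    # gene-major order, samples in column order: matches the long dialect
    order = {g: i for i, g in enumerate(df["gene_id"])}
    long_df["__g"] = long_df["gene_id"].map(order)
    sample_order = {s: i for i, s in enumerate(pairs)}
    long_df["__s"] = long_df["sample_id"].map(sample_order)
    long_df = long_df.sort_values(["__g", "__s"], kind="stable")
    return long_df.drop(columns=["__g", "__s"]).reset_index(drop=True)


def read_allelic_counts(path, format: str = "long_tsv") -> pd.DataFrame:
    """Read a haplotype-resolved count table.

    ``long_tsv`` has one row per (gene, sample); ``wide_tsv`` has one row per
    gene and paired ``<sample>_hap1`` / ``<sample>_hap2`` columns. Both parse
    to the identical long internal layout.
    """
    df = _read_tsv(path)
    if format == "long_tsv":
        return validate_allelic_counts(df)
    if format == "wide_tsv":
        return validate_allelic_counts(_wide_to_long(df))
    raise FormatError(f"unknown count table format: {format!r}")


def write_allelic_counts(df: pd.DataFrame, path, format: str = "long_tsv") -> None:
    if format == "long_tsv":
        write_tsv(df, path)
        return
    if format == "wide_tsv":
        wide = df.pivot(index=["gene_id", "chromosome"], columns="sample_id",
                        values=["count_hap1", "count_hap2"])
        if wide.isna().any().any():
            raise IntegrityError(
                "wide count output requires a complete gene x sample grid"
            )
        wide = wide.astype(np.int64)
        wide.columns = [f"{sample}_{hap.split('_')[1]}"
                        for hap, sample in wide.columns]
        wide = wide.reindex(sorted(wide.columns), axis=1).reset_index()
        write_tsv(wide, path)
        return
    raise FormatError(f"unknown count table format: {format!r}")


# ---------------------------------------------------------------------------
# sample sheets

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _to_bool(series: pd.Series, name: str) -> pd.Series:
    lowered = series.fillna("").astype(str).str.strip().str.lower()
    unknown = ~(lowered.isin(_TRUE) | lowered.isin(_FALSE))
    if unknown.any():
        raise FormatError(f"column {name!r}: unrecognised boolean "
                          f"{series[unknown].iloc[0]!r}")
    return lowered.isin(_TRUE)


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, SHEET_COLUMNS, "sample sheet")
    out = df.copy()
    out["dox_days"] = pd.to_numeric(out["dox_days"])
    out["washout_days"] = pd.to_numeric(out["washout_days"])
    out["replicate"] = pd.to_numeric(out["replicate"]).astype(int)
    out["auxin"] = _to_bool(out["auxin"], "auxin")
    if (out["dox_days"] < 0).any() or (out["washout_days"] < 0).any():
        raise IntegrityError("treatment durations must be non-negative")
    bad_hap = ~out["xi_haplotype"].isin(HAPLOTYPES)
    if bad_hap.any():
        raise FormatError(
            f"unknown xi_haplotype value {out.loc[bad_hap, 'xi_haplotype'].iloc[0]!r}"
        )
    if out["sample_id"].duplicated().any():
        dup = out.loc[out["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise IntegrityError(f"duplicate sample_id: {dup!r}")
    if out["xi_haplotype"].nunique() > 1:
        raise IntegrityError("xi_haplotype must be constant within one series")
    out["condition_label"] = [
        condition_label(d, w, a)
        for d, w, a in zip(out["dox_days"], out["washout_days"], out["auxin"])
    ]
    return out[SHEET_COLUMNS + ["condition_label"]].reset_index(drop=True)


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(_read_tsv(path))


# ---------------------------------------------------------------------------
# gene annotation (GTF / BED)

_STRANDS = {"+": "+", "-": "-"}


def _prescan_lines(path, min_fields: int, int_fields: tuple[int, ...],
                   what: str) -> None:
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            if what == "BED" and stripped.startswith(("track", "browser")):
                continue
            fields = stripped.split("\t")
            if len(fields) < min_fields:
                raise FormatError(
                    f"{what} line {lineno}: expected >= {min_fields} fields, "
                    f"got {len(fields)}"
                )
            for idx in int_fields:
                try:
                    int(fields[idx])
                except ValueError:
                    raise FormatError(
                        f"{what} line {lineno}: field {idx + 1} is not an "
                        f"integer ({fields[idx]!r})"
                    ) from None


def _finalize_annotation(df: pd.DataFrame) -> pd.DataFrame:
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise IntegrityError(f"duplicate gene_id in annotation: {dup!r}")
    if (df["start"] > df["end"]).any():
        raise IntegrityError("annotation has start > end")
    df["strand"] = df["strand"].map(_STRANDS).fillna("unknown")
    return df[ANNOTATION_COLUMNS].reset_index(drop=True)


def read_gene_annotation(path, format: str = "gtf") -> pd.DataFrame:
    """Read gene coordinates from GTF or BED6.

    GTF ``gene`` features are used directly (GTF is already 1-based closed);
    BED is converted from 0-based half-open: start -> chromStart + 1,
    end -> chromEnd.
    """
    import pyranges as pr

    path = str(path)
    if format == "gtf":
        _prescan_lines(path, min_fields=9, int_fields=(3, 4), what="GTF")
        ranges = pr.read_gtf(path).df
        if "Feature" in ranges.columns:
            genes = ranges[ranges["Feature"] == "gene"].copy()
            if genes.empty:
                genes = ranges.copy()
        else:
            genes = ranges.copy()
        if "gene_id" not in genes.columns:
            raise FormatError("GTF: no gene_id attribute found")
        out = pd.DataFrame({
            "gene_id": genes["gene_id"].astype(str),
            "chromosome": genes["Chromosome"].astype(str),
            "start": genes["Start"].astype(np.int64) + 1,  # pyranges is 0-based
            "end": genes["End"].astype(np.int64),
            "strand": genes.get("Strand", pd.Series(["unknown"] * len(genes))).astype(str),
        })
        return _finalize_annotation(out)
    if format == "bed":
        _prescan_lines(path, min_fields=4, int_fields=(1, 2), what="BED")
        ranges = pr.read_bed(path).df
        if "Name" not in ranges.columns:
            raise FormatError("BED: gene names require at least 4 columns")
        out = pd.DataFrame({
            "gene_id": ranges["Name"].astype(str),
            "chromosome": ranges["Chromosome"].astype(str),
            "start": ranges["Start"].astype(np.int64) + 1,
            "end": ranges["End"].astype(np.int64),
            "strand": ranges.get("Strand", pd.Series(["unknown"] * len(ranges))).astype(str),
        })
        return _finalize_annotation(out)
    raise FormatError(f"unknown annotation format: {format!r}")


def write_gene_annotation_bed(df: pd.DataFrame, path) -> None:
    """Write the internal 1-based annotation back out as BED6."""
    bed = pd.DataFrame({
        "chrom": df["chromosome"],
        "chromStart": df["start"] - 1,
        "chromEnd": df["end"],
        "name": df["gene_id"],
        "score": 0,
        "strand": df["strand"].map(lambda s: s if s in _STRANDS else "."),
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# literature study matrix

def validate_study_matrix(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ["gene_id", "study_id", "call"], "study matrix")
    out = df.copy()
    bad = ~out["call"].isin(STUDY_CALLS)
    if bad.any():
        raise FormatError(f"unknown study call {out.loc[bad, 'call'].iloc[0]!r}")
    if out.duplicated(subset=["gene_id", "study_id"]).any():
        raise IntegrityError("duplicate (gene, study) pair in study matrix")
    return out[["gene_id", "study_id", "call"]].reset_index(drop=True)


def read_study_matrix(path) -> pd.DataFrame:
    return validate_study_matrix(_read_tsv(path))
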