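"""Readers and writers for the pipeline's tab/comma-separated formats.

Formats
-------
* Expression TSV: first column ``gene_id``, remaining columns sample ids,
  strictly positive linear intensities.
* Metadata TSV: ``sample_id``, ``tissue`` (NC|AdC|SCC), ``subject_id``.
* Annotation TSV: ``gene_id``, ``catalytic`` (0|1), ``classes``
  (semicolon-separated subset of sugar/amino-acid/nucleotide/energy).
* Isotopologue CSV (long): ``sample_id, subject_id, tissue, tracer,
  metabolite, n_c, n_n, mass_shift, intensity``.

All readers validate the schema and raise :class:`SchemaError` naming the
file and the offending column.  Writers emit a fixed float format so reruns
are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .signature import ExpressionCohort

__all__ = [
    "SchemaError",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_cohort",
    "write_cohort",
    "read_annotation",
    "write_annotation",
    "read_isotopologues",
    "write_isotopologues",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.10g"


class SchemaError(ValueError):
    """A file does not match its documented schema."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise SchemaError(f"{path}: first column must be 'gene_id', "
                          f"got {df.columns[0]!r}")
    df = df.set_index("gene_id")
    if df.shape[1] == 0:
        raise SchemaError(f"{path}: no sample columns")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric expression value ({exc})")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id", "tissue"], path)
    if "subject_id" not in df.columns:
        df["subject_id"] = df["sample_id"]
    return df.set_index("sample_id")


def write_metadata(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_cohort(expression_path, metadata_path) -> ExpressionCohort:
    matrix = read_expression(expression_path)
    metadata = read_metadata(metadata_path)
    try:
        return ExpressionCohort(matrix=matrix, metadata=metadata)
    except ValueError as exc:
        raise SchemaError(
            f"{expression_path} + {metadata_path}: {exc}"
        ) from exc


def write_cohort(cohort: ExpressionCohort, expression_path, metadata_path
                 ) -> None:
    write_expression(cohort.matrix, expression_path)
    write_metadata(cohort.metadata, metadata_path)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    _require_columns(df, ["gene_id", "catalytic", "classes"], path)
    return df.set_index("gene_id")


def write_annotation(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


ISOTOPOLOGUE_COLUMNS = [
    "sample_id", "subject_id", "tissue", "tracer", "metabolite",
    "n_c", "n_n", "mass_shift", "intensity",
]


def read_isotopologues(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ISOTOPOLOGUE_COLUMNS, path)
    for col in ("n_c", "n_n", "mass_shift"):
        try:
            df[col] = df[col].astype(int)
        except ValueError as exc:
            raise SchemaError(f"{path}: column {col!r} must be integer "
                              f"({exc})")
    df["intensity"] = df["intensity"].astype(float)
    if (df["intensity"] < 0).any():
        raise SchemaError(f"{path}: negative intensity values")
    bad = set(df["tissue"]) - {"NC", "AdC", "SCC"}
    if bad:
        raise SchemaError(f"{path}: unknown tissue class(es) {sorted(bad)}")
    return df


def write_isotopologues(df: pd.DataFrame, path) -> None:
    df[ISOTOPOLOGUE_COLUMNS].to_csv(path, index=False,
                                    float_format=FLOAT_FORMAT)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
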