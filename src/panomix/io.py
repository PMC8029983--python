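"""Readers and writers for the pipeline's tabular formats.

All formats are plain TSV (gzip accepted transparently via the ``.gz``
suffix): expression/beta matrices with a feature-id first column, a clinical
sample sheet, a minimal three-column mutation table, a GISTIC-style
thresholded gene x sample copy-number table, a two-column CpG->gene map, and
Broad-dialect GMT pathway files.  Missing methylation beta values are the
literal string ``NA``.  Every reader validates its contract and raises
:class:`~panomix.exceptions.FormatError` rather than coercing silently.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CNV_ALPHABET, ExpressionMatrix, GeneSetCollection, NORMAL, TUMOR
from .exceptions import FormatError

_STAGES = {"I", "II", "III", "IV"}
_N_STATUS = {"N0", "N+", "NX"}
_M_STATUS = {"M0", "M+", "MX"}

#: variant classifications dropped by the non-synonymous filter
SILENT_CLASSES = frozenset(
    {
        "silent",
        "synonymous",
        "synonymous_variant",
        "3'utr",
        "5'utr",
        "3'flank",
        "5'flank",
        "intron",
        "igr",
        "rna",
        "splice_region",
    }
)


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    # pandas infers gzip from the .gz suffix
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, **kw)


def read_matrix(path: str | Path, kind: str) -> ExpressionMatrix:
    """Read a feature x sample TSV matrix.

    The first column holds gene/CpG/miRNA identifiers and the header row the
    sample ids.  ``kind`` selects validation: ``counts`` must be nonnegative
    integers, ``beta`` must lie in [0, 1] with ``NA`` allowed, ``array`` and
    ``mirna`` must be complete numeric matrices.
    """
    df = _read_tsv(path, index_col=0)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    return ExpressionMatrix(df, kind=kind)


def write_matrix(matrix: ExpressionMatrix | pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    df.to_csv(path, sep="\t", na_rep="NA", index_label=index_label)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index=index, index_label=index_label)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate the clinical sample sheet.

    Required columns: ``sample_id`` (unique) and ``group`` (tumor/normal).
    Optional closed-vocabulary columns: ``stage`` (I-IV), ``n_status``
    (N0/N+/NX), ``m_status`` (M0/M+/MX).  Any pair of columns
    ``<endpoint>_time`` / ``<endpoint>_event`` defines a right-censored
    endpoint (time in days, event 0/1); within a row the event flag must be
    present exactly when the time is.  Optional covariates: ``afp`` (ng/mL),
    ``tumor_size`` (cm), ``tnm`` (ordinal), ``batch``.
    """
    df = _read_tsv(path)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"sample sheet missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in sample sheet")
    bad = set(df["group"]) - {TUMOR, NORMAL}
    if bad:
        raise FormatError(f"unknown group labels: {sorted(bad)}")
    for col, vocab in (("stage", _STAGES), ("n_status", _N_STATUS), ("m_status", _M_STATUS)):
        if col in df.columns:
            vals = set(df[col].dropna().astype(str)) - vocab
            if vals:
                raise FormatError(f"unknown {col} values: {sorted(vals)}")
    for col in df.columns:
        if col.endswith("_time"):
            ev = col[: -len("_time")] + "_event"
            if ev not in df.columns:
                raise FormatError(f"endpoint column {col!r} lacks paired {ev!r}")
            t = pd.to_numeric(df[col])
            e = pd.to_numeric(df[ev])
            if (t.notna() != e.notna()).any():
                raise FormatError(f"event flag must accompany time for endpoint {col!r}")
            if (t.dropna() < 0).any():
                raise FormatError(f"negative time in {col!r}")
            if not set(e.dropna().unique()) <= {0, 1}:
                raise FormatError(f"event flags in {ev!r} must be 0/1")
    for col in ("afp", "tumor_size"):
        if col in df.columns and (pd.to_numeric(df[col]).dropna() < 0).any():
            raise FormatError(f"negative values in {col!r}")
    return df.set_index("sample_id")


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index=True, index_label="sample_id")


def read_mutations(path: str | Path, nonsyn_only: bool = True) -> pd.DataFrame:
    """Read a minimal mutation table (columns gene, sample, classification).

    With ``nonsyn_only`` (the default) rows whose variant classification is
    silent/synonymous or non-coding are removed, leaving only protein-altering
    classes.
    """
    df = _read_tsv(path, dtype=str)
    for col in ("gene", "sample", "classification"):
        if col not in df.columns:
            raise FormatError(f"mutation table missing required column {col!r}")
    if nonsyn_only and len(df):
        keep = ~df["classification"].str.lower().isin(SILENT_CLASSES)
        df = df.loc[keep].reset_index(drop=True)
    return df


def read_cnv(path: str | Path) -> pd.DataFrame:
    """Read a GISTIC-style thresholded gene x sample copy-number table.

    Calls must come from the discrete alphabet {-2, -1, 0, 1, 2}.
    """
    df = _read_tsv(path, index_col=0)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric CNV call: {exc}") from exc
    if df.isna().any().any():
        raise FormatError("missing CNV calls are not allowed")
    bad = set(np.unique(df.to_numpy())) - set(CNV_ALPHABET)
    if bad:
        raise FormatError(f"CNV calls outside {{-2..2}}: {sorted(bad)}")
    return df.astype(int)


def read_cpg_map(path: str | Path) -> pd.Series:
    """Read a two-column (cpg_id, gene) map; every CpG maps to one gene."""
    df = _read_tsv(path, dtype=str)
    for col in ("cpg_id", "gene"):
        if col not in df.columns:
            raise FormatError(f"CpG map missing column {col!r}")
    if df["cpg_id"].duplicated().any():
        raise FormatError("CpG mapped to multiple genes")
    return df.set_index("cpg_id")["gene"]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name <tab> description <tab> genes...

    Gene symbols are deduplicated within each set; duplicate set names and
    lines with fewer than three fields are errors.
    """
    sets: dict[str, frozenset[str]] = {}
    opener = __import__("gzip").open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"duplicate gene set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line list (e.g. a miRNA target list)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for g in genes:
            fh.write(f"{g}\n")
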