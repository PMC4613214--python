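"""Reading and writing the package's tabular formats.

Supported layouts for Cq tables:

* **long** — columns ``gene, sample, tissue, condition, bio_rep, tech_rep,
  cq`` (``tech_rep`` optional); one row per well.
* **wide** — first column ``gene``, remaining columns are sample ids; a
  sidecar annotation table maps ``sample`` to ``tissue, condition,
  bio_rep[, tech_rep]``.

Conventions: UTF-8, dot decimals regardless of locale, ``NA``/empty cells
mean missing, lines starting with ``#`` are comments (used for provenance
headers).  Row numbers in error messages count the header as row 1.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable

import pandas as pd

from .core import (
    CqDataset,
    EfficiencyTable,
    FormatError,
    IntegrityError,
    ParseError,
    PreconditionError,
    QuantityMatrix,
)

NA_TOKENS = {"", "NA", "NaN", "nan", "na", "N/A", "null"}


def _sep_for(path, fmt: str | None) -> str:
    if fmt == "tsv":
        return "\t"
    if fmt == "csv":
        return ","
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _read_raw(path, fmt: str | None) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=_sep_for(path, fmt),
        dtype=str,
        keep_default_na=False,
        comment="#",
        skip_blank_lines=True,
        encoding="utf-8",
    )


def _parse_numeric(col: pd.Series, name: str) -> pd.Series:
    # float() is correctly rounded (unlike pandas' C parser), so values
    # written by write_table round-trip bit-exactly
    raw = col.str.strip()
    values = []
    for idx, text in raw.items():
        if text in NA_TOKENS:
            values.append(float("nan"))
            continue
        try:
            values.append(float(text))
        except ValueError:
            raise ParseError(
                f"non-numeric {name} value {text!r} at row {int(idx) + 2} "
                "(header counted as row 1)"
            ) from None
    return pd.Series(values, index=col.index, dtype=float)


def read_cq_table(path, layout: str = "long", annotations=None, fmt: str | None = None) -> CqDataset:
    """Read a Cq table from CSV/TSV and return a validated :class:`CqDataset`.

    ``layout='wide'`` requires ``annotations``: a path to the sample
    annotation table.  Blank/NA Cq cells become missing values.
    """
    if layout not in ("long", "wide"):
        raise PreconditionError(f"layout must be 'long' or 'wide', got {layout!r}")
    if layout == "long":
        df = _read_raw(path, fmt)
        required = ["gene", "sample", "tissue", "condition", "bio_rep", "cq"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError("missing required column(s): " + ", ".join(missing))
        df["cq"] = _parse_numeric(df["cq"], "cq")
        return CqDataset(df)

    if annotations is None:
        raise PreconditionError("wide layout requires a sample annotation table")
    mat = _read_raw(path, fmt)
    if mat.shape[1] < 2:
        raise FormatError("wide table needs a gene column plus sample columns")
    gene_col = mat.columns[0]
    long = mat.melt(id_vars=[gene_col], var_name="sample", value_name="cq")
    long = long.rename(columns={gene_col: "gene"})
    ann = _read_raw(annotations, fmt)
    required = ["sample", "tissue", "condition", "bio_rep"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise FormatError(
            "annotation table missing column(s): " + ", ".join(missing)
        )
    unannotated = set(long["sample"]) - set(ann["sample"])
    if unannotated:
        raise FormatError(
            "sample(s) without annotations: " + ", ".join(sorted(unannotated))
        )
    long = long.merge(ann, on="sample", how="left")
    long["cq"] = _parse_numeric(long["cq"], "cq")
    return CqDataset(long)


def read_efficiency_table(path, fmt: str | None = None) -> EfficiencyTable:
    """Read a per-gene efficiency table (columns ``gene, efficiency``)."""
    df = _read_raw(path, fmt)
    missing = [c for c in ("gene", "efficiency") if c not in df.columns]
    if missing:
        raise FormatError("missing required column(s): " + ", ".join(missing))
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise IntegrityError(f"duplicate efficiency entry for gene {dup!r}")
    eff = _parse_numeric(df["efficiency"], "efficiency")
    if eff.isna().any():
        gene = df.loc[eff.isna(), "gene"].iloc[0]
        raise ParseError(f"missing efficiency for gene {gene!r}")
    return EfficiencyTable(dict(zip(df["gene"], eff)))


def write_table(obj, path, fmt: str | None = None, header_comments: Iterable[str] = ()) -> None:
    """Write a package result to CSV/TSV with deterministic ordering.

    * :class:`CqDataset` — long layout, rows sorted by gene then sample
      annotations; missing Cq written as ``NA`` (lossless round trip).
    * ranking/score tables (any DataFrame with a ``rank`` column) — rows
      sorted by rank ascending.
    * other DataFrames — written as-is, without the index.
    * dataclass results with a tabular attribute are not auto-converted;
      pass their ``.ranking`` / table attribute instead.

    ``header_comments`` lines are prefixed with ``"# "`` above the header.
    """
    if isinstance(obj, CqDataset):
        sort_cols = ["gene", "tissue", "condition", "bio_rep"]
        if obj.has_tech_reps:
            sort_cols.append("tech_rep")
        df = obj.data.sort_values(sort_cols, kind="mergesort")
    elif isinstance(obj, QuantityMatrix):
        df = obj.quantities.rename_axis("gene").reset_index()
    elif isinstance(obj, pd.DataFrame):
        df = obj
        if "rank" in df.columns:
            df = df.sort_values("rank", kind="mergesort")
    elif isinstance(obj, pd.Series):
        df = obj.rename_axis(obj.index.name or "key").reset_index()
    elif dataclasses.is_dataclass(obj) and hasattr(obj, "ranking"):
        df = obj.ranking.sort_values("rank", kind="mergesort")
    else:
        raise PreconditionError(
            f"don't know how to serialize objects of type {type(obj).__name__}"
        )
    sep = _sep_for(path, fmt)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, sep=sep, na_rep="NA")
    # fsync not needed; an unwritable path raises OSError from open() above
    assert os.path.exists(path)
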