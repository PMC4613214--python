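"""Core data model for RT-qPCR quantification-cycle (Cq) data.

A Cq value is the PCR cycle at which a well's fluorescence crosses the
detection threshold; lower Cq means more template.  One cycle corresponds
to a factor of E in abundance, where E is the gene's amplification
efficiency (2.0 = perfect doubling per cycle).

The central container is :class:`CqDataset`, a long-format table with one
row per well, annotated with tissue, condition (e.g. a treatment time
point), biological replicate and, optionally, technical replicate.  The
``sample`` column is the unique per-well identifier; the biological sample
is identified by ``(tissue, condition, bio_rep)``.

Transformations provided here:

* :func:`average_technical_replicates` — collapse wells to biological
  samples by arithmetic mean on the Cq scale.
* :func:`to_quantities` — efficiency-corrected relative quantities
  ``q = E^-(Cq - min Cq)``, anchored so each gene's maximum quantity is 1.
* :func:`summarize` — per-gene descriptive statistics (mean, SD, range in
  cycles) computed over condition means, i.e. describing treatment-driven
  change rather than replicate scatter.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

CQ_LOWER = 0.0
CQ_UPPER = 45.0
REQUIRED_COLUMNS = ("gene", "sample", "tissue", "condition", "bio_rep", "cq")

#: Typical range for per-cycle amplification factors; values outside it are
#: suspicious (E < 1.6 suggests poor assays, E > 2.2 is physically implausible).
EFFICIENCY_TYPICAL_RANGE = (1.6, 2.2)


class RefstabError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RefstabError):
    """A table is structurally malformed (e.g. a required column is missing)."""


class ParseError(RefstabError):
    """A cell could not be parsed as the expected type."""


class IntegrityError(RefstabError):
    """Data violate a dataset invariant (duplicates, out-of-range values...)."""


class PreconditionError(RefstabError):
    """An operation was called on inputs that do not meet its preconditions."""


def _require_nonempty_labels(df: pd.DataFrame, col: str) -> None:
    bad = df[col].isin(("", "nan", "NA", "None"))
    if bad.any():
        raise IntegrityError(f"column {col!r} contains empty/missing labels")


@dataclasses.dataclass(frozen=True)
class CqDataset:
    """Annotated gene x sample matrix of quantification cycles.

    ``data`` holds one row per well with columns ``gene``, ``sample``,
    ``tissue``, ``condition``, ``bio_rep``, ``cq`` and optionally
    ``tech_rep``.  Invariants enforced at construction:

    * every present Cq is finite and inside the open interval (0, 45);
      missing wells are NaN,
    * (gene, sample) pairs are unique; at least 2 genes and 2 samples,
    * every sample carries consistent tissue/condition annotations and
      positive integer replicate indices.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(
                "missing required column(s): " + ", ".join(missing)
            )
        for col in ("gene", "sample", "tissue", "condition"):
            df[col] = df[col].astype(str)
            _require_nonempty_labels(df, col)
        rep_cols = ["bio_rep"] + (["tech_rep"] if "tech_rep" in df.columns else [])
        for col in rep_cols:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any() or (vals <= 0).any() or (vals != vals.round()).any():
                raise IntegrityError(f"column {col!r} must hold positive integers")
            df[col] = vals.astype(int)
        if not pd.api.types.is_numeric_dtype(df["cq"]):
            df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
        df["cq"] = df["cq"].astype(float)
        present = df["cq"].dropna()
        if len(present) and (
            (~np.isfinite(present.to_numpy())).any()
            or (present <= CQ_LOWER).any()
            or (present >= CQ_UPPER).any()
        ):
            raise IntegrityError(
                f"Cq values must be finite and in the open interval "
                f"({CQ_LOWER:g}, {CQ_UPPER:g})"
            )
        dup = df.duplicated(subset=["gene", "sample"])
        if dup.any():
            g, s = df.loc[dup.idxmax(), ["gene", "sample"]]
            raise IntegrityError(f"duplicate (gene, sample) pair: ({g!r}, {s!r})")
        if df["gene"].nunique() < 2 or df["sample"].nunique() < 2:
            raise IntegrityError("a dataset needs at least 2 genes and 2 samples")
        ann_cols = ["tissue", "condition", "bio_rep"]
        if "tech_rep" in df.columns:
            ann_cols.append("tech_rep")
        if (df.groupby("sample")[ann_cols].nunique() > 1).any().any():
            raise IntegrityError("inconsistent annotations for the same sample id")
        keep = list(REQUIRED_COLUMNS[:-1])
        if "tech_rep" in df.columns:
            keep.append("tech_rep")
        keep.append("cq")
        object.__setattr__(self, "data", df[keep].reset_index(drop=True))

    # -- basic views ---------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.data["sample"]))

    @property
    def tissues(self) -> list[str]:
        return list(pd.unique(self.data["tissue"]))

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.data["condition"]))

    @property
    def has_tech_reps(self) -> bool:
        return "tech_rep" in self.data.columns

    def subset(self, genes=None, tissue: str | None = None) -> "CqDataset":
        """Restrict to the given genes and/or one tissue."""
        df = self.data
        if tissue is not None:
            if tissue not in self.tissues:
                raise PreconditionError(f"unknown tissue {tissue!r}")
            df = df[df["tissue"] == tissue]
        if genes is not None:
            genes = [str(g) for g in genes]
            unknown = set(genes) - set(df["gene"])
            if unknown:
                raise PreconditionError(
                    "unknown gene(s): " + ", ".join(sorted(unknown))
                )
            df = df[df["gene"].isin(genes)]
        return CqDataset(df.reset_index(drop=True))

    def pivot(self) -> pd.DataFrame:
        """Gene x sample matrix of Cq values (genes sorted, samples in
        order of first appearance)."""
        wide = self.data.pivot(index="gene", columns="sample", values="cq")
        return wide.reindex(index=self.genes, columns=self.samples)

    def sample_info(self) -> pd.DataFrame:
        """Per-sample annotations, indexed by sample id."""
        cols = ["tissue", "condition", "bio_rep"]
        if self.has_tech_reps:
            cols.append("tech_rep")
        info = self.data.drop_duplicates("sample").set_index("sample")[cols]
        return info.reindex(self.samples)

    def equals(self, other: "CqDataset") -> bool:
        """Value equality up to row order (Cq compared exactly, NaN == NaN)."""
        if not isinstance(other, CqDataset):
            return False
        if set(self.data.columns) != set(other.data.columns):
            return False
        key = ["gene", "sample"]
        a = self.data.sort_values(key, kind="mergesort").reset_index(drop=True)
        b = other.data.sort_values(key, kind="mergesort").reset_index(drop=True)
        b = b[a.columns]
        if not a.drop(columns="cq").equals(b.drop(columns="cq")):
            return False
        ca, cb = a["cq"].to_numpy(), b["cq"].to_numpy()
        both_nan = np.isnan(ca) & np.isnan(cb)
        return bool(np.all(both_nan | (ca == cb)))


@dataclasses.dataclass
class EfficiencyTable:
    """Per-gene amplification factor E (fold amplification per cycle).

    E is the base of the exponential, matching the scale on which standard
    curves report it (1.9-2.1 for good assays), not a percent efficiency.
    Genes without an entry fall back to perfect doubling (E = 2.0) with a
    warning.
    """

    values: Mapping[str, float]
    default: float = 2.0

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        lo, hi = EFFICIENCY_TYPICAL_RANGE
        for gene, e in dict(self.values).items():
            e = float(e)
            if not np.isfinite(e) or e <= 1.0:
                raise IntegrityError(
                    f"amplification factor for {gene!r} must exceed 1, got {e!r}"
                )
            if not lo <= e <= hi:
                warnings.warn(
                    f"amplification factor {e:g} for {gene!r} is outside the "
                    f"typical range [{lo}, {hi}]",
                    stacklevel=2,
                )
            clean[str(gene)] = e
        self.values = clean

    def get(self, gene: str) -> float:
        if gene not in self.values:
            warnings.warn(
                f"no amplification factor for {gene!r}; assuming perfect "
                f"doubling (E = {self.default})",
                stacklevel=2,
            )
            return self.default
        return self.values[gene]

    def vector(self, genes) -> np.ndarray:
        return np.array([self.get(g) for g in genes], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": sorted(self.values), "efficiency": [self.values[g] for g in sorted(self.values)]}
        )


@dataclasses.dataclass(frozen=True)
class QuantityMatrix:
    """Efficiency-transformed relative quantities q = E^-(Cq - anchor).

    The anchor is each gene's minimum observed Cq, so q lies in (0, 1] and
    each gene's maximum over samples is exactly 1.
    """

    quantities: pd.DataFrame  # genes x samples
    anchor_cq: pd.Series  # per-gene Cq at which q == 1
    sample_info: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.quantities.index)

    @property
    def samples(self) -> list[str]:
        return list(self.quantities.columns)


def average_technical_replicates(ds: CqDataset) -> CqDataset:
    """Collapse technical replicates to one Cq per biological sample.

    The arithmetic mean of the present technical replicates is used;
    biological samples whose replicates are all missing stay missing.
    New sample ids are ``tissue:condition:b<bio_rep>``.  Datasets without
    a ``tech_rep`` column are returned unchanged.
    """
    if not ds.has_tech_reps:
        return ds
    grouped = (
        ds.data.groupby(["gene", "tissue", "condition", "bio_rep"], as_index=False)[
            "cq"
        ].mean()
    )
    grouped["sample"] = (
        grouped["tissue"]
        + ":"
        + grouped["condition"]
        + ":b"
        + grouped["bio_rep"].astype(str)
    )
    return CqDataset(grouped[["gene", "sample", "tissue", "condition", "bio_rep", "cq"]])


def to_quantities(ds: CqDataset, eff: EfficiencyTable) -> QuantityMatrix:
    """Transform Cq values into relative quantities ``q = E^-(Cq - min Cq)``.

    The dataset must already be collapsed to one well per biological
    sample (see :func:`average_technical_replicates`).  The sample with
    the lowest Cq of each gene gets q = 1 exactly; one cycle above the
    anchor gives q = 1/E.
    """
    if ds.has_tech_reps:
        per_bio = ds.data.groupby(["gene", "tissue", "condition", "bio_rep"]).size()
        if (per_bio > 1).any():
            raise PreconditionError(
                "dataset still carries technical replicates; call "
                "average_technical_replicates first"
            )
    wide = ds.pivot()
    all_missing = wide.isna().all(axis=1)
    if all_missing.any():
        raise PreconditionError(
            "gene(s) with no Cq values: "
            + ", ".join(wide.index[all_missing])
        )
    anchor = wide.min(axis=1)
    e = eff.vector(wide.index)
    q = np.power(e[:, None], -(wide.to_numpy() - anchor.to_numpy()[:, None]))
    quantities = pd.DataFrame(q, index=wide.index, columns=wide.columns)
    return QuantityMatrix(quantities, anchor.rename("anchor_cq"), ds.sample_info())


def summarize(ds: CqDataset, group_by: str = "tissue") -> pd.DataFrame:
    """Per-gene descriptive statistics of Cq, per tissue or overall.

    Technical and biological replicates are averaged first; the statistics
    (mean, sample SD, min, max, range in cycles) are taken over condition
    means, so the ``range_cq`` column measures treatment-driven cycle
    variation, not replicate scatter.
    """
    if group_by not in ("tissue", "all"):
        raise PreconditionError(
            f"group_by must be 'tissue' or 'all', got {group_by!r}"
        )
    df = average_technical_replicates(ds).data
    keys = ["gene"] + (["tissue"] if group_by == "tissue" else [])
    cond_means = df.groupby(keys + ["condition"], as_index=False)["cq"].mean()
    g = cond_means.groupby(keys)["cq"]
    out = g.agg(
        mean_cq="mean",
        sd_cq=lambda s: s.std(ddof=1),
        min_cq="min",
        max_cq="max",
    ).reset_index()
    out["range_cq"] = out["max_cq"] - out["min_cq"]
    return out


def rank_table(scores: pd.Series, score_col: str) -> pd.DataFrame:
    """Turn a per-gene score series (lower = better) into a ranking table.

    Ties are broken by gene identifier (lexicographic) and flagged in the
    ``tied`` column; ranks are the positions 1..G after sorting.
    """
    df = scores.rename(score_col).rename_axis("gene").reset_index()
    df = df.sort_values([score_col, "gene"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["tied"] = df[score_col].duplicated(keep=False)
    return df
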