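"""Efficiency-corrected relative quantification of genes of interest.

The relative quantity of a gene of interest (GOI) in sample s is

    RQ_s = E ^ (mean control Cq - Cq_s)

so salt-induced genes (lower Cq than control) show RQ > 1 and the
geometric mean RQ over control samples is exactly 1.  Normalized
expression is RQ divided by the per-sample normalization factor NF of a
chosen reference-gene set (the GrayNorm-calibrated geometric mean), and
profiles are displayed as log2 values so 0 means unchanged.

:func:`compare_strategies` quantifies how much each normalization
strategy moves the profiles away from the non-normalized ones; under the
premise that the treatment groups are biologically comparable, smaller
displacement means the reference set injects less of its own biology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    CqDataset,
    EfficiencyTable,
    PreconditionError,
    average_technical_replicates,
)
from .graynorm import graynorm_quantities


def relative_quantity(
    ds: CqDataset, eff: EfficiencyTable, goi: str, control_condition: str
) -> pd.Series:
    """Per-sample control-calibrated relative quantity of one gene."""
    ds = average_technical_replicates(ds)
    goi = str(goi)
    if goi not in ds.genes:
        raise PreconditionError(f"gene of interest {goi!r} not in dataset")
    cal = graynorm_quantities(ds.subset(genes=ds.genes), eff, control_condition)
    return cal.quantities.loc[goi].rename("rq")


def normalize_expression(rq: pd.Series, nf) -> pd.DataFrame:
    """Divide per-sample RQ by the normalization factor; add a log2 column.

    ``nf`` is a per-sample Series or a
    :class:`~refstab.genorm.NormalizationFactor`.  Sample sets must match.
    """
    nf_values = getattr(nf, "values_series", None)
    if nf_values is None:
        nf_values = nf.values if hasattr(nf, "values") and isinstance(nf.values, pd.Series) else nf
    if not isinstance(nf_values, pd.Series):
        raise PreconditionError("nf must be a per-sample Series or NormalizationFactor")
    if set(rq.index) != set(nf_values.index):
        raise PreconditionError("RQ and NF cover different sample sets")
    nf_values = nf_values.reindex(rq.index)
    normalized = rq / nf_values
    return pd.DataFrame(
        {
            "sample": rq.index,
            "rq": rq.to_numpy(),
            "nf": nf_values.to_numpy(),
            "normalized": normalized.to_numpy(),
            "log2_normalized": np.log2(normalized.to_numpy()),
        }
    )


def fold_discrepancy(var_a: float, var_b: float, base: float = 2.0) -> float:
    """Fold difference in final quantification caused by normalizing with
    a reference gene carrying ``var_a`` instead of ``var_b`` cycles of
    variation: ``base ** (var_a - var_b)``."""
    if base <= 1.0:
        raise PreconditionError("the amplification base must exceed 1")
    return float(base ** (var_a - var_b))


def compare_strategies(
    ds: CqDataset,
    eff: EfficiencyTable,
    gois,
    strategies: dict,
    control_condition: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition-mean log2 expression per GOI under each normalization
    strategy, plus a per-strategy deviation summary.

    ``strategies`` maps a label to a reference-gene list, or to
    ``None``/``"none"`` for no normalization.  Returns ``(profiles,
    summary)``:

    * profiles — goi, condition, strategy, mean_log2, se_log2 (mean and
      standard error over biological replicates);
    * summary — strategy, mean_abs_deviation: the mean over GOIs and
      conditions of |mean_log2 - mean_log2 without normalization|.
    """
    ds = average_technical_replicates(ds)
    if len(ds.tissues) > 1:
        raise PreconditionError(
            "dataset spans multiple tissues; analyze one tissue at a time"
        )
    gois = [str(g) for g in gois]
    cal = graynorm_quantities(ds, eff, control_condition)
    log_q = np.log2(cal.quantities.to_numpy())
    gene_index = {g: i for i, g in enumerate(cal.quantities.index)}
    cond = cal.sample_info["condition"]
    conditions = list(pd.unique(cond))

    log_nf: dict[str, np.ndarray] = {}
    for label, gene_set in strategies.items():
        if gene_set is None or (isinstance(gene_set, str) and gene_set == "none"):
            log_nf[label] = np.zeros(log_q.shape[1])
            continue
        genes = [str(g) for g in gene_set]
        unknown = [g for g in genes if g not in gene_index]
        if unknown:
            raise PreconditionError(
                f"strategy {label!r} uses unknown gene(s): " + ", ".join(unknown)
            )
        log_nf[label] = log_q[[gene_index[g] for g in genes]].mean(axis=0)

    rows = []
    baseline: dict[tuple, float] = {}
    for goi in gois:
        if goi not in gene_index:
            raise PreconditionError(f"gene of interest {goi!r} not in dataset")
        log_rq = log_q[gene_index[goi]]
        for c in conditions:
            cols = (cond == c).to_numpy()
            vals = log_rq[cols]
            baseline[(goi, c)] = float(np.nanmean(vals))
        for label in strategies:
            log_norm = log_rq - log_nf[label]
            for c in conditions:
                cols = (cond == c).to_numpy()
                vals = log_norm[cols]
                vals = vals[~np.isnan(vals)]
                mean = float(vals.mean())
                se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
                rows.append(
                    {
                        "goi": goi,
                        "condition": c,
                        "strategy": label,
                        "mean_log2": mean,
                        "se_log2": se,
                    }
                )
    profiles = pd.DataFrame(rows)
    devs = profiles.assign(
        dev=lambda df: np.abs(
            df["mean_log2"]
            - df.apply(lambda r: baseline[(r["goi"], r["condition"])], axis=1)
        )
    )
    summary = (
        devs.groupby("strategy", as_index=False)["dev"]
        .mean()
        .rename(columns={"dev": "mean_abs_deviation"})
    )
    return profiles, summary
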