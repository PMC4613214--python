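"""GrayNorm: rank reference-gene combinations by condition-level 1/NF drift.

Quantities are calibrated against the control condition: for gene g and
sample s,

    q_gs = E_g ^ (mean control Cq of g  -  Cq_gs)

so the control-condition geometric mean of every gene is exactly 1.  For
a candidate combination, NF_s is the geometric mean of its genes'
calibrated quantities in sample s.  Genes of interest are later divided
by NF, so the reciprocal 1/NF is what a combination *adds* to their
profiles: the closer the per-condition averages of 1/NF stay to 1.0, the
less biological variation the combination injects.

Two indices summarise a combination: ``cv_inter`` (the coefficient of
variation, in percent, of the per-condition mean 1/NF values) and the
``cumulative deviation`` (the sum over non-control conditions of
|mean 1/NF - 1|).  The cumulative deviation is the primary ranking key.
Unlike the stepwise methods, every combination can be scored
exhaustively in one pass.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .core import (
    CqDataset,
    EfficiencyTable,
    PreconditionError,
    average_technical_replicates,
)

ENUMERATION_GUARD = 20  # 2^20 combinations is the desk-scale promise


@dataclasses.dataclass(frozen=True)
class CalibratedQuantities:
    """Control-calibrated quantities; per-gene geometric mean over the
    control samples is exactly 1 (unlike :class:`~refstab.core.QuantityMatrix`,
    values may exceed 1)."""

    quantities: pd.DataFrame  # genes x samples
    sample_info: pd.DataFrame
    control: str


@dataclasses.dataclass(frozen=True)
class CombinationScore:
    """Scores for one reference-gene combination (lower = better)."""

    genes: tuple
    condition_means: pd.Series  # mean 1/NF per condition
    cv_inter: float  # percent
    cumulative_deviation: float
    rank: int | None = None

    @property
    def size(self) -> int:
        return len(self.genes)


def graynorm_quantities(
    ds: CqDataset, eff: EfficiencyTable, control_condition: str
) -> CalibratedQuantities:
    """Calibrate quantities to the control condition's mean Cq per gene."""
    ds = average_technical_replicates(ds)
    control = str(control_condition)
    if control not in ds.conditions:
        raise PreconditionError(f"control condition {control!r} not in dataset")
    wide = ds.pivot()
    info = ds.sample_info()
    ctrl_cols = info.index[info["condition"] == control]
    ctrl_mean = wide[list(ctrl_cols)].mean(axis=1)
    absent = ctrl_mean.isna()
    if absent.any():
        raise PreconditionError(
            "gene(s) without control-condition measurements: "
            + ", ".join(wide.index[absent])
        )
    e = eff.vector(wide.index)
    q = np.power(e[:, None], ctrl_mean.to_numpy()[:, None] - wide.to_numpy())
    return CalibratedQuantities(
        pd.DataFrame(q, index=wide.index, columns=wide.columns), info, control
    )


def _score(
    log_q: np.ndarray,
    gene_idx,
    cond_labels: pd.Series,
    conditions: list,
    control: str,
) -> tuple[pd.Series, float, float]:
    log_nf = log_q[list(gene_idx)].mean(axis=0)
    inv_nf = np.power(2.0, -log_nf)
    means = {}
    for cond in conditions:
        cols = (cond_labels == cond).to_numpy()
        vals = inv_nf[cols]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise PreconditionError(f"no usable samples in condition {cond!r}")
        means[cond] = float(vals.mean())
    cm = pd.Series(means, name="mean_inv_nf")
    cv = float(100.0 * cm.std(ddof=1) / cm.mean())
    cumdev = float(sum(abs(cm[c] - 1.0) for c in conditions if c != control))
    return cm, cv, cumdev


def graynorm_score(
    ds: CqDataset,
    eff: EfficiencyTable,
    combination,
    control_condition: str,
) -> CombinationScore:
    """Score one combination: per-condition mean 1/NF, cv_inter and
    cumulative deviation."""
    cal = graynorm_quantities(ds, eff, control_condition)
    genes = tuple(sorted(str(g) for g in combination))
    if not genes:
        raise PreconditionError("the combination must be non-empty")
    unknown = set(genes) - set(cal.quantities.index)
    if unknown:
        raise PreconditionError("unknown gene(s): " + ", ".join(sorted(unknown)))
    conditions = list(pd.unique(cal.sample_info["condition"]))
    if len(conditions) < 2:
        raise PreconditionError("GrayNorm needs at least 2 conditions")
    log_q = np.log2(cal.quantities.to_numpy())
    idx = [list(cal.quantities.index).index(g) for g in genes]
    cm, cv, cumdev = _score(
        log_q, idx, cal.sample_info["condition"], conditions, cal.control
    )
    return CombinationScore(genes, cm, cv, cumdev)


def graynorm_rank_all(
    ds: CqDataset,
    eff: EfficiencyTable,
    control_condition: str,
    min_size: int = 1,
    max_size: int | None = None,
    max_genes: int = ENUMERATION_GUARD,
) -> list[CombinationScore]:
    """Score every gene combination and sort ascending by cumulative
    deviation (ties: smaller set, then lexicographic gene list).

    Refuses datasets with more than ``max_genes`` genes (the 2^G
    enumeration guard); raise the guard explicitly to go bigger.
    """
    cal = graynorm_quantities(ds, eff, control_condition)
    genes = sorted(cal.quantities.index)
    g = len(genes)
    if g > max_genes:
        raise PreconditionError(
            f"{g} genes imply 2^{g} combinations; raise max_genes to enumerate"
        )
    if max_size is None:
        max_size = g
    if not 1 <= min_size <= max_size <= g:
        raise PreconditionError(
            f"invalid combination sizes: min {min_size}, max {max_size}, G {g}"
        )
    conditions = list(pd.unique(cal.sample_info["condition"]))
    if len(conditions) < 2:
        raise PreconditionError("GrayNorm needs at least 2 conditions")
    log_q = np.log2(cal.quantities.to_numpy())
    cond_labels = cal.sample_info["condition"]
    scored = []
    for size in range(min_size, max_size + 1):
        for combo in itertools.combinations(range(g), size):
            cm, cv, cumdev = _score(log_q, combo, cond_labels, conditions, cal.control)
            scored.append(
                CombinationScore(tuple(genes[i] for i in combo), cm, cv, cumdev)
            )
    scored.sort(key=lambda s: (s.cumulative_deviation, s.size, s.genes))
    return [dataclasses.replace(s, rank=i + 1) for i, s in enumerate(scored)]


def select_combination(ranked: list[CombinationScore], min_genes: int = 3) -> CombinationScore:
    """First combination in rank order with at least ``min_genes`` genes."""
    if not ranked:
        raise PreconditionError("the ranked combination list is empty")
    for score in ranked:
        if score.size >= min_genes:
            return score
    raise PreconditionError(
        f"no combination has at least {min_genes} genes"
    )


def combination_table(ranked: list[CombinationScore]) -> pd.DataFrame:
    """Long table: combination (semicolon-joined), size, cv_inter,
    cumulative_deviation, rank."""
    return pd.DataFrame(
        {
            "combination": [";".join(s.genes) for s in ranked],
            "size": [s.size for s in ranked],
            "cv_inter": [s.cv_inter for s in ranked],
            "cumulative_deviation": [s.cumulative_deviation for s in ranked],
            "rank": [s.rank for s in ranked],
        }
    )
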