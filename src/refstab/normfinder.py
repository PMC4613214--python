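"""Model-based stability estimation (NormFinder-style variance decomposition).

Expression is analysed on the log2 scale of efficiency-corrected
quantities.  After centring each sample across genes (which removes
sample-specific loading effects), the remaining variation of each gene is
decomposed into an intragroup variance (replicate scatter within each
sample group) and an intergroup deviation (a systematic shift of the
gene's level between groups).  The reported stability value combines
both:

    stability_g = mean over groups k of ( |d~_gk| + sqrt(sigma2_gk / n_k) )

where ``sigma2_gk`` is a bias-corrected intragroup variance estimate
(clipped at zero) and ``d~_gk`` is the intergroup deviation shrunk toward
zero by its sampling variance (an empirical-Bayes step that avoids
rewarding noise in small groups).  Lower values = more stable.  With a
single group the stability is simply the intragroup SD.

Exact numeric agreement with the original Excel/VBA applet is not a goal;
rank agreement on data with known ground truth is.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd

from .core import (
    CqDataset,
    EfficiencyTable,
    PreconditionError,
    average_technical_replicates,
    rank_table,
    to_quantities,
)

GROUPINGS = ("bio_rep", "condition", "none")


@dataclasses.dataclass(frozen=True)
class NormFinderResult:
    """Per-gene stability values plus per-group diagnostics.

    ``group_stats`` is a long table with one row per (gene, group):
    ``n`` (samples in the group), ``intragroup_var`` (sigma2_gk),
    ``intergroup_dev`` (raw d_gk) and ``intergroup_dev_shrunk`` (d~_gk).
    """

    ranking: pd.DataFrame  # gene, stability, rank, tied
    group_stats: pd.DataFrame
    grouping: str
    log_base: int = 2

    @property
    def stability(self) -> pd.Series:
        return self.ranking.set_index("gene")["stability"]

    @property
    def n_groups(self) -> int:
        return self.group_stats["group"].nunique()

    @property
    def ordering(self) -> tuple:
        return tuple(self.ranking.sort_values("rank")["gene"])


def normfinder_stability(
    ds: CqDataset, eff: EfficiencyTable, groups: str = "bio_rep"
) -> NormFinderResult:
    """Estimate per-gene stability values by variance decomposition.

    ``groups`` selects the grouping variable: ``"bio_rep"`` (each
    biological replicate series is a group — the default, giving e.g. 3
    groups of 6 time points in a one-tissue time course), ``"condition"``
    (treatment groups) or ``"none"`` (a single group; intragroup SD only).

    Requires >= 3 genes and >= 2 samples in every group.  Samples with
    any missing gene are dropped with a warning (the decomposition needs
    a complete matrix).
    """
    if groups not in GROUPINGS:
        raise PreconditionError(
            f"unknown grouping {groups!r}; choose one of {GROUPINGS}"
        )
    ds = average_technical_replicates(ds)
    if len(ds.tissues) > 1:
        raise PreconditionError(
            "dataset spans multiple tissues; analyze one tissue at a time"
        )
    qm = to_quantities(ds, eff)
    y = np.log2(qm.quantities.to_numpy())
    genes = qm.genes
    g = len(genes)
    if g < 3:
        raise PreconditionError("the decomposition needs at least 3 genes")
    complete = ~np.isnan(y).any(axis=0)
    if not complete.all():
        warnings.warn(
            f"dropping {int((~complete).sum())} sample(s) with missing values",
            stacklevel=2,
        )
    y = y[:, complete]
    info = qm.sample_info.loc[complete]
    if groups == "none":
        labels = pd.Series("all", index=info.index)
    else:
        labels = info[groups].astype(str)
    group_names = list(pd.unique(labels))
    k = len(group_names)
    n_k = np.array([(labels == name).sum() for name in group_names])
    if (n_k < 2).any():
        small = [name for name, n in zip(group_names, n_k) if n < 2]
        raise PreconditionError(
            "group(s) with fewer than 2 samples: " + ", ".join(small)
        )

    # (1) centre each sample across genes
    z = y - y.mean(axis=0, keepdims=True)

    # (2) per-group means and residual variances
    zbar = np.empty((g, k))
    s2 = np.empty((g, k))
    for idx, name in enumerate(group_names):
        cols = (labels == name).to_numpy()
        zbar[:, idx] = z[:, cols].mean(axis=1)
        s2[:, idx] = z[:, cols].var(axis=1, ddof=1)

    # (3) bias-corrected intragroup variance, clipped at zero
    sigma2 = np.maximum(
        0.0, s2 * (1.0 - 2.0 / g) + s2.sum(axis=0, keepdims=True) / (g * (g - 1))
    )
    samp_var = sigma2 / n_k[None, :]

    if k == 1:
        stability = np.sqrt(sigma2[:, 0])
        d = np.zeros((g, 1))
        d_shrunk = np.zeros((g, 1))
    else:
        # (4) intergroup deviations, shrunk by their sampling variance
        d = zbar - zbar.mean(axis=1, keepdims=True)
        gamma2 = np.maximum(0.0, d.var(axis=1, ddof=1) - samp_var.mean(axis=1))
        denom = gamma2[:, None] + samp_var
        with np.errstate(invalid="ignore"):
            shrink = np.where(denom > 0, gamma2[:, None] / np.where(denom > 0, denom, 1.0), 0.0)
        d_shrunk = d * shrink
        # (5) combine group-wise
        stability = (np.abs(d_shrunk) + np.sqrt(samp_var)).mean(axis=1)

    ranking = rank_table(pd.Series(stability, index=genes), "stability")
    records = []
    for gi, gene in enumerate(genes):
        for ki, name in enumerate(group_names):
            records.append(
                {
                    "gene": gene,
                    "group": name,
                    "n": int(n_k[ki]),
                    "intragroup_var": sigma2[gi, ki],
                    "intergroup_dev": d[gi, ki],
                    "intergroup_dev_shrunk": d_shrunk[gi, ki],
                }
            )
    return NormFinderResult(
        ranking=ranking,
        group_stats=pd.DataFrame(records),
        grouping=groups,
    )


def normfinder_best_pair(result: NormFinderResult):
    """Best two-gene combination under the combined-stability criterion.

    The pair (i, j) is scored by

        mean over groups of ( |(d~_ik + d~_jk)/2| + sqrt((s2_ik + s2_jk)/(4 n_k)) )

    so two genes whose intergroup deviations cancel can beat either
    singleton.  Requires >= 2 groups; ties resolve to the
    lexicographically first pair.  Returns ``(pair, value)``.
    """
    if result.n_groups < 2:
        raise PreconditionError(
            "pair search needs >= 2 groups (it exploits intergroup "
            "cancellation); use the single-gene ranking instead"
        )
    gs = result.group_stats
    d = gs.pivot(index="gene", columns="group", values="intergroup_dev_shrunk")
    sigma2 = gs.pivot(index="gene", columns="group", values="intragroup_var")
    n = gs.pivot(index="gene", columns="group", values="n")
    genes = sorted(d.index)
    best_pair, best_val = None, np.inf
    for a, b in itertools.combinations(genes, 2):
        val = float(
            np.mean(
                np.abs((d.loc[a] + d.loc[b]) / 2.0)
                + np.sqrt((sigma2.loc[a] + sigma2.loc[b]) / (4.0 * n.loc[a]))
            )
        )
        if val < best_val:
            best_pair, best_val = (a, b), val
    return best_pair, best_val
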