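"""geNorm: pairwise-variation stability, iterative ranking and the V rule.

For genes j, k with relative quantities q the log2 expression ratios
A_jk,s = log2(q_js / q_ks) are formed per sample; their sample SD, V_jk,
is small when the two genes co-vary.  The stability measure of gene j is

    M_j = mean over partners k != j of V_jk

(low M = stable or co-regulated).  Ranking proceeds by iteratively
excluding the gene with the highest M and recomputing on the remainder;
the final two genes cannot be resolved and share rank 1.

To decide how many reference genes a normalization factor (NF, the
geometric mean of the chosen genes' quantities) should contain, the
pairwise variation V_n/n+1 = SD(log2(NF_n / NF_n+1)) is computed along
the ranked gene list; V below 0.15 suggests n genes suffice, with a
floor of three genes to dilute residual co-regulation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import PreconditionError, QuantityMatrix, rank_table


def _quantity_frame(q) -> pd.DataFrame:
    mat = q.quantities if isinstance(q, QuantityMatrix) else q
    if (mat.to_numpy() <= 0).any():
        raise PreconditionError("quantities must be strictly positive")
    return mat


@dataclasses.dataclass(frozen=True)
class GenormResult:
    """Outcome of the iterative exclusion ranking.

    Each gene's ``m_value`` is its M at the step it was excluded (the
    final pair: their M in the two-gene set).  ``exclusion_order`` lists
    genes from first excluded (least stable) to the final pair.  The last
    two genes share rank 1; ranks then continue at 3.
    """

    ranking: pd.DataFrame  # gene, m_value, rank, tied
    exclusion_order: tuple
    initial_pair_sd: pd.DataFrame
    ties: tuple  # (step, tied genes) records

    @property
    def best_pair(self) -> tuple:
        return tuple(self.ranking.loc[self.ranking["rank"] == 1, "gene"])

    @property
    def ordering(self) -> tuple:
        """Genes from most to least stable (final pair lexicographic)."""
        return tuple(self.ranking.sort_values(["rank", "gene"])["gene"])


@dataclasses.dataclass(frozen=True)
class PairwiseVariationSeries:
    """V_n/n+1 values for n = 2..G-1 along a ranked gene list."""

    values: pd.Series  # index n, value V_n/n+1
    genes: tuple = ()

    def __post_init__(self):
        if (self.values < 0).any():
            raise PreconditionError("pairwise variations must be >= 0")


@dataclasses.dataclass(frozen=True)
class NormalizationFactor:
    """Per-sample geometric mean of a reference-gene set's quantities."""

    values: pd.Series
    genes: tuple


@dataclasses.dataclass(frozen=True)
class RecommendedCount:
    n: int
    rule: str
    threshold: float
    min_genes: int


def genorm_m(q) -> pd.Series:
    """Per-gene M values for the current gene set.

    ``q`` is a :class:`QuantityMatrix` or a positive gene x sample
    DataFrame.  Samples are dropped pairwise when either gene is missing.
    """
    mat = _quantity_frame(q)
    genes = list(mat.index)
    g = len(genes)
    if g < 2:
        raise PreconditionError("M needs at least 2 genes")
    logs = np.log2(mat.to_numpy())
    v = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            a = logs[i] - logs[j]
            a = a[~np.isnan(a)]
            if a.size < 2:
                raise PreconditionError(
                    f"genes {genes[i]!r} and {genes[j]!r} share fewer than 2 samples"
                )
            v[i, j] = v[j, i] = float(np.std(a, ddof=1))
    return pd.Series(v.sum(axis=1) / (g - 1), index=genes, name="m_value")


def genorm_rank(q) -> GenormResult:
    """Iterative exclusion ranking by M.

    At every step the gene with the highest M among the remaining set is
    excluded (ties: the lexicographically last gene, recorded in
    ``ties``) and M is recomputed, until two genes remain; those tie for
    rank 1.
    """
    mat = _quantity_frame(q)
    if len(mat.index) < 3:
        raise PreconditionError("iterative ranking needs at least 3 genes")
    remaining = sorted(mat.index)
    g = len(remaining)
    initial_m = genorm_m(mat.loc[remaining])
    initial_sd = _pair_sd_matrix(mat.loc[remaining])
    records: dict[str, float] = {}
    ranks: dict[str, int] = {}
    exclusion = []
    ties = []
    step_rank = g
    while len(remaining) > 2:
        m = genorm_m(mat.loc[remaining])
        worst_val = m.max()
        tied = sorted(m.index[m == worst_val])
        if len(tied) > 1:
            ties.append((step_rank, tuple(tied)))
        worst = tied[-1]  # lexicographically last among tied
        records[worst] = float(worst_val)
        ranks[worst] = step_rank
        exclusion.append(worst)
        remaining.remove(worst)
        step_rank -= 1
    m_final = genorm_m(mat.loc[remaining])
    for gene in remaining:
        records[gene] = float(m_final[gene])
        ranks[gene] = 1
    exclusion.extend(remaining)
    rows = pd.DataFrame(
        {
            "gene": list(records),
            "m_value": [records[g_] for g_ in records],
            "rank": [ranks[g_] for g_ in records],
        }
    ).sort_values(["rank", "gene"], kind="mergesort").reset_index(drop=True)
    rows["tied"] = rows["rank"] == 1
    return GenormResult(
        ranking=rows,
        exclusion_order=tuple(exclusion),
        initial_pair_sd=initial_sd,
        ties=tuple(ties),
    )


def _pair_sd_matrix(mat: pd.DataFrame) -> pd.DataFrame:
    genes = list(mat.index)
    logs = np.log2(mat.to_numpy())
    g = len(genes)
    v = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            a = logs[i] - logs[j]
            a = a[~np.isnan(a)]
            v[i, j] = v[j, i] = float(np.std(a, ddof=1)) if a.size >= 2 else np.nan
    return pd.DataFrame(v, index=genes, columns=genes)


def normalization_factor(q, gene_set) -> NormalizationFactor:
    """Per-sample geometric mean of the chosen genes' quantities."""
    mat = _quantity_frame(q)
    genes = tuple(str(g) for g in gene_set)
    if not genes:
        raise PreconditionError("the reference-gene set must be non-empty")
    unknown = set(genes) - set(mat.index)
    if unknown:
        raise PreconditionError("unknown gene(s): " + ", ".join(sorted(unknown)))
    logs = np.log2(mat.loc[list(genes)].to_numpy())
    nf = np.power(2.0, logs.mean(axis=0))
    return NormalizationFactor(pd.Series(nf, index=mat.columns, name="nf"), genes)


def pairwise_variation(q, ranked_genes) -> PairwiseVariationSeries:
    """V_n/n+1 series for n = 2..G-1 along ``ranked_genes`` (best first).

    Samples with a missing value in any ranked gene are dropped so every
    NF_n uses the same sample set.
    """
    mat = _quantity_frame(q)
    ranked = [str(g) for g in ranked_genes]
    if len(ranked) < 3:
        raise PreconditionError("pairwise variation needs at least 3 ranked genes")
    unknown = set(ranked) - set(mat.index)
    if unknown:
        raise PreconditionError("unknown gene(s): " + ", ".join(sorted(unknown)))
    logs = np.log2(mat.loc[ranked].to_numpy())
    complete = ~np.isnan(logs).any(axis=0)
    logs = logs[:, complete]
    if logs.shape[1] < 2:
        raise PreconditionError("fewer than 2 complete samples")
    values = {}
    for n in range(2, len(ranked)):
        log_nf_n = logs[:n].mean(axis=0)
        log_nf_n1 = logs[: n + 1].mean(axis=0)
        values[n] = float(np.std(log_nf_n - log_nf_n1, ddof=1))
    series = pd.Series(values, name="v")
    series.index.name = "n"
    return PairwiseVariationSeries(series, tuple(ranked))


def recommend_count(
    series: PairwiseVariationSeries, threshold: float = 0.15, min_genes: int = 3
) -> RecommendedCount:
    """How many reference genes to use, from the V_n/n+1 series.

    The smallest n with V_n/n+1 below ``threshold`` is chosen; if that n
    is below ``min_genes`` the floor applies (using at least three genes
    dilutes the influence of a co-regulated pair).  If no V falls below
    the threshold, n+1 genes at the series minimum are recommended.
    """
    v = series.values
    below = v.index[v < threshold]
    if len(below):
        n_raw = int(below.min())
        if n_raw < min_genes:
            return RecommendedCount(min_genes, "minimum-genes floor", threshold, min_genes)
        return RecommendedCount(n_raw, "threshold", threshold, min_genes)
    n_min = int(v.idxmin())
    n = n_min + 1
    if n < min_genes:
        return RecommendedCount(min_genes, "minimum-genes floor", threshold, min_genes)
    return RecommendedCount(n, "minimum of V", threshold, min_genes)
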