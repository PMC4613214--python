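"""The comparative ΔCt method for reference-gene stability.

For every ordered pair of genes the per-sample difference ΔCt = Cq_i -
Cq_j is formed; if both genes are stable (or co-regulated) this
difference is constant across samples.  Each gene is scored by the mean,
over all partners, of the sample standard deviation of these differences
(mSD, in cycles); small mSD = stable.  The method works on raw Cq values
only — no efficiency correction — which is exactly what makes it a quick
first screen.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import CqDataset, PreconditionError, average_technical_replicates, rank_table


@dataclasses.dataclass(frozen=True)
class PairwiseDctResult:
    """Pairwise ΔCt standard deviations and the derived mSD ranking.

    ``sd_matrix`` is symmetric with a zero diagonal (the diagonal is
    excluded from mSD).  ``flagged_pairs`` lists gene pairs whose SD was
    computed on fewer than 3 shared samples.
    """

    sd_matrix: pd.DataFrame
    ranking: pd.DataFrame  # columns: gene, msd, rank, tied
    flagged_pairs: tuple

    @property
    def msd(self) -> pd.Series:
        return self.ranking.set_index("gene")["msd"].reindex(self.sd_matrix.index)

    @property
    def ordering(self) -> tuple:
        """Genes from most to least stable."""
        return tuple(self.ranking.sort_values("rank")["gene"])


def pairwise_dct(ds: CqDataset) -> PairwiseDctResult:
    """Compute pairwise ΔCt SDs and the per-gene mSD ranking.

    Technical replicates are averaged first; every biological sample
    (condition x replicate) is a column.  Samples where either gene of a
    pair is missing are dropped pairwise; a pair sharing fewer than 2
    samples is an error, fewer than 3 is flagged.
    """
    ds = average_technical_replicates(ds)
    wide = ds.pivot()
    genes = list(wide.index)
    g = len(genes)
    mat = wide.to_numpy()
    sd = np.zeros((g, g))
    flagged = []
    for i in range(g):
        for j in range(i + 1, g):
            d = mat[i] - mat[j]
            d = d[~np.isnan(d)]
            if d.size < 2:
                raise PreconditionError(
                    f"genes {genes[i]!r} and {genes[j]!r} share fewer than 2 samples"
                )
            if d.size < 3:
                flagged.append((genes[i], genes[j]))
            sd[i, j] = sd[j, i] = float(np.std(d, ddof=1))
    msd = pd.Series(sd.sum(axis=1) / (g - 1), index=genes, name="msd")
    return PairwiseDctResult(
        sd_matrix=pd.DataFrame(sd, index=genes, columns=genes),
        ranking=rank_table(msd, "msd"),
        flagged_pairs=tuple(flagged),
    )


def dct_boxplot_data(result: PairwiseDctResult):
    """Plot-ready distribution of each gene's G-1 pairwise SDs.

    Returns ``(vectors, summary)``: a dict mapping gene to its vector of
    SDs against all partners, and a DataFrame with quartiles and Tukey
    whiskers (most extreme values within 1.5 IQR of the quartiles).
    """
    genes = list(result.sd_matrix.index)
    vectors: dict[str, np.ndarray] = {}
    rows = []
    for i, gene in enumerate(genes):
        v = result.sd_matrix.iloc[i].to_numpy()
        v = np.delete(v, i)
        vectors[gene] = v
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo = v[v >= q1 - 1.5 * iqr].min()
        hi = v[v <= q3 + 1.5 * iqr].max()
        rows.append(
            {
                "gene": gene,
                "q1": q1,
                "median": med,
                "q3": q3,
                "whisker_low": lo,
                "whisker_high": hi,
            }
        )
    return vectors, pd.DataFrame(rows)
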