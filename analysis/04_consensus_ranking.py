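"""Consensus gene ranking per tissue via Cross-Entropy rank aggregation.

The ΔCt, NormFinder, geNorm and GrayNorm single-gene orderings are merged
by minimizing the total Spearman footrule distance; for ten genes the CE
sampler is used and its optimum is reported with the convergence trace.
"""

import argparse
from pathlib import Path

import pandas as pd

from refstab import (
    __version__,
    aggregate_ce,
    graynorm_rank_all,
    read_cq_table,
    read_efficiency_table,
    write_table,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    rankdir = args.outdir / "rankings"
    data = args.outdir / "data"
    if not rankdir.exists():
        raise SystemExit(f"{rankdir} not found; run 03_stability_rankings.py first")
    ds = read_cq_table(data / "cq_data.csv")
    eff = read_efficiency_table(data / "efficiencies.csv")
    truth = pd.read_csv(data / "ground_truth_genes.csv", comment="#")
    refs = list(truth.loc[truth["role"] == "reference", "gene"])

    head = [f"refstab {__version__}", f"analysis: 04_consensus_ranking seed={args.seed}"]
    outdir = args.outdir / "consensus"
    outdir.mkdir(parents=True, exist_ok=True)
    for tissue in ds.tissues:
        lists = []
        for m in ("dct", "normfinder", "genorm"):
            t = pd.read_csv(rankdir / f"rank_{m}_{tissue}.csv", comment="#")
            lists.append(list(t.sort_values(["rank", "gene"])["gene"]))
        singles = graynorm_rank_all(
            ds.subset(genes=refs, tissue=tissue), eff, "0", min_size=1, max_size=1
        )
        lists.append([s.genes[0] for s in singles])
        result = aggregate_ce(lists, seed=args.seed)
        table = pd.DataFrame(
            {"rank": range(1, len(result.consensus) + 1), "gene": result.consensus}
        )
        write_table(table, outdir / f"consensus_{tissue}.csv",
                    header_comments=head + [f"objective: {result.objective}"])
        print(
            f"[{tissue}] consensus top 3: {', '.join(result.consensus[:3])} "
            f"(objective {result.objective:.0f}, {len(result.trace)} CE iterations)"
        )
    print(f"consensus tables written under {outdir}/")


if __name__ == "__main__":
    main()
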