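"""Per-tissue stability rankings: ΔCt mSD, NormFinder and geNorm.

Each tissue is analyzed separately on the candidate reference genes.
geNorm additionally yields the V_n/n+1 series and the recommended number
of reference genes per tissue.
"""

import argparse
from pathlib import Path

import pandas as pd

from refstab import (
    __version__,
    average_technical_replicates,
    genorm_rank,
    normfinder_stability,
    pairwise_dct,
    pairwise_variation,
    read_cq_table,
    read_efficiency_table,
    recommend_count,
    to_quantities,
    write_table,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = args.outdir / "data"
    if not (data / "cq_data.csv").exists():
        raise SystemExit(f"{data}/cq_data.csv not found; run 01_simulate_dataset.py first")
    ds = read_cq_table(data / "cq_data.csv")
    eff = read_efficiency_table(data / "efficiencies.csv")
    truth = pd.read_csv(data / "ground_truth_genes.csv", comment="#")
    refs = list(truth.loc[truth["role"] == "reference", "gene"])

    outdir = args.outdir / "rankings"
    outdir.mkdir(parents=True, exist_ok=True)
    head = [f"refstab {__version__}", "analysis: 03_stability_rankings"]
    reco_rows = []
    for tissue in ds.tissues:
        sub = average_technical_replicates(ds.subset(genes=refs, tissue=tissue))
        dct = pairwise_dct(sub)
        nf = normfinder_stability(sub, eff, groups="bio_rep")
        q = to_quantities(sub, eff)
        gn = genorm_rank(q)
        write_table(dct.ranking, outdir / f"rank_dct_{tissue}.csv", header_comments=head)
        write_table(nf.ranking, outdir / f"rank_normfinder_{tissue}.csv", header_comments=head)
        write_table(gn.ranking, outdir / f"rank_genorm_{tissue}.csv", header_comments=head)
        series = pairwise_variation(q, gn.ordering)
        write_table(series.values.reset_index(), outdir / f"v_series_{tissue}.csv",
                    header_comments=head)
        reco = recommend_count(series)
        reco_rows.append({"tissue": tissue, "n": reco.n, "rule": reco.rule})
        print(f"[{tissue}]")
        print(f"  dct top 3:        {', '.join(dct.ordering[:3])}")
        print(f"  normfinder top 3: {', '.join(nf.ordering[:3])}")
        print(f"  genorm best pair: {' + '.join(gn.best_pair)}")
        print(f"  recommended gene count: {reco.n} ({reco.rule})")
    write_table(pd.DataFrame(reco_rows), outdir / "gene_count_recommendation.csv",
                header_comments=head)
    print(f"ranking tables written under {outdir}/")


if __name__ == "__main__":
    main()
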