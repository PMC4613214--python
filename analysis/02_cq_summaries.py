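"""Descriptive Cq summaries: expression levels and cycle variation.

Per gene and tissue: mean Cq (expression level) and the range of
condition-mean Cq values (treatment-driven cycle variation).  This is
the first look a validation study takes: which candidate references
drift visibly with the treatment before any stability statistic is run.
"""

import argparse
from pathlib import Path

from refstab import __version__, read_cq_table, summarize, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = args.outdir / "data" / "cq_data.csv"
    if not data.exists():
        raise SystemExit(f"{data} not found; run 01_simulate_dataset.py first")
    ds = read_cq_table(data)
    per_tissue = summarize(ds, group_by="tissue")
    overall = summarize(ds, group_by="all")
    head = [f"refstab {__version__}", "analysis: 02_cq_summaries"]
    write_table(per_tissue, args.outdir / "cq_summary_by_tissue.csv", header_comments=head)
    write_table(overall, args.outdir / "cq_summary_overall.csv", header_comments=head)

    print(f"Cq summaries for {len(ds.genes)} genes in {len(ds.tissues)} tissues")
    lo = overall.loc[overall["mean_cq"].idxmin()]
    hi = overall.loc[overall["mean_cq"].idxmax()]
    print(f"highest expression: {lo['gene']} (mean Cq {lo['mean_cq']:.2f})")
    print(f"lowest expression:  {hi['gene']} (mean Cq {hi['mean_cq']:.2f})")
    for t in ds.tissues:
        sub = per_tissue[per_tissue["tissue"] == t]
        stable = sub.loc[sub["range_cq"].idxmin()]
        variable = sub.loc[sub["range_cq"].idxmax()]
        print(
            f"{t}: least variation {stable['gene']} ({stable['range_cq']:.2f} cycles), "
            f"most variation {variable['gene']} ({variable['range_cq']:.2f} cycles)"
        )


if __name__ == "__main__":
    main()
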