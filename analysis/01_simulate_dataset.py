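"""Generate the synthetic salt-stress Cq dataset the analyses run on.

The study design: 10 candidate reference genes and 9 salt-responsive
genes of interest, measured in leaf, stem and root over a 0-12 h salt
time course with 3 biological x 3 technical replicates.  Ground truth
(per-gene condition-response amplitude, per-GOI log2 trajectories) is
written alongside so later stages can be scored against it.
"""

import argparse
from pathlib import Path

from refstab import __version__, salt_stress_dataset, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    ds, truth, eff = salt_stress_dataset(args.seed)
    outdir = args.outdir / "data"
    outdir.mkdir(parents=True, exist_ok=True)
    head = [f"refstab {__version__}", f"analysis: 01_simulate_dataset seed={args.seed}"]
    write_table(ds, outdir / "cq_data.csv", header_comments=head)
    write_table(eff.to_frame(), outdir / "efficiencies.csv", header_comments=head)
    write_table(truth.gene_table, outdir / "ground_truth_genes.csv", header_comments=head)
    write_table(
        truth.goi_trajectories.reset_index(),
        outdir / "ground_truth_goi.csv",
        header_comments=head,
    )

    cq = ds.data["cq"]
    print(f"simulated {len(ds.genes)} genes x {len(ds.samples)} wells (seed {args.seed})")
    print(f"observed Cq range: {cq.min():.2f} - {cq.max():.2f} cycles")
    print(f"reference genes: {', '.join(truth.reference_genes)}")
    print(f"genes of interest: {', '.join(truth.goi_genes)}")
    print(f"tables written under {outdir}/")


if __name__ == "__main__":
    main()
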