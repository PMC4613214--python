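# refstab

Reference-gene stability evaluation and normalization for RT-qPCR data.

Relative quantification by RT-qPCR divides every gene-of-interest (GOI)
measurement by a normalization factor built from "reference" genes that are
assumed stable. When a reference gene itself responds to the treatment, that
response is silently imprinted on every normalized profile: a reference
carrying `a` cycles of treatment-driven variation instead of `b` distorts the
final quantification by `E^(a-b)`-fold (7.6-fold for 3.22 vs 0.3 cycles at
E = 2). `refstab` implements the standard toolbox for choosing references
before any GOI is quantified, plus the downstream quantification itself:

* **ΔCt (mSD)** — for genes *i*, *j* the per-sample difference
  ΔCt = Cq_i − Cq_j is constant iff both are stable (or co-regulated); gene
  *i*'s score is mSD_i = mean_j SD_s(ΔCt_ij,s). Raw Cq only, no efficiency.
* **NormFinder-style decomposition** — on log2 efficiency-corrected
  quantities, after per-sample centring, each gene's variation is split into
  intragroup variance σ²_gk and intergroup deviation d_gk;
  stability_g = mean_k(|d̃_gk| + √(σ̂²_gk/n_k)) with the deviation shrunk by
  its sampling variance.
* **geNorm** — M_j = mean_k SD_s(log2 q_js/q_ks), iterative exclusion of the
  highest-M gene, and the pairwise variation
  V_n/n+1 = SD_s(log2 NF_n,s/NF_n+1,s) with the `V < 0.15` / "at least three
  genes" rule for how many references to use.
* **GrayNorm** — every combination of candidates is scored by how far the
  per-condition averages of 1/NF (NF = geometric mean of control-calibrated
  quantities) drift from 1.0: `cv_inter` and the cumulative deviation
  Σ_c |mean_c(1/NF) − 1| over treated conditions.
* **Consensus ranking** — Cross-Entropy Monte Carlo minimization of the total
  Spearman footrule distance to the method rankings, with an exhaustive
  enumerator as the exact small-instance oracle.
* **Quantification** — RQ_s = E^(mean control Cq − Cq_s), division by NF,
  log2 display, and a strategy comparison that measures how far each
  candidate reference set moves GOI profiles from the non-normalized data.

A synthetic Cq generator (`refstab.simulate`) produces salt-stress-shaped
time-course datasets (3 tissues × 6 time points × 3 biological × 3 technical
replicates, 10 candidate references spanning 0.5–3.3 cycles of treatment
response, 9 GOIs with known log2 trajectories) so every stage can be tested
against ground truth.

## Worked example

```python
from refstab import (salt_stress_dataset, average_technical_replicates,
                     pairwise_dct, graynorm_rank_all, select_combination)

ds, truth, eff = salt_stress_dataset(seed=1)
leaf = average_technical_replicates(ds.subset(genes=truth.reference_genes,
                                              tissue="leaf"))

dct = pairwise_dct(leaf)
print(dct.ranking.head(3).to_string(index=False))

ranked = graynorm_rank_all(leaf, eff, control_condition="0")
best3 = select_combination(ranked, min_genes=3)
print("GrayNorm pick:", " + ".join(best3.genes),
      f"(cumulative deviation {best3.cumulative_deviation:.3f})")
```

prints

```
  gene      msd  rank  tied
   HIS 0.511809     1 False
   UBQ 0.539327     2 False
eIF-5A 0.545095     3 False
```

— the three least treatment-responsive candidates, ranked by mean pairwise
ΔCt SD in cycles (lower = more stable) — and

```
GrayNorm pick: 60S + EF1a + HIS + RP + UBQ (cumulative deviation 0.158)
```

the first combination of ≥ 3 genes whose condition-averaged 1/NF stays
closest to 1.0 (the deviation is summed over the five treated time points).

## The analysis, step by step

The `analysis/` scripts chain the stages on the synthetic dataset and write
their tables under `results/`:

```sh
python analysis/01_simulate_dataset.py --seed 1   # data + ground truth
python analysis/02_cq_summaries.py                # expression levels, cycle ranges
python analysis/03_stability_rankings.py          # ΔCt / NormFinder / geNorm per tissue
python analysis/04_consensus_ranking.py           # CE consensus of the four rankings
python analysis/05_graynorm_combinations.py       # all 1023 combinations per tissue
python analysis/06_goi_normalization.py           # GOI profiles under each strategy
```

The same stages are available as a CLI (`refstab simulate|summarize|rank|
aggregate|graynorm|normalize`) for user-supplied Cq tables (long or wide
CSV/TSV; see `refstab --help`).

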