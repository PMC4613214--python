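# Methods

## Data model and conventions

A Cq value is the PCR cycle at which a well crosses the fluorescence
threshold; one cycle corresponds to a factor E in template abundance, where E
is the per-gene amplification efficiency expressed as the exponential base
(2.0 = perfect doubling), not a percentage. Typical assay values are 1.9–2.1;
values outside [1.6, 2.2] trigger a warning and E ≤ 1 is rejected. Genes
without an efficiency entry fall back to E = 2.0 with a warning, consistent
with back-of-envelope fold arithmetic being done in powers of two.

Datasets are long tables with one row per well. The `sample` column is the
unique well identifier; the biological sample is the `(tissue, condition,
bio_rep)` triple, and `tech_rep` distinguishes wells of the same biological
sample. Present Cq values must be finite and inside (0, 45) — the cycler's
physical range — and missing wells are allowed (failed reactions happen on
real plates) and dropped pairwise by downstream methods.

Technical replicates are collapsed by arithmetic mean on the Cq scale before
every stability analysis; replicate structure is consumed only by the
NormFinder grouping. Descriptive cycle ranges are computed over *condition
means* (biological replicates averaged first), so they measure
treatment-driven drift rather than replicate scatter.

All stability analyses operate on a single tissue at a time; the CLI and the
analysis drivers loop over tissues. This mirrors how validation experiments
are interpreted — a reference set is chosen per tissue.

## Stability statistics

**ΔCt.** For each ordered gene pair the per-sample Cq difference is formed;
its sample SD (n−1 denominator throughout the package) is small iff the two
genes co-vary. mSD_i averages gene i's SDs over all partners. Computed on raw
Cq — the method's simplicity (no efficiency input) is its point. Pairs
sharing fewer than two samples are an error; fewer than three, flagged.

**NormFinder-style decomposition.** Input is y = log2 of the
efficiency-corrected quantities q = E^−(Cq − min Cq). Each sample is centred
across genes (removing sample-loading effects), then per group k the gene
means z̄_gk and residual variances s²_gk are taken. The intragroup variance
estimate corrects for the centring-induced coupling between genes,

    σ̂²_gk = max(0, s²_gk·(1 − 2/G) + Σ_g' s²_g'k / (G(G−1))),

and the intergroup deviation d_gk = z̄_gk − mean_k z̄_gk is shrunk by its
sampling variance, d̃ = d·γ̂²/(γ̂² + σ̂²/n_k) with γ̂² the across-group
variance of d minus the mean sampling variance (clipped at 0). The stability
value mean_k(|d̃_gk| + √(σ̂²_gk/n_k)) rewards genes that are both quiet
within groups and level across groups; with a single group it degenerates to
the intragroup SD. The grouping variable defaults to the biological
replicate (three groups of six time points in the preset design) and can be
switched to the condition. Exact numeric agreement with the original
Excel/VBA tool is explicitly not a contract — rank agreement under known
ground truth is what the tests pin down.

Because the per-sample centring forces the G deviations to sum to zero, with
few genes a strong group shift in one gene leaks (with opposite sign) into
the others; the best-pair search exploits exactly this cancellation, which is
why it requires at least two groups.

**geNorm.** M_j is the mean SD of log2 expression ratios against all
partners; the gene with the highest M is excluded and M recomputed until two
genes remain, which are mutually unrankable and share rank 1 (ranks then
continue at 3 — competition ranking, since a strict 1..G permutation would
contradict the tie). Each gene's reported M is its value at exclusion time.
Ties on the highest M exclude the lexicographically last gene and are
recorded. Low M also rewards co-regulation — the known caveat, and the reason
the gene-count rule floors at three genes. V_n/n+1 is the SD of
log2(NF_n/NF_n+1) along the ranked list; the recommended count is the
smallest n with V < 0.15 (floored at 3), or n+1 at the series minimum when no
V clears the threshold.

**GrayNorm.** Quantities are calibrated against the control condition:
q_gs = E^(mean control Cq − Cq_gs), where the mean is arithmetic on the Cq
scale — equivalently the *geometric* mean of quantities over control samples
is exactly 1. (An arithmetic-mean-of-quantities calibration cannot make both
statements exact; the geometric reading keeps the calibration identity exact
and is what the tests assert.) Per-condition averages of 1/NF are arithmetic
means over biological samples, so the control condition's average is ≈1
rather than identically 1; the cumulative deviation therefore sums over
non-control conditions only. The primary ranking key is the cumulative
deviation (cv_inter is reported alongside), ties prefer smaller combinations
then lexicographic order, and enumeration is guarded at 2^20 sets.

## Consensus ranking

The consensus ordering minimizes the weighted sum of Spearman footrule
distances to the input rankings (equal weights by default; any number of
lists is accepted). The Cross-Entropy sampler keeps an item×position
probability matrix, draws N = max(100, 10·n²) permutations per iteration by
sequential sampling without replacement, and blends the matrix toward the
elite fraction (rho = 0.1) with smoothing 0.25, stopping after 15
unimproved iterations. These defaults follow the commonly used CE rank
aggregation settings; the best-so-far trace is non-increasing by
construction and the reported objective is exactly recomputable from the
output. An exhaustive enumerator (≤ 9 items, lexicographically smallest
optimum, co-optimality logged) provides the exact oracle used in testing.

## Quantification

RQ_s = E^(mean control Cq − Cq_s), so induction (lower Cq) gives RQ > 1 and
the control-condition geometric mean is 1. The sign convention is chosen so
that salt-induced genes display positive log2 fold changes; the alternative
(treated − control in the exponent) would invert every profile. Normalized
expression is RQ/NF with NF from the same control-calibrated quantities;
profiles are summarized per condition as mean ± SE over biological
replicates of log2 values (linear in Cq, hence unbiased under Gaussian Cq
noise). The strategy comparison reports, per reference set, the mean over
GOIs and conditions of |mean log2 normalized − mean log2 non-normalized|:
under the design assumption that treatment groups are biologically
comparable, a reference set that moves profiles less injects less of its own
regulation. The comparison is against the non-normalized profile, so it
penalizes reference-gene biology but cannot detect sample-loading artifacts
that normalization is supposed to fix — it is a tie-breaker between candidate
sets, not an absolute accuracy measure.

## Synthetic data

The generator emulates a salt-stress time course at the Cq level:

    Cq[g,t,c,r,k] = μ_g + β_g·f_g(c) + b[t,c,r] + ε[g,t,c,r,k]

with f_g a response shape (flat, ramp up/down, early/late pulse) normalized
to peak-to-peak 1 so β_g *is* the gene's true treatment-driven cycle
variation, b ~ N(0, σ_b²) a biological deviate shared by all genes of a
sample (the loading/extraction variation that normalization exists to
remove), and ε ~ N(0, σ_t²) independent per well. GOIs carry their true log2
trajectory via Cq = μ − FC(c)/log2(E). Gaussian noise on the Cq scale is the
natural choice because Cq is the measurement scale and variability is
reported in cycles. Defaults σ_b = 0.2, σ_t = 0.1 cycles are stated
assumptions (no replicate-level variance decomposition is available to
calibrate them) and are tunable in the config.

The preset mirrors the study design this package targets: 3 tissues × 6 time
points × 3 biological × 3 technical replicates; 10 candidate references with
mean Cq spread over ~19.7–29.6 (UBQ most abundant, TUB least) and amplitudes
0.5–3.3 cycles; 9 GOIs with induced trajectories up to 5 log2 units. Shapes
are deliberately varied across genes: if all references shared one response
shape, pairwise methods (ΔCt, geNorm) would score mid-amplitude genes as most
stable — mean_j|β_i − β_j| is minimized at the amplitude median — breaking
the intended ground-truth ordering by |β|. With heterogeneous shapes the
pairwise variances add approximately in quadrature and the ordering by
amplitude is recovered. The generator does not simulate amplification
curves, efficiency mis-estimation, inter-plate effects, or non-Gaussian
outliers, so passing recovery tests demonstrate correctness of the
statistics under the stated noise model, not robustness to every artifact of
real plates.

The GOI-recovery experiment runs on a preset variant whose three most stable
references (HIS, RP, UBQ) have amplitude 0: recovering true fold changes
without bias is only promised for *truly* stable references — a reference
carrying even 0.5 cycles of response biases normalized profiles by up to
~0.2 log2 units, which is precisely the phenomenon the stability statistics
exist to avoid.

## Numerical choices and scales

Sample SDs use the n−1 denominator everywhere. Quantities at the per-gene
anchor are exactly 1 (exponent is exactly 0.0). Geometric means are computed
as 2^(mean log2). Ties in rankings break lexicographically by gene id and are
flagged. Problem sizes in the validation experiments — 200 random 4-gene ×
6-sample datasets for oracle agreement, 100 six-item instances for CE vs
exhaustive, 100 simulated studies for recovery — were chosen as the package's
own desk-scale defaults; all complete in well under a minute each on one
core. CSV round trips are bit-exact: values are written with shortest-repr
formatting and parsed with correctly-rounded `float()`.

## Known limitations

* The NormFinder estimator follows the published variance-decomposition
  scheme but is not a byte-level reimplementation of the retired VBA applet.
* GrayNorm condition averages use biological-replicate-level 1/NF values;
  technical replicates are always averaged first.
* No instrument-native file parsing (RDML, .eds) and no standard-curve or
  LinRegPCR efficiency estimation — efficiencies are inputs.
* The strategy-comparison statistic presumes comparable treatment groups;
  under genuinely global expression shifts it would favor under-correction.
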