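# Methods

## Scope and data model

proteoflow performs the *downstream* half of a label-free DDA proteomics
analysis: it starts from a protein-group summary table (MaxQuant
`proteinGroups.txt` dialect) and ends at differential-expression calls,
QC figures and enrichment statistics.  Feature detection and
quantification of raw spectra are upstream and out of scope.

All statistics operate on an `IntensityTable`: a proteins × samples
matrix of **log2** intensities in which a raw intensity of 0 ("not
detected") is a missing value, never log2(0).  The log scale is the only
scale on which the normalization strategies below — all of which subtract
medians or means — are meaningful.  Rows flagged as decoys
("Reverse"), site-only identifications or potential contaminants are
removed at import; rows sharing a gene symbol are merged by summing raw
intensities before the log transform.

Sample names encode the experimental hierarchy
(`line_treatment_replicate` by default, separator configurable).  The
analysis-design tree splits every name into components; a *level* slices
samples into groups (level 0 = first component, …).  Every analysis is
parameterized by one level, and group names are the joined prefix
components, which makes them unique by construction.

## Detection thresholding

Missingness in label-free MS is abundance-dependent (left-censoring), so
a protein is only compared between groups when it is detected in enough
samples per group.  The required fraction of detected samples is

    f(n) = 1.0                                  for n ≤ n_full  (default 3)
    f(n) = 0.5                                  for n ≥ n_half  (default 12)
    f(n) = 0.5 + 0.5 · σ(−k·(n − m))            otherwise,

with σ the standard logistic, midpoint m = (n_full + n_half)/2 = 7.5
samples and rate k = 1 per sample.  Only the two plateaus are normative;
the logistic interpolation is this package's choice — smooth, monotone,
and clamped so the endpoints hold exactly.  The minimum detection count
is ⌈f(n)·n⌉: rounding up means the threshold is never satisfied by fewer
detections than the fraction implies.

For a pair of groups each protein gets exactly one label: *comparable*
(above threshold in both), *unique in A* (above threshold in A and
entirely undetected in B; sporadic detection in B disqualifies
uniqueness), *unique in B*, or *not considered*.  Totality and symmetry
of this labeling are enforced by exhaustive enumeration in the test
suite.

## Normalization

Six options, named exactly as they appear in the configuration:

| method | operation |
|---|---|
| `none` | identity |
| `median_norm` | subtract (sample median − grand mean of medians) from each sample |
| `quantile_norm_missing_handled` | rank each sample, assign the cross-sample mean of order statistics; missing cells are filled by resampling (with replacement, seeded) from the sample's own observed values, then restored to missing |
| `trqn` | mean-center each sample → quantile normalize → add the mean back |
| `trqn_missing_handled` | as `trqn`, with the missing-value handling above |
| `trmn` | mean-center each sample → median normalize → add the mean back |

Ties in the quantile ranks receive the mean of the reference values over
the tied span (the standard convention).  Plain quantile normalization
*refuses* incomplete matrices instead of silently dropping rows — that is
precisely what the missing-handled variant is for.  Filled values never
leave the normalization step; every method returns the input missing
mask bit-identically.  Missing-value resampling is per sample, which
preserves each sample's observed intensity distribution.

## Differential statistics

The volcano analysis uses an empirical-Bayes moderated two-sample
t-test.  Per protein, pooled residual variance s_g² with d_g = n_A + n_B
− 2 degrees of freedom (counts after missing-value removal) is shrunk
toward a prior:

    s̃_g² = (d0·s0² + d_g·s_g²) / (d0 + d_g),
    t_g = (mean_A − mean_B) / sqrt(s̃_g²·(1/n_A + 1/n_B)),   df = d0 + d_g.

(d0, s0²) are estimated by the method of moments on log s_g², using the
digamma/trigamma moments of log-chi-square variates and a Newton
iteration for the trigamma inverse.  With the intensity–variance trend
enabled (the default in the volcano), the constant prior is replaced by
a lowess fit (span 0.3) of the log variances on average log2 intensity,
interpolated to every protein.  Limiting cases anchor the
implementation: d0 → 0 reproduces the ordinary pooled t-test to 1e−9 and
d0 → ∞ uses the prior alone; on simulated null data the test holds its
nominal level.  P-values are two-sided; multiple testing uses
Benjamini–Hochberg.  The fold-change direction is mean(A) − mean(B)
where A is the first-named group, recorded in the output headers.

Proteins unique to one group carry no p-value (there is nothing to
compare against); the volcano reports them separately with their
within-group mean intensities.  Comparable proteins that nonetheless
retain fewer than two observations in a group (possible only for group
sizes below 3) are excluded from testing rather than fitted.

Pathway scatter p-values use the ordinary pooled-variance t-test, per
group pair, only where both groups are above threshold.  GO enrichment
builds, per term and group, the 2×2 table (in term / not in term) ×
(detected / not detected) over the measured proteome as background, with
"detected in the group" meaning at least one observation; the p-value is
the hypergeometric upper tail (one-tailed Fisher exact test toward
enrichment).  Both background and detection conventions were design
choices; alternatives (whole-annotation-universe background,
above-threshold detection) would shift absolute p-values but not the
ranking of terms within a dataset.

## Exploratory conventions

* **PCA** uses complete-case proteins only (detected in every sample) —
  no imputation enters the ordination.
* **Relative SD** is computed on linear-scale intensities (2^x), since a
  percent coefficient of variation of log values is not
  scale-meaningful; the x-axis stays log2.  Only above-threshold
  proteins enter, and counts below the 10/20/30% lines are reported.
* **Rank plots** order proteins by group-mean intensity; percentile =
  100·i/(N−1), so the highest intensity is exactly 0% and the lowest
  exactly 100% (a single protein ranks 0%).
* **Venn diagrams** compute all 2^k − 1 exclusive regions; k ≤ 3 is
  drawn classically with circles, 4–6 as an intersection-size bar chart
  with a combination matrix, and k > 6 is an error.
* Pathway and GO term lists are flat text files (one gene symbol per
  line, filename = term name); membership is matched case-insensitively
  against protein identifiers.  No ontology parsing or DAG propagation
  is performed.

## Reproducibility

Every run writes, per analysis, one PDF and one CSV containing exactly
the plotted numbers, plus `config.yml` — the complete effective
configuration including defaults and the package version — and a
timestamped log with the input checksum.  Given the same input file,
configuration and seed, all CSVs are byte-identical across runs (the
only randomness in the pipeline is the seeded missing-value resampling).
Analyses are isolated: one failing analysis is logged and the rest
complete.

## Synthetic data

The fixture generator emulates the statistical structure of a label-free
DDA benchmark: per-protein base abundances drawn log-normally (log2 mean
25, SD 2 — typical orbitrap protein intensities span roughly 2^20–2^30),
replicate noise of 0.3 log2 units, per-sample systematic shifts (SD 0.5
log2 units) that normalization is expected to remove, and
intensity-dependent dropout with logistic probability (midpoint at log2
intensity 21, rate 1 per log2 unit — low-abundance proteins are censored
more often, the regime the detection threshold exists for).  A
configurable fraction of proteins (default 10%) is shifted by a fixed
effect (default 1 log2 unit) in one group; 5/2/2% of rows are flagged as
contaminant/decoy/site-only.  All three intensity flavors are written:
LFQ as the shift-free signal (mimicking its cross-sample normalization),
raw as signal + sample shift, iBAQ as raw scaled by a random
theoretical-peptide count.

What the generator does **not** emulate: peptide-level aggregation
noise, shared-peptide protein-group ambiguity, correlated protein
covariation, batch structure beyond per-sample shifts, and
heavy-tailed contaminant intensity profiles.  Passing tests therefore
demonstrate correctness of the computations under a realistic
missing-not-at-random intensity model, not robustness to every artifact
of real acquisitions.

The effect-recovery check (AUROC of planted proteins under the volcano
ranking) runs the generator with dropout disabled: it isolates the
inferential power of the moderated test from censoring effects, which
the thresholding analyses cover separately.

## Problem sizes and numerical choices

Test and verification workloads are sized for fast, deterministic runs:
normalization invariants on 1000 proteins × 12 samples, null simulations
with 500 proteins at 4 vs 4, effect recovery with 500 proteins (10%
planted), exact Fisher enumeration over all 2×2 tables with total ≤ 20,
and end-to-end determinism on a 200-protein 2×3×2 fixture.  Numerical
tolerances: median equalization and moderated-t limiting cases to 1e−9;
oracle equivalences (Fisher, quantile reference, Pearson) to 1e−12.
P-values are clipped into (0, 1] at the smallest positive float; an
exactly zero pooled variance with zero mean difference is reported as
t = 0, p = 1.

## Known limitations

* Only the MaxQuant protein-group dialect is read natively; other
  formats require implementing the three-method `BaseReader` interface.
* No imputation for downstream inference; proteins failing the
  detection threshold are excluded, not filled in.
* The moderated model assumes approximately normal log2 intensities
  within groups and exchangeable variances around the (possibly
  intensity-dependent) prior; ordinary and moderated tests are both
  two-sided with no one-sided option.
* Venn analyses cap at six sets; larger designs should be compared at a
  coarser level.
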