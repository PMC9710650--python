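# proteoflow

Standardized downstream analysis of label-free, data-dependent-acquisition
(DDA) shotgun proteomics.  proteoflow imports MaxQuant-style
`proteinGroups.txt` tables (raw, LFQ or iBAQ intensities), builds a
tree-structured analysis design from the sample names, applies detection
thresholding and one of five normalization strategies, and runs a
catalogue of QC, exploratory and differential analyses.  Every analysis
writes a PDF figure *and* a CSV of the plotted numbers, and the complete
run configuration is saved so any result can be reproduced exactly.

It is aimed at groups who analyze label-free proteome experiments
repeatedly and want the steps between "MaxQuant finished" and
"differentially expressed protein list" to be scripted, versioned and
identical across projects.

## The core model

**Detection thresholding.**  Proteins drop out of MS data preferentially
at low abundance, so a protein is compared between groups only when
detected (raw intensity > 0) in enough samples per group.  The required
fraction follows a sigmoidal curve — 100 % of samples for groups of up
to 3, relaxing to 50 % for groups of 12 or more:

    f(n) = 0.5 + 0.5·σ(−k(n − 7.5)),  clamped to 1 for n ≤ 3 and 0.5 for n ≥ 12

with minimum count ⌈f(n)·n⌉.  For a group pair each protein is
*comparable* (above threshold in both), *unique* to one group (above
threshold there, entirely undetected in the other), or *not considered*.

**Moderated differential testing.**  Comparable proteins are tested with
an empirical-Bayes moderated t-statistic: per-protein variances s_g²
(d_g df) are shrunk toward a prior s0² with d0 prior df,

    s̃_g² = (d0·s0² + d_g·s_g²)/(d0 + d_g),    t_g = Δmean / √(s̃_g²(1/n_A + 1/n_B)),

where (d0, s0²) come from a method-of-moments fit on log s_g² and the
prior follows a lowess trend in average intensity (the intensity–
variance correction).  P-values are BH-adjusted.  Enrichment of GO-term
protein lists uses the one-tailed Fisher exact test against the measured
background.

See `docs/methods.md` for the full account, including normalization
definitions and the synthetic-data model.

## Worked example

Generate a synthetic benchmark-style dataset (1000 proteins, 2 cell
lines × 3 treatments × 2 replicates, intensity-dependent dropout, 10 %
of proteins shifted by 1 log2 unit in line B) and analyze it at level 0
(grouping by cell line):

```sh
proteoflow make-fixture --out demo --seed 42
proteoflow analyze --input demo/proteinGroups.txt --out demo/results \
    --level 0 --normalization median_norm \
    --analyses detection_counts,pca_overview,volcano
```

`detection_counts.csv` — how often proteins are detected across the six
samples of group A (the group total counts proteins seen at least once):

```
group times_detected  proteins
    A              1         4
    A              2        12
    A              3        24
    A              4        42
    A              5       127
    A              6       699
    A          total       908
```

Most proteins are seen in all six samples; the low-count tail is the
low-abundance dropout regime the threshold function guards against.

`pca_overview.csv` — samples projected on the first two principal
components of the 604 complete-case proteins; PC1 (30.6 % of variance)
separates the two cell lines:

```
   sample    PC1    PC2  group
A_ctrl_r1  -4.57  -3.88      A
A_ctrl_r2  -4.95  -1.19      A
  A_t1_r1  -4.86   2.66      A
  A_t1_r2  -4.03   0.69      A
```

`volcano.csv` — of 1000 measured proteins, 604 are comparable between
the lines and 306 fall below threshold; 80 proteins reach an adjusted
p < 0.05, led by planted effects recovered near their true 1-log2-unit
size:

```
  protein  log2_fc    p_value  adjusted_p_value
GENE00450    -1.29   4.4e-12         1.7e-09
GENE00487    -1.32   5.6e-12         1.7e-09
GENE00748    -1.31   1.7e-11         2.9e-09
```

(negative fold change = higher in line B, where the effect was planted).
Each CSV sits next to a PDF with the corresponding figure, plus
`config.yml` and `run.log`.  `proteoflow qc` bundles the QC analyses
into one multi-page report.

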