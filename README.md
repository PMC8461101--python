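# tamnk

Quantitative analysis of tumor-associated macrophage (TAM) balance in tumor
expression data: single-cell QC and normalization, single-sample gene-set
enrichment, a TAM-to-NK prognostic score, macrophage polarization annotation,
maximally-selected-cutpoint survival stratification, and ligand–receptor
interaction scoring — plus synthetic single-cell and survival-cohort
generators so the whole pipeline is testable without any external download.

## Who this is for

Computational biologists studying the tumor microenvironment who want a
small, fully reproducible implementation of the TAM-to-NK scoring and
prognosis workflow: score immune signatures per cell or per patient, split a
cohort at a data-driven score cutpoint, and quantify the survival difference
between the resulting groups.

## The score and the statistics

The core quantity is the **TAM-to-NK score**. For an observation *j* (a cell
or a patient) and single-sample enrichment operator *E*,

```
score_j = E_j(TAM) / E_j(NK)        (ratio form)
score_j = E_j(TAM) − E_j(NK)        (difference form, default)
```

where TAM is a 12-gene monocyte/TAM signature (*APOE, C1QA, C1QB, C1QC,
CCL12, CCL6, CCL8, LYZ2, PF4, WFDC17, CSF1R, CXCL14*) and NK is a 10-gene
NK-like signature (*AW112010, CCL5, CD3E, CD52, GZMA, GZMB, GZMC, IL2RB,
LTB, NKG7*). Enrichment *E* is one of three single-sample methods:

* **gsva** — kernel-CDF transform of each gene across observations
  (gaussian kernel, bandwidth SD/4; poisson kernel for counts), then a
  weighted Kolmogorov–Smirnov random walk over the per-observation gene
  ranking;
* **ssgsea** — rank weights |r|^τ (τ = 0.25) and the running-sum area
  statistic, normalized to [−1, 1];
* **zscore** — combined z-score Σ z_g / √|set| over per-gene standardized
  expression (default for patient cohorts).

Prognosis: subjects are split low/high at the score cutpoint *c* maximizing
the absolute standardized log-rank statistic over candidate cutpoints inside
the 10–90% score-quantile window (maxstat). Significance of the selected
split is assessed by a score-permutation null (which accounts for having
selected the maximum); group survival is summarized with the Kaplan–Meier
product-limit estimator, the two-group log-rank test, and a binary-covariate
Cox model (Breslow ties, Newton–Raphson), reported as a low-vs-high hazard
ratio — HR > 1 means a low TAM-to-NK score predicts poor prognosis.

## Worked example

Run the bundled fully-synthetic demo (360 simulated tumor cells across six
populations, plus a 120-patient cohort with a planted hazard ratio of 2):

```bash
tamnk all --outdir demo_out --seed 7
```

This writes QC reports, enrichment and score tables, ligand–receptor scores,
Kaplan–Meier curves and a survival report. `demo_out/survival_report.json`
contains (seed 7):

```
"cutpoint": -1.362,  "n_low": 54,  "n_high": 66,
"perm_p": 0.00498,
"hr": 2.788,  "logrank_p": 8.09e-06
```

Reading: the maxstat split found a TAM-to-NK cutpoint at −1.362; the 54
low-score patients have a 2.79-fold higher hazard than the 66 high-score
patients (log-rank p ≈ 8×10⁻⁶), and the selection-adjusted permutation test
confirms the split is not an artifact of cutpoint optimization
(perm p ≈ 0.005) — recovering the planted "low score, poor prognosis"
structure.

The same stages are available individually (`tamnk simulate|qc|enrich|
score|polarize|lr|survive`) and as a Python API of sklearn-style estimators
(`QCFilter`, `LogNormalizer`, `GeneSetScorer`, `TamNkScorer`,
`PolarizationAnnotator`, `MaxstatStratifier`).

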