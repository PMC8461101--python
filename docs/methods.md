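# Methods

This note documents the models, defaults and numerical choices behind
`tamnk`, and what the synthetic-data generators do and do not emulate.

## Expression containers and gene symbols

Expression is held as a genes × observations matrix tagged `counts`
(non-negative integers) or `lognorm`. Gene symbols are uppercased on ingest
so mouse-style symbols (`Cd74`) and human symbols (`CD74`) resolve
identically — the signatures were derived in mouse tumors and are applied to
human cohorts, so a shared namespace is required. A small alias table maps
typographical variants that appear in the literature (`Folr2x` → FOLR2,
`CAF1R` → CSF1R) to official symbols. `AW112010` is a mouse transcript with
no human ortholog; on human data it simply fails to match and is dropped at
scoring time (sets falling below `min_set_genes` matched genes are skipped
with a warning).

## Cell QC and normalization

Per-cell metrics are the number of detected genes, total UMI, and
mitochondrial percentage (genes matching the prefixes `MT-`/`mt-`,
configurable). Cells are kept when

* `min_genes ≤ n_genes ≤ max_genes` (inclusive; defaults 500 and 50,000),
* `total_umi < max_umi` (strict; default 30,000),
* `pct_mito < max_pct_mito` (strict; default 20).

The gene bounds are read as inclusive ("between") and the UMI/mito caps as
strict ("less than"); the boundary semantics are pinned by tests.
Normalization is the standard library-size recipe: each cell is scaled to
10,000 counts and transformed with natural log1p,
`v = ln(1 + 10000·c/total)`. This satisfies the per-cell identity
`Σ_g (exp(v_g) − 1) = 10000` (used as a self-check) and is equivariant to
scaling a cell's counts. Threshold filtering runs before doublet flagging
in the pipeline; the order is configurable and recorded in the manifest.

## Doublet flagging

A cell is flagged as a putative doublet when at least two
population-specific marker panels are highly expressed: each panel's mean
log1p count per cell is z-scored across cells and compared with a threshold
(default z > 2). This is a transparent, model-free rule.

**Known limitation.** The z-score of a panel's positive cells is bounded by
√((1−p)/p), where p is the positive population's fraction of all cells: a
panel whose cell type makes up ≥20% of the data can never exceed z = 2, and
doublets involving a population with no marker panel (e.g. tumor cells)
elevate only one panel and are undetectable by the ≥2-panel rule. The
threshold rule therefore has high precision (singlet false-positive rates
near zero in our simulations) but structurally limited recall on realistic
compositions; model-based detectors exist precisely to overcome this and
are out of scope here. The test suite asserts what the rule does guarantee:
exact agreement with an independent per-cell recomputation, and a flagging
rate for planted marker–marker doublets far above the singlet rate.

## Single-sample enrichment

Three methods sit behind one interface.

* **gsva.** Each gene's profile across observations is mapped to CDF space
  with a kernel estimate — gaussian kernel with per-gene bandwidth
  SD/4 for continuous input, a Poisson kernel (rates x_k + 0.5) for counts,
  or plain empirical-CDF ranks scaled into (0,1) (`kernel="none"`). Genes
  are then ranked per observation and a weighted KS-like random walk is
  taken over the ranking: in-set steps weighted |rank|^τ (τ = 1, normalized
  to sum 1), out-of-set steps uniform. `es_mode="diff"` returns
  max-positive + min-negative deviation; `"max"` the largest-magnitude
  deviation with sign. Scores lie in [−1, 1]; a set spanning the whole
  ranking is defined as ES = 1 (the walk has no down-steps).
* **ssgsea.** Ranks of raw expression per observation, weights |rank|^τ
  with τ = 0.25, and the running-sum area statistic. The area is normalized
  into [−1, 1] by the maximum area attainable with the same in-set weight
  multiset (weights relocated to the top of the ranking, largest first; an
  exchange argument shows this bounds any placement), so a perfectly
  top-enriched set scores exactly 1.
* **zscore.** Per-gene standardization across observations (sample SD,
  ddof = 1; constant genes contribute 0) and the combined z-score
  Σ z_g / √|set|.

Ranking ties are broken by gene symbol (lexicographic), which is both
deterministic and invariant to the row order of the input matrix. Default
method is `zscore` for patient cohorts and `ssgsea` with `kernel="none"`
for per-cell scoring — kernel CDF estimation across sparse single cells is
unstable, whereas rank-based scoring is not. Note that for τ > 0 the
weighted walk has a positive mean under random set placement (in-set steps
are up-weighted near the top of the ranking); only the unweighted walk
(τ = 0) is symmetric around 0 under label permutation.

## TAM-to-NK score

Default mode is the difference `E(TAM) − E(NK)`, which is always defined;
the literal ratio `E(TAM)/E(NK)` is available but undefined when
|E(NK)| < ε (default 10⁻⁸) — enrichment scores can be zero or negative, so
the ratio is numerically unstable, while the difference preserves the
ordering the survival split needs. The number of observations a ratio-mode
run drops is logged, and dropped subjects are counted in the survival
report.

## Polarization annotation

Rather than re-clustering, cells are annotated by their marker-panel
evidence directly: the panel score is the mean log-normalized expression of
the panel's genes (M0: CD74/C1QA/APOE; M1: CXCL2/IL1B/CXCL10; M2:
CCL8/CBR2/FOLR2), and a cell is labeled by the argmax panel only when it
exceeds the runner-up by more than a margin δ (default 0; exact ties are
always UNASSIGNED).

## Ligand–receptor scoring

For a ligand→receptor pair between a sender and a receiver population, the
per-sample score combines the ligand's mean expression over sender cells
(L̄) and the receptor's over receiver cells (R̄) as (L̄+R̄)/2 (default,
the plain "average expression" reading) or L̄·R̄ (field convention,
annihilates when either side is silent); the final score averages samples.
Built-in axes: CCL3–CCR5, CSF1–CSF1R, ICAM1–ITGAL, CCL4–CCR5.

## Survival stratification

* **Kaplan–Meier** product-limit estimator, evaluated at every distinct
  observed time (censored-only times reduce the risk set without dropping
  the curve).
* **Log-rank**: at each event time a 2×2 table contributes observed minus
  hypergeometric-expected events and the pooled variance; the statistic is
  χ² with 1 df. Zero total events returns (0, p = 1) with a log message.
* **Maxstat**: candidate cutpoints are midpoints between consecutive
  distinct scores inside the 10–90% score-quantile window (the maxstat
  convention; configurable). The statistic at each candidate is the signed
  standardized log-rank (O−E)/√V between score≤c and score>c; the chosen
  cutpoint maximizes |statistic| (smallest candidate on exact ties). The
  p-value is a score-permutation test with add-one smoothing,
  (1 + #{perm max ≥ observed max})/(1 + n_perm), which is exact at these
  sample sizes and needs no asymptotic approximation constants; n_perm
  (default 1000) and the seed are configuration. Candidate statistics for
  all cutpoints and permutations are computed with a shared vectorized
  prefix formulation (cells sorted by score; cumulative risk/death counts
  give every prefix's log-rank in one pass), which keeps permutation nulls
  cheap.
* **Cox hazard ratio**: single binary covariate, Breslow tie handling,
  Newton–Raphson on the partial likelihood to |Δβ| < 10⁻⁸ (≤50
  iterations), Wald CI and p from observed information. The covariate codes
  low = 1 against the high-score reference, so HR > 1 reads "low TAM-to-NK
  score, poor prognosis". Monotone likelihoods (all events in one group)
  are capped at |β| = 15 and flagged.

## Synthetic data

`simulate_single_cell` draws negative-binomial counts with variance
μ + μ²·φ (dispersion φ = 0.1 by default, a typical UMI-level value).
Gene-level baseline abundances are gamma-distributed (a few genes dominate
the library, as in real data); per-cell library sizes are lognormal with
mean `lib_size_mean` (default 5,000). Each cell type's marker panel is
shifted up by `marker_log2_fc` (default 3) in mean space, and cell-type
signature genes (the TAM/NK lists) by half that, with means renormalized so
the expected library size is preserved. Ten `MT-` genes receive on average
`mito_fraction_mean` (default 5%) of each library. Doublets are raw count
sums of two random parents of different types — modeling physical
co-encapsulation and guaranteeing elevated UMI — and are labeled as such.
Identical configs (including seed) are bit-reproducible.

What it does not emulate: batch effects, ambient RNA, dropout beyond NB
sampling, trajectory structure, or realistic gene–gene correlation — so
passing tests demonstrate the pipeline's statistical behaviour under its
stated model, not robustness to those artifacts.

`simulate_cohort` plants a two-group prognostic structure: half the
patients ("low") have TAM-list genes shifted down and NK-list genes up by
`score_shift`/2 each (default shift 1.0 on the log scale) and survival is
exponential with hazard `baseline_hazard × true_hr_low_vs_high` (defaults
0.1 and 2.0) against the high group's baseline — the simplest model
satisfying proportional hazards, which is what the Cox estimator assumes.
Censoring is independent Uniform(0, c) with c solved numerically so the
expected censoring fraction matches `censor_rate` (default 0.2).

## Problem sizes used by tests and the acceptance script

Enrichment oracle checks use a 10-gene × 6-observation matrix; doublet
recovery a 500-cell simulation with a tumor-cell-majority composition
(300 tumor + 5×40 immune/stromal cells — dissociated solid tumors are
typically dominated by tumor cells); maxstat validity 100 null replicates
at n = 200 with 500 permutations each; hazard-ratio recovery 50 replicates
at n = 500 with 199-permutation maxstat inside the full pipeline. These
sizes give stable rates while keeping a full run to a few minutes on one
CPU.

## Known limitations

* The doublet-flag recall ceiling described above.
* Per-cell GSVA on sparse counts is noisy; the per-cell default is
  rank-based ssGSEA for that reason, and the GSVA kernel path is intended
  for bulk or pseudobulk input.
* The Cox model is univariate by design; no multivariate adjustment or
  competing risks.
* The maxstat permutation p is exact only conditional on the observed
  score multiset and censoring pattern; the Lausen–Schumacher asymptotic
  correction is deliberately not implemented.
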