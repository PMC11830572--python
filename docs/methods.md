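# Methods

## The measurement and the model

5hmC-Seal sequencing of cell-free DNA yields, per sample, a set of
hydroxymethylated regions (hMRs, peaks) and read counts over a common
region set. We model the count of region *i* in sample *j* as negative
binomial,

    K_ij ~ NB(mean = mu_ij, dispersion = alpha_i),   Var = mu + alpha mu^2,
    log mu_ij = log s_j + beta_0i + beta_1i * x_j,

with `s_j` a per-sample normalization constant, `x_j` the group indicator
of the contrast (reference group 0), `beta_1i` the natural-log group
effect (reported as log2FC = beta_1 / ln 2), and `alpha_i` a per-region
dispersion. This is the standard count-GLM used for differential
enrichment of sequencing regions.

**Size factors** are median-of-ratios: the reference is the per-region
geometric mean over samples, computed on regions with nonzero counts in
every sample; `s_j` is the median of sample *j*'s count/reference ratios.
When no region is positive everywhere (sparse matrices), a
pseudo-reference over each region's nonzero entries is available behind a
`fallback` flag.

**Dispersion** is estimated per region by method of moments on normalized
counts with group means removed: `alpha = clip((v - m)/m^2, 1e-8, 10)`
with pooled within-group variance `v` and pooled mean `m`. There is no
empirical-Bayes shrinkage and no fold-change shrinkage; results therefore
differ from shrinkage-based tools in small samples. The choice is
validated by simulation rather than by output matching: at 20 + 20
samples and 20 000 null regions the Wald test's type-I error at p < .01
is ~0.013 (band 0.005–0.02) and the null p-value distribution is uniform
to Kolmogorov–Smirnov distance < 0.02 (see `tests/test_acceptance.py`).

**Fitting.** Each region's two-parameter GLM is solved by iteratively
reweighted least squares with expected-information weights
`w = mu/(1 + alpha mu)`, vectorized across all regions (2×2 systems in
closed form), convergence `|delta beta| < 1e-8`, at most 100 iterations.
Standard errors come from the Fisher information at the optimum; p-values
are two-sided normal. All-zero regions are flagged (p = 1, log2FC = 0).
A region whose contrast group is entirely zero drifts to the `|beta_1| <= 20`
cap and is flagged non-converged rather than erroring. Agreement with an
independent Nelder–Mead maximization of the NB likelihood is 1e-6 on
random 3+3 fixtures.

**DhMR calls** use `|log2FC| >= 0.5` (inclusive) and `p < 0.01` (strict);
a 0.35 preset mirrors the relaxed threshold used for some contrasts. Raw
p-values are thresholded (matching the published procedure); a
Benjamini–Hochberg `padj` column is emitted for users who prefer FDR.

## Marker selection

Features entering selection are `log2(count/s_j + 1)`, z-scored with
statistics of the data being fitted (training cohort only for the final
model; the leakage test in the suite verifies validation data never
touches the standardization).

The cohort (two groups) is split 2:1 into training and validation,
stratified per class with `round(2/3 * n_class)` (round-half-even)
training samples. The published cohort's 44+22 / 26+10 split is not
reproducible from "2:1" under any standard rounding; no attempt is made
to match it.

Selection is a stability consensus over recursive feature elimination
(RFE):

* estimator: logistic regression with L2 penalty `lambda/2 ||beta||^2`
  (intercept unpenalized) and balanced class weights
  `w_i = n / (2 n_class(i))`, solved by a damped Newton method (strictly
  convex for lambda > 0; gradient norm < 1e-6 at the solution; verified
  against scikit-learn's lbfgs solver to 1e-5). An in-house solver is
  used because stability selection performs on the order of a million
  small fits; it is JIT-compiled when numba is present.
* RFE: at each size, lambda is chosen by stratified 2-fold
  cross-validated accuracy (ties prefer stronger regularization), the
  model is refitted, and the `ceil(0.1 * remaining)` features with
  smallest |weight| are dropped (ties lexicographic). The selected set is
  the smallest size whose CV accuracy ties the maximum.
* consensus: five rounds, each on a stratified 4/5 subsample of the
  training cohort, each running 100 RFE repeats with distinct derived
  seeds. A marker is *observed* in a round when it appears in at least
  30% of that round's selected sets, and enters the panel when observed
  in at least 3 of 5 rounds.

The 30% within-round threshold deserves a note. "Observed" is read as
recurrent presence rather than majority presence: because the RFE rule is
parsimonious (smallest size at the accuracy optimum), a majority rule
collapses every round onto the few strongest markers and discards the
complementary ones a consensus panel is meant to capture. At 30% the
procedure recovers planted multi-marker panels reliably (below) while
still rejecting one-off noise selections. The threshold is exposed as a
parameter (`within_round_rule`).

**Recovery behavior.** With 10 planted markers (|log2FC| in 1.2–2,
dispersion 0.4–0.8, typical of small-region cfDNA counts across
patients) among 500 candidates and 66 training samples, the consensus
panel contains at least 7 of the 10 planted markers in ~88% of 50
replicates. Two regimes bracket this: with low dispersion the markers are
individually so strong that CV accuracy saturates and RFE keeps only 2–3
of them (the panel is small but perfect); with dispersion beyond ~1 the
markers no longer clear the p < .01 differential gate at this sample
size. The consensus machinery matters precisely in the intermediate
regime where markers are jointly but not singly informative.

## Evaluation

ROC curves enumerate all distinct score thresholds with tie grouping, so
the trapezoidal AUC equals the Mann–Whitney statistic U/(n+ n−) exactly
(asserted as a cross-module identity). Confusion matrices use predicted
probability >= 0.5 by default (flag-adjustable). Per-marker AUC is
reported in class-1-high orientation `max(a, 1-a)` with an explicit
orientation flag rather than silently folding. PCA is column-centered
SVD. Survival: per-group Kaplan–Meier product-limit curves and the
unstratified two-sample log-rank test (lifelines); marker levels are
dichotomized at the median, strictly-greater = high (the published
cutoff is unstated; quantile rules are pluggable).

## Synthetic cohort

The generator emulates the study's structure, not its sequences:

* **Genome/genes**: 3 chromosomes, 150 genes (4–20 kb, 1–6 exons,
  intron-weighted segment lengths), non-overlapping, both strands, gene
  spacing >= 12 kb so promoter windows never collide.
* **Regions**: 800 candidate hMRs, widths 100–999 bp, placed mutually
  disjoint with planted feature labels drawn from an intron-heavy mix
  (promoter .12 / exon .13 / intron .55 / intergenic .20, echoing
  observed cfDNA peak distributions); placement respects the annotation
  priority rules so planted labels are exactly recoverable.
* **Counts**: baselines `q_i` log-normal (median 50 reads), depths `s_j`
  log-normal (sd 0.25 on the log scale), dispersions uniform 0.05–0.3, a
  5% differential fraction with |log2FC| uniform 0.5–2 and random sign,
  planted only between the PC-like and MLM-like groups (the third group
  reuses reference parameters; the analyses are pairwise). The stored
  library size is the realized column total, matching how RPM/FPKM are
  computed downstream.
* **Cohort**: 70 PC / 32 MLM / 31 SLM (scalable).
* **Coverage**: deterministic piecewise-constant track — background 0.5,
  gene bodies 5.0, and a strand-aware V-shaped dip around each TSS
  (multiplier 0.3 at the TSS tapering to 1 at ±1 kb), emulating the
  nucleosome-depleted dip seen in gene-body 5hmC profiles.
* **Survival**: exponential event times with hazard
  `h0 * HR^{I[level > median]}` (OS baseline 0.02/month, HR 2.5, EFS
  baseline 1.5×), independent exponential censoring (0.01/month).

One seed drives everything; sub-generators are derived by fixed stream
offsets so, e.g., adding regions does not perturb gene simulation, and
every artifact is byte-identical across runs with the same seed.

What the generator does **not** emulate: read-level data (peaks are
thresholded counts, not MACS calls), batch effects, GC/mappability bias,
correlated regions (each region's counts are independent given the
design), or inter-marker correlation within a patient. Passing tests
therefore demonstrate correctness of the estimators and procedures under
the stated model, and calibrated behavior under NB sampling — not
robustness to artifacts real cfDNA data may carry.

## Metagene profiles

Gene bodies are rescaled to 100 bins, flanks of 2 kb use 20 fixed-width
bins each; the bin value is the *mean per-bp coverage* inside the bin (so
unequal gene lengths are comparable), averaged over genes, reversed for
minus-strand genes (bin 0 is always 5'-most), and converted to RPM with
the sample's library size. Genes shorter than the body bin count are
skipped and reported. Profiles are linear in the track and
strand-symmetric (both asserted).

## Numerical and procedural choices

* Interval merging is 0-gap (abutting intervals merge), asserted equal to
  a per-bp occupancy oracle on 200 random instances.
* Retention filter: support **> 10** and width **< 1000** (strict, per
  the published wording); blacklist overlap of even 1 bp excludes.
* Annotation: promoter = any overlap with TSS ± 2 kb; body/downstream
  labels use the region midpoint; nearest gene minimizes |midpoint −
  TSS|; all ties lexicographic. UTRs are folded into exon.
* Wilcoxon rank-sum uses exact enumeration when n_x n_y <= 1e4 and no
  ties, otherwise the tie-corrected normal approximation.
* Default problem sizes (800 regions / 133 samples for the pipeline;
  20 000 regions for null calibration; 50 replicates for stability
  recovery; 10 replicates for the recovery summary in the acceptance
  script) were chosen so the whole suite and script each run in minutes
  on a single CPU while keeping Monte-Carlo error well inside the
  asserted bands.

## Known limitations

* No empirical-Bayes dispersion moderation: in cohorts of ~10 samples per
  group the Wald test will be less stable than shrinkage-based tools; the
  calibration shown holds at 20/group.
* The differential gate (raw p < .01) and all published thresholds are
  reproduced verbatim; multiple-testing control is advisory only.
* Peak calling, alignment, and QC are out of scope; peaks and counts are
  consumed as inputs.
* The upstream flank of a gene closer than the flank width to the
  chromosome origin is skipped in metagene profiles rather than
  truncated.
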