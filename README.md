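# portal5hmc

Analysis pipeline for 5-hydroxymethylcytosine (5hmC) profiles of cell-free
DNA from portal venous blood, built around the question of whether cfDNA
hydroxymethylation can warn of metachronous liver metastasis (MLM) in
colorectal cancer before it is clinically visible. The package covers the
full downstream path from per-sample hydroxymethylated regions (hMRs) and a
regions × samples read-count matrix to a validated marker panel:

1. **Regions** — merge per-sample peak calls (0-gap, bedtools semantics),
   retain regions supported by more than 10 samples and narrower than
   1000 bp, exclude blacklisted intervals, and annotate against gene models
   (promoter = TSS ± 2 kb, then exon > intron > downstream > intergenic by
   fixed priority).
2. **Differential** — negative-binomial Wald test per region. With counts
   K<sub>ij</sub> ~ NB(μ<sub>ij</sub>, α<sub>i</sub>),
   log μ<sub>ij</sub> = log s<sub>j</sub> + β<sub>0i</sub> + β<sub>1i</sub> x<sub>j</sub>,
   where s<sub>j</sub> are median-of-ratios size factors and x<sub>j</sub>
   indicates the contrast group; the Wald statistic is
   z = β̂₁ / se(β̂₁) and a region is a DhMR when |log₂FC| ≥ 0.5 and
   p < 0.01 (presets 0.35 and 0.5 are provided).
3. **Markers** — stratified 2:1 training/validation split; five rounds of
   stratified 4/5 subsampling, each running 100 re-seeded passes of
   recursive feature elimination under an L2-penalized class-balanced
   logistic estimator with internal 2-fold accuracy cross-validation;
   markers observed in at least 3 of 5 rounds form the consensus panel,
   on which the final penalized logistic model is trained.
4. **Evaluation** — ROC/AUC (trapezoidal, equal to the Mann–Whitney
   U/(n₊n₋)), confusion matrices, per-marker AUC, PCA, Pearson
   correlation, and Kaplan–Meier / log-rank survival stratification by
   marker level.
5. **Synthetic cohort** — a seeded generator emulating the three-group
   cohort (70 PC / 32 MLM / 31 SLM), intron-enriched region placement,
   NB counts with sample-specific depths and planted fold changes,
   gene-body-enriched coverage with a TSS dip, and exponential survival
   whose hazard depends on a marker's level — so the entire pipeline runs
   and is tested without any controlled-access human data.

## Worked example

```sh
portal5hmc simulate --seed 3 --out sim
portal5hmc diff --counts sim/counts.tsv --libsizes sim/library_sizes.tsv \
    --samples sim/samples.tsv --groups PC,MLM --out dhmr.tsv
portal5hmc select --counts sim/counts.tsv --libsizes sim/library_sizes.tsv \
    --samples sim/samples.tsv --dhmr dhmr.tsv --groups PC,MLM --out sel
portal5hmc evaluate --model sel/model.json --counts sim/counts.tsv \
    --libsizes sim/library_sizes.tsv --samples sim/samples.tsv \
    --groups PC,MLM --out ev
```

prints

```
21 up, 20 down of 800 regions (|log2FC| >= 0.5, p < 0.01)
panel of 1 markers (>= 3 of 5 rounds)
AUC 1.000, sensitivity 1.000, specificity 1.000
```

41 of the 800 simulated regions are called differential between the
PC-like and MLM-like groups (40 were planted, so the calls sit at the
expected mix of power and the 1% false-positive rate). At the default
generator settings the planted effects are strong, so the consensus panel
collapses onto a single sufficient marker and separates the groups
perfectly; `docs/methods.md` discusses the high-dispersion regime in which
the panel spreads over many complementary markers, as in real cohorts.
`portal5hmc run --out DIR` executes the same chain end-to-end from one
config and writes a `report.json` whose counts are checked against every
artifact.

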