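# regmra

Reverse-engineering of tumor regulatory networks and master-regulator
analysis, built as a tested, fully synthetic-data-driven pipeline. The
package is aimed at computational biologists who want the classic
"regulome" workflow — mutual-information network inference, master
regulator analysis against cell-of-origin signatures, per-sample regulon
activity, survival stratification, and regulon methylation enrichment — as
reusable, inspectable Python, with a generator that plants the exact
statistical structure the analysis is supposed to find.

## The method

**Network inference (TNI).** For an expression cohort X (genes × samples,
log2) and a regulator list, mutual information is estimated for every
(TF, gene) pair on rank-transformed values with equal-frequency binning
into B = ⌊√n⌋ bins. Spurious associations are removed with an empirical
permutation null pooled across pairs (BH-adjusted p ≤ 0.05), and indirect
edges are pruned with the ARACNe data-processing inequality: in each fully
connected (TF1, TF2, g) triplet the weakest TF–g edge is dropped. Each
regulon carries a mode of action per target, m ∈ {−1, +1}, the sign of the
TF–target Spearman correlation; regulons with fewer than 15 genes are
excluded from downstream analyses.

**Master regulator analysis (MRA).** A gene signature (differential
expression between tumor and putative cell-of-origin samples, Welch t-test,
BH ≤ 0.05) is tested for over-representation in every regulon with the
one-tailed hypergeometric test

    p = Σ_{j≥k} C(K,j) C(N−K, n−j) / C(N,n),

BH across regulons; TFs passing in *every* network × signature combination
form the consensus MR set.

**Regulon activity (GSEA2).** Expression is z-scored per gene; per sample,
genes ranked by z feed a two-tailed weighted KS enrichment score,
dES = ES(positive targets) − ES(negative targets) ∈ [−2, 2] — positive when
the regulon is activated, negative when repressed. Activity profiles are
clustered (average linkage, 1 − Pearson), regulon pairs are labeled
agonist/antagonist by the sign agreement of their shared targets, and
cohorts are median-split per regulon into high/low activity for
Kaplan–Meier + log-rank survival comparison.

**Methylation.** Probe-wise case/control Welch tests on M-values
(Bonferroni < 0.01) define differentially methylated genes (any-probe
rule), and each regulon is tested for DM-gene enrichment (Fisher,
Bonferroni < 0.01) per network.

The synthetic generator plants two mutually antagonistic MR clusters
(2 + 5 TFs) whose shared targets carry opposite regulatory signs across
clusters, anticorrelated latent activities, survival effects with opposite
signs per cluster, and methylation shifts concentrated in regulon targets —
so every downstream claim has a ground truth to be scored against. See
`docs/methods.md` for the model and all parameter choices.

## Worked example

```python
import regmra as r

cfg = r.PipelineConfig(seed=1)          # the default study conditions
report = r.run_pipeline(cfg)

st = report["stages"]
print(st["consensus"]["mrs"])
print(st["networks"]["network1"]["recovery"])
print(st["survival"]["cohort2"]["direction_accuracy"])
```

prints

```
['TF01', 'TF02', 'TF03', 'TF04', 'TF05', 'TF06', 'TF07']
{'precision': 0.9513, 'recall': 0.9071, 'mode_agreement': 1.0, ...}
1.0
```

meaning: the four MRA runs (2 networks × 2 signatures) agree on exactly the
seven planted master regulators; the first inferred network recovers the
planted regulons with 95% per-target precision and 91% recall, with every
recovered mode matching the planted regulatory sign; and all regulons'
prognostic directions (cluster A protective, cluster B adverse) are called
correctly in the survival screen.

The same pipeline is scriptable from a shell:

```bash
regmra run --seed 1 --outdir out/          # full pipeline + run_report.json
regmra simulate --outdir sim/              # truth + one cohort as TSV
regmra infer --expr sim/expression.tsv --tfs sim/tfs.txt --outdir net/
```

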