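# Methods

`regmra` reimplements a master-regulator workflow for tumor transcriptomics:
mutual-information (MI) regulatory network inference, master-regulator
analysis (MRA) against cell-of-origin gene signatures, per-sample two-tailed
regulon activity, survival stratification by regulon activity, and regulon
enrichment of differential methylation. Every stage is exercised against a
synthetic-cohort generator that plants the structure the workflow is meant
to detect, so the whole stack is testable without any external download.

## The planted model

The generator assumes a linear-Gaussian model of log2 expression,

    x_gs = Σ_t w_tg · a_ts + ε_gs,     ε ~ N(0, σ²),

where `a_ts` is the latent activity of TF `t` in sample `s` and `w_tg` the
signed regulatory weight. A TF's own transcript reads out its activity with
a smaller observation noise (sd 0.3 by default) — the regulator's expression
is the proxy MI-based inference conditions on, so its fidelity is part of
the planted model.

Seven of the ten TFs are planted master regulators (MRs), partitioned into
two clusters of 2 and 5. Each MR regulon holds 40 targets: a pool of 12
(30%) shared across *all* MRs with opposite signs between clusters and
equal signs within a cluster — the agonist/antagonist fingerprint — and 28
private targets with random signs. The three remaining TFs are decoys with
5-target regulons, deliberately below the size-15 regulon filter, so both
the filter and MRA specificity are exercised. MR activities are standard
normal but share one latent axis with loading +0.6 (cluster A) or −0.6
(cluster B), which makes the two clusters' mean activities anticorrelated
across samples, as in the antagonistic activity heatmaps the analysis
produces.

Effect sizes are study conditions chosen once, not fitted quantities:
regulatory weight |w| = 2 and residual sd 1 put the TF–target correlation
near 0.86 for private targets, i.e. clearly detectable but far from
noise-free; coupling 0.6 keeps cluster antagonism strong (mean-activity
correlation ≈ −0.7) while limiting spurious cross-regulator correlation;
signature cohorts use n = 20 per group with an antagonistic per-cluster
activity shift of ±3 (a shift applied equally to both clusters would cancel
on the sign-flipped shared targets); survival uses log-hazard effects −1
(cluster A, protective) and +1 (cluster B) with 20% censoring; methylation
plants Δβ = 0.4 with probe noise sd 0.05 in a 15-case / 9-control design.

What the generator does *not* emulate: probe-level microarray structure,
batch effects, library-size or count noise, correlated measurement error,
and any nonlinearity in regulation. Passing tests therefore demonstrate
that the algorithms recover the planted statistical structure under
idealized noise, not that real cohorts would behave as cleanly.

## Network inference

MI between each regulator and every other gene is a plug-in estimate on
rank-transformed values with equal-frequency binning into B = ⌊√n⌋ bins
(natural log). Ranks use average ties; constant genes are flagged, not
dropped. For a deterministic monotone pair the estimate equals the bin
entropy ln B exactly, which the tests rely on.

Significance uses an empirical null pooled across all (TF, target) pairs:
each permutation draws one random relabeling of samples for the targets and
recomputes every pair's MI, giving `n_perm × pairs` null draws; empirical
p-values use the add-one rule and Benjamini–Hochberg is applied globally
across pairs (per-TF adjustment is available behind a flag). Defaults:
500 permutations, BH α = 0.05.

The data-processing inequality (DPI) prunes indirect edges: in every
triplet (TF1, TF2, g) with all three edges present, the weaker TF–g edge is
removed when it is weaker than both other edges by more than `dpi_eps`
(default 0; DPI can be switched off). Removals are computed against the
pre-pruning edge set, so the result does not depend on iteration order, and
the anchoring TF–TF edge is never removed by its own triplet. Note that a
*literally* noise-free chain makes all three MIs equal (each variable is a
monotone function of the same latent), so the chain construction used to
validate DPI adds a small per-step noise (sd 0.3) to make the indirect edge
strictly weakest — which is the regime DPI addresses.

Mode of action is the sign of the Spearman correlation between TF and
target; zero/undefined correlations drop the target with a warning.
Regulons below 15 targets are retained in the raw listing but excluded from
MRA, association maps, activity and methylation enrichment. Bootstrap
consensus inference is intentionally out of scope.

## Signatures and MRA

Signatures come from a Welch t-test per gene on log2 expression between a
tumor group and a putative cell-of-origin group, BH-adjusted, signature =
genes with adjusted p ≤ 0.05. (The original workflow this emulates derived
signatures from an RNA-seq differential-expression tool; a two-sample test
is the appropriate machinery for the generator's Gaussian matrices, and the
MRA stage only consumes a gene set — plain gene-list signatures are also
accepted.) The signature is used unsigned in MRA; signed statistics are
retained for reporting.

MRA runs one one-tailed hypergeometric over-representation test per
size-filtered regulon. The test universe is the intersection of the network
universe with the signature-tested genes; since nothing pins this choice
down externally, the universe is recorded in the result and the plain
network universe is used for list-based signatures. BH across regulons at
α = 0.05 defines the MR set; the consensus is the strict intersection of
the MR sets across all supplied network × signature analyses.

## Regulon activity

Expression is z-scored per gene across the cohort (sample sd, n−1). Per
sample, genes are ranked by z descending — ties broken by gene id so the
ranking is deterministic — and each regulon is scored with a weighted
Kolmogorov–Smirnov running sum: hits increment by |z|/Σ_hits|z|, misses
decrement by 1/(N−hits); the enrichment score ES is the signed
maximum-magnitude deviation (ties between the positive and negative extreme
resolve to the positive one; the weight exponent on |z| is 1 and
configurable). The two-tailed activity is dES = ES(positive targets) −
ES(negative targets) ∈ [−2, 2]; an empty positive or negative subset
contributes 0, so one-sided regulons still score. No permutation
normalization is applied: the raw dES is reported (and labeled as such in
the output metadata) because it is deterministic and testable; nothing in
the emulated workflow specifies a normalization formula.

Activity supports projection: a cohort too small for inference is scored
with a network inferred elsewhere, intersecting each regulon with the
available genes and flagging regulons that lose more than half their
targets.

Association maps label regulon pairs by the fraction of mutually regulated
genes with agreeing modes (> 0.5 agonist, < 0.5 antagonist, = 0.5
ambiguous), with a configurable minimum overlap (default 1). Hierarchical
clustering of activity uses average linkage on 1 − Pearson distance for
regulons and Euclidean distance for samples; merges follow scipy's
deterministic nearest-neighbour-chain order.

## Survival

Samples are split at the median of each regulon's activity: strictly above
→ "high", at or below → "low" (the tie convention is a documented choice;
nothing external fixes it). Survival curves use the Kaplan–Meier
product-limit estimator; groups are compared with the standard unweighted
log-rank test (hypergeometric variance, 1 df). The prognostic direction
("good" = high activity lives longer) compares KM median survival of the
two groups, falling back to restricted mean survival time when the medians
tie or are both undefined. The screen reports raw and BH-adjusted p-values;
the raw values are the headline numbers, matching the per-regulon reporting
convention of the emulated analysis. The simulator's survival generator is
exponential proportional hazards on the mean cluster activities with
uniform (0, τ) censoring, τ solved by bisection from the closed-form
censoring probability so the expected censored fraction matches the
requested rate.

## Methylation

Beta values are compared on the M-value scale, M = log2(β/(1−β)) with β
clipped to [1e−3, 1−1e−3], Welch t-test per probe, Bonferroni across probes
at 0.01. A gene is differentially methylated when at least one of its
probes is (the any-probe rule; a majority rule would be stricter — the
choice is documented, not externally fixed). Each size-filtered regulon is
then tested for over-representation of DM genes against the universe of
probe-mapped genes in the network universe, Bonferroni across regulons at
0.01, run once per network. Array preprocessing and failed-position QC are
reduced to an optional probe mask on input.

## Problem sizes and determinism

The default study conditions are 10 TFs, 500 genes, cohorts of 120 samples
(plus a 44-sample survival cohort scored by projection), 500 permutations
for the edge null — sizes at which a full pipeline run takes seconds and
repeated-seed properties (consensus recovery, survival power, methylation
enrichment) can be measured over 20 seeds in the test suite. All
randomness flows from one integer seed through `numpy.random.SeedSequence`
spawning; reports are JSON with sorted keys, and rerunning with the same
config and seed reproduces them byte-identically.

## Known limitations

- The MI estimator's plug-in bias at B = ⌊√n⌋ is large relative to weak
  signals; the pooled permutation null absorbs the bias but power against
  correlations below ~0.5 is limited at n ≈ 120.
- Targets regulated by many TFs at once (the cross-cluster shared pool)
  correlate only partially with each individual regulator and are the main
  source of missed edges.
- The consensus is a strict intersection: a single under-powered analysis
  can empty it.
- Direction calls for survival rest on KM medians of median-split groups
  and can be unstable in very small cohorts.
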