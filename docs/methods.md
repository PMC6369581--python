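# Methods

This note documents the models, conventions, and numerical choices behind
`methnet`, and what the synthetic cohorts do and do not establish.

## Synthetic cohort model

The generator emulates a five-phenotype tumor cohort (normal, stages
I–IV).  Default sample counts follow a TCGA-like stomach-cancer cohort
(27 normal; 35/93/92/23 matched tumor samples in stages I–IV); sizes are
fully configurable.

**Methylation.**  Each probe carries a per-phenotype *mode*, low
(unmethylated) or high (methylated); per-sample beta values are drawn from
Beta(mμ, m(1−μ)) with mode mean μ (defaults 0.10 / 0.85) and concentration
m = 20.  This reproduces the bimodal beta-value histogram of methylation
arrays without modelling array chemistry.  A configurable fraction of
probes (default 20%) sits in the high mode, matching the convention that
most promoter probes are unmethylated.

**Probe–gene coupling.**  Planted pairs receive expression built from the
standardized within-phenotype beta as
`e = −c·z(β) + √(1−c²)·ε`, giving Pearson correlation −c per phenotype
(Spearman follows closely); c defaults to 0.8.

**Regulation and gating.**  Regulated targets receive
`e_t = b_t + Σ_f a·g(β)·z_f − z(β) + ε`, where `z_f` is the TF's
standardized expression, `a` the edge effect size (default 1.0),
`ε ~ N(0, 0.3²)`, and `g(β) = 1/(1+exp((β−0.5)/0.1))` a smooth gate that
closes when the promoter is methylated — the affinity-reduction
assumption, made differentiable.  The `−z(β)` term is direct methylation
silencing, so regulated targets are themselves confirmable probe–gene
pairs (ground truth counts them as planted pairs).

**Rewiring.**  Per stage, a set of regulated-target promoters flips mode
relative to baseline: high→low flips enable regulation there (edge *gain*
vs normal), low→high flips silence it (*loss*).  Gain-designated targets
start in the high mode so the gain is visible against normal.

**Motifs and sequence.**  Each TF gets a sharply peaked PFM (0.85
consensus / 0.05 off-consensus) of length 8; the consensus is embedded,
on a random strand at a random non-overlapping offset, in the 201-bp
promoter window of every target it regulates.

**What the generator does not emulate:** array noise and batch effects,
copy-number and tumor-purity confounding, read-level RNA-seq, linkage
between neighbouring probes, and realistic motif information content or
GC composition.  Passing recovery tests therefore show that the pipeline's
logic is correct and calibrated under its own assumptions, not that the
same sensitivities would hold on real arrays.

## Statistical conventions

* **Promoter window:** |probe − TSS| ≤ 2000 bp, inclusive on both
  boundaries, strand-symmetric.
* **Spearman t:** average ranks for ties; t = r√(n−2)/√(1−r²); two-sided
  Student-t tail with n−2 df; |r| = 1 reported as t = ±∞, p = 0; constant
  vectors yield NaN and are excluded rather than raised.
* **BH family:** all candidate pairs tested within one stage (per-stage
  decision rule); a pooled variant is available.  The normal phenotype is
  excluded from confirmation by default (no matched normal samples in the
  emulated cohort); a flag includes it.
* **Trimming:** for each probe the 10% lowest- and highest-methylation
  samples are excluded *from the pooled stage+normal sample* before the
  rank-sum test.  Per-group trimming (each group's own extremes) is
  available but not the default: measured under the global null it
  inflates the rejection rate to ≈0.12 at nominal 0.05, because removing
  each group's own tails shrinks within-group dispersion; pooled trimming
  preserves exchangeability (measured ≈0.05).  Δmean is computed on the
  trimmed values.
* **Wilcoxon branches:** exact null enumeration when n_x+n_y ≤ 12 with no
  ties, otherwise the normal approximation with tie and continuity
  correction.
* **State classification:** on the phenotype mean beta; boundaries at
  0.25/0.75 fall into the hemi class.  The thresholds are a standard
  beta-value convention (configurable) — the source data's exact values
  are not published.

## PWM scanning

Scores are log₂((p+π)/(1+4π)/b) bits with pseudocount π (default 0.01) and
background b (default uniform).  `N` contributes 0 (background-
equivalent).  Minus-strand hits are found by scanning with the
reverse-complemented matrix and reported at plus-strand coordinates.

P-values come from an exact DP over the lattice of scores rounded to a
granularity g (default 1e-3 bits): the distribution of the rounded score
of a random background L-mer is built by convolution; p(s) = P(S ≥ s).
Queries allow a slack of L lattice units, which guarantees the bracket
`P(S_exact ≥ s+2gL) ≤ p(s) ≤ P(S_exact ≥ s−2gL)` — an absolute p-value
tolerance is unattainable whenever two distinct words score within one
lattice step, since a single word at L=3 already carries probability
1/64.  The slack makes p conservative (never smaller than exact), which
is the safe direction for hit thresholding.  Both-strand hits are
Bonferroni-combined (min(1, 2p)) before the 1e-4 candidate threshold.

## Network inference

Per target, expression (standardized to unit variance) is regressed on
candidate TFs with a bagged ensemble of CART regression trees; edge weight
is the mean per-feature impurity reduction (so weights sum roughly to the
explained variance).  Guided regularization is two-pass: a plain ensemble
yields imp₀, and the second pass draws each tree's feature subset with
probability ∝ (1−γ) + γ·imp₀/max(imp₀) (γ = 0.5 by default; γ = 0 gives a
plain ensemble for ablation).  Defaults: 500 trees, √p features per
split, leaf size 2, q = 2, density 0.05 — conventional values in the
tree-ensemble GRN literature; the acceptance surface is recovery on
synthetic data, not numerical identity with any particular
implementation.  Samples are canonically ordered before fitting, so
results are invariant to input column order; per-target seeds derive from
one network seed.

**Normalization modes.**  `per_target` (default) rescales each target's
weight vector to unit q-norm, making targets comparable when each has
many candidate TFs — the situation with a real motif library (hundreds of
candidates per promoter).  At desk scale with only tens of TFs it erases
the column scale that separates regulated from silent targets: a
pure-noise column normalized to unit norm looks as strong as a signal
column.  Two alternatives are provided: `global_quantile` (divide the
whole matrix by its median nonzero weight) and `none` (raw importances).
Between-network subtraction uses `none` in the differential-network
experiments, since raw importances are already on a common scale and any
per-network rescaling injects spurious deltas into stable edges.

**Sparsity.**  The top ceil(density × #candidate edges) edges by weight
are kept, ties broken lexicographically by (tf, target).

## Differential networks

Edge universes are unioned (missing weight = 0); edges rank by |Δw|
descending with the same lexicographic tie-break; the top k (default
1000) are labelled gain (Δw > 0) or loss.  In-degree is the nonzero
in-edge count of the sparsified network.  A target's methylation
direction comes from its most significant assigned probe (smallest p_adj,
then largest |Δmean|, then probe id); if no probe is significant the raw
Δmean sign is used, `none` without assigned probes.  The consistency
filter retains in-degree-up+hypo and in-degree-down+hyper targets; the
filter is applied before the top-k ranking by default (a switch ranks
globally first, as the original order of operations is ambiguous).

## Problem sizes in tests and the acceptance script

All recovery experiments run on generated cohorts sized for a single CPU:

* pair recovery: 500 probes × 400 genes, 30 samples/phenotype, coupling
  0.8, 50 planted pairs, 20 seeds;
* DM calibration: 50 null cohorts of 200 probes × 30+30 samples; power:
  modes (0.25, 0.65) so each planted flip is exactly |Δ| = 0.4;
* network recovery: 40 TFs × 200 targets, effect 1.0, noise 0.3, n = 30,
  25 trees, density 1 for AUROC scoring, 10 seeds (5 in the script), with
  a shuffled-target negative control;
* differential networks: 30 TFs × 70 regulated targets, 80
  samples/phenotype, effect 2.0, 16 flips/stage, 50 trees, density 0.06,
  k = 60 (scaled to the ≈50 planted rewired edges, the same binding
  fraction as a top-1000 cut against a genome-scale candidate set),
  raw-importance subtraction.

The tree counts used in the experiments (25–50) are smaller than the
500-tree default; recovery was verified stable at these sizes.

## Known limitations

* Enhancer methylation is out of scope; only promoter windows are scanned.
* The scanner is not methylation-aware (CpG state does not alter scores).
* The consistency filter's raw-sign fallback assigns a direction to every
  probe-linked target, so targets with no real methylation change can pass
  when network noise moves their in-degree; at genome scale the top-k cut
  absorbs this, at desk scale it is the main precision cost in the
  differential-network experiment.
* Tree-ensemble importances are biased toward high-variance predictors;
  no bias correction is applied beyond the guided second pass.
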