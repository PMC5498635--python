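# Methods

## Problem and model

`chromacc` predicts gene-level chromatin accessibility (a binary
open/closed state of each gene's regulatory region) from transcriptomics
alone.  The premise is that a gene's expression level carries most of the
information about whether its promoter/gene body sits in nucleosome-depleted
chromatin: genes expressed at all are almost always accessible, and genes
deep in heterochromatin are silent.  The decision boundary, however, is not
a single universal FPKM cutoff — it is learned from paired RNA-seq /
DNase-seq training samples.

### Training labels

For each training sample, DNase hotspot intervals are intersected with each
gene's *regulatory region*: the gene body (UTRs included, isoforms condensed
to the union span) plus a TSS-anchored promoter window.  A gene is labeled
*open* when at least one hotspot shares at least one base pair with this
region, *closed* otherwise.  Overlap is strand-blind on the peak side; the
promoter window is strand-aware (for a − strand gene the TSS is its 3'-most
coordinate and "upstream" extends toward larger coordinates).  The promoter
extent is an explicit parameter (default −1000/+100 bp around the TSS)
because promoter definitions differ between annotation tools; there is no
hidden default buried in an external dependency.

### Predictors

Each gene contributes three predictors: raw FPKM `e_i`, and the Mahalanobis
distance of `e_i` to the empirical expression distribution of each class,

    d(e_i) = (e_i − μ_X) · S_X⁻¹ · (e_i − μ_X)'

computed for X = the accessible and X = the inaccessible training genes
(sample mean and n−1 variance; in this 1-D setting the distance is the
squared standardized deviation — no square root).  Both distances are
included.  Expression is used raw rather than log-transformed: the distance
formula operates on `e_i` directly and decision trees are invariant to
monotone transforms, so a log only reparametrizes split thresholds.  A
`log1p` switch exists on `TrainingConfig` for users who want it; it is off
by default.  Class statistics are *stored in the model* and reused at
prediction time — an unseen sample carries no labels to refit from, and
refitting would break the determinism property below.

### Three layers

* **L_B** — per sample, `n_lb_trees` classification trees (default 1000),
  each grown fully (no depth limit, mirroring default MATLAB-style
  `fitctree` growth) on a fresh uniform subsample without replacement of
  `subsample_size` genes (default 1000; clamped with a warning when a
  sample has fewer genes).  Subsampling deliberately thins near-duplicate
  low-expression values so trees do not split on the fourth decimal of
  FPKM.  A tree's score is the open-class fraction of training genes in the
  leaf the query gene reaches, so every score is in [0, 1].
  `estimate_num_lb_trees` estimates the ensemble size as four times the
  Monte-Carlo mean number of subsample batches needed to draw every gene at
  least once (a batched coupon-collector process); at 20,000 genes and
  batches of 1000 it lands near 800, consistent with the 1000-tree default.
  It is offered as a utility, not wired in.
* **L_M** — per sample, the gene × tree score matrix is centered and
  rotated by PCA; the smallest number of leading components whose
  cumulative explained variance reaches `pca_variance` (default 0.95) is
  kept, and a RUSBoost classifier is fit on the projections.  The PCA basis
  is fit once on the training score matrix and stored; queries are
  projected with the stored basis.
* **L_U** — one RUSBoost classifier over the vector of all samples' L_M
  scores.  Its training rows pool every (training sample s, gene g) pair:
  the features are all samples' L_M scores evaluated on s's expression
  (including s's own L_M — the combiner sees every middle-layer opinion),
  the label is s's accessibility of g.  Gene universes are intersected
  across samples, with a logged count of dropped genes.  The final score is
  the L_U output in [0, 1]; a gene is called open at `decision_threshold`
  (default 0.5).

### RUSBoost

Training accessibility labels are imbalanced, so the middle and upper
boosters use random undersampling per boosting round: each round draws,
with probabilities proportional to the current boosting weights (Gumbel
top-k sampling without replacement), a majority-class subsample equal to
the minority count, fits a depth-limited tree (default depth 3) on the
balanced set, then computes the weighted error ε on the **full** training
set and applies the standard AdaBoost update with coefficient
α = learning_rate · ln((1−ε)/ε).  Rounds with ε ≥ 0.5 are discarded; if
every round is discarded the best rejected learner is returned with a
warning rather than looping forever.  A perfect round (ε ≈ 0, capped at
1e−10) terminates boosting early, since weights would no longer change.
The final score is the normalized weighted vote for the open class.

### Determinism

All randomness (subsample draws, tree tie-breaking, undersampling) derives
from the single `TrainingConfig.seed` through a `numpy` `SeedSequence`
tree.  Identical data, config and seed reproduce bit-identical serialized
models, and predictions depend on a gene only through its FPKM value —
equal expression implies equal score and label.  Serialized models are
wrapped in a versioned archive; an archive from a different format version
is rejected explicitly.

## Gold standard and evaluation

The accessible reference set is the union, over all available TFBS ChIP-seq
experiments, of genes whose regulatory region overlaps at least one binding
peak (intragenic binding counts: intragenic enhancers act as alternative
promoters).  The inaccessible set contains genes overlapping ChromHMM
segments whose state is annotated to H3K9me3 alone or to the
H3K36me3+H3K4me3+H3K9me3 combination typical of ZNF genes and repeats.
Mark matching is exact-set equality by default; a `superset_match` flag
relaxes it, since "annotated to" is ambiguous for composite states.  The
state→marks mapping is user-supplied JSON — Roadmap's 15/18/25-state models
name states differently, so nothing is hardcoded.  Genes claimed by both
lines of evidence are moved to a conflict set and excluded from both sides.

Accessible genes are the positive class; precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 their harmonic mean with the 0/0 → 0 convention.
Expression-cutoff sweeps keep gold genes with FPKM strictly greater than
the cutoff (cutoff 0 meaning *all* genes); a cutoff that empties the gold
standard yields an `undefined`-flagged result rather than an exception.
Genes present in the gold standard but absent from the predictions raise an
error — silently dropping them would inflate scores.  Misclassification
profiles report, per category of GC bin, gene type, chromosome or
expression bin (first bin [0, 0.1) FPKM), both the within-category error
fraction and each category's share of all errors.

Leave-one-out validation retrains without one unit (cell type or
chromosome) and reports the Pearson correlation between the fold model's
and the full model's continuous prediction scores on the held-out unit;
correlations of binary labels can be derived from the returned scores, but
continuous scores are the default because they are strictly more
informative.

## Peak-caller parameter optimization

A peak-caller run at one threshold is scored, without any gold standard, by
the recall of its called peaks against the model's predictions: the
reference positives are the genes predicted open with FPKM > 0.01, and the
run's observed positives are the genes its peaks label open via the same
overlap rule as training.  The denominator is the predicted-open set (the
natural reading of recall with predictions as the truth side); genes
predicted closed do not enter the measure.  Runs are ranked by this recall,
ties broken toward the more stringent threshold (direction configurable per
caller, since z-score thresholds grow with stringency while FDR thresholds
shrink) and flagged.  `regress_f1_on_recall` fits OLS of gold-standard F1
on recall, reporting R² and adjusted R² = 1 − (1−R²)(n−1)/(n−p−1), p = 1,
with each (threshold, cell line, replicate) tuple one point.

## Synthetic data generator

The generator emulates the coupling the model assumes, per cell type:

* a fraction `frac_silent` (default 0.3) of genes has FPKM 0;
* expressed genes draw FPKM from a two-component lognormal mixture
  (defaults: log-mean 1.0, log-sd 1.0 for the accessible-like component;
  log-mean −3.0, log-sd 1.0 for the inaccessible-like component);
* the true label is Bernoulli with P(open | e) = logistic((e − θ)·s),
  θ = 0.5 FPKM, s = 50 /FPKM by default — a sharp link whose location the
  trained model should recover — then flipped with probability
  `label_noise` (default 0.02);
* one DNase hotspot (300 bp) is placed uniformly inside each open gene's
  body, missed with probability `fn_peak_rate` (0.02) and spuriously added
  to closed genes with probability `fp_peak_rate` (0.02).

Genes (default 20,000 over 4 chromosomes, lengths 3–10 kb) are placed
non-overlapping with ≥ 2.5 kb gaps, and all placed features keep ≥ 1200 bp
from gene ends — more than the default promoter extent — so a feature never
overlaps a neighbor's regulatory region and zero-noise samples round-trip
exactly through the labeling rule.  Gold-standard simulation assigns each
open gene's TFBS peak to one of several pseudo-experiments and covers
closed genes with heterochromatin-typical segments (80% H3K9me3-alone, 20%
three-mark states); `coverage` < 1 makes the gold standard a strict subset
of truth and `conflict_rate` injects genes with both kinds of evidence.
Degraded peak-caller runs delete true hotspots and add spurious peaks at
per-run rates, emulating a threshold grid of decreasing quality.

What the generator does **not** emulate: distal enhancer–gene wiring,
mappability artifacts, GC/expression coupling, replicate-specific library
effects, or any peak caller's internal signal model.  Tests passing on this
generator therefore certify the algorithmic pipeline (labeling, layered
fitting, evaluation, ranking) under the stated statistical link, not
performance on real ENCODE/Roadmap data.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run the default cohort
(6 cell types × 20,000 genes) with a desk-scale configuration — 150
bottom-layer trees per sample and 30 boosting rounds, other parameters at
their defaults — chosen once so a full session completes in minutes on a
single CPU; the architecture is unchanged and results at this scale are
stable across seeds.  Other numerical choices: PCA uses an economy SVD with
a 1e−12 tolerance on the cumulative-variance comparison; tree tie-breaks
are delegated to seeded scikit-learn trees so the config seed alone
controls stochasticity; a class with fewer than two members or zero
expression variance raises an error instead of being epsilon-inflated.

## Known limitations

* Predictions are gene-level; the model says nothing about individual peak
  locations within a regulatory region.
* A single expression value drives everything: genes silenced by
  post-transcriptional mechanisms but residing in open chromatin are
  systematically misclassified, which is why evaluation above a small FPKM
  floor is the informative regime.
* Cancer-genome structural variation breaks the annotation↔expression
  correspondence the labeling rule assumes; training on such samples is
  possible but the labels inherit the misalignment.
* The L_U input dimension equals the number of training samples, so a
  model must be retrained (not patched) when samples are added or removed.
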