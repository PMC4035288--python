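# Methods

## Problem and overall design

Histological grading of breast tumours separates well-differentiated
(G1) from poorly differentiated (G3) disease reliably, but the
intermediate G2 call is largely a mixture of molecularly G1-like and
G3-like tumours. The package treats that mixture hypothesis as an
operational model: signatures are learned from G1/G3 contrasts only,
G2 samples are relabelled by a classifier trained on G1/G3, and the
relabeling is judged by whether the two relabelled groups separate in
relapse-free survival while each stays indistinguishable from its
histological counterpart.

The pipeline is a chain of small, independently tested stages:
batch harmonisation → SAM differential expression (mRNA, miRNA) →
gene-level CNA calls → directional set intersection → SVM
classification and G2 relabeling → survival validation. The fitted
components (SAM analysis, the SVM workflow, the Cox model) are exposed
as model objects whose `fit()` returns a results object; the pipeline
module composes them functionally, since the chain as a whole is set
algebra rather than a single estimable model.

## Differential expression

The moderated two-class statistic is `d_i = Δmean / (s_i + s0)` with
the pooled standard error `s_i` defined from within-class sums of
squares and `n_A + n_B − 2` degrees of freedom. The fudge factor `s0`
stabilises `d` for low-variance features: candidates are the 0, 5, …,
100 percentiles of `{s_i}`; for each candidate, features are binned
into deciles of `s_i` and the coefficient of variation of the per-bin
median absolute deviations of `d` is minimised (ties to the smallest
percentile). q-values are permutation-based with the null proportion
π₀ fixed at 1 — a deliberately conservative choice, exposed as a knob —
and are made monotone in |d| by a running maximum so ranks never
invert. Permutations are full label shuffles (class sizes preserved);
an exhaustive mode enumerates all distinct assignments and is used to
validate the sampled mode exactly on small designs. Features with zero
pooled variance get `d = 0`, `q = 1` and a per-feature flag rather
than an error. The significance threshold defaults to `q < 0.01`.

Batch harmonisation has two modes. `meanvar` rescales each gene's
batch slice to the gene's grand mean and its pooled *within-batch*
standard deviation; using the within-batch pooled sd (not the grand
sd) is what makes the operation exactly idempotent. Zero-variance
slices are centred only. `eb` follows the parametric empirical-Bayes
scheme used for microarray batch correction: genes are standardised
with sample-size-weighted grand means and pooled sds, per-batch
location and scale estimates are shrunk under a normal /
inverse-gamma prior with method-of-moments hyperparameters, the
coupled posterior updates are iterated to 1e-8, and the shrunken
effects are removed. Batches with fewer than two samples are rejected
(their variance is undefined).

## Copy number

Only segmented data are consumed (segmentation itself is out of
scope). Two value encodings are supported because segmenters differ:
absolute copies (diploid 2; gain ≥ 2.5, loss ≤ 1.5) and log2 ratios
(± 0.3). Gene calls use any-overlap (≥ 1 bp, half-open coordinates,
strand ignored): the simplest defensible reading of "genes within
altered regions". A gene overlapping both a gain and a loss segment in
one sample is a conflict, excluded from frequency counts and logged —
double counting would otherwise inflate both sets. Per-grade
frequencies rank genes by their dominant alteration frequency and one
combined top-K (default 6000) is taken, ties broken lexically for
determinism; per-type selection is available via the CLI flag. A
shortfall against K is logged, not an error.

## Integration

Direction bookkeeping uses the single G1-vs-G3 contrast; "up in G1" is
derived as "down in G3". Stage II intersects calls with concordant
CNA per grade; stage III requires, in addition, that a class gene be
targeted by at least one miRNA called in the *opposite* direction
(regulator up ⇒ target down), and a class miRNA is any
correctly-directed miRNA whose targets intersect the class genes. A
gene may appear in two classes across grades; the signature unions
deduplicate. Downsizing intersects the candidate signature with the
*union* of the reference signatures (not their common intersection),
with a per-reference membership report — the variant that lets a gene
survive when present in only one reference.

## Classification

The grid "C, γ in (0, 5] in 30 steps" excludes zero (both are
degenerate) and spans three kernels: dot, radial and ANOVA
(`(Σ_d exp(−γ(x_d−y_d)²))^degree`, degree defaulting to 1). All
kernels are passed to the soft-margin optimiser (scikit-learn's SVC)
as precomputed Gram matrices so the three share one code path and the
optimiser stays an exchangeable component. Grid selection is by mean
stratified k-fold CV accuracy *inside the training data only* (flat,
not nested — documented choice), with the first-best grid point kept
for determinism. Fold-level metrics get normal-approximation 95%
intervals (`mean ± 1.96 sd/√k`, clipped to [0, 1]); single train/test
evaluations use binomial proportion intervals. Sensitivity is G3
recall, specificity G1 recall, AUC the tie-aware rank statistic with
G3 positive.

Reclassification trains the winning grid point on all G1/G3 samples,
labels every G2 sample G1\* or G3\* by the decision sign, then re-runs
the grid search on the relabelled set (`reuse_params` skips the
re-search) and evaluates on the original G1/G3 samples. If all G2
samples land on one side the retrain step is skipped and the result
flagged degenerate.

## Survival

Kaplan-Meier is the plain product-limit estimator; censored
observations at an event time remain at risk at that time. The
log-rank statistic is the standard `(ΣO−E)²/ΣV` with hypergeometric
variance, referred to χ²₁; with no events it degenerates to (0, 1)
with a flag. The Cox model is univariate on a binary group indicator,
maximised by Newton-Raphson to |Δβ| < 1e-9 with Breslow tie handling
by default — survival times in months tie often, and Breslow is the
simplest consistent choice; Efron is available behind a flag and
coincides with Breslow in the absence of ties. Hazard ratios are
`exp(β̂)` with Wald 95% intervals. A monotone partial likelihood
(complete separation of events) is detected both by a pre-check and by
divergence of β̂, and raises with advice to use an exact or penalised
method. Hazard ratios were chosen over O/E ratios to match standard
survival software conventions.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any
particular dataset: a balanced three-grade design (78/78/78 by
default, mirroring a balanced selection from merged cohorts), three
batches with per-gene additive shifts and a multiplicative noise
scale, Gaussian log2 expression (baseline N(7, 1), noise sd 1.0),
planted grade effects of δ = 1.5 log2 units at 60 + 60 informative
genes out of 2000, and G2 as an unattenuated latent Bernoulli(0.5)
mixture of the G1 and G3 expression models. miRNAs are planted
anticorrelated with their targets (regulators of up genes are down in
G3 by the same magnitude); enough miRNAs are planted to cover every
informative gene at `targets_per_mirna = 5` targets each, so class
recovery has an exact target. CNA plants are one segment per altered
gene per carrier sample (gain CN 3, loss CN 1, carrier frequency 0.6
in the concordant grade), split across the four directional classes so
all of them are exercised. Relapse times are exponential with rates
0.01 (latent G1) and 0.04 (latent G3) per month — a hazard ratio of 4 —
with uniform censoring at rate 0.2. The toy genome is one chromosome
with gene *i* at `[1000·i, 1000·i + 500)`.

What the generator does *not* emulate: probe-level noise,
dosage-to-expression coupling, realistic segment-length and LD
structure, correlated gene modules, non-Gaussian tails. Passing tests
therefore demonstrate correctness of the algorithms under their own
assumptions, not performance on real microarray cohorts; the published
headline numbers from real data (signature sizes, accuracies, p-values)
depend on those cohorts and are not contracts here.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; SEG inputs in 1-based
  inclusive convention must be shifted before loading.
- One master seed fans out per stage via CRC32 of `"stage:seed"`
  (kept below 2³¹), so each stage is independently reproducible and
  the end-to-end report is byte-identical across runs.
- Tie-breaks are everywhere deterministic: lexical gene ids at the
  top-K boundary, the smallest fudge-factor percentile, the first-best
  grid point.
- Test and example problem sizes (hundreds to a few thousand features,
  tens of samples, reduced kernel/parameter grids, 100–300
  permutations) were chosen so the full suite and the acceptance
  script run comfortably on a single CPU; they are the package's own
  defaults for simulation studies, and all thresholds asserted in
  tests derive from the planted conditions, not from tuning.

## Known limitations

- SAM here is two-class only: no paired designs, multi-class or
  survival variants.
- The EB batch adjustment runs without covariates; grade effects that
  are confounded with batch will be partially absorbed.
- The Cox model is univariate; no multivariate adjustment, competing
  risks or time-varying effects.
- The classifier does not calibrate probabilities; decision scores are
  only rank-meaningful.
- miRNA targets are consumed from a table, never predicted.
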