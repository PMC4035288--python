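# gradeweaver

Histological grade is one of the strongest prognostic factors in breast
cancer, but the intermediate grade (G2) is notoriously unreliable: a
large fraction of tumours called G2 behave molecularly like either the
well-differentiated G1 or the poorly differentiated G3 class.
`gradeweaver` implements a multi-omic pipeline that (i) derives compact
gene and miRNA signatures by intersecting differential expression,
gene-level copy-number alterations (CNA) and miRNA-target relations in
a direction-aware way, (ii) uses an SVM trained on G1/G3 tumours to
reclassify G2 tumours into G1-like (G1\*) and G3-like (G3\*) groups,
and (iii) validates the relabeling by relapse-free survival analysis.
A synthetic cohort generator with ground truth makes every stage
testable without microarray downloads.

It is written for computational biologists who want a transparent,
fully tested reference implementation of this integration strategy —
each stage is a small, documented function or model object.

## Method

**Differential expression (SAM).** For each feature the moderated
statistic is

```
d_i = (mean_B − mean_A) / (s_i + s0),
s_i = sqrt((1/n_A + 1/n_B) (SS_A + SS_B) / (n_A + n_B − 2)),
```

with the fudge factor `s0` chosen over percentile candidates of
`{s_i}` to minimise the coefficient of variation of the per-decile
median absolute deviations of `d`. False-discovery q-values come from
label permutations (π₀ fixed at 1, monotone in |d|); features with
`q < 0.01` are called up or down. Batches are harmonised beforehand,
either by exact per-gene mean/variance rescaling or by parametric
empirical-Bayes shrinkage of per-batch location and scale.

**Copy number.** Segments are classified gain/loss by thresholds
(absolute CN ≥ 2.5 / ≤ 1.5, or log2-ratio ± 0.3); a gene is altered in
a sample if its interval overlaps an altered segment (half-open, ≥ 1
bp). Per-grade alteration frequencies rank genes; the top-K (default
6000) split into amplified and deleted sets.

**Integration.** Stage II intersects expression calls with concordant
CNA per grade (e.g. up-in-G3 ∩ amplified-in-G3). Stage III keeps
stage-II genes targeted by oppositely-directed miRNAs, producing four
classes (down/deleted genes with up miRNAs and up/amplified genes with
down miRNAs, per grade); their unions are the gene and miRNA
signatures. A signature can be further downsized by intersecting it
with the union of published reference signatures.

**Classification.** An SVM (linear, RBF or ANOVA kernel; C and γ on a
grid of 30 values in (0, 5]) is selected by stratified 10-fold CV
accuracy on G1/G3. Sensitivity is G3 recall, specificity G1 recall,
AUC the rank statistic of the decision scores. The trained model
assigns each G2 sample a G1\*/G3\* label; a fresh model trained on the
relabelled set is then evaluated against the original G1/G3 samples.

**Survival.** Kaplan-Meier curves, the two-group log-rank test and a
univariate Cox model (Breslow ties, Newton-Raphson) compare G1\* vs
G3\*, G1 vs G1\* and G3 vs G3\*.

## Worked example

```python
from gradeweaver import CohortConfig, generate_cohort, PipelineConfig, run_all
from gradeweaver.classify import ClassifierConfig

cohort = generate_cohort(CohortConfig(seed=123))   # 78 tumours per grade
config = PipelineConfig(
    sam_B=150,
    classifier=ClassifierConfig(kernels=("linear", "rbf"),
                                c_grid=[0.5, 2.0], gamma_grid=[0.01, 0.1]),
    seed=123,
)
report = run_all(cohort.mrna, cohort.mirna, cohort.segments,
                 cohort.samples, cohort.genes, cohort.targets,
                 config, approaches=("III",))
r = report["approaches"]["III"]
print("signature genes:", r["set_sizes"]["gene_signature"])
print("CV accuracy:", r["cv"]["accuracy"]["estimate"])
print("G1* vs G3* log-rank p:",
      [s for s in r["survival"] if s["label"] == "G1* vs G3*"][0]["logrank_p"])
```

On the default synthetic conditions this prints the 120 planted
signature genes recovered in full, a cross-validated accuracy of 1.0
(the planted effect of 1.5 log2 units over unit noise is strongly
separable at n = 78 + 78), and a G1\* vs G3\* log-rank p-value far
below 0.01 — relabelled G3-like tumours relapse markedly faster, while
G1 vs G1\* shows no significant difference.

The same pipeline is available from the shell:

```
gradeweaver simulate --seed 123 --out cohort/
gradeweaver run --dir cohort/ --approach III --small-grid --out report.json
```

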