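# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the design decisions taken where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic multi-cohort study

The generator emulates the structure of four public whole-blood cohorts:
two microarray studies contrasting septic shock (SS) with healthy controls
(HC) (51/22 and 28/25 samples), one milder sepsis (Sep) vs HC study
(35/18) used for exclusion, and one three-cohort RNA-seq study (SS 19 /
Sep 20 / HC 40). Expression is generated additively on the log2 scale:

```
value(g, s) = baseline(g) + shift(g, d) + effect(g, cohort(s), d) + noise(g, s)
```

with per-gene baselines N(8, 1.5²), per-dataset per-gene batch shifts
N(0, 0.3²), and residual noise N(0, 0.5²). Planted effects:

| Block | n | SS | Sep | Scope |
| --- | --- | --- | --- | --- |
| hub genes (GZMB, PRF1, KLRD1, SH2D1A, LCK, CD247) | 6 | −1.8 | −0.9 | severity-scaled |
| NK-pathway co-regulated block | 40 | −0.8 | −0.4 | severity-scaled |
| generic infection response | 100 | ±0.8 | ±0.8 | all datasets |
| shock-specific background DEGs | 200 | ±0.8 | 0 | all datasets |

The hub SS effect (−1.8) sits deliberately below the −1.5 hub-selection
cutoff. Background and infection-response blocks are split evenly up/down
so the ranked list is not direction-biased. The exclusion cohort models a
milder, community-acquired sepsis population in which the NK-cytotoxicity
module is not perturbed: its *panel* effects are scaled by a per-dataset
severity factor (default 0 for that dataset, 1 elsewhere), while the
generic infection-response block is planted at full strength everywhere —
it is exactly what the exclusion step is meant to remove. The Sep pathway
effect (−0.4, half the SS effect) mirrors the hub ratio; neither value is
observable in the real cohorts, so the generator simply keeps the ordering
HC < Sep < SS in severity.

One global seed drives a dedicated child stream for the shared baselines
and one child stream per dataset, so a dataset simulated alone is
bit-identical to the same dataset inside the multi-cohort run.

The qPCR readout models threshold cycles `Ct = 30 − log2 expression +
ε_gene` plus a stable reference gene `Ct_ref = 18 + ε_ref` with a *shared*
per-sample reference error; ΔΔCt subtracts the HC-cohort mean ΔCt, and the
returned log2 value is −ΔΔCt. Noiselessly this equals HC-centred log2
expression, so planted fold changes propagate exactly; with noise, the
shared reference error induces correlated noise across panel genes, which
is the realistic failure mode of ΔΔCt normalization.

What the generator does **not** model: probe-level microarray effects,
count noise or library-size variation in RNA-seq, within-cohort severity
gradients, age/sex covariates, or gene–gene correlation beyond the planted
co-regulated blocks. Passing tests therefore demonstrate the correctness
and internal coherence of the pipeline under idealized additive-Gaussian
conditions, not clinical performance.

## Differential expression

Two-group pooled-variance linear model on log2 values; logFC is the
difference of cohort means. Variance moderation shrinks per-gene variances
toward a prior `s̃² = (d₀s₀² + ds²)/(d₀ + d)` and augments the degrees of
freedom by d₀. The prior is estimated by closed-form moment matching: under
a scaled-inverse-χ² prior, `s²/s₀² ~ F(d, d₀)`, whose squared coefficient
of variation `2(d + d₀ − 2)/(d(d₀ − 4))` is equated to the empirical one;
when the empirical spread is at or below what d residual df alone produce,
d₀ = ∞ (complete shrinkage, normal reference distribution). This is
intentionally simpler than full empirical-Bayes machinery; the contract —
verified in tests — is a valid moderated t that reduces to the ordinary
pooled t as d₀ → 0. The adjustment is Benjamini–Hochberg (the standard
default for this analysis); DEG thresholds are strict inequalities
(`q < 0.05`, `|logFC| > 0.6`), so boundary values are excluded. The
cross-cohort intersection requires direction consistency by default,
consistent with reporting separate up/down counts.

## Preranked enrichment

Genes are ranked by logFC descending, ties broken lexicographically by
symbol for determinism. The running statistic increments at in-set genes
by `|logFC|^p / N_R` (p = 1; N_R the in-set sum, with an unweighted
fallback when all in-set metrics are zero) and decrements at misses by
`1/(N − k)`; ES is the signed extremum. Because the walk only changes
slope at hits, the implementation evaluates the O(k) candidate extrema (at
each hit for the maximum, just before each hit for the minimum); a naive
O(N) re-walk serves as the oracle in the tests, never as the
implementation. Ties between the positive and negative extremum resolve to
the positive one. The null distribution permutes set membership
(size-preserving gene-label permutation, 1000 draws by default, seeded and
vectorized); NES divides ES by the mean |null ES| of matching sign, and
the permutation p uses the add-one estimator over same-sign nulls. With no
same-sign null the record is flagged degenerate with p = 1.

**Hub selection.** Leading edges of the significantly down-regulated sets
(ES < 0, permutation p < 0.05 in every discovery cohort) are intersected
across cohorts; candidates then pass a logFC < −1.5 cutoff. The cutoff is
applied to the **mean** logFC across the discovery cohorts by default
(`rule="mean"`), with a stricter every-cohort mode available
(`rule="all"`). Rationale: the cutoff sits only ~2.3 standard errors from
the planted hub effect in an individual cohort of these sizes, so the
per-cohort rule lets single-cohort sampling noise veto true hub genes
(per-gene pass probability ≈ 0.976 per cohort, i.e. exact recovery of a
six-gene panel in only ~86 % of replicates); the combined-evidence rule
judges each candidate on the pooled estimate, as one would in practice.

## LDA stage

Standard two-class Fisher discriminant with a pooled within-class
covariance; the direction solves `S_p w = μ₁ − μ₀` (diagonal ridge
`1e−6·tr(S_p)/d` only when the plain solve is ill-conditioned, since a
six-gene panel can exceed small class counts) and is rescaled to unit
projected within-class variance, making LD1 gaps pooled-SD units and hence
comparable across datasets. Orientation fixes the disease class on the
high side. **Centering** is the midpoint of the two class means rather
than the overall training mean: the overall mean moves with the case/
control mix of a cohort, which would offset LD1 values of differently
balanced cohorts against each other by several SD when rows are pooled
into the stacked dataset; the midpoint is prevalence-invariant and
coincides with the overall mean for balanced data. Posteriors are
equal-variance Gaussian on LD1 with priors equal to training proportions
(uniform selectable). The evaluation protocol refits the scorer inside
each dataset's stratified 50/50 training half.

## Risk-score stage

`RS = Σ wᵢ(eᵢ − uᵢ)/sᵢ` with uᵢ, sᵢ the mean and SD over *all* samples of
the dataset being scored (sample SD, ddof 1) and recomputed on each new
dataset — this is what lets the score transfer across platforms; a
frozen-reference mode carries u, s instead. Default weights are unit
magnitude with sign equal to the discovery logFC sign, so a down-regulated
panel gives disease the higher score (logFC-proportional and fully custom
weights are provided). The binary cutoff is the crossing of the two
class-wise Gaussian-KDE densities (Silverman bandwidth) located between
the class means, interpolated linearly on a 512-point grid and taken
nearest the class-mean midpoint when several crossings exist; if the
densities do not cross between the means (effectively identical
distributions) the midpoint is returned with a warning. Youden's J is the
alternative cutoff.

## Stacked meta-model

Rows (LD1, RS) from every cohort containing both target and reference
classes are concatenated; labels are 1 for the target cohort, 0 for the
reference; other cohorts (sepsis, when training shock vs control) ride
along unlabelled for later scoring. Features are standardized inside the
model and the scaling stored. The penalized objective is mean negative
binomial log-likelihood plus `λ(α‖β‖₁ + (1−α)‖β‖₂²/2)` with α = 1 and an
unpenalized intercept, solved by cyclic coordinate descent on the IRLS
quadratic with soft-thresholding, warm-started along a 100-point λ path
from the closed-form λ_max down four decades. λ* minimizes the mean
20-fold (stratified, seeded; folds reduced to the smaller class count when
necessary) cross-validated binomial deviance; the 1-SE value is reported
as well. Numerical guards: logits clipped at ±30, IRLS weights floored at
1e−5, at most 100 IRLS iterations of at most 50 coordinate sweeps
(convergence when the largest coefficient change drops below the
tolerance, default 1e−7). Once a training fit saturates (deviance < 1e−5
under complete separation) the saturated solution is carried down the rest
of the path, since smaller penalties can only inflate coefficients without
changing any prediction; diverging coefficients (>1e6) truncate the path
with a flag. Classification thresholds the positive-class probability at
0.5, ties classified positive.

**Shock-vs-sepsis protocol.** The meta-model is trained on shock-vs-control
rows and applied to the unlabelled sepsis rows; accuracy is measured on a
cohort's held-out shock rows plus its sepsis rows (shock = positive).
A direct shock-vs-sepsis training mode exists
(`build_stacked_dataset(target="SS", reference="Sep")`).

Under the generator's homogeneous conditions this protocol has a known
structural limit, visible in the evaluation numbers: the sepsis cohort
sits exactly midway between control and shock (planted −0.9 vs −1.8), so
any boundary trained to separate shock from control lands essentially *on*
the sepsis mean. The dataset-local LDA posterior then enjoys a small
systematic advantage — its proportional priors shift the boundary by
`log(π₀/π₁)/Δ` toward the rarer shock class, away from the sepsis mean —
while the merged meta-model's near-separation boundary jitters around the
midpoint and tilts slightly the other way (the pooled training rows are
shock-heavy). The stacked model therefore does not dominate the
single-stage rules on shock-vs-sepsis here, although it does inherit the
useful behaviour of suppressing incoherent features: the lasso typically
zeroes the risk-score coefficient, whose whole-sample standardization
carries cohort-composition offsets across datasets. Separating
heterogeneous severity classes whose means interpolate is a harder problem
than this stacking can solve; on real cohorts, non-Gaussian structure may
change this picture in either direction.

## Evaluation

Confusion-matrix metrics leave undefined ratios absent rather than zero.
AUC is computed twice on purpose — trapezoidal integration of the
threshold-swept ROC polyline, and the midrank Mann–Whitney statistic —
and the two must agree to 1e−12 (ties collapse to single sweep points,
producing exactly the diagonal segments midranks imply). Panel PCA centres
genes, takes the SVD, and fixes each component's sign by its
largest-magnitude loading.

## Problem sizes

Defaults reflect the emulated study: 2000 genes, the four cohort layouts
above, 1000 permutations for stand-alone GSEA (200 inside the end-to-end
pipeline, where only the leading edges of the clearly significant sets are
consumed), 100-point λ path, 20-fold CV. The end-to-end acceptance checks
run 50 seeded replicates of the full study; `scripts/acceptance.py` uses
20 replicates for its summary quantities and 10 for the qPCR transfer.

## Known limitations

- The moderated-t prior is a moment-matched approximation, adequate for
  calling strongly planted effects, not a drop-in for limma on real data.
- The permutation p-value is gene-label based; it ignores inter-gene
  correlation, which inflates significance on correlated real data.
- Stage-1 risk standardization "among whole samples" makes scores depend
  on a cohort's case/control mix; cross-cohort pooling of risk scores
  should be interpreted with that in mind (see the stacked-model note).
- The density-crossing cutoff is noisy in the low-density valley between
  well-separated classes (unbiased, sd ≈ 0.2 score units at n = 200/class).
- No survival modelling, no covariate adjustment, no multi-class (>2)
  discriminants.
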