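# sepxfinder

Whole-blood transcriptomic biomarker discovery and classification for
**sepsis and septic shock**. The package implements, as a tested and
reusable pipeline, a workflow in which a panel of six NK-cell-cytotoxicity
hub genes (*GZMB, PRF1, KLRD1, SH2D1A, LCK, CD247*) is discovered from
multi-cohort expression data and then drives a three-stage classifier that
separates septic-shock patients (SS) from healthy controls (HC) and from
sepsis patients (Sep), transferring across platforms (microarray, RNA-seq,
RT-qPCR).

It is aimed at computational biologists who want to reproduce, stress-test
or adapt this kind of hub-gene + stacked-classifier design without access
to the original patient cohorts: a synthetic multi-cohort generator with
planted effects makes every stage verifiable against known truth.

## The method

**Discovery.** Per cohort, per-gene two-group differential expression on
the log2 scale (pooled-variance t, optional empirical-Bayes variance
moderation, Benjamini–Hochberg FDR; DEG rule `q < 0.05` and `|logFC| >
0.6`). DEGs shared by the shock cohorts (direction-consistent) are pruned
of generic infection-response genes using a sepsis-only cohort, then ranked
by fold change and walked with a preranked, weighted Kolmogorov–Smirnov
enrichment statistic (weight `|logFC|^p`, `p = 1`; size-preserving
gene-label permutations; NES normalized by the mean same-sign null |ES|).
Leading edges of the significantly down-regulated sets are intersected
across cohorts and genes with mean logFC < −1.5 form the hub panel.

**Classification.** Three estimators, all scikit-learn style:

- `LinearDiscriminantScorer` — two-class Fisher LDA. The direction solves
  `S_p w = μ₁ − μ₀` and is scaled so `wᵀS_p w = 1`; LD1 = `wᵀ(x − c)` with
  `c` the midpoint of the class means, oriented so disease scores higher.
- `RiskScorer` — the panel risk score `RS = Σᵢ wᵢ (eᵢ − uᵢ)/sᵢ` with `uᵢ, sᵢ`
  taken over all samples of the dataset being scored and unit weights signed
  so disease scores higher; the binary cutoff is the crossing of the two
  class-wise kernel density estimates.
- `SepxFindeR` — an L1-penalized logistic meta-model on the stacked
  two-feature dataset (LD1, RS) pooled across cohorts, solved by cyclic
  coordinate descent on the IRLS quadratic over a 100-point λ path from
  λ_max down four decades, with λ chosen at minimum 20-fold cross-validated
  binomial deviance.

## Worked example

```python
import sepxfinder as sx

study = sx.run_study(seed=1)       # simulate 4 cohorts, discover, fit, evaluate
print(study.panel)
print(study.summary["sepx_ss_hc_accuracy"], study.summary["sepx_ss_hc_auc"])

transfer = sx.qpcr_transfer_experiment(study, seed=2)
print(transfer["accuracy_qpcr"])
```

prints

```
['CD247', 'SH2D1A', 'GZMB', 'PRF1', 'LCK', 'KLRD1']
1.0 1.0
0.9787234042553191
```

Reading: discovery recovered exactly the six planted hub genes (sorted by
mean fold change, most down-regulated first); the stacked meta-model
classified all 94 held-out shock/control samples correctly (accuracy 1.0,
AUC 1.0); replaying the same cohorts through the 2^−ΔΔCt qPCR readout
(Ct noise sd 0.3) and re-deriving the stage-1 scores cost about two
percentage points (97.9 % accuracy on the same held-out rows).

The same chain is available from the shell:

```bash
sepxfinder run-all --outdir out --seed 1       # JSON report in out/report.json
sepxfinder simulate --outdir data --seed 1     # expression + sample-sheet TSVs
sepxfinder discover deg --expr data/array1.expr.tsv --sheet data/array1.sheet.tsv \
    --group2 SS --group1 HC --out deg.tsv
```

## Layout

| Module | Contents |
| --- | --- |
| `sepxfinder.simulate` | multi-cohort synthetic generator, qPCR readout |
| `sepxfinder.diffexp` | moderated t, BH adjustment, DEG calling/intersection |
| `sepxfinder.gsea` | preranked enrichment walk, permutation NES, leading edge, hub rule |
| `sepxfinder.lda` | `LinearDiscriminantScorer`, stratified 50/50 split |
| `sepxfinder.risk` | `RiskScorer`, density cutoff |
| `sepxfinder.ensemble` | stacked dataset, penalized logistic path, `SepxFindeR` |
| `sepxfinder.metrics` | confusion metrics, dual-route ROC/AUC, panel PCA |
| `sepxfinder.io` | TSV/GMT/JSON readers and writers |
| `sepxfinder.pipeline` | discovery and end-to-end orchestration |
| `sepxfinder.cli` | `sepxfinder` command-line interface |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
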