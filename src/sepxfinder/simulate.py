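"""Synthetic multi-cohort whole-blood expression generator.

Emulates the structure of the four public sepsis cohorts the method was
developed on: two microarray studies contrasting septic shock (SS) with
healthy controls (HC), one milder sepsis (Sep) vs HC study used to exclude
generic infection-response genes, and one three-cohort RNA-seq study.
Effects are planted additively on the log2 scale:

    value(g, s) = baseline(g) + dataset_shift(g, d) + effect(g, cohort(s), d)
                  + noise(g, s)

The six NK-cytotoxicity hub genes (GZMB, PRF1, KLRD1, SH2D1A, LCK, CD247)
are strongly down-regulated in SS (default logFC -1.8, below the -1.5
hub-selection cutoff) and moderately down in Sep; a co-regulated pathway
block and symmetric up/down background DEGs provide realistic competition
for the discovery stages.  A separate block of "sepsis response" genes is
planted in *both* Sep and SS of every dataset: these are what the exclusion
dataset removes.  Per-dataset additive per-gene shifts emulate platform /
batch differences; they cancel in within-dataset fold changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import COHORTS, ExpressionMatrix, make_sample_sheet

logger = logging.getLogger(__name__)

HUB_GENES = ("GZMB", "PRF1", "KLRD1", "SH2D1A", "LCK", "CD247")


def _default_cohort_sizes() -> dict[str, dict[str, int]]:
    # Day-1 sample counts of the four source cohorts.
    return {
        "array1": {"SS": 51, "HC": 22},
        "array2": {"SS": 28, "HC": 25},
        "array3": {"Sep": 35, "HC": 18},
        "rnaseq": {"SS": 19, "Sep": 20, "HC": 40},
    }


def _default_platforms() -> dict[str, str]:
    return {
        "array1": "microarray",
        "array2": "microarray",
        "array3": "microarray",
        "rnaseq": "rnaseq",
    }


def _default_severity() -> dict[str, float]:
    # The exclusion cohort (mild, community-acquired sepsis) shows no
    # NK-cytotoxicity signal; its panel effects are switched off.
    return {"array3": 0.0}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    All fold changes are log2 and refer to the named cohort vs HC.
    ``dataset_severity`` scales the NK-panel (hub + pathway) effects per
    dataset; generic sepsis-response and background DEG effects are not
    scaled.  ``n_genes`` is the total gene count including planted genes.
    """

    n_genes: int = 2000
    hub_genes: tuple[str, ...] = HUB_GENES
    n_pathway_genes: int = 40
    hub_logfc_ss: float = -1.8
    hub_logfc_sep: float = -0.9
    pathway_logfc_ss: float = -0.8
    pathway_logfc_sep: float = -0.4
    n_background_degs: int = 200
    background_logfc: float = 0.8
    n_sepsis_degs: int = 100
    sepsis_logfc: float = 0.8
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.5
    dataset_shift_sd: float = 0.3
    cohort_sizes: dict[str, dict[str, int]] = field(default_factory=_default_cohort_sizes)
    platforms: dict[str, str] = field(default_factory=_default_platforms)
    dataset_severity: dict[str, float] = field(default_factory=_default_severity)
    seed: int = 0

    def __post_init__(self) -> None:
        planted = (
            len(self.hub_genes)
            + self.n_pathway_genes
            + self.n_background_degs
            + self.n_sepsis_degs
        )
        if self.n_genes < planted + 10:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {planted} planted genes"
            )
        for ds, sizes in self.cohort_sizes.items():
            for cohort, n in sizes.items():
                if cohort not in COHORTS:
                    raise ValueError(f"unknown cohort {cohort!r} in dataset {ds!r}")
                if n < 2:
                    raise ValueError(
                        f"cohort {cohort} of dataset {ds} has {n} samples (< 2)"
                    )

    # -- gene bookkeeping --------------------------------------------------

    @property
    def pathway_genes(self) -> list[str]:
        return [f"NKP{i:03d}" for i in range(1, self.n_pathway_genes + 1)]

    @property
    def sepsis_deg_genes(self) -> list[str]:
        return [f"SEPR{i:03d}" for i in range(1, self.n_sepsis_degs + 1)]

    @property
    def background_deg_genes(self) -> list[str]:
        return [f"BGD{i:03d}" for i in range(1, self.n_background_degs + 1)]

    @property
    def gene_ids(self) -> list[str]:
        planted = (
            list(self.hub_genes)
            + self.pathway_genes
            + self.sepsis_deg_genes
            + self.background_deg_genes
        )
        n_rest = self.n_genes - len(planted)
        rest = [f"G{i:05d}" for i in range(1, n_rest + 1)]
        return planted + rest

    def severity(self, dataset_id: str) -> float:
        return self.dataset_severity.get(dataset_id, 1.0)


def _effect_table(config: SimulationConfig, dataset_id: str) -> pd.DataFrame:
    """Per-gene planted effect for each cohort (genes x {HC, Sep, SS})."""
    genes = config.gene_ids
    eff = pd.DataFrame(0.0, index=genes, columns=list(COHORTS))
    sev = config.severity(dataset_id)
    hub = list(config.hub_genes)
    eff.loc[hub, "SS"] = config.hub_logfc_ss * sev
    eff.loc[hub, "Sep"] = config.hub_logfc_sep * sev
    pw = config.pathway_genes
    eff.loc[pw, "SS"] = config.pathway_logfc_ss * sev
    eff.loc[pw, "Sep"] = config.pathway_logfc_sep * sev
    # Generic infection response: same planted effect in Sep and SS, half
    # up- and half down-regulated, not severity-scaled.
    sep_genes = config.sepsis_deg_genes
    half = len(sep_genes) // 2
    signs = np.array([1.0] * half + [-1.0] * (len(sep_genes) - half))
    eff.loc[sep_genes, "SS"] = signs * config.sepsis_logfc
    eff.loc[sep_genes, "Sep"] = signs * config.sepsis_logfc
    # Shock-specific background DEGs, split evenly up/down.
    bg = config.background_deg_genes
    half = len(bg) // 2
    signs = np.array([1.0] * half + [-1.0] * (len(bg) - half))
    eff.loc[bg, "SS"] = signs * config.background_logfc
    return eff


def _baseline(config: SimulationConfig) -> np.ndarray:
    """Per-gene baseline shared by every dataset (child stream 0)."""
    rng = np.random.default_rng([config.seed, 0])
    return rng.normal(config.baseline_mean, config.baseline_sd, size=len(config.gene_ids))


def _dataset_rng(config: SimulationConfig, dataset_id: str) -> np.random.Generator:
    idx = list(config.cohort_sizes).index(dataset_id)
    return np.random.default_rng([config.seed, idx + 1])


def simulate_cohort_expression(
    config: SimulationConfig, dataset_id: str
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate one dataset's expression matrix and sample sheet.

    Deterministic for a fixed ``config.seed``: the baseline draws come from
    a dedicated child stream shared across datasets, and each dataset has
    its own child stream for shifts and noise, so simulating a dataset on
    its own or as part of :func:`simulate_multi_dataset` gives identical
    values.
    """
    if dataset_id not in config.cohort_sizes:
        raise KeyError(f"unknown dataset_id {dataset_id!r}")
    sizes = config.cohort_sizes[dataset_id]
    genes = config.gene_ids
    baseline = _baseline(config)
    rng = _dataset_rng(config, dataset_id)
    shift = rng.normal(0.0, config.dataset_shift_sd, size=len(genes))
    eff = _effect_table(config, dataset_id)

    cols, cohorts = [], []
    for cohort in COHORTS:  # fixed order keeps sample ids stable
        n = sizes.get(cohort, 0)
        for i in range(n):
            cols.append(f"{dataset_id}_{cohort}_{i + 1:03d}")
            cohorts.append(cohort)
    effect_mat = eff[cohorts].to_numpy()  # genes x samples
    noise = rng.normal(0.0, config.noise_sd, size=effect_mat.shape)
    values = baseline[:, None] + shift[:, None] + effect_mat + noise
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=cols),
        dataset_id=dataset_id,
        platform=config.platforms.get(dataset_id, "microarray"),
    )
    sheet = make_sample_sheet(cols, dataset_id, cohorts)
    logger.info(
        "simulated dataset %s: %d genes x %d samples (seed=%s)",
        dataset_id, expr.n_genes, expr.n_samples, config.seed,
    )
    return expr, sheet


def simulate_multi_dataset(
    config: SimulationConfig,
) -> list[tuple[ExpressionMatrix, pd.DataFrame]]:
    """Generate every configured dataset with independent per-dataset shifts."""
    if not config.cohort_sizes:
        raise ValueError("no datasets configured")
    return [simulate_cohort_expression(config, ds) for ds in config.cohort_sizes]


def simulate_qpcr_panel(
    expr: ExpressionMatrix,
    sheet: pd.DataFrame,
    panel: list[str],
    ct_noise_sd: float = 0.3,
    seed: int = 0,
    ct_intercept: float = 30.0,
) -> ExpressionMatrix:
    """Simulate a 2^-ddCt qPCR readout of ``panel`` for the same samples.

    Each gene's threshold cycle is ``Ct = ct_intercept - log2_expression +
    noise``; a stable reference gene contributes its own per-sample noise.
    dCt = Ct_gene - Ct_ref, ddCt subtracts the mean dCt of the HC
    (calibrator) cohort, and the returned log2 value is
    ``log2(2^-ddCt) = -ddCt``.  In the noiseless limit this equals the
    HC-centred log2 expression, so planted fold changes carry over exactly.
    """
    panel = list(panel)
    sub = expr.subset_genes(panel)  # raises KeyError on missing genes
    hc = sheet.loc[sheet["cohort"] == "HC", "sample_id"]
    hc = [s for s in hc if s in expr.sample_ids]
    if not hc:
        raise ValueError("qPCR simulation needs at least one HC calibrator sample")
    rng = np.random.default_rng(seed)
    log2e = sub.values
    ct_gene = ct_intercept - log2e + rng.normal(0.0, ct_noise_sd, size=log2e.shape)
    # stable reference gene: constant expression, so Ct_ref is an intercept
    # plus per-sample noise; the intercept cancels in ddCt.
    ct_ref = 18.0 + rng.normal(0.0, ct_noise_sd, size=log2e.shape[1])
    dct = ct_gene - ct_ref[None, :]
    ddct = dct.sub(dct[hc].mean(axis=1), axis=0)
    out = -ddct
    return ExpressionMatrix(out, dataset_id=f"{expr.dataset_id}_qpcr", platform="qpcr")


def reference_gene_sets(config: SimulationConfig) -> dict[str, list[str]]:
    """Gene sets mirroring the pathway annotation the discovery stage needs.

    The NK-cytotoxicity set contains the hub genes plus the co-regulated
    pathway block; the infection-response set collects the generic sepsis
    DEGs; a third set of unperturbed background genes acts as a negative
    control.
    """
    genes = config.gene_ids
    n_planted = (
        len(config.hub_genes)
        + config.n_pathway_genes
        + config.n_sepsis_degs
        + config.n_background_degs
    )
    background = genes[n_planted:]
    return {
        "NK_CELL_MEDIATED_CYTOTOXICITY": list(config.hub_genes) + config.pathway_genes,
        "INFECTION_RESPONSE": list(config.sepsis_deg_genes),
        "NEUTRAL_CONTROL": background[: min(50, len(background))],
    }
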