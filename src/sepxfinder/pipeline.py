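"""End-to-end orchestration: discovery, stage-1 scoring, stacking, evaluation.

The discovery chain mirrors the biomarker workflow: per-dataset septic-shock
vs healthy-control differential expression, direction-consistent DEG
intersection across the shock cohorts, removal of generic infection-response
DEGs via the mild-sepsis cohort, preranked GSEA of the surviving genes per
shock cohort, intersection of the leading edges of the significantly
down-regulated gene sets, and finally the logFC < -1.5 hub cutoff.

The classification chain fits, per dataset, an LDA scorer (on a stratified
training half) and a risk scorer (standardized over all samples of the
dataset), pools the (LD1, risk score) rows into a stacked dataset and trains
the L1-penalized logistic meta-model on the training rows.  Cohorts outside
{target, reference} (i.e. sepsis rows when training shock vs control) are
carried through unlabelled and classified afterwards, which is how the
meta-model separates septic shock from sepsis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .diffexp import call_degs, exclude_condition_degs, fit_gene_stats, intersect_degs
from .ensemble import SepxFindeR, build_stacked_dataset, fit_lasso_cv
from .gsea import GseaConfig, rank_by_logfc, run_gsea, select_hub_genes
from .lda import SplitSpec, fit_lda, project_ld1, train_test_split_sheet
from .metrics import confusion_metrics, roc_auc
from .risk import fit_risk_model, score_samples
from .simulate import SimulationConfig, simulate_multi_dataset, simulate_qpcr_panel

logger = logging.getLogger(__name__)

Dataset = tuple[ExpressionMatrix, pd.DataFrame]


@dataclass
class DiscoveryResult:
    hub_genes: list[str]
    candidates: list[str]
    common_degs: list[str]
    surviving_degs: list[str]
    deg_tables: dict[str, pd.DataFrame]
    exclusion_table: pd.DataFrame | None
    gsea_tables: dict[str, pd.DataFrame]
    significant_sets: list[str]


def discover_hub_panel(
    datasets: dict[str, Dataset],
    gene_sets: dict[str, list[str]],
    ss_dataset_ids: list[str],
    exclusion_dataset_id: str | None = None,
    alpha: float = 0.05,
    lfc_min: float = 0.6,
    lfc_cutoff: float = -1.5,
    gsea_config: GseaConfig | None = None,
    gsea_alpha: float = 0.05,
    moderate: bool = True,
) -> DiscoveryResult:
    """Run the full hub-gene discovery chain.

    ``ss_dataset_ids`` name the shock-vs-control discovery cohorts (at
    least two); ``exclusion_dataset_id`` optionally names a sepsis-vs-control
    cohort whose DEGs are removed from the common set.
    """
    if len(ss_dataset_ids) < 2:
        raise ValueError("discovery needs at least two shock-vs-control datasets")
    gsea_config = gsea_config or GseaConfig()

    deg_tables: dict[str, pd.DataFrame] = {}
    for ds in ss_dataset_ids:
        expr, sheet = datasets[ds]
        table = fit_gene_stats(expr, sheet, "SS", "HC", moderate=moderate)
        deg_tables[ds] = call_degs(table, alpha=alpha, lfc_min=lfc_min)
    common = intersect_degs(list(deg_tables.values()), direction_consistent=True)
    logger.info("common DEGs across %s: %d", ss_dataset_ids, len(common))

    exclusion_table = None
    surviving = list(common)
    if exclusion_dataset_id is not None:
        expr, sheet = datasets[exclusion_dataset_id]
        exclusion_table = call_degs(
            fit_gene_stats(expr, sheet, "Sep", "HC", moderate=moderate),
            alpha=alpha, lfc_min=lfc_min,
        )
        surviving = exclude_condition_degs(common, exclusion_table)
        logger.info("after exclusion: %d genes", len(surviving))

    gsea_tables: dict[str, pd.DataFrame] = {}
    per_ds_signif: list[set[str]] = []
    for ds in ss_dataset_ids:
        ranked = rank_by_logfc(deg_tables[ds], surviving) if surviving else None
        if ranked is None or len(ranked) < 3:
            gsea_tables[ds] = pd.DataFrame()
            per_ds_signif.append(set())
            continue
        tab = run_gsea(ranked, gene_sets, gsea_config)
        gsea_tables[ds] = tab
        signif = set(
            tab.index[(tab["ES"] < 0) & (tab["p_perm"] < gsea_alpha) & ~tab["degenerate"]]
        )
        per_ds_signif.append(signif)

    significant = sorted(set.intersection(*per_ds_signif)) if per_ds_signif else []
    leading_edges = []
    for ds in ss_dataset_ids:
        le: set[str] = set()
        for name in significant:
            le |= set(gsea_tables[ds].loc[name, "leading_edge"])
        leading_edges.append(sorted(le))

    candidates: list[str] = []
    hubs: list[str] = []
    if significant and all(leading_edges):
        common_le = set(leading_edges[0])
        for le in leading_edges[1:]:
            common_le &= set(le)
        candidates = sorted(common_le)
        hubs = select_hub_genes(leading_edges, list(deg_tables.values()), lfc_cutoff)
    logger.info("hub panel: %s (from %d candidates)", hubs, len(candidates))
    return DiscoveryResult(
        hub_genes=hubs,
        candidates=candidates,
        common_degs=common,
        surviving_degs=surviving,
        deg_tables=deg_tables,
        exclusion_table=exclusion_table,
        gsea_tables=gsea_tables,
        significant_sets=significant,
    )


@dataclass
class FittedDataset:
    """Stage-1 scorers and per-sample scores for one dataset."""

    dataset_id: str
    lda: object
    risk: object
    train_ids: list[str]
    test_ids: list[str]
    ld1: pd.Series
    rs: pd.Series
    sheet: pd.DataFrame


def fit_stage1(
    expr: ExpressionMatrix,
    sheet: pd.DataFrame,
    panel: list[str],
    seed: int = 0,
    train_fraction: float = 0.5,
    positive: str = "SS",
    reference: str = "HC",
    deg_table: pd.DataFrame | None = None,
) -> FittedDataset:
    """Fit LDA (training half) and risk (whole dataset) scorers for one dataset.

    The train/test split is stratified over the two labelled cohorts; other
    cohorts present in the dataset are never part of the split but are
    scored by both models.
    """
    two = sheet[sheet["cohort"].isin([reference, positive])]
    train_ids, test_ids = train_test_split_sheet(
        two, SplitSpec(train_fraction=train_fraction, seed=seed)
    )
    if deg_table is None:
        deg_table = fit_gene_stats(expr, sheet, positive, reference)
    lda = fit_lda(
        expr, sheet, panel, negative=reference, positive=positive, sample_ids=train_ids
    )
    risk = fit_risk_model(
        expr, sheet, panel,
        weight_mode="signed_unit", deg_table=deg_table,
        positive=positive, negative=reference,
        cutoff_sample_ids=train_ids,
    )
    return FittedDataset(
        dataset_id=expr.dataset_id,
        lda=lda,
        risk=risk,
        train_ids=train_ids,
        test_ids=test_ids,
        ld1=project_ld1(lda, expr),
        rs=score_samples(risk, expr),
        sheet=sheet,
    )


@dataclass
class StudyResult:
    """Everything the end-to-end run produces."""

    discovery: DiscoveryResult | None
    panel: list[str]
    stage1: dict[str, FittedDataset]
    stacked: pd.DataFrame
    model: SepxFindeR
    datasets: dict[str, Dataset] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def build_sepxfinder_pipeline(
    datasets: dict[str, Dataset],
    panel: list[str],
    seed: int = 0,
    target: str = "SS",
    reference: str = "HC",
    train_fraction: float = 0.5,
    nfold: int = 20,
    n_lambda: int = 100,
) -> tuple[dict[str, FittedDataset], pd.DataFrame, SepxFindeR]:
    """Fit stage-1 scorers per eligible dataset, stack, fit the meta-model."""
    stage1: dict[str, FittedDataset] = {}
    for i, (ds, (expr, sheet)) in enumerate(datasets.items()):
        cohorts = set(sheet["cohort"])
        if not {target, reference} <= cohorts:
            logger.info("dataset %s lacks %s/%s; skipped from stacking", ds, target, reference)
            continue
        stage1[ds] = fit_stage1(
            expr, sheet, panel,
            seed=(seed * 1009 + i) % (2**31),
            train_fraction=train_fraction,
            positive=target, reference=reference,
        )
    if not stage1:
        raise ValueError("no dataset contains both target and reference cohorts")
    stacked = build_stacked_dataset(
        [(fd.ld1, fd.rs, fd.sheet) for fd in stage1.values()],
        target=target, reference=reference, keep_cohorts=("Sep",),
    )
    train_sets = {s for fd in stage1.values() for s in fd.train_ids}
    stacked["split"] = np.where(
        stacked["sample_id"].isin(train_sets), "train",
        np.where(stacked["label"].notna(), "test", "extra"),
    )
    train_rows = stacked[(stacked["split"] == "train") & stacked["label"].notna()]
    model = fit_lasso_cv(
        train_rows, nfold=nfold, n_lambda=n_lambda, seed=seed % (2**31)
    )
    return stage1, stacked, model


def _accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    rep = confusion_metrics(y_true, y_pred)
    return rep.accuracy if rep.accuracy is not None else float("nan")


def evaluate_study(
    stage1: dict[str, FittedDataset],
    stacked: pd.DataFrame,
    model: SepxFindeR,
    sep_cohort: str = "Sep",
) -> dict:
    """Held-out shock-vs-control metrics plus the shock-vs-sepsis comparison.

    Shock-vs-control numbers pool the test halves of every dataset.  The
    shock-vs-sepsis comparison uses datasets containing the sepsis cohort:
    their held-out shock rows plus all sepsis rows, classified by the
    meta-model and by each dataset's own stage-1 rules (posterior for LDA,
    density cutoff for the risk score).
    """
    test = stacked[(stacked["split"] == "test")]
    X_test = test[["LD1", "RS"]].to_numpy()
    y_test = test["label"].to_numpy()
    acc_ss_hc = _accuracy(y_test, model.predict(X_test))
    _, auc_meta = roc_auc(model.predict_proba(X_test)[:, 1], y_test)
    _, auc_ld1 = roc_auc(test["LD1"].to_numpy(), y_test)
    _, auc_rs = roc_auc(test["RS"].to_numpy(), y_test)

    # stage-1 held-out accuracies (their own decision rules), pooled
    lda_correct, risk_correct, n_stage1 = 0, 0, 0
    for fd in stage1.values():
        sheet_i = fd.sheet.set_index("sample_id")
        ids = [s for s in fd.test_ids]
        truth = (sheet_i.loc[ids, "cohort"] == fd.lda.class_labels_[1]).to_numpy()
        ld1 = fd.ld1.loc[ids].to_numpy()
        m0, m1 = fd.lda.proj_means_
        log_odds = np.log(fd.lda.priors_[1] / fd.lda.priors_[0]) - 0.5 * (
            (ld1 - m1) ** 2 - (ld1 - m0) ** 2
        )
        lda_correct += int(np.sum((log_odds >= 0) == truth))
        rs = fd.rs.loc[ids].to_numpy()
        risk_correct += int(np.sum((rs >= fd.risk.cutoff_) == truth))
        n_stage1 += len(ids)

    out = {
        "sepx_ss_hc_accuracy": acc_ss_hc,
        "sepx_ss_hc_auc": auc_meta,
        "ld1_ss_hc_auc": auc_ld1,
        "rs_ss_hc_auc": auc_rs,
        "lda_ss_hc_accuracy": lda_correct / n_stage1 if n_stage1 else float("nan"),
        "risk_ss_hc_accuracy": risk_correct / n_stage1 if n_stage1 else float("nan"),
        "n_test": int(len(test)),
    }

    # shock vs sepsis: held-out shock rows + sepsis rows of sepsis-bearing datasets
    sep_rows = stacked[stacked["cohort"] == sep_cohort]
    if len(sep_rows):
        sep_ds = set(sep_rows["dataset_id"])
        eval_rows = stacked[
            (stacked["dataset_id"].isin(sep_ds))
            & (
                (stacked["cohort"] == sep_cohort)
                | ((stacked["split"] == "test") & (stacked["label"] == 1.0))
            )
        ]
        y = (eval_rows["cohort"] != sep_cohort).astype(int).to_numpy()  # 1 = shock
        X = eval_rows[["LD1", "RS"]].to_numpy()
        out["sepx_ss_sep_accuracy"] = _accuracy(y, model.predict(X))
        lda_pred = np.zeros(len(eval_rows), dtype=int)
        risk_pred = np.zeros(len(eval_rows), dtype=int)
        for i, (_, row) in enumerate(eval_rows.iterrows()):
            fd = stage1[row["dataset_id"]]
            m0, m1 = fd.lda.proj_means_
            log_odds = np.log(fd.lda.priors_[1] / fd.lda.priors_[0]) - 0.5 * (
                (row["LD1"] - m1) ** 2 - (row["LD1"] - m0) ** 2
            )
            lda_pred[i] = int(log_odds >= 0)
            risk_pred[i] = int(row["RS"] >= fd.risk.cutoff_)
        out["lda_ss_sep_accuracy"] = _accuracy(y, lda_pred)
        out["risk_ss_sep_accuracy"] = _accuracy(y, risk_pred)
        out["n_ss_sep"] = int(len(eval_rows))
    return out


def run_study(
    config: SimulationConfig | None = None,
    seed: int = 0,
    gsea_config: GseaConfig | None = None,
    nfold: int = 20,
    n_lambda: int = 100,
) -> StudyResult:
    """Simulate the multi-cohort study, discover the panel, fit and evaluate.

    The discovered panel (not the planted one) feeds the model stages, so
    the whole chain is exercised end to end.
    """
    from .simulate import reference_gene_sets

    config = config or SimulationConfig(seed=seed)
    if config.seed != seed:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})
    gsea_config = gsea_config or GseaConfig(n_permutations=200, seed=seed)
    sims = simulate_multi_dataset(config)
    datasets = {expr.dataset_id: (expr, sheet) for expr, sheet in sims}

    ds_ids = list(datasets)
    ss_ids = [
        ds for ds, (e, sh) in datasets.items()
        if {"SS", "HC"} <= set(sh["cohort"]) and "Sep" not in set(sh["cohort"])
    ]
    excl_ids = [
        ds for ds, (e, sh) in datasets.items()
        if "Sep" in set(sh["cohort"]) and "SS" not in set(sh["cohort"])
    ]
    discovery = discover_hub_panel(
        datasets,
        reference_gene_sets(config),
        ss_dataset_ids=ss_ids or ds_ids[:2],
        exclusion_dataset_id=excl_ids[0] if excl_ids else None,
        gsea_config=gsea_config,
    )
    panel = discovery.hub_genes
    if len(panel) < 2:
        raise ValueError(f"discovered panel too small to fit models: {panel}")
    stage1, stacked, model = build_sepxfinder_pipeline(
        datasets, panel, seed=seed, nfold=nfold, n_lambda=n_lambda
    )
    summary = evaluate_study(stage1, stacked, model)
    summary["panel"] = panel
    summary["n_common_degs"] = len(discovery.common_degs)
    summary["exact_recovery"] = sorted(panel) == sorted(config.hub_genes)
    return StudyResult(
        discovery=discovery, panel=panel, stage1=stage1,
        stacked=stacked, model=model, datasets=datasets, summary=summary,
    )


def qpcr_transfer_experiment(
    study: "StudyResult",
    ct_noise_sd: float = 0.3,
    seed: int = 0,
    target: str = "SS",
    reference: str = "HC",
) -> dict:
    """Replay the study's cohorts through the 2^-ddCt qPCR model and re-score.

    Every dataset that entered the stacked model is read out again through
    the Ct model (per-gene and shared per-sample reference noise of
    ``ct_noise_sd`` cycles).  Stage-1 scorers are re-derived the way a qPCR
    site would: the LDA scorer is refit on the same training half of the
    qPCR values, the risk score keeps its weights but re-standardizes u, s
    on the qPCR dataset.  The meta-model transfers unchanged and is
    evaluated on the same held-out rows as the original platform, giving a
    paired cross-platform accuracy comparison.
    """
    panel = study.panel
    correct_q, n_total = 0, 0
    for i, (ds, fd) in enumerate(study.stage1.items()):
        expr, sheet = study.datasets[ds]
        qpcr = simulate_qpcr_panel(
            expr, sheet, panel, ct_noise_sd=ct_noise_sd,
            seed=(seed * 2**16 + 101 * i + 11) % (2**31),
        )
        lda_q = fit_lda(
            qpcr, sheet, panel, negative=reference, positive=target,
            sample_ids=fd.train_ids,
        )
        risk_q = fd.risk.refit_reference(qpcr.panel_matrix(panel))
        ld1 = project_ld1(lda_q, qpcr)
        rs = pd.Series(
            risk_q.transform(qpcr.panel_matrix(panel)), index=qpcr.sample_ids
        )
        sheet_i = sheet.set_index("sample_id")
        y = (sheet_i.loc[fd.test_ids, "cohort"] == target).astype(int).to_numpy()
        feats = np.column_stack(
            [ld1.loc[fd.test_ids].to_numpy(), rs.loc[fd.test_ids].to_numpy()]
        )
        correct_q += int(np.sum(study.model.predict(feats) == y))
        n_total += len(fd.test_ids)
    acc_qpcr = correct_q / n_total
    acc_array = study.summary["sepx_ss_hc_accuracy"]
    return {
        "accuracy_microarray": acc_array,
        "accuracy_qpcr": acc_qpcr,
        "accuracy_drop_pp": 100.0 * (acc_array - acc_qpcr),
        "n_test": n_total,
    }
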