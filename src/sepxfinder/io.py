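"""TSV / GMT / JSON readers and writers for every pipeline artifact."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_sample_sheet
from .ensemble import SepxFindeR
from .lda import LinearDiscriminantScorer
from .risk import RiskScorer


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_expression_tsv(
    path, dataset_id: str | None = None, platform: str = "microarray"
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.index.name!r}")
    if dataset_id is None:
        dataset_id = Path(path).stem
    return ExpressionMatrix(df, dataset_id=dataset_id, platform=platform)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet[["sample_id", "dataset_id", "cohort"]].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    try:
        return validate_sample_sheet(sheet)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_deg_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "gene_id"
    out.rename(columns={"p_value": "p", "q_value": "q"}).to_csv(path, sep="\t")


def read_deg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.rename(columns={"p": "p_value", "q": "q_value"})
    df["is_deg"] = df["is_deg"].astype(bool)
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: set name, description, then tab-separated genes.

    Tolerates trailing empty fields; duplicate set names and malformed rows
    raise with the offending line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected name, description, genes")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
            genes = [g for g in fields[2:] if g.strip()]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_stacked_tsv(stacked: pd.DataFrame, path) -> None:
    stacked.to_csv(path, sep="\t", index=False)


def read_stacked_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


_MODEL_KINDS = {
    "lda": LinearDiscriminantScorer,
    "risk": RiskScorer,
    "sepxfinder": SepxFindeR,
}


def save_model(model, path) -> None:
    """Serialize a fitted estimator (LDA, risk, or meta-model) to JSON."""
    payload = model.to_dict()
    if hasattr(model, "panel_"):
        payload["panel"] = list(model.panel_)
    if hasattr(model, "class_labels_"):
        payload["class_labels"] = list(model.class_labels_)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path):
    with open(path) as fh:
        payload = json.load(fh)
    kind = payload.get("kind")
    if kind not in _MODEL_KINDS:
        raise ValueError(f"{path}: unknown model kind {kind!r}")
    model = _MODEL_KINDS[kind].from_dict(payload)
    if payload.get("panel"):
        model.panel_ = list(payload["panel"])
    if payload.get("class_labels"):
        model.class_labels_ = tuple(payload["class_labels"])
    return model
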