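"""In-memory containers shared by every pipeline stage.

Expression data is held as a genes x samples :class:`pandas.DataFrame` on the
log2 scale regardless of the originating platform (microarray log2 intensity,
log2(TPM+1)-like RNA-seq values, or -ddCt from qPCR), so that fold changes,
z-scores and discriminant projections mean the same thing everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Closed set of cohort labels: healthy control, sepsis, septic shock.
COHORTS = ("HC", "Sep", "SS")

PLATFORMS = ("microarray", "rnaseq", "qpcr")


@dataclass
class ExpressionMatrix:
    """A genes x samples log2 expression matrix tagged with its dataset.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene symbol, columns by sample id, finite floats.
    dataset_id : str
        Label of the dataset (cohort study) the samples belong to.
    platform : str
        One of ``"microarray"``, ``"rnaseq"``, ``"qpcr"``.
    """

    values: pd.DataFrame
    dataset_id: str = "dataset"
    platform: str = "microarray"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        self.values.index.name = "gene_id"
        self.values.columns.name = None
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][:5].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression values must be finite")
        if self.platform not in PLATFORMS:
            raise ValueError(
                f"platform {self.platform!r} not in {PLATFORMS}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not present: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.dataset_id, self.platform)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not present: {missing}")
        return ExpressionMatrix(self.values[list(samples)], self.dataset_id, self.platform)

    def panel_matrix(self, panel: list[str]) -> np.ndarray:
        """Samples x panel-genes array (the orientation estimators expect)."""
        return self.subset_genes(panel).values.to_numpy().T


def make_sample_sheet(
    sample_ids: list[str], dataset_id: str, cohorts: list[str]
) -> pd.DataFrame:
    """Build a sample sheet (``sample_id``, ``dataset_id``, ``cohort``)."""
    sheet = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "dataset_id": dataset_id,
            "cohort": list(cohorts),
        }
    )
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    required = ["sample_id", "dataset_id", "cohort"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()[:5]
        raise ValueError(f"duplicate sample ids in sheet: {dup}")
    bad = sheet.loc[~sheet["cohort"].isin(COHORTS)]
    if len(bad):
        row = bad.iloc[0]
        # +2: header line plus 1-based counting, matching the on-disk TSV
        raise ValueError(
            f"unknown cohort label {row['cohort']!r} for sample "
            f"{row['sample_id']!r} (line {bad.index[0] + 2})"
        )
    return sheet.reset_index(drop=True)


def cohort_samples(sheet: pd.DataFrame, cohort: str) -> list[str]:
    """Sample ids of one cohort, in sheet order."""
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    return sheet.loc[sheet["cohort"] == cohort, "sample_id"].tolist()


def check_alignment(expr: ExpressionMatrix, sheet: pd.DataFrame) -> None:
    """Every expression sample must have exactly one sheet row."""
    sheet_ids = set(sheet["sample_id"])
    missing = [s for s in expr.sample_ids if s not in sheet_ids]
    if missing:
        raise ValueError(f"samples missing from sheet: {missing[:5]}")
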