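import numpy as np
import pandas as pd
import pytest

from sepxfinder import ExpressionMatrix, SimulationConfig, make_sample_sheet


@pytest.fixture
def small_config():
    """Compact study conditions: same planted effects, fewer genes/samples."""
    return SimulationConfig(
        n_genes=400,
        n_pathway_genes=20,
        n_background_degs=60,
        n_sepsis_degs=40,
        cohort_sizes={
            "array1": {"SS": 20, "HC": 20},
            "array2": {"SS": 18, "HC": 16},
            "array3": {"Sep": 16, "HC": 14},
            "rnaseq": {"SS": 12, "Sep": 12, "HC": 16},
        },
        seed=11,
    )


@pytest.fixture
def noiseless_config():
    return SimulationConfig(
        n_genes=200,
        n_pathway_genes=10,
        n_background_degs=20,
        n_sepsis_degs=10,
        noise_sd=0.0,
        dataset_shift_sd=0.0,
        cohort_sizes={"d": {"SS": 4, "Sep": 4, "HC": 4}},
        platforms={"d": "microarray"},
        seed=5,
    )


@pytest.fixture
def toy_two_cohorts():
    """Deterministic 4-gene matrix with a clear SS-vs-HC signal."""
    rng = np.random.default_rng(42)
    genes = ["GA", "GB", "GC", "GD"]
    hc = rng.normal(8.0, 0.3, size=(4, 10))
    ss = rng.normal(8.0, 0.3, size=(4, 10))
    ss[:2] -= 2.0  # GA, GB down in shock
    vals = np.hstack([hc, ss])
    cols = [f"hc{i}" for i in range(10)] + [f"ss{i}" for i in range(10)]
    expr = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=cols), "toy")
    sheet = make_sample_sheet(cols, "toy", ["HC"] * 10 + ["SS"] * 10)
    return expr, sheet
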