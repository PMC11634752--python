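"""Differential expression: t-test oracle, BH brute force, DEG set algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sepxfinder import (
    ExpressionMatrix,
    adjust_bh,
    call_degs,
    exclude_condition_degs,
    fit_gene_stats,
    intersect_degs,
    make_sample_sheet,
    simulate_cohort_expression,
)
from sepxfinder.simulate import SimulationConfig


def _expr_from_groups(groups: dict[str, np.ndarray], genes=None) -> tuple:
    """Build a tiny ExpressionMatrix/sheet from per-cohort gene x sample blocks."""
    mats, cols, cohorts = [], [], []
    for cohort, block in groups.items():
        block = np.atleast_2d(np.asarray(block, dtype=float))
        mats.append(block)
        cols += [f"{cohort.lower()}{i}" for i in range(block.shape[1])]
        cohorts += [cohort] * block.shape[1]
    genes = genes or [f"g{i}" for i in range(mats[0].shape[0])]
    expr = ExpressionMatrix(
        pd.DataFrame(np.hstack(mats), index=genes, columns=cols), "tiny"
    )
    return expr, make_sample_sheet(cols, "tiny", cohorts)


class TestFitGeneStats:
    def test_textbook_pooled_t(self):
        expr, sheet = _expr_from_groups({"HC": [[2, 3, 4]], "SS": [[5, 6, 7]]})
        tab = fit_gene_stats(expr, sheet, "SS", "HC", moderate=False)
        t_ref, p_ref = stats.ttest_ind([5, 6, 7], [2, 3, 4], equal_var=True)
        assert tab["logFC"].iloc[0] == pytest.approx(3.0)
        assert tab["t"].iloc[0] == pytest.approx(t_ref)
        assert tab["p_value"].iloc[0] == pytest.approx(p_ref)

    def test_null_gene(self):
        expr, sheet = _expr_from_groups(
            {"HC": [[1, 2, 3], [5, 5, 6]], "SS": [[1, 2, 3], [7, 8, 7]]}
        )
        tab = fit_gene_stats(expr, sheet, "SS", "HC", moderate=False)
        assert tab["logFC"].iloc[0] == 0.0
        assert tab["p_value"].iloc[0] == pytest.approx(1.0)

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(5, 8))
        expr1, sheet = _expr_from_groups({"HC": block[:, :4], "SS": block[:, 4:]})
        expr2, _ = _expr_from_groups({"HC": block[:, :4] + 7.5, "SS": block[:, 4:] + 7.5})
        t1 = fit_gene_stats(expr1, sheet, "SS", "HC")
        t2 = fit_gene_stats(expr2, sheet, "SS", "HC")
        for col in ("logFC", "t", "p_value"):
            np.testing.assert_allclose(t1[col], t2[col], atol=1e-10)

    def test_moderated_matches_oracle_in_zero_prior_limit(self, monkeypatch):
        """With the prior forced to d0 -> 0, moderated t equals the plain t."""
        import sepxfinder.diffexp as dmod

        rng = np.random.default_rng(1)
        expr, sheet = _expr_from_groups(
            {"HC": rng.normal(size=(40, 6)), "SS": rng.normal(size=(40, 6))}
        )
        plain = fit_gene_stats(expr, sheet, "SS", "HC", moderate=False)
        monkeypatch.setattr(dmod, "_moment_match_prior", lambda v, d: (1e-9, 1.0))
        mod = fit_gene_stats(expr, sheet, "SS", "HC", moderate=True)
        np.testing.assert_allclose(mod["t"], plain["t"], rtol=1e-6)
        np.testing.assert_allclose(mod["p_value"], plain["p_value"], rtol=1e-5)

    def test_moderated_p_monotone_in_abs_t(self):
        rng = np.random.default_rng(2)
        expr, sheet = _expr_from_groups(
            {"HC": rng.normal(size=(100, 5)), "SS": rng.normal(size=(100, 5))}
        )
        tab = fit_gene_stats(expr, sheet, "SS", "HC", moderate=True)
        order = np.argsort(np.abs(tab["t"].to_numpy()))
        assert np.all(np.diff(tab["p_value"].to_numpy()[order]) <= 1e-12)

    def test_moderation_shrinks_variance_outliers(self):
        """A gene with wildly inflated sample variance gains |t| under moderation."""
        rng = np.random.default_rng(3)
        hc = rng.normal(0, 0.3, size=(200, 10))
        ss = rng.normal(0, 0.3, size=(200, 10))
        ss[0] += 1.0
        hc[0, 0] += 8.0  # one outlier inflates gene 0's variance
        expr, sheet = _expr_from_groups({"HC": hc, "SS": ss})
        plain = fit_gene_stats(expr, sheet, "SS", "HC", moderate=False)
        mod = fit_gene_stats(expr, sheet, "SS", "HC", moderate=True)
        assert abs(mod["t"].iloc[0]) > abs(plain["t"].iloc[0])

    def test_missing_cohort_raises(self):
        expr, sheet = _expr_from_groups({"HC": [[1, 2, 3]], "SS": [[1, 2, 3]]})
        with pytest.raises(ValueError):
            fit_gene_stats(expr, sheet, "Sep", "HC")


def _bh_bruteforce(p):
    """Stepwise BH from the definition: q_i = min_{j: p_(j) >= p_(i)} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for i in range(m):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(m) if p[order[j]] >= p[i] - 1e-15
        ]
        q[i] = min(1.0, min(candidates))
    return q


class TestBenjaminiHochberg:
    def test_single_p(self):
        assert adjust_bh([0.03]) == pytest.approx([0.03])

    def test_stepwise_by_hand(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_ties_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_bruteforce(self, p):
        np.testing.assert_allclose(adjust_bh(p), _bh_bruteforce(p), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=30))
    def test_order_preserving_and_dominating(self, p):
        q = adjust_bh(p)
        p = np.asarray(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0 + 1e-15)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)


def _table(records):
    tab = pd.DataFrame(records).set_index("gene_id")
    tab["t"] = 0.0
    tab["p_value"] = tab["q_value"]
    return tab


class TestDegCalling:
    def test_strict_boundaries(self):
        tab = _table(
            [
                {"gene_id": "a", "logFC": 0.7, "q_value": 0.04},
                {"gene_id": "b", "logFC": 0.6, "q_value": 0.04},
                {"gene_id": "c", "logFC": 0.7, "q_value": 0.05},
            ]
        )
        out = call_degs(tab)
        assert out.loc["a", "is_deg"]
        assert not out.loc["b", "is_deg"]  # |logFC| must exceed 0.6 strictly
        assert not out.loc["c", "is_deg"]  # q must be below 0.05 strictly

    def test_empty_table(self):
        tab = _table([{"gene_id": "x", "logFC": 0.0, "q_value": 1.0}]).iloc[:0]
        assert call_degs(tab)["is_deg"].tolist() == []

    def test_gene_order_invariance(self):
        recs = [
            {"gene_id": g, "logFC": lf, "q_value": q}
            for g, lf, q in [("a", 1.0, 0.01), ("b", -2.0, 0.2), ("c", 0.9, 0.001)]
        ]
        fwd = call_degs(_table(recs))
        rev = call_degs(_table(recs[::-1]))
        assert fwd.loc[list("abc"), "is_deg"].tolist() == rev.loc[list("abc"), "is_deg"].tolist()

    def test_planted_hubs_called_down(self, small_config):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimulationConfig(**{**small_config.__dict__, "seed": seed})
            expr, sheet = simulate_cohort_expression(cfg, "array1")
            tab = fit_gene_stats(expr, sheet, "SS", "HC")
            down = tab.loc[list(cfg.hub_genes)]
            if bool((down["is_deg"] & (down["logFC"] < 0)).all()):
                hits += 1
        assert hits >= 0.95 * n_seeds


class TestDegSetAlgebra:
    def _mk(self, degs, signs=None):
        signs = signs or {}
        recs = [
            {"gene_id": g, "logFC": signs.get(g, -1.0), "q_value": 0.01 if flag else 0.9}
            for g, flag in degs.items()
        ]
        return call_degs(_table(recs))

    def test_disjoint_sets_empty(self):
        a = self._mk({"x": True, "y": False})
        b = self._mk({"x": False, "y": True})
        assert intersect_degs([a, b]) == []

    def test_idempotent(self):
        a = self._mk({"x": True, "y": True, "z": False})
        assert intersect_degs([a, a]) == ["x", "y"]

    def test_direction_consistency_drops_flipped_gene(self):
        a = self._mk({"x": True, "y": True, "z": True})
        b = self._mk({"x": True, "y": True, "z": True}, signs={"z": 2.0})
        assert intersect_degs([a, b], direction_consistent=True) == ["x", "y"]
        assert intersect_degs([a, b], direction_consistent=False) == ["x", "y", "z"]

    def test_exclusion_no_degs_keeps_input(self):
        excl = self._mk({"x": False, "y": False})
        assert exclude_condition_degs(["a", "b"], excl) == ["a", "b"]

    def test_exclusion_set_difference(self):
        excl = self._mk({"B": True, "C": False})
        assert exclude_condition_degs(["A", "B", "C"], excl) == ["A", "C"]

    def test_hub_genes_survive_exclusion_on_planted_data(self, small_config):
        expr, sheet = simulate_cohort_expression(small_config, "array3")
        excl = fit_gene_stats(expr, sheet, "Sep", "HC")
        survivors = exclude_condition_degs(list(small_config.hub_genes), excl)
        assert survivors == list(small_config.hub_genes)
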