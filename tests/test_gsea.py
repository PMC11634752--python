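"""Enrichment walk against a from-definition oracle, leading edges, hub rule."""

import warnings

import numpy as np
import pandas as pd
import pytest

from sepxfinder import (
    GseaConfig,
    enrichment_score,
    leading_edge,
    make_ranked_list,
    permutation_nes,
    select_hub_genes,
)
from sepxfinder.gsea import rank_by_logfc


def walk_oracle(ranked, gene_set, p=1.0):
    """Naive O(N) re-walk of the running statistic, straight from the definition."""
    members = set(gene_set)
    hits = np.array([g in members for g in ranked.genes])
    n, k = len(ranked), int(hits.sum())
    w = np.abs(ranked.metric) ** p
    nr = w[hits].sum()
    if nr == 0:
        w = np.ones(n)
        nr = float(k)
    running = np.empty(n)
    acc = 0.0
    for i in range(n):
        if hits[i]:
            acc += w[i] / nr
        else:
            acc -= 1.0 / (n - k)
        running[i] = acc
    i_ext = int(np.argmax(np.abs(running)))
    best = running[i_ext]
    # resolve +/- ties toward the positive extremum, as the implementation does
    if abs(running.max()) == abs(running.min()) and best < 0:
        i_ext = int(np.argmax(running))
        best = running[i_ext]
    return float(best), i_ext + 1


def random_instance(rng, n=None, k=None):
    n = n or int(rng.integers(5, 60))
    k = k or int(rng.integers(1, n - 1))
    genes = [f"g{i:03d}" for i in range(n)]
    metric = rng.normal(size=n)
    ranked = make_ranked_list(genes, metric)
    gene_set = list(rng.choice(genes, size=k, replace=False))
    return ranked, gene_set


class TestEnrichmentScore:
    def test_top_packed_set_scores_one(self):
        ranked = make_ranked_list([f"g{i}" for i in range(10)], np.arange(10, 0, -1))
        es, peak = enrichment_score(ranked, [f"g{i}" for i in range(3)])
        assert es == pytest.approx(1.0)
        assert peak == 3

    def test_bottom_packed_set_scores_minus_one(self):
        metric = np.arange(10, 0, -1.0) - 8.0  # bottom genes negative
        ranked = make_ranked_list([f"g{i}" for i in range(10)], metric)
        bottom = list(ranked.genes[-3:])
        es, peak = enrichment_score(ranked, bottom)
        assert es == pytest.approx(-1.0)
        assert peak == 7  # position just before the first bottom hit

    def test_five_gene_walk_by_hand(self):
        # metrics (3,2,1,-1,-2), hits at ranks 1 and 4, p=1
        ranked = make_ranked_list(list("abcde"), [3, 2, 1, -1, -2])
        es, peak = enrichment_score(ranked, ["a", "d"], p=1.0)
        # explicit walk: nr=4; steps: +3/4, -1/3, -1/3, +1/4, -1/3
        walk = np.cumsum([3 / 4, -1 / 3, -1 / 3, 1 / 4, -1 / 3])
        assert es == pytest.approx(walk[0])  # extremum at the first position
        assert peak == 1

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            ranked, gene_set = random_instance(rng)
            es, peak = enrichment_score(ranked, gene_set)
            es_ref, peak_ref = walk_oracle(ranked, gene_set)
            assert es == pytest.approx(es_ref, abs=1e-12)
            assert abs(es) <= 1.0 + 1e-12

    def test_scale_invariance_at_unit_exponent(self):
        rng = np.random.default_rng(7)
        ranked, gene_set = random_instance(rng, n=30, k=6)
        es1, _ = enrichment_score(ranked, gene_set, p=1.0)
        scaled = make_ranked_list(ranked.genes, ranked.metric * 37.5)
        es2, _ = enrichment_score(scaled, gene_set, p=1.0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_empty_and_full_intersections_rejected(self):
        ranked = make_ranked_list(list("abc"), [3, 2, 1])
        with pytest.raises(ValueError):
            enrichment_score(ranked, ["zz"])
        with pytest.raises(ValueError):
            enrichment_score(ranked, list("abc"))

    def test_tie_break_is_lexicographic(self):
        ranked = make_ranked_list(["zeta", "alpha", "mid"], [1.0, 1.0, 0.5])
        assert ranked.genes.tolist() == ["alpha", "zeta", "mid"]


class TestLeadingEdge:
    def test_top_set_full_edge(self):
        ranked = make_ranked_list([f"g{i}" for i in range(8)], np.arange(8, 0, -1))
        members = [f"g{i}" for i in range(3)]
        es, peak = enrichment_score(ranked, members)
        assert sorted(leading_edge(ranked, members, es, peak)) == sorted(members)

    def test_bottom_set_full_edge(self):
        metric = np.arange(8, 0, -1.0) - 6.0
        ranked = make_ranked_list([f"g{i}" for i in range(8)], metric)
        members = list(ranked.genes[-3:])
        es, peak = enrichment_score(ranked, members)
        assert es < 0
        assert sorted(leading_edge(ranked, members, es, peak)) == sorted(members)

    def test_positive_peak_prefix_by_hand(self):
        # N=6, hits at ranks 2, 3, 6, positive peak at rank 3
        ranked = make_ranked_list(list("abcdef"), [6, 5, 4, 3, 2, 1])
        members = ["b", "c", "f"]
        es, peak = enrichment_score(ranked, members)
        assert es > 0 and peak == 3
        assert leading_edge(ranked, members, es, peak) == ["b", "c"]

    def test_zero_es_warns_and_returns_empty(self):
        ranked = make_ranked_list(list("ab"), [1.0, -1.0])
        with pytest.warns(UserWarning):
            assert leading_edge(ranked, ["a"], 0.0, 1) == []


class TestPermutationNes:
    def test_determinism(self):
        rng = np.random.default_rng(11)
        ranked, gene_set = random_instance(rng, n=50, k=8)
        cfg = GseaConfig(n_permutations=200, seed=99)
        a = permutation_nes(ranked, gene_set, cfg)
        b = permutation_nes(ranked, gene_set, cfg)
        assert a.es == b.es and a.nes == b.nes and a.p_perm == b.p_perm

    def test_sign_consistency_and_bounds(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            ranked, gene_set = random_instance(rng, n=40)
            rec = permutation_nes(ranked, gene_set, GseaConfig(n_permutations=100, seed=5))
            if not rec.degenerate:
                assert np.sign(rec.nes) == np.sign(rec.es)
            assert 0.0 < rec.p_perm <= 1.0
            assert set(rec.leading_edge) <= set(gene_set)

    def test_planted_downregulated_set_detected(self, small_config):
        from sepxfinder import fit_gene_stats, simulate_cohort_expression

        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            from sepxfinder.simulate import SimulationConfig

            cfg = SimulationConfig(**{**small_config.__dict__, "seed": seed})
            expr, sheet = simulate_cohort_expression(cfg, "array1")
            tab = fit_gene_stats(expr, sheet, "SS", "HC")
            ranked = rank_by_logfc(tab)
            nk = list(cfg.hub_genes) + cfg.pathway_genes
            rec = permutation_nes(
                ranked, nk, GseaConfig(n_permutations=200, seed=seed)
            )
            if rec.es < 0 and rec.p_perm < 0.05:
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_null_p_values_roughly_uniform(self):
        """Type-I error of the permutation p at the 5% level (scaled replicate)."""
        rng = np.random.default_rng(17)
        genes = [f"g{i:03d}" for i in range(200)]
        ranked = make_ranked_list(genes, rng.normal(size=200))
        pvals = []
        for i in range(150):
            gene_set = list(rng.choice(genes, size=15, replace=False))
            rec = permutation_nes(
                ranked, gene_set, GseaConfig(n_permutations=250, seed=1000 + i)
            )
            pvals.append(rec.p_perm)
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.01 <= frac <= 0.09


class TestHubSelection:
    def _deg(self, lfc: dict):
        tab = pd.DataFrame({"logFC": pd.Series(lfc)})
        tab["t"] = 0.0
        tab["p_value"] = 0.01
        tab["q_value"] = 0.01
        tab["is_deg"] = True
        return tab

    def test_candidate_fixture_selects_the_six_hubs(self):
        """Twelve overlapping candidates, of which exactly six clear logFC < -1.5."""
        hubs = ["GZMB", "PRF1", "KLRD1", "SH2D1A", "LCK", "CD247"]
        others = ["KIR2DL1", "FASLG", "NCR3", "IFNG", "TNFSF10", "RAC2"]
        lfc1 = {g: -1.9 for g in hubs} | {g: -1.0 for g in others}
        lfc2 = {g: -1.7 for g in hubs} | {g: -1.2 for g in others}
        got = select_hub_genes([hubs + others, others + hubs], [self._deg(lfc1), self._deg(lfc2)])
        assert sorted(got) == sorted(hubs)
        # both cutoff readings agree on this fixture
        got_all = select_hub_genes(
            [hubs + others, others + hubs], [self._deg(lfc1), self._deg(lfc2)], rule="all"
        )
        assert sorted(got_all) == sorted(hubs)

    def test_sorted_by_mean_logfc(self):
        lfc1 = {"A": -2.5, "B": -1.8, "C": -3.0}
        lfc2 = {"A": -2.5, "B": -1.9, "C": -2.9}
        got = select_hub_genes([["A", "B", "C"]] * 2, [self._deg(lfc1), self._deg(lfc2)])
        assert got == ["C", "A", "B"]

    def test_disjoint_leading_edges_empty(self):
        t = self._deg({"A": -2.0, "B": -2.0})
        assert select_hub_genes([["A"], ["B"]], [t, t]) == []

    def test_no_cutoff_returns_intersection(self):
        t = self._deg({"A": -0.1, "B": -5.0, "C": 2.0})
        got = select_hub_genes([["A", "B"], ["B", "A"]], [t, t], lfc_cutoff=np.inf)
        assert sorted(got) == ["A", "B"]

    def test_missing_gene_raises(self):
        t = self._deg({"A": -2.0})
        with pytest.raises(KeyError):
            select_hub_genes([["A", "B"], ["A", "B"]], [t, t])
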