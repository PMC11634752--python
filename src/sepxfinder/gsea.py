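"""Preranked gene-set enrichment: weighted KS walk, permutation NES, leading edge.

Genes are ranked by their log2 fold change (descending).  Walking the list,
in-set genes ("hits") advance the running statistic by their
|metric|^p / N_R (N_R the sum over in-set genes), misses retreat it by
1/(N - k).  The enrichment score (ES) is the signed extremum of the walk;
the leading edge is the in-set prefix (positive ES) or suffix (negative ES)
up to / from the extremum.  Significance comes from size-preserving
gene-label permutations; NES normalizes by the mean |null ES| of matching
sign.

The walk only changes slope at hit positions, so the extremum is computed
from the O(k) candidate values at each hit (maximum) and just before each
hit (minimum); the naive O(N) re-walk lives in the test suite as the
independent oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes ordered by a ranking metric, best (most positive) first."""

    genes: np.ndarray
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.metric = np.asarray(self.metric, dtype=float)
        if self.genes.size != self.metric.size:
            raise ValueError("genes and metric must have equal length")
        if len(set(self.genes)) != self.genes.size:
            raise ValueError("ranked list contains duplicate genes")
        if not np.all(np.isfinite(self.metric)):
            raise ValueError("ranking metric must be finite")

    def __len__(self) -> int:
        return int(self.genes.size)


def make_ranked_list(gene_ids, metric) -> RankedList:
    """Sort genes by metric descending; ties break lexicographically by symbol."""
    genes = np.asarray(list(gene_ids), dtype=object)
    metric = np.asarray(metric, dtype=float)
    order = np.lexsort((genes.astype(str), -metric))
    return RankedList(genes[order], metric[order])


def rank_by_logfc(deg_table: pd.DataFrame, genes: list[str] | None = None) -> RankedList:
    """Ranked list from a DEG table's logFC column, optionally restricted."""
    tab = deg_table if genes is None else deg_table.loc[list(genes)]
    return make_ranked_list(tab.index.to_numpy(), tab["logFC"].to_numpy())


@dataclass
class GseaConfig:
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight exponent must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass
class GseaRecord:
    set_name: str
    es: float
    nes: float
    p_perm: float
    leading_edge: list[str] = field(default_factory=list)
    peak_index: int = 0
    n_same_sign: int = 0
    degenerate: bool = False


def _hit_positions(ranked: RankedList, gene_set) -> np.ndarray:
    members = set(gene_set)
    pos = np.flatnonzero(np.fromiter((g in members for g in ranked.genes), bool, len(ranked)))
    if pos.size == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if pos.size == len(ranked):
        raise ValueError("gene set covers the entire ranked list")
    return pos


def _es_from_positions(
    pos: np.ndarray, abs_metric_p: np.ndarray, n_total: int
) -> tuple[float, int]:
    """ES and 1-based peak position from sorted 0-based hit positions.

    ``abs_metric_p`` is |metric|^p for the whole ranked list.
    """
    k = pos.size
    w = abs_metric_p[pos]
    nr = w.sum()
    if nr == 0:  # all in-set metrics zero: fall back to unweighted hits
        w = np.ones(k)
        nr = float(k)
    cumw = np.cumsum(w) / nr
    j = np.arange(k)
    miss_frac = (pos - j) / (n_total - k)
    d_hit = cumw - miss_frac
    d_before = np.concatenate(([0.0], cumw[:-1])) - miss_frac
    jmax = int(np.argmax(d_hit))
    jmin = int(np.argmin(d_before))
    d_max, d_min = float(d_hit[jmax]), float(d_before[jmin])
    if d_max >= -d_min:  # ties resolve to the positive extremum
        return d_max, int(pos[jmax]) + 1
    return d_min, int(pos[jmin])  # 1-based position just before hit jmin


def enrichment_score(
    ranked: RankedList, gene_set, p: float = 1.0
) -> tuple[float, int]:
    """Signed extremum of the weighted KS walk and its 1-based position."""
    pos = _hit_positions(ranked, gene_set)
    return _es_from_positions(pos, np.abs(ranked.metric) ** p, len(ranked))


def _null_es(
    abs_metric_p: np.ndarray, n_total: int, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized null ES for size-k random gene sets (label permutation)."""
    base = np.tile(np.arange(n_total), (n_perm, 1))
    posmat = np.sort(rng.permuted(base, axis=1)[:, :k], axis=1)
    w = abs_metric_p[posmat]
    nr = w.sum(axis=1)
    zero = nr == 0
    if np.any(zero):
        w[zero] = 1.0
        nr[zero] = k
    cumw = np.cumsum(w, axis=1) / nr[:, None]
    j = np.arange(k)[None, :]
    miss_frac = (posmat - j) / (n_total - k)
    d_hit = cumw - miss_frac
    d_before = cumw - w / nr[:, None] - miss_frac
    d_max = d_hit.max(axis=1)
    d_min = d_before.min(axis=1)
    return np.where(d_max >= -d_min, d_max, d_min)


def permutation_nes(
    ranked: RankedList,
    gene_set,
    config: GseaConfig | None = None,
    set_name: str = "gene_set",
) -> GseaRecord:
    """ES with permutation NES and p-value, plus the leading-edge genes.

    p_perm uses the add-one estimator over null ES values whose sign matches
    the observed ES; with no same-sign null realizations the record is
    flagged degenerate with p_perm = 1.
    """
    config = config or GseaConfig()
    abs_p = np.abs(ranked.metric) ** config.weight_exponent
    pos = _hit_positions(ranked, gene_set)
    es, peak = _es_from_positions(pos, abs_p, len(ranked))
    rng = np.random.default_rng(config.seed)
    null = _null_es(abs_p, len(ranked), pos.size, config.n_permutations, rng)
    same = null[np.sign(null) == np.sign(es)] if es != 0 else np.array([])
    n_same = int(same.size)
    if es == 0 or n_same == 0:
        nes = np.nan
        p_perm = 1.0
        degenerate = True
    else:
        nes = float(es / np.mean(np.abs(same)))
        p_perm = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + n_same)
        degenerate = False
    le = leading_edge(ranked, gene_set, es, peak) if es != 0 else []
    return GseaRecord(
        set_name=set_name, es=float(es), nes=nes, p_perm=float(p_perm),
        leading_edge=le, peak_index=peak, n_same_sign=n_same, degenerate=degenerate,
    )


def leading_edge(ranked: RankedList, gene_set, es: float, peak_index: int) -> list[str]:
    """In-set genes up to the peak (ES > 0) or from the peak on (ES < 0).

    Positions are 1-based ranks.  A zero ES is degenerate and yields an
    empty leading edge with a warning.
    """
    if es == 0:
        warnings.warn("zero enrichment score: empty leading edge", stacklevel=2)
        return []
    members = set(gene_set)
    out = []
    for i, g in enumerate(ranked.genes, start=1):
        if g not in members:
            continue
        if (es > 0 and i <= peak_index) or (es < 0 and i >= peak_index):
            out.append(g)
    return out


def select_hub_genes(
    leading_edges: list[list[str]],
    deg_tables: list[pd.DataFrame],
    lfc_cutoff: float = -1.5,
    rule: str = "mean",
) -> list[str]:
    """Intersect leading edges, then apply the logFC hub cutoff.

    ``rule="mean"`` (default) requires the mean logFC across the discovery
    tables to fall below the cutoff — the combined-evidence reading, which
    does not let one cohort's sampling noise veto a gene; ``rule="all"``
    requires every individual table to clear it.  Returns the hub panel
    sorted by mean logFC ascending (most down first).  Raises KeyError if a
    candidate gene is absent from any DEG table.
    """
    if len(leading_edges) < 2:
        raise ValueError("need leading edges from at least two datasets")
    if rule not in ("mean", "all"):
        raise ValueError(f"unknown rule {rule!r}")
    common = set(leading_edges[0])
    for le in leading_edges[1:]:
        common &= set(le)
    hubs = []
    for g in sorted(common):
        lfcs = []
        for tab in deg_tables:
            if g not in tab.index:
                raise KeyError(f"gene {g!r} missing from a DEG table")
            lfcs.append(float(tab.loc[g, "logFC"]))
        passed = (
            float(np.mean(lfcs)) < lfc_cutoff
            if rule == "mean"
            else all(x < lfc_cutoff for x in lfcs)
        )
        if passed:
            hubs.append((float(np.mean(lfcs)), g))
    hubs.sort()
    result = [g for _, g in hubs]
    logger.info("hub selection: %d/%d candidates below logFC %g", len(result), len(common), lfc_cutoff)
    return result


def run_gsea(
    ranked: RankedList, gene_sets: dict[str, list[str]], config: GseaConfig | None = None
) -> pd.DataFrame:
    """Run permutation GSEA for every set; skips sets with no overlap."""
    config = config or GseaConfig()
    rows = []
    for i, (name, members) in enumerate(gene_sets.items()):
        try:
            # distinct child seed per set, derived deterministically
            cfg = GseaConfig(config.weight_exponent, config.n_permutations,
                             (config.seed * 100003 + i) % (2**31))
            rec = permutation_nes(ranked, members, cfg, set_name=name)
        except ValueError as exc:
            logger.warning("skipping gene set %s: %s", name, exc)
            continue
        rows.append(rec)
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in rows],
            "ES": [r.es for r in rows],
            "NES": [r.nes for r in rows],
            "p_perm": [r.p_perm for r in rows],
            "leading_edge": [r.leading_edge for r in rows],
            "degenerate": [r.degenerate for r in rows],
        }
    ).set_index("set_name")
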