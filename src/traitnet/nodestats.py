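"""Node centralities, permutation nulls, and Pearson edge validation.

Betweenness follows Freeman's definition with fractional counting: node v
scores sum_{s<t, v not in {s,t}} sigma_st(v) / sigma_st over unordered
pairs, unnormalized, so values like 185.25 arise on a 50-node graph.
Significance comes from a permutation null that independently permutes
every feature's BLUP profile across lines — destroying all inter-feature
association while preserving each marginal — rebuilds the network under the
same fixed cutoffs, and records each original node's degree and
betweenness. Edges are additionally validated with the Pearson correlation
of the two profiles and its square (shared variance), binned as in
descriptive reporting of linear dependency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import BlupMatrix

logger = logging.getLogger(__name__)

ABS_R_BINS = ("<=0.4", "0.4-0.6", ">0.6")
SHARED_VAR_BINS = ("<=20%", "20-40%", ">40%")


def betweenness(G: nx.Graph) -> pd.Series:
    """Unnormalized Freeman betweenness (unordered pairs, fractional)."""
    bc = nx.betweenness_centrality(G, normalized=False)
    return pd.Series(bc, name="betweenness").sort_index()


def node_statistics(G: nx.Graph) -> pd.DataFrame:
    """Per-node degree and betweenness, sorted by node id."""
    deg = pd.Series(dict(G.degree), name="degree").sort_index()
    return pd.DataFrame({"degree": deg, "betweenness": betweenness(G)})


# ---------------------------------------------------------------------------
# fast Spearman adjacency used by the permutation loop


def _column_ranks(m: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, m)


def _spearman_from_ranks(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """rho = Pearson correlation of average ranks; p via the t approximation."""
    n = ranks.shape[0]
    rho = np.corrcoef(ranks, rowvar=False)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t)] = 0.0  # |rho| == 1
    np.fill_diagonal(p, 1.0)
    return rho, p


def _adjacency(rho: np.ndarray, p: np.ndarray, r_cutoff: float,
               p_cutoff: float) -> np.ndarray:
    A = (np.abs(rho) >= r_cutoff) & (p <= p_cutoff)
    np.fill_diagonal(A, False)
    return A


def _graph_stats(A: np.ndarray, need_betweenness: bool) -> tuple[np.ndarray, np.ndarray]:
    degree = A.sum(axis=0).astype(float)
    if not need_betweenness:
        return degree, np.zeros_like(degree)
    ii, jj = np.nonzero(np.triu(A, k=1))
    g = ig.Graph(n=A.shape[0], edges=list(zip(ii.tolist(), jj.tolist())),
                 directed=False)
    bt = np.asarray(g.betweenness(directed=False), dtype=float)
    return degree, bt


@dataclass
class PermutationResult:
    """Observed degree/betweenness with permutation p-values per node."""

    table: pd.DataFrame  # index feature; degree, betweenness, p_degree, p_betweenness
    n_iter: int
    mode: str


def permutation_test(
    blups: BlupMatrix,
    r_cutoff: float,
    p_cutoff: float,
    n_iter: int = 10_000,
    seed: int = 0,
    mode: str = "profiles",
    statistics: tuple = ("degree", "betweenness"),
    tie_randomized: bool = False,
) -> PermutationResult:
    """Permutation p-values for node degree and betweenness.

    ``mode="profiles"`` (default) permutes every feature's BLUP values
    across lines independently each iteration and rebuilds the network with
    the same fixed cutoffs — the null of no inter-feature association.
    ``mode="rewire"`` instead applies degree-preserving edge rewiring to
    the observed graph (a structural null; degrees are preserved, so only
    betweenness p-values are informative there).

    p = (1 + #{permuted >= observed}) / (1 + n_iter), so the smallest
    attainable p is 1/(1 + n_iter) and an observed statistic of 0 gives
    p = 1. With ``tie_randomized=True`` ties between permuted and observed
    statistics are broken uniformly at random, which makes the p-value
    exactly uniform under the null (useful for calibration diagnostics)
    at the cost of reproducible conservatism.
    """
    if n_iter < 100:
        raise ValueError("n_iter < 100 gives unstable p-values")
    if mode not in ("profiles", "rewire"):
        raise ValueError("mode must be 'profiles' or 'rewire'")
    need_bt = "betweenness" in statistics
    rng = np.random.default_rng(seed)
    feats = list(blups.values.columns)
    m = blups.values.to_numpy(dtype=float)
    n_lines, n_feat = m.shape

    ranks = _column_ranks(m)
    rho, p = _spearman_from_ranks(ranks)
    A_obs = _adjacency(rho, p, r_cutoff, p_cutoff)
    deg_obs, bt_obs = _graph_stats(A_obs, need_bt)

    ge_deg = np.zeros(n_feat)
    gt_deg = np.zeros(n_feat)
    ge_bt = np.zeros(n_feat)
    gt_bt = np.zeros(n_feat)

    if mode == "profiles":
        for _ in range(n_iter):
            # independent permutation of every feature's rank vector
            idx = np.argsort(rng.random((n_lines, n_feat)), axis=0)
            work = np.take_along_axis(ranks, idx, axis=0)
            rho_p, p_p = _spearman_from_ranks(work)
            A = _adjacency(rho_p, p_p, r_cutoff, p_cutoff)
            deg, bt = _graph_stats(A, need_bt)
            ge_deg += deg >= deg_obs
            gt_deg += deg > deg_obs
            ge_bt += bt >= bt_obs
            gt_bt += bt > bt_obs
    else:
        import random as _random

        _random.seed(int(seed))
        base, _ = _graph_stats(A_obs, need_betweenness=False)
        ii, jj = np.nonzero(np.triu(A_obs, k=1))
        for _ in range(n_iter):
            g = ig.Graph(
                n=n_feat, edges=list(zip(ii.tolist(), jj.tolist())), directed=False
            )
            g.rewire(n=10 * g.ecount())
            bt = np.asarray(g.betweenness(directed=False), dtype=float)
            deg = np.asarray(g.degree(), dtype=float)
            ge_deg += deg >= deg_obs
            gt_deg += deg > deg_obs
            ge_bt += bt >= bt_obs
            gt_bt += bt > bt_obs

    def pvals(ge: np.ndarray, gt: np.ndarray) -> np.ndarray:
        if tie_randomized:
            u = rng.random(n_feat)
            return (gt + u * (1.0 + ge - gt)) / (1.0 + n_iter)
        return (1.0 + ge) / (1.0 + n_iter)

    table = pd.DataFrame(
        {
            "degree": deg_obs,
            "betweenness": bt_obs if need_bt else np.nan,
            "p_degree": pvals(ge_deg, gt_deg),
            "p_betweenness": pvals(ge_bt, gt_bt) if need_bt else np.nan,
        },
        index=pd.Index(feats, name="feature_id"),
    )
    return PermutationResult(table, n_iter=n_iter, mode=mode)


# ---------------------------------------------------------------------------
# Pearson edge validation


def _abs_r_bin(r: float) -> str:
    a = abs(r)
    if a <= 0.4:
        return ABS_R_BINS[0]
    if a <= 0.6:
        return ABS_R_BINS[1]
    return ABS_R_BINS[2]


def _shared_var_bin(r2_percent: float) -> str:
    if r2_percent <= 20:
        return SHARED_VAR_BINS[0]
    if r2_percent <= 40:
        return SHARED_VAR_BINS[1]
    return SHARED_VAR_BINS[2]


@dataclass
class EdgeValidation:
    """Pearson linear-dependency and shared-variance classification of edges."""

    table: pd.DataFrame  # feature_a, feature_b, pearson_r, shared_variance_pct, bins
    abs_r_counts: pd.Series
    shared_variance_counts: pd.Series


def edge_validation(blups: BlupMatrix, G: nx.Graph) -> EdgeValidation:
    """Pearson r and shared variance (r^2) for every network edge.

    Bins: |r| <= 0.4 / (0.4, 0.6] / > 0.6 and r^2 <= 20% / (20, 40]% /
    > 40%. An edge with a constant endpoint gets a missing r and is flagged
    rather than binned. Bin counts always sum to the number of binnable
    edges.
    """
    missing = [n for n in G.nodes if n not in blups.values.columns]
    if missing:
        raise ValueError(f"network nodes absent from BLUP matrix: {missing}")
    rows = []
    for a, b in sorted(map(lambda e: tuple(sorted(e)), G.edges)):
        x = blups.values[a].to_numpy()
        y = blups.values[b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((a, b, np.nan, np.nan, None, None, True))
            continue
        r = float(stats.pearsonr(x, y).statistic)
        r2 = 100.0 * r * r
        rows.append((a, b, r, r2, _abs_r_bin(r), _shared_var_bin(r2), False))
    table = pd.DataFrame(
        rows,
        columns=[
            "feature_a", "feature_b", "pearson_r", "shared_variance_pct",
            "abs_r_bin", "shared_variance_bin", "degenerate",
        ],
    )
    abs_counts = (
        table["abs_r_bin"].value_counts().reindex(ABS_R_BINS, fill_value=0)
    )
    sv_counts = (
        table["shared_variance_bin"]
        .value_counts()
        .reindex(SHARED_VAR_BINS, fill_value=0)
    )
    return EdgeValidation(table, abs_counts, sv_counts)
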