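"""Spearman correlation structure and threshold-calibrated trait networks.

Edges connect features whose line-level BLUP profiles are rank-correlated:
a pair enters the network when |rho| >= r_cutoff and p <= p_cutoff. The
p-cutoff is the largest p-value still called significant by the
Benjamini-Hochberg step-up at the target FDR q; the r-cutoff is the
smallest candidate at which four global network properties (average degree,
mean local clustering, density, diameter) are stable across a grid of
p-value thresholds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BlupMatrix

logger = logging.getLogger(__name__)

DEFAULT_P_GRID = (0.01, 0.02, 0.03, 0.04, 0.05)
DEFAULT_R_CANDIDATES = tuple(np.round(np.arange(0.10, 0.601, 0.05), 2))


@dataclass
class CorrelationResult:
    """Symmetric Spearman rho / p / BH-q matrices over feature pairs."""

    features: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n_samples: int
    dropped: list[str] = field(default_factory=list)

    def pair_table(self) -> pd.DataFrame:
        """Tidy upper-triangle listing (feature_a, feature_b, rho, p, q)."""
        rows = []
        feats = self.features
        for i, a in enumerate(feats):
            for b in feats[i + 1:]:
                rows.append(
                    (a, b, self.rho.loc[a, b], self.p.loc[a, b], self.q.loc[a, b])
                )
        return pd.DataFrame(rows, columns=["feature_a", "feature_b", "rho", "p", "q"])


def spearman_all_pairs(blups: BlupMatrix) -> CorrelationResult:
    """All-pairs Spearman rank correlation over line-level BLUP profiles.

    Uses average ranks for ties and the two-sided t approximation with
    n - 2 degrees of freedom for p-values. Zero-variance features are
    excluded with a warning; fewer than 5 lines is an error. q-values are
    Benjamini-Hochberg over the upper-triangle p-values (diagonal excluded).
    """
    m = blups.values
    n = len(m)
    if n < 5:
        raise ValueError(f"need >= 5 lines for rank correlation, got {n}")
    variances = m.var(axis=0)
    constant = list(m.columns[variances == 0])
    if constant:
        warnings.warn(
            f"excluding {len(constant)} zero-variance features: {constant}",
            RuntimeWarning,
        )
        m = m.drop(columns=constant)
    feats = list(m.columns)
    if len(feats) < 2:
        raise ValueError("need >= 2 non-constant features")
    res = stats.spearmanr(m.to_numpy())
    if np.ndim(res.statistic) == 0:  # scipy collapses the 2-feature case
        r, pv = float(res.statistic), float(res.pvalue)
        rho = np.array([[1.0, r], [r, 1.0]])
        p = np.array([[np.nan, pv], [pv, np.nan]])
    else:
        rho = np.atleast_2d(np.asarray(res.statistic))
        p = np.atleast_2d(np.asarray(res.pvalue))
    np.fill_diagonal(rho, 1.0)
    iu = np.triu_indices(len(feats), k=1)
    q_flat = multipletests(p[iu], method="fdr_bh")[1]
    q = np.full_like(p, np.nan)
    q[iu] = q_flat
    q.T[iu] = q_flat
    p = p.copy()
    np.fill_diagonal(p, np.nan)
    mk = lambda a: pd.DataFrame(a, index=feats, columns=feats)
    return CorrelationResult(feats, mk(rho), mk(p), mk(q), n_samples=n,
                             dropped=constant)


def bh_threshold(p_values, q_target: float = 0.05) -> float:
    """Benjamini-Hochberg step-up p-value cutoff at FDR level ``q_target``.

    Returns the largest sorted p_(i) with p_(i) <= (i/m) * q_target, or 0.0
    if nothing passes.
    """
    p = np.asarray(list(p_values), dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q_target < 1:
        raise ValueError("q_target must be in (0, 1)")
    p.sort()
    m = p.size
    crit = (np.arange(1, m + 1) / m) * q_target
    passing = np.nonzero(p <= crit)[0]
    return float(p[passing[-1]]) if passing.size else 0.0


def build_network(
    corr: CorrelationResult,
    r_cutoff: float,
    p_cutoff: float,
    annotations: pd.DataFrame | None = None,
) -> nx.Graph:
    """Build the trait network: edge iff |rho| >= r_cutoff and p <= p_cutoff.

    Absolute rho is thresholded so that negative correlations are kept as
    signed edges. Features without any retained edge are dropped from the
    node set. Edge attributes: rho, p, q, sign ('+' / '-').
    """
    if not (0 < r_cutoff < 1 and 0 < p_cutoff < 1):
        raise ValueError("cutoffs must lie in (0, 1)")
    G = nx.Graph(r_cutoff=float(r_cutoff), p_cutoff=float(p_cutoff))
    feats = corr.features
    rho = corr.rho.to_numpy()
    p = corr.p.to_numpy()
    q = corr.q.to_numpy()
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            if abs(rho[i, j]) >= r_cutoff and p[i, j] <= p_cutoff:
                G.add_edge(
                    feats[i],
                    feats[j],
                    rho=float(rho[i, j]),
                    p=float(p[i, j]),
                    q=float(q[i, j]),
                    sign="+" if rho[i, j] >= 0 else "-",
                )
    if annotations is not None:
        for node in G.nodes:
            if node in annotations.index:
                G.nodes[node]["molecular_class"] = str(
                    annotations.loc[node, "molecular_class"]
                )
                G.nodes[node]["compound_class"] = str(
                    annotations.loc[node, "compound_class"]
                )
    return G


@dataclass
class NetworkProperties:
    """The four global properties used for threshold calibration."""

    n_nodes: int
    n_edges: int
    average_degree: float | None
    clustering_coefficient: float | None
    density: float | None
    diameter: int | None
    n_components: int

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "average_degree": self.average_degree,
            "clustering_coefficient": self.clustering_coefficient,
            "density": self.density,
            "diameter": self.diameter,
            "n_components": self.n_components,
        }


def network_properties(
    G: nx.Graph, clustering: str = "average_local"
) -> NetworkProperties:
    """Average degree, clustering, density, and largest-component diameter.

    Average degree is 2E/N; density 2E/(N(N-1)); clustering is the mean
    local (Watts-Strogatz) coefficient by default (nodes of degree < 2
    contribute 0), or the global transitivity with ``clustering="global"``.
    The diameter is taken on the largest connected component.
    """
    n, e = G.number_of_nodes(), G.number_of_edges()
    if n == 0:
        return NetworkProperties(0, 0, None, None, None, None, 0)
    comps = list(nx.connected_components(G))
    largest = max(comps, key=lambda c: (len(c), sorted(c)))
    diameter = nx.diameter(G.subgraph(largest)) if len(largest) > 1 else 0
    if clustering == "global":
        cc = nx.transitivity(G)
    else:
        cc = nx.average_clustering(G)
    return NetworkProperties(
        n_nodes=n,
        n_edges=e,
        average_degree=2 * e / n,
        clustering_coefficient=cc,
        density=nx.density(G),
        diameter=diameter,
        n_components=len(comps),
    )


@dataclass
class ThresholdCalibration:
    """Stability scan over candidate r-cutoffs across a p-value grid."""

    p_cutoff: float
    r_cutoff: float
    scan: pd.DataFrame  # one row per (candidate_r, p); the four properties
    verdicts: pd.Series  # candidate_r -> stable?


def _relative_range(values: list[float]) -> float:
    vals = np.asarray(values, dtype=float)
    if np.isnan(vals).any():
        return np.inf
    span = vals.max() - vals.min()
    center = abs(vals.mean())
    if center == 0:
        return 0.0 if span == 0 else np.inf
    return span / center


def select_r_cutoff(
    corr: CorrelationResult,
    p_grid=DEFAULT_P_GRID,
    candidates=DEFAULT_R_CANDIDATES,
    tolerance: float = 0.01,
    diameter_tolerance: int = 0,
    q_target: float = 0.05,
) -> ThresholdCalibration:
    """Choose the correlation cutoff by network-property stability.

    For each candidate r, networks are built at every p in ``p_grid`` and
    the four properties computed. A candidate is stable when the relative
    range of average degree, clustering and density across the grid is
    <= ``tolerance`` and the diameter's absolute range is
    <= ``diameter_tolerance``. The smallest stable candidate becomes the
    r-cutoff; the BH step-up on the upper-triangle p-values sets the
    p-cutoff. Raises ValueError if no candidate is stable.
    """
    p_grid = sorted(p_grid)
    if len(p_grid) < 3:
        raise ValueError("p_grid needs at least 3 points")
    candidates = sorted(candidates)
    iu = np.triu_indices(len(corr.features), k=1)
    p_cutoff = bh_threshold(corr.p.to_numpy()[iu], q_target=q_target)

    rows = []
    verdicts = {}
    for r in candidates:
        props_per_p = []
        for p_val in p_grid:
            G = build_network(corr, r, p_val)
            props = network_properties(G)
            props_per_p.append(props)
            rows.append({"candidate_r": r, "p": p_val, **props.as_dict()})
        stable = all(
            _relative_range([getattr(pr, name) for pr in props_per_p]) <= tolerance
            for name in ("average_degree", "clustering_coefficient", "density")
        )
        diams = [pr.diameter for pr in props_per_p]
        if any(d is None for d in diams):
            stable = False
        else:
            stable = stable and (max(diams) - min(diams)) <= diameter_tolerance
        verdicts[r] = stable
    verdicts = pd.Series(verdicts, name="stable")
    stable_rs = verdicts.index[verdicts]
    if len(stable_rs) == 0:
        raise ValueError(
            "no candidate correlation cutoff is stable across the p-grid; "
            "widen the candidate range or relax the tolerance"
        )
    r_cutoff = float(stable_rs[0])
    logger.info("calibrated thresholds: r >= %.2f, p <= %.6g", r_cutoff, p_cutoff)
    return ThresholdCalibration(
        p_cutoff=p_cutoff,
        r_cutoff=r_cutoff,
        scan=pd.DataFrame(rows),
        verdicts=verdicts,
    )
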