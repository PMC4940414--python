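"""Walktrap communities and the degree-based Wilcoxon significance test.

Communities are detected on the unweighted graph with the Pons-Latapy
walktrap algorithm (short random walks; dendrogram cut at maximum
modularity). Each community with more than four nodes is tested for
structural salience: every member's degree inside the isolated community
subgraph is paired with its degree in the full network after all
community-internal edges are removed, and a one-sided Wilcoxon signed-rank
test asks whether internal connectivity exceeds the residual connectivity.
Non-significant or untestable communities are merged into the adjacent
significant community sharing the most edges, and the test is repeated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: marker for communities too small to test (size <= MIN_TESTABLE_SIZE)
NOT_TESTED = None
MIN_TESTABLE_SIZE = 4  # significance requires more than four nodes

EXACT_TEST_LIMIT = 25  # informative pairs; above this, normal approximation


@dataclass
class CommunityPartition:
    """Node -> community assignment with significance and merge provenance."""

    assignment: dict  # node -> community id (int, 1-based)
    p_values: dict = field(default_factory=dict)  # cid -> float | NOT_TESTED
    merged_from: dict = field(default_factory=dict)  # cid -> sorted original cids
    unmerged: list = field(default_factory=list)  # flagged standalone cids

    @property
    def communities(self) -> dict:
        """community id -> sorted member list."""
        out: dict = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return {cid: sorted(members, key=str)
                for cid, members in sorted(out.items())}

    @property
    def sizes(self) -> dict:
        return {cid: len(m) for cid, m in self.communities.items()}

    def relabeled(self) -> "CommunityPartition":
        """Renumber community ids 1..k by decreasing size (ties: node order)."""
        comms = self.communities
        order = sorted(comms, key=lambda c: (-len(comms[c]),
                                             [str(n) for n in comms[c]]))
        mapping = {old: new + 1 for new, old in enumerate(order)}
        return CommunityPartition(
            assignment={n: mapping[c] for n, c in self.assignment.items()},
            p_values={mapping[c]: p for c, p in self.p_values.items()},
            merged_from={
                mapping[c]: origins for c, origins in self.merged_from.items()
            },
            unmerged=[mapping[c] for c in self.unmerged],
        )


def _to_igraph(G: nx.Graph) -> tuple[ig.Graph, list]:
    nodes = sorted(G.nodes, key=str)
    index = {n: i for i, n in enumerate(nodes)}
    edges = sorted((index[a], index[b]) if index[a] < index[b] else
                   (index[b], index[a]) for a, b in G.edges)
    return ig.Graph(n=len(nodes), edges=edges, directed=False), nodes


def walktrap(G: nx.Graph, steps: int = 4) -> CommunityPartition:
    """Pons-Latapy walktrap partition of the unweighted graph.

    Random-walk distances with ``steps`` steps drive the agglomeration; the
    dendrogram is cut at maximum modularity. Edge weights are deliberately
    ignored. A graph with no edges yields singleton communities. Nodes are
    indexed in sorted order so the result is deterministic.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    graph, nodes = _to_igraph(G)
    if graph.ecount() == 0:
        assignment = {n: i + 1 for i, n in enumerate(nodes)}
        return CommunityPartition(assignment)
    dendrogram = graph.community_walktrap(steps=steps)
    clustering = dendrogram.as_clustering()
    assignment = {nodes[v]: cid + 1 for v, cid in enumerate(clustering.membership)}
    part = CommunityPartition(assignment).relabeled()
    logger.info("walktrap found %d communities", len(part.communities))
    return part


@dataclass
class DegreePairs:
    """Per-member internal vs residual degree for one community.

    ``internal`` is the degree within the isolated community subgraph;
    ``residual`` the degree in the full network after deleting all
    community-internal edges. internal + residual = full degree, always.
    """

    nodes: list
    internal: np.ndarray
    residual: np.ndarray


def degree_pairs(G: nx.Graph, community) -> DegreePairs:
    """Split each member's degree into community-internal and residual."""
    members = sorted(community, key=str)
    if not members:
        raise ValueError("empty community")
    unknown = set(members) - set(G.nodes)
    if unknown:
        raise ValueError(f"community nodes absent from graph: {sorted(unknown)}")
    sub = G.subgraph(members)
    internal = np.array([sub.degree(n) for n in members], dtype=int)
    total = np.array([G.degree(n) for n in members], dtype=int)
    return DegreePairs(members, internal, total - internal)


def community_significance(pairs: DegreePairs):
    """One-sided Wilcoxon signed-rank test: internal degree > residual degree.

    Zero differences are dropped (Wilcoxon convention); with no informative
    pairs the p-value is 1 (no evidence of salient structure). The exact
    null distribution is used for up to 25 informative pairs, the normal
    approximation with continuity correction above. Communities of four or
    fewer nodes return the NOT_TESTED marker, never a p-value.
    """
    if len(pairs.nodes) <= MIN_TESTABLE_SIZE:
        return NOT_TESTED
    diffs = pairs.internal - pairs.residual
    informative = diffs[diffs != 0]
    if informative.size == 0:
        return 1.0
    method = "exact" if informative.size <= EXACT_TEST_LIMIT else "approx"
    res = stats.wilcoxon(
        pairs.internal,
        pairs.residual,
        alternative="greater",
        zero_method="wilcox",
        correction=True,
        method=method,
    )
    return float(res.pvalue)


def attach_significance(G: nx.Graph, partition: CommunityPartition) -> CommunityPartition:
    """Attach a significance p-value (or NOT_TESTED) to every community."""
    p_values = {}
    for cid, members in partition.communities.items():
        p_values[cid] = community_significance(degree_pairs(G, members))
    return CommunityPartition(
        dict(partition.assignment), p_values, dict(partition.merged_from),
        list(partition.unmerged),
    )


def _inter_edges(G: nx.Graph, members_a, members_b) -> int:
    sa, sb = set(members_a), set(members_b)
    return sum(1 for a, b in G.edges if (a in sa and b in sb) or (a in sb and b in sa))


def merge_communities(
    G: nx.Graph, partition: CommunityPartition, alpha: float = 0.05
) -> CommunityPartition:
    """Fold non-significant communities into adjacent significant ones.

    Repeatedly: test every community; each community with p > alpha or too
    small to test is merged into the significant community to which it has
    the most inter-community edges (ties broken toward the larger
    community, then the lowest id), and significance is re-tested. Stops
    when all communities are significant or nothing can be merged; a
    non-significant community with no edges to any significant community is
    left standalone and flagged. The merged community keeps the absorbing
    community's id and records its origins.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    part = attach_significance(G, partition)
    origins = {cid: sorted(part.merged_from.get(cid, [cid]))
               for cid in part.communities}
    stuck: set = set()
    while True:
        comms = part.communities
        insignificant = [
            cid for cid, p in part.p_values.items()
            if (p is NOT_TESTED or p > alpha) and cid not in stuck
        ]
        significant = [
            cid for cid, p in part.p_values.items()
            if p is not NOT_TESTED and p <= alpha
        ]
        if not insignificant:
            break
        if not significant:
            logger.warning(
                "no significant communities; partition returned unchanged"
            )
            part.unmerged = sorted(set(insignificant) | stuck)
            return part
        merged_any = False
        for cid in sorted(insignificant):
            counts = {
                t: _inter_edges(G, comms[cid], comms[t]) for t in significant
            }
            best = max(
                counts,
                key=lambda t: (counts[t], len(comms[t]), -t),
            )
            if counts[best] == 0:
                stuck.add(cid)
                continue
            logger.info(
                "merging community %s (p=%s) into %s (%d shared edges)",
                cid, part.p_values[cid], best, counts[best],
            )
            assignment = {
                n: (best if c == cid else c) for n, c in part.assignment.items()
            }
            origins[best] = sorted(set(origins[best]) | set(origins.pop(cid)))
            part = attach_significance(G, CommunityPartition(assignment))
            stuck.clear()  # merging may open a path for previously stuck ones
            merged_any = True
            break
        if not merged_any:
            break
    part.merged_from = {
        cid: origins[cid] for cid in part.communities if len(origins[cid]) > 1
    }
    part.unmerged = sorted(stuck)
    if part.unmerged:
        logger.warning("standalone non-significant communities: %s", part.unmerged)
    return part
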