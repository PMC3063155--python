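"""Knowledge-discovery applications on top of the model and the graph.

Three tools combine the knowledge graph (what is already curated) with
the topic-model association measure (what the literature suggests):

* **Association prediction** — candidate partners of a source entity are
  found through ρ-paths (indirect typed paths) in the graph; a candidate
  is *valid* when its symmetric-KL distance to the source is at or below
  a threshold (default 5). Among the paths connecting a valid pair, the
  one with the smallest accumulated sKL is reported.

* **Near-shortest association search** — all simple paths between two
  entities whose hop count is strictly below (1+β)·L_min (L_min the
  shortest hop distance, β a slack parameter), found by a distance-pruned
  depth-first search after a single shortest-distance pass from the
  target; paths are then ranked by accumulated pairwise sKL.

* **Connectivity maps** — for a disease, collect its linked genes
  (optionally expanded one step through gene-gene interactions), the
  drugs targeting them, and tabulate drug × gene sKL scores; rows and
  columns are ordered by average-linkage hierarchical clustering of the
  score matrix. Gene importance is 1/(1 + sKL(gene, disease)) and a
  drug's rank score is the summed importance of its targeted genes.

Entities missing from the model receive a sentinel pairwise score of
2 × the sKL threshold, keeping tables total while pushing unknowns to
the weak end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage

from .graph import KnowledgeGraph, _COMPOUNDISH
from .measures import symmetric_kl
from .model import PosteriorEstimates

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig", "AssociationPath", "PredictedAssociation",
    "ConnectivityMap", "predict_associations", "near_shortest_paths",
    "rank_paths", "build_connectivity_map", "cluster_map",
]


@dataclass(frozen=True)
class SearchConfig:
    """Search knobs: slack β, hop cap and the sKL validity threshold."""

    slack: float = 0.5
    max_len: int = 4
    skl_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.slack < 0:
            raise ValueError("slack must be >= 0")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")

    @property
    def sentinel(self) -> float:
        return 2.0 * self.skl_threshold


@dataclass
class AssociationPath:
    """An ordered entity sequence with relations and accumulated sKL."""

    nodes: list[str]
    relations: list[str]
    accumulated_skl: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.relations) != len(self.nodes) - 1:
            raise ValueError("need exactly one relation per hop")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("path nodes must be distinct")
        if self.hop_length < 1:
            raise ValueError("a path needs at least one hop")

    @property
    def hop_length(self) -> int:
        return len(self.nodes) - 1


@dataclass
class PredictedAssociation:
    target: str
    skl: float
    best_path: AssociationPath
    is_known_link: bool  # a direct edge already connects source and target


def _pair_skl(est: PosteriorEstimates, a: str, b: str,
              sentinel: float) -> float:
    try:
        return symmetric_kl(est.theta_row(a), est.theta_row(b))
    except KeyError:
        logger.info("no topic profile for %r/%r pair; sentinel %.3g used",
                    a, b, sentinel)
        return sentinel


def _path_from_nodes(graph: KnowledgeGraph, nodes: list[str]) -> AssociationPath:
    rels = [graph.relation(a, b) for a, b in zip(nodes, nodes[1:])]
    return AssociationPath(list(nodes), rels)


def rank_paths(paths: list[AssociationPath], est: PosteriorEstimates,
               config: SearchConfig = SearchConfig()) -> list[AssociationPath]:
    """Score paths by accumulated pairwise sKL and sort ascending.

    Ties break toward fewer hops, then lexicographic node ids. Nodes
    without a topic profile contribute the sentinel score, sinking their
    path toward the bottom.
    """
    for p in paths:
        p.accumulated_skl = sum(
            _pair_skl(est, a, b, config.sentinel)
            for a, b in zip(p.nodes, p.nodes[1:]))
    return sorted(paths, key=lambda p: (p.accumulated_skl, p.hop_length,
                                        tuple(p.nodes)))


def near_shortest_paths(graph: KnowledgeGraph, v_i: str, v_j: str,
                        config: SearchConfig = SearchConfig(),
                        est: PosteriorEstimates | None = None,
                        ) -> list[AssociationPath]:
    """All simple paths v_i → v_j with hops < (1+β)·L_min, ranked.

    Stage 1 computes shortest hop distances from every node to ``v_j``
    (unit edge weights). Stage 2 runs a depth-first enumeration from
    ``v_i``, pruning any prefix that provably cannot finish under the
    strict bound; ``config.max_len`` also caps hop count. With ``est``
    given, paths come back ranked by accumulated sKL; otherwise by
    (hops, node ids).
    """
    for n in (v_i, v_j):
        if n not in graph:
            raise KeyError(f"unknown node {n!r}")
    g = graph.g if not graph.directed else graph.g.reverse(copy=False)
    dist = nx.single_source_shortest_path_length(g, v_j)
    if v_i not in dist:
        logger.info("near_shortest_paths: %r unreachable from %r", v_j, v_i)
        return []
    l_min = dist[v_i]
    # strict (1+β)·L_min bound on hop count; the shortest paths themselves
    # are always admitted (otherwise β = 0 would return nothing)
    bound = (1.0 + config.slack) * l_min
    found: list[list[str]] = []

    def admissible(total: int) -> bool:
        return (total == l_min or total < bound) and total <= config.max_len

    def dfs(path: list[str], hops: int) -> None:
        head = path[-1]
        if head == v_j and hops >= 1:
            found.append(list(path))
            return
        for nxt in sorted(graph.g.neighbors(head)):
            if nxt in path:
                continue
            h = hops + 1
            d = dist.get(nxt)
            if d is None or not admissible(h + d):
                continue
            path.append(nxt)
            dfs(path, h)
            path.pop()

    if l_min >= 1:
        dfs([v_i], 0)
    paths = [_path_from_nodes(graph, nodes) for nodes in found]
    if est is not None:
        return rank_paths(paths, est, config)
    return sorted(paths, key=lambda p: (p.hop_length, tuple(p.nodes)))


def predict_associations(graph: KnowledgeGraph, est: PosteriorEstimates,
                         source: str, target_type: str,
                         config: SearchConfig = SearchConfig(),
                         ) -> list[PredictedAssociation]:
    """Valid extended associations from ``source`` to nodes of ``target_type``.

    Candidates are nodes of the target type reachable from the source by
    a simple ρ-path of at most ``config.max_len`` edges. A candidate is
    valid when sKL(source, candidate) ≤ the threshold (inclusive).
    For each valid candidate, every connecting path within the hop cap is
    scored by accumulated pairwise sKL and the smallest-scoring one is
    reported; direct graph edges mark the candidate as a known link.
    Output sorts ascending by the pair's sKL.
    """
    if source not in graph:
        raise KeyError(f"unknown node {source!r}")
    if not est.has_bioterm(source):
        present = [n for n in sorted(graph.g.nodes) if est.has_bioterm(n)]
        raise KeyError(
            f"source {source!r} has no topic profile; graph nodes with "
            f"profiles: {present}")
    # enumerate simple paths from source, collecting those ending on the type
    candidate_paths: dict[str, list[list[str]]] = {}

    def dfs(path: list[str], hops: int) -> None:
        head = path[-1]
        if head != source and graph.node_type(head) == target_type:
            candidate_paths.setdefault(head, []).append(list(path))
        if hops == config.max_len:
            return
        for nxt in sorted(graph.g.neighbors(head)):
            if nxt not in path:
                path.append(nxt)
                dfs(path, hops + 1)
                path.pop()

    dfs([source], 0)
    out: list[PredictedAssociation] = []
    for target, node_paths in candidate_paths.items():
        pair = symmetric_kl(est.theta_row(source), est.theta_row(target)) \
            if est.has_bioterm(target) else config.sentinel
        if pair > config.skl_threshold:
            continue
        paths = rank_paths(
            [_path_from_nodes(graph, p) for p in node_paths], est, config)
        out.append(PredictedAssociation(
            target, pair, paths[0],
            is_known_link=graph.g.has_edge(source, target)))
    return sorted(out, key=lambda r: (r.skl, r.target))


@dataclass
class ConnectivityMap:
    """Drug × gene sKL score table with clustering leaf orders."""

    disease: str
    drugs: list[str]       # row labels, rank order (strongest first)
    genes: list[str]       # column labels, rank order
    scores: np.ndarray     # (|drugs|, |genes|), smaller = stronger
    gene_importance: dict[str, float] = field(default_factory=dict)
    drug_rank_score: dict[str, float] = field(default_factory=dict)
    row_order: list[int] | None = None
    col_order: list[int] | None = None


def build_connectivity_map(graph: KnowledgeGraph, est: PosteriorEstimates,
                           disease: str, expand_ppi: bool = True,
                           config: SearchConfig = SearchConfig(),
                           ) -> ConnectivityMap:
    """Disease-specific drug-gene connectivity map (see module docstring).

    Steps: disease-linked genes → optional one-step gene-gene expansion →
    genes ranked by importance 1/(1+sKL(gene, disease)) → drugs targeting
    at least one selected gene, ranked by summed importance of their
    targets → sKL score table.
    """
    if disease not in graph:
        raise KeyError(f"unknown node {disease!r}")
    if graph.node_type(disease) != "disease":
        raise ValueError(f"{disease!r} is not a disease node")
    genes = {n for n in graph.neighbors(disease, "gene-disease")}
    if expand_ppi:
        for gset in [graph.neighbors(g, "gene-gene") for g in sorted(genes)]:
            genes |= gset
    if not genes:
        raise ValueError(f"disease {disease!r} has no linked genes; "
                         "cannot build a connectivity map")
    importance = {g: 1.0 / (1.0 + _pair_skl(est, g, disease, config.sentinel))
                  for g in genes}
    gene_order = sorted(genes, key=lambda g: (-importance[g], g))
    drug_scores: dict[str, float] = {}
    for g in gene_order:
        for nb in graph.neighbors(g):
            if graph.node_type(nb) in _COMPOUNDISH \
                    and graph.relation(g, nb) == "compound-gene":
                drug_scores[nb] = drug_scores.get(nb, 0.0) + importance[g]
    if not drug_scores:
        raise ValueError(f"no drugs target the gene set of {disease!r}")
    drug_order = sorted(drug_scores, key=lambda d: (-drug_scores[d], d))
    scores = np.array([
        [_pair_skl(est, d, g, config.sentinel) for g in gene_order]
        for d in drug_order])
    return ConnectivityMap(disease, drug_order, gene_order, scores,
                           gene_importance=importance,
                           drug_rank_score=drug_scores)


def cluster_map(cmap: ConnectivityMap) -> ConnectivityMap:
    """Attach hierarchical-clustering leaf orders to a connectivity map.

    Average-linkage agglomerative clustering on Euclidean distances
    between score rows (drugs) and between score columns (genes); the
    score values themselves are unchanged. Degenerate single-row or
    single-column maps get identity orders.
    """
    def order(mat: np.ndarray) -> list[int]:
        if mat.shape[0] < 2:
            return list(range(mat.shape[0]))
        return [int(i) for i in leaves_list(linkage(mat, method="average",
                                                    metric="euclidean"))]

    cmap.row_order = order(cmap.scores)
    cmap.col_order = order(cmap.scores.T)
    return cmap
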