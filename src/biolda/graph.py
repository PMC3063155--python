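"""Typed heterogeneous network of bio-entities (drugs, genes, diseases, ...).

A small flat-file stand-in for a semantic-web chemogenomics repository:
nodes carry one of the six bio-term types and edges one of eight relation
kinds (compound-compound, compound-gene, compound-disease,
compound-side_effect, compound-pathway, gene-gene, gene-disease,
gene-pathway). Drug nodes are distinct from compound nodes but are valid
on the compound side of any compound-* relation, since drugs are the
approved subset of compounds. Edges are undirected by default; no
self-loops.

Backed by a :class:`networkx.Graph` with ``type`` node attributes and
``relation`` edge attributes.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .corpus import TERM_TYPES

logger = logging.getLogger(__name__)

__all__ = ["KnowledgeGraph", "RELATIONS", "relation_for", "load_graph"]

#: relation -> (allowed types of endpoint a, allowed types of endpoint b)
_COMPOUNDISH = frozenset({"compound", "drug"})
RELATIONS: dict[str, tuple[frozenset, frozenset]] = {
    "compound-compound": (_COMPOUNDISH, _COMPOUNDISH),
    "compound-gene": (_COMPOUNDISH, frozenset({"gene"})),
    "compound-disease": (_COMPOUNDISH, frozenset({"disease"})),
    "compound-side_effect": (_COMPOUNDISH, frozenset({"side_effect"})),
    "compound-pathway": (_COMPOUNDISH, frozenset({"pathway"})),
    "gene-gene": (frozenset({"gene"}), frozenset({"gene"})),
    "gene-disease": (frozenset({"gene"}), frozenset({"disease"})),
    "gene-pathway": (frozenset({"gene"}), frozenset({"pathway"})),
}


class GraphFormatError(ValueError):
    """Malformed edge-list row or type-inconsistent edge."""


def _relation_fits(relation: str, type_a: str, type_b: str) -> bool:
    allowed_a, allowed_b = RELATIONS[relation]
    return ((type_a in allowed_a and type_b in allowed_b)
            or (type_b in allowed_a and type_a in allowed_b))


def relation_for(type_a: str, type_b: str) -> str:
    """The canonical relation kind linking two node types."""
    for rel in RELATIONS:
        if _relation_fits(rel, type_a, type_b):
            return rel
    raise GraphFormatError(f"no relation links types {type_a!r} and {type_b!r}")


class KnowledgeGraph:
    """Typed node/edge store with relation-consistency validation."""

    def __init__(self, directed: bool = False):
        self.g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
        self.directed = directed

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.g

    def node_type(self, node_id: str) -> str:
        try:
            return self.g.nodes[node_id]["type"]
        except KeyError:
            raise KeyError(f"unknown node {node_id!r}") from None

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, t in self.g.nodes(data="type") if t == node_type)

    def add_node(self, node_id: str, node_type: str) -> None:
        if node_type not in TERM_TYPES:
            raise GraphFormatError(f"unknown node type {node_type!r}")
        existing = self.g.nodes.get(node_id)
        if existing is not None and existing["type"] != node_type:
            raise GraphFormatError(
                f"node {node_id!r} redeclared as {node_type!r}, "
                f"was {existing['type']!r}")
        self.g.add_node(node_id, type=node_type)

    def add_edge(self, a: str, b: str, relation: str) -> None:
        if a == b:
            raise GraphFormatError(f"self-loop on {a!r} rejected")
        if relation not in RELATIONS:
            raise GraphFormatError(f"unknown relation {relation!r}")
        ta, tb = self.node_type(a), self.node_type(b)
        if not _relation_fits(relation, ta, tb):
            raise GraphFormatError(
                f"relation {relation!r} cannot link {ta!r} node {a!r} "
                f"to {tb!r} node {b!r}")
        self.g.add_edge(a, b, relation=relation)

    def relation(self, a: str, b: str) -> str:
        return self.g.edges[a, b]["relation"]

    # ------------------------------------------------------------------
    def neighbors(self, node_id: str,
                  relation_filter: str | None = None) -> set[str]:
        """Adjacent node ids, optionally restricted to one relation kind."""
        if node_id not in self.g:
            raise KeyError(f"unknown node {node_id!r}")
        if relation_filter is None:
            return set(self.g.neighbors(node_id))
        return {v for v in self.g.neighbors(node_id)
                if self.g.edges[node_id, v]["relation"] == relation_filter}

    def rho_paths(self, source: str, target: str,
                  pattern: Sequence[str], max_len: int = 3) -> list[list[str]]:
        """Simple paths whose node-type sequence matches ``pattern``.

        ``pattern`` is an ordered list of node types beginning with the
        source's type and ending with the target's; the path's edge count
        is ``len(pattern) - 1`` and must not exceed ``max_len``. No node
        repeats along a path.
        """
        for n in (source, target):
            if n not in self.g:
                raise KeyError(f"unknown node {n!r}")
        if len(pattern) < 2:
            raise ValueError("pattern needs at least two node types")
        if self.node_type(source) != pattern[0]:
            raise ValueError(
                f"pattern starts with {pattern[0]!r} but source {source!r} "
                f"is a {self.node_type(source)!r}")
        if self.node_type(target) != pattern[-1]:
            raise ValueError(
                f"pattern ends with {pattern[-1]!r} but target {target!r} "
                f"is a {self.node_type(target)!r}")
        if len(pattern) - 1 > max_len:
            return []
        out: list[list[str]] = []

        def dfs(path: list[str]) -> None:
            depth = len(path)
            if depth == len(pattern):
                if path[-1] == target:
                    out.append(list(path))
                return
            want = pattern[depth]
            for nxt in sorted(self.g.neighbors(path[-1])):
                if nxt in path:
                    continue
                if self.g.nodes[nxt]["type"] != want:
                    continue
                if depth == len(pattern) - 1 and nxt != target:
                    continue
                path.append(nxt)
                dfs(path)
                path.pop()

        dfs([source])
        return out

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            rows = []
            for u, v, rel in self.g.edges(data="relation"):
                a, b = (u, v) if self.directed else sorted((u, v))
                rows.append((a, self.node_type(a), rel, b, self.node_type(b)))
            for row in sorted(rows):
                fh.write("\t".join(row) + "\n")

    @classmethod
    def load(cls, path: str | Path, directed: bool = False) -> "KnowledgeGraph":
        """Read a 5-column TSV edge list: id_a, type_a, relation, id_b, type_b.

        Duplicate edges collapse; type or relation inconsistencies raise
        :class:`GraphFormatError` naming the line.
        """
        kg = cls(directed=directed)
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 5:
                    raise GraphFormatError(
                        f"{path}: line {lineno}: expected 5 columns, got {len(cols)}")
                a, ta, rel, b, tb = (c.strip() for c in cols)
                try:
                    kg.add_node(a, ta)
                    kg.add_node(b, tb)
                    kg.add_edge(a, b, rel)
                except GraphFormatError as exc:
                    raise GraphFormatError(
                        f"{path}: line {lineno}: {exc}") from None
        return kg

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, str, str, str]],
                   directed: bool = False) -> "KnowledgeGraph":
        """Build from (id_a, type_a, relation, id_b, type_b) tuples."""
        kg = cls(directed=directed)
        for a, ta, rel, b, tb in edges:
            kg.add_node(a, ta)
            kg.add_node(b, tb)
            kg.add_edge(a, b, rel)
        return kg


def load_graph(path: str | Path, directed: bool = False) -> KnowledgeGraph:
    """Module-level alias for :meth:`KnowledgeGraph.load`."""
    return KnowledgeGraph.load(path, directed=directed)
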