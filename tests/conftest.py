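"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: counts
are rebuilt token by token, conditionals are evaluated directly from the
smoothed-count product, and path enumeration walks every simple path.
"""

import numpy as np
import pytest

from biolda.corpus import Corpus, Document
from biolda.graph import KnowledgeGraph


# ----------------------------------------------------------------------
# oracles
# ----------------------------------------------------------------------

def recount(state):
    """Rebuild all count matrices from (z, x) assignments from scratch."""
    B, V, J, T = state.shape
    n_bt = np.zeros((B, T), dtype=np.int64)
    n_wt = np.zeros((V, T), dtype=np.int64)
    n_jt = np.zeros((J, T), dtype=np.int64)
    n_t = np.zeros(T, dtype=np.int64)
    n_b = np.zeros(B, dtype=np.int64)
    for i in range(state.n_tokens):
        z, x, w = int(state.z[i]), int(state.x[i]), int(state.w[i])
        j = int(state.j_doc[state.tok_doc[i]])
        n_bt[x, z] += 1
        n_wt[w, z] += 1
        n_jt[j, z] += 1
        n_t[z] += 1
        n_b[x] += 1
    return n_bt, n_wt, n_jt, n_t, n_b


def brute_force_conditional(state, i):
    """Direct evaluation of the joint conditional for token i.

    Recomputes counts from assignments with token i withheld, then
    evaluates the smoothed product over every (b in b_d, t) outcome and
    normalizes. Never touches the package's count arrays.
    """
    B, V, J, T = state.shape
    cfg = state.config
    alpha = cfg.resolved_alpha
    d = int(state.tok_doc[i])
    wi, ji = int(state.w[i]), int(state.j_doc[d])
    n_bt = np.zeros((B, T))
    n_wt = np.zeros((V, T))
    n_jt = np.zeros((J, T))
    n_t = np.zeros(T)
    n_b = np.zeros(B)
    for k in range(state.n_tokens):
        if k == i:
            continue
        z, x, w = int(state.z[k]), int(state.x[k]), int(state.w[k])
        j = int(state.j_doc[state.tok_doc[k]])
        n_bt[x, z] += 1
        n_wt[w, z] += 1
        n_jt[j, z] += 1
        n_t[z] += 1
        n_b[x] += 1
    bd = state.doc_bioterms(d)
    tab = np.zeros((len(bd), T))
    for r, b in enumerate(bd):
        for t in range(T):
            p = (n_bt[b, t] + alpha) / (n_b[b] + T * alpha)
            p *= (n_wt[wi, t] + cfg.beta) / (n_t[t] + V * cfg.beta)
            if cfg.journal_component_enabled:
                p *= (n_jt[ji, t] + cfg.mu) / (n_t[t] + J * cfg.mu)
            tab[r, t] = p
    return tab / tab.sum()


def all_simple_paths(graph: KnowledgeGraph, src: str, dst: str, max_hops: int):
    """Every simple path src -> dst with at most max_hops edges."""
    out = []

    def walk(path):
        if path[-1] == dst and len(path) > 1:
            out.append(list(path))
            return
        if len(path) - 1 == max_hops:
            return
        for nxt in sorted(graph.g.neighbors(path[-1])):
            if nxt not in path:
                path.append(nxt)
                walk(path)
                path.pop()

    walk([src])
    return out


def random_typed_graph(rng, max_nodes=12, edge_p=0.3) -> KnowledgeGraph:
    """Random small typed graph with relation-consistent edges."""
    from biolda.graph import relation_for, GraphFormatError
    types = ["drug", "gene", "disease", "compound", "pathway"]
    n = int(rng.integers(4, max_nodes + 1))
    kg = KnowledgeGraph()
    names = []
    for k in range(n):
        t = types[int(rng.integers(0, len(types)))]
        name = f"n{k}_{t}"
        kg.add_node(name, t)
        names.append(name)
    for a in range(n):
        for b in range(a + 1, n):
            try:
                rel = relation_for(kg.node_type(names[a]), kg.node_type(names[b]))
            except GraphFormatError:
                continue
            if rng.random() < edge_p:
                kg.add_edge(names[a], names[b], rel)
    return kg


# ----------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------

@pytest.fixture
def tiny_corpus() -> Corpus:
    """Hand-built 2-document corpus with 6 tokens total."""
    docs = [
        Document("d0", 0, np.array([0, 1, 2, 0], dtype=np.int32),
                 np.array([0, 1], dtype=np.int32)),
        Document("d1", 1, np.array([2, 3], dtype=np.int32),
                 np.array([1, 2], dtype=np.int32)),
    ]
    c = Corpus(docs, vocabulary=["w0", "w1", "w2", "w3"],
               bioterms=[("B0", "drug"), ("B1", "gene"), ("B2", "disease")],
               journals=["J0", "J1"])
    c.validate()
    return c


@pytest.fixture
def toy_graph() -> KnowledgeGraph:
    """Planted gene-disease-drug paths around a source gene."""
    edges = [
        ("G1", "gene", "gene-disease", "Dis1", "disease"),
        ("Dis1", "disease", "compound-disease", "R1", "drug"),
        ("Dis1", "disease", "compound-disease", "R2", "drug"),
        ("G1", "gene", "gene-disease", "Dis2", "disease"),
        ("Dis2", "disease", "compound-disease", "R3", "drug"),
        ("G1", "gene", "gene-gene", "G2", "gene"),
        ("G2", "gene", "compound-gene", "R4", "drug"),
        ("R5", "drug", "compound-gene", "G1", "gene"),
    ]
    return KnowledgeGraph.from_edges(edges)
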