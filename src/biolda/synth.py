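"""Synthetic corpora and graphs drawn from the model's own assumptions.

The corpus generator executes the generative process the sampler inverts:
topic tables θ, φ, ψ are drawn from symmetric Dirichlets; each document
gets a journal, a bio-term subset b_d, and tokens produced by
bio-term → topic → word draws. Ground-truth tables ride along so recovery
can be measured. Small Dirichlet concentrations give well-separated
topics (defaults: 0.1 for φ, 0.5 for θ) — the regime where recovery at
desk scale is meaningful.

The graph generator plants requested type-patterned paths into a random
typed network whose edges always respect the relation/type constraints,
so path-search code can be tested against known answers.

What these fixtures deliberately do *not* emulate: Zipfian word
frequencies, burstiness, correlated bio-term mentions, or any real
curated network's degree structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import Corpus, Document, TERM_TYPES
from .graph import KnowledgeGraph, relation_for

__all__ = ["GroundTruth", "generate_corpus", "generate_graph"]


@dataclass
class GroundTruth:
    """True parameter tables behind a generated corpus."""

    theta: np.ndarray  # (B, T)
    phi: np.ndarray    # (T, V)
    psi: np.ndarray    # (T, J)
    z: list[np.ndarray]  # per-document true topic assignments
    x: list[np.ndarray]  # per-document true bio-term assignments
    seed: int

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "theta_true.tsv", self.theta, delimiter="\t")
        np.savetxt(directory / "phi_true.tsv", self.phi, delimiter="\t")
        np.savetxt(directory / "psi_true.tsv", self.psi, delimiter="\t")


_BT_TYPES = ("drug", "gene", "disease")


def generate_corpus(n_topics: int = 3, n_bioterms: int = 6,
                    vocab_size: int = 30, n_journals: int = 3,
                    n_docs: int = 500, doc_length: int = 50,
                    bioterms_per_doc: int = 2,
                    phi_concentration: float = 0.1,
                    theta_concentration: float = 0.5,
                    psi_concentration: float = 0.5,
                    seed: int = 0) -> tuple[Corpus, GroundTruth]:
    """Sample a corpus from known θ/φ/ψ.

    Per document: journal ~ Uniform(J); b_d = uniform subset of
    ``bioterms_per_doc`` bio-terms; each token draws x ~ Uniform(b_d),
    z ~ Cat(θ_x), w ~ Cat(φ_z). Deterministic under ``seed``.
    """
    if min(n_topics, n_bioterms, vocab_size, n_journals,
           doc_length, bioterms_per_doc) < 1:
        raise ValueError("all size parameters must be >= 1")
    if bioterms_per_doc > n_bioterms:
        raise ValueError("bioterms_per_doc cannot exceed n_bioterms")
    rng = np.random.default_rng(seed)
    theta = rng.dirichlet([theta_concentration] * n_topics, size=n_bioterms)
    phi = rng.dirichlet([phi_concentration] * vocab_size, size=n_topics)
    psi = rng.dirichlet([psi_concentration] * n_journals, size=n_topics)
    vocabulary = [f"w{v}" for v in range(vocab_size)]
    bioterms = [(f"B{b}", _BT_TYPES[b % len(_BT_TYPES)])
                for b in range(n_bioterms)]
    journals = [f"J{j}" for j in range(n_journals)]
    docs: list[Document] = []
    z_true: list[np.ndarray] = []
    x_true: list[np.ndarray] = []
    for d in range(n_docs):
        journal = int(rng.integers(0, n_journals))
        bd = np.sort(rng.choice(n_bioterms, size=bioterms_per_doc,
                                replace=False)).astype(np.int32)
        x = bd[rng.integers(0, len(bd), size=doc_length)]
        z = np.array([rng.choice(n_topics, p=theta[b]) for b in x],
                     dtype=np.int32)
        w = np.array([rng.choice(vocab_size, p=phi[t]) for t in z],
                     dtype=np.int32)
        docs.append(Document(f"doc{d}", journal, w, bd))
        z_true.append(z)
        x_true.append(x.astype(np.int32))
    corpus = Corpus(docs, vocabulary, bioterms, journals)
    if n_docs:
        corpus.validate()
    return corpus, GroundTruth(theta, phi, psi, z_true, x_true, seed)


def generate_graph(n_per_type: dict[str, int] | None = None,
                   planted_paths: list[list[str]] | None = None,
                   edge_density: float = 0.05,
                   seed: int = 0) -> KnowledgeGraph:
    """Random typed graph with each requested type pattern planted once.

    ``planted_paths`` are node-type sequences (e.g.
    ``["gene", "disease", "drug"]``); each is instantiated as a chain of
    distinct nodes with the canonical relation for every consecutive type
    pair. Remaining node pairs that admit a relation gain an edge with
    probability ``edge_density``. Deterministic under ``seed``.
    """
    if n_per_type is None:
        n_per_type = {"drug": 4, "gene": 4, "disease": 3}
    for t in n_per_type:
        if t not in TERM_TYPES:
            raise ValueError(f"unknown node type {t!r}")
    rng = np.random.default_rng(seed)
    kg = KnowledgeGraph()
    pools: dict[str, list[str]] = {}
    for t, n in sorted(n_per_type.items()):
        pools[t] = [f"{t}{i}" for i in range(n)]
        for node in pools[t]:
            kg.add_node(node, t)
    for pattern in planted_paths or []:
        for t in pattern:
            if t not in pools or not pools[t]:
                raise ValueError(f"pattern {pattern} needs nodes of type {t!r}")
        # pick distinct nodes along the chain
        chain: list[str] = []
        for t in pattern:
            choices = [n for n in pools[t] if n not in chain]
            if not choices:
                raise ValueError(
                    f"not enough {t!r} nodes to plant pattern {pattern}")
            chain.append(choices[int(rng.integers(0, len(choices)))])
        for a, b in zip(chain, chain[1:]):
            kg.add_edge(a, b, relation_for(kg.node_type(a), kg.node_type(b)))
    if edge_density > 0:
        allnodes = sorted(kg.g.nodes)
        for i, a in enumerate(allnodes):
            for b in allnodes[i + 1:]:
                if kg.g.has_edge(a, b):
                    continue
                try:
                    rel = relation_for(kg.node_type(a), kg.node_type(b))
                except Exception:
                    continue
                if rng.random() < edge_density:
                    kg.add_edge(a, b, rel)
    return kg
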