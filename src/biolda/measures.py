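"""Information-theoretic association measures over bio-term topic profiles.

A bio-term's row of θ is its topic distribution. Its Shannon entropy
H(b) = −Σ_t θ[b,t]·ln θ[b,t] says whether the term is topically focused
(low H) or spread over many topics (high H). The association between two
bio-terms is the symmetric Kullback-Leibler divergence of their rows,

    sKL(p, q) = KL(p‖q) + KL(q‖p),

where *smaller means more strongly associated*. Because θ rows are
smoothed (strictly positive), sKL is always finite.

The classical literature baseline is the PMI-style co-occurrence score

    Θ(b_i, b_j) = log2[ (N·df(b_i,b_j) + λ) / (df(b_i)·df(b_j) + λ) ],

with document frequencies df, collection size N and a small constant
λ (= 1 by default) guarding zeros. Positive Θ marks over-represented
pairs, negative Θ under-represented ones; pairs never co-mentioned score
strongly negative, which is exactly the failure mode the topic-model
measure is designed to avoid.

Natural log is the default base for entropy and KL so the two stay
commensurable; pass ``base=2`` for bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .corpus import Corpus
from .model import PosteriorEstimates

__all__ = [
    "bioterm_entropy", "kl_divergence", "symmetric_kl",
    "CooccurrenceCounts", "cooccurrence_score", "cooccurrence_counts",
    "AssociationScore", "pairwise_association_table",
]

_NORM_TOL = 1e-9


def _check_distribution(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D probability vector")
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"probability vector sums to {p.sum()!r}, not 1")
    return p


def bioterm_entropy(theta_row: Sequence[float], base: float | None = None) -> float:
    """Shannon entropy of a topic distribution (0·ln 0 := 0)."""
    p = _check_distribution(theta_row)
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def kl_divergence(p: Sequence[float], q: Sequence[float],
                  base: float | None = None) -> float:
    """KL(p‖q) = Σ p ln(p/q); requires q > 0 wherever p > 0."""
    p = _check_distribution(p)
    q = _check_distribution(q)
    if p.shape != q.shape:
        raise ValueError("p and q must have equal length")
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("KL undefined: q has a zero where p is positive")
    d = float((p[mask] * np.log(p[mask] / q[mask])).sum())
    if base is not None:
        d /= np.log(base)
    return max(d, 0.0)


def symmetric_kl(p: Sequence[float], q: Sequence[float],
                 base: float | None = None) -> float:
    """sKL(p,q) = KL(p‖q) + KL(q‖p). Smaller = stronger association."""
    return kl_divergence(p, q, base) + kl_divergence(q, p, base)


@dataclass(frozen=True)
class CooccurrenceCounts:
    """Document-frequency counts for one bio-term pair."""

    df_i: int
    df_j: int
    df_ij: int
    n_docs: int
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not (0 <= self.df_ij <= min(self.df_i, self.df_j) <= self.n_docs):
            raise ValueError(
                "need df_ij <= min(df_i, df_j) <= n_docs "
                f"(got {self.df_ij}, {self.df_i}, {self.df_j}, {self.n_docs})")


def cooccurrence_score(c: CooccurrenceCounts) -> float:
    """PMI-style co-occurrence association Θ (see module docstring)."""
    return float(np.log2((c.n_docs * c.df_ij + c.lam)
                         / (c.df_i * c.df_j + c.lam)))


def cooccurrence_counts(corpus: Corpus, i: int, j: int,
                        lam: float = 1.0) -> CooccurrenceCounts:
    """Count document frequencies of bio-term ids i, j in a corpus."""
    df_i = df_j = df_ij = 0
    for d in corpus.documents:
        hi = i in d.bioterms
        hj = j in d.bioterms
        df_i += hi
        df_j += hj
        df_ij += hi and hj
    return CooccurrenceCounts(df_i, df_j, df_ij, corpus.n_docs, lam)


@dataclass(frozen=True)
class AssociationScore:
    bioterm_i: str
    bioterm_j: str
    score: float
    method: str  # "biolda" | "cooccurrence"


def pairwise_association_table(
    est: PosteriorEstimates,
    pairs: Iterable[tuple[str, str]],
    cutoff: float | None = None,
    base: float | None = None,
) -> list[AssociationScore]:
    """Symmetric-KL association for each pair of canonical bio-term ids.

    With ``cutoff`` set, pairs scoring above it are dropped (the bound is
    inclusive: a score exactly at the cutoff stays). Unknown ids raise
    ``KeyError``.
    """
    out = []
    for i, j in pairs:
        s = symmetric_kl(est.theta_row(i), est.theta_row(j), base)
        if cutoff is None or s <= cutoff:
            out.append(AssociationScore(i, j, s, "biolda"))
    return out


def all_pairs(ids: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered id pairs, in deterministic order."""
    return list(combinations(ids, 2))
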