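"""The Bio-LDA model: entity-conditioned latent Dirichlet allocation.

Each document carries a set of bio-terms ``b_d`` (drugs, genes, diseases,
...). Generatively, every token first picks a bio-term uniformly from
``b_d``, the bio-term's topic distribution θ_b emits a topic, and the
topic emits both the word (via φ_t) and the document's journal (via ψ_t).
Inference is collapsed Gibbs sampling over the per-token pair
``(x_di, z_di)``, sampled jointly; with Dirichlet concentrations α, β, µ
on θ, φ, ψ the conditional for token *i* of document *d* is

    P(x=b, z=t | rest) ∝  (n_bt + α)/(n_b + Tα)
                        · (n_wt + β)/(n_t + Vβ)
                        · (n_jt + µ)/(n_t + Jµ)      [journal factor optional]

with all counts excluding the current token. The uniform 1/|b_d| factor of
the bio-term draw is constant across outcomes and cancels. Disabling the
journal factor and giving every document its own singleton pseudo bio-term
recovers the standard collapsed LDA sampler (document-topic counts playing
the role of ``n_bt``), which serves as the plain-LDA baseline.

Point estimates after sampling are the smoothed conditionals

    θ[b,t] = (n_bt + α)/(n_b + Tα)      (topic given bio-term)
    φ[t,w] = (n_wt + β)/(n_t + Vβ)      (word given topic)
    ψ[t,j] = (n_jt + µ)/(n_t + Jµ)      (journal given topic)

whose strictly positive rows make the downstream KL-divergence association
measures finite.

The public entry point is the :class:`BioLDA` estimator
(``fit``/``transform``, sklearn conventions); ``train`` and friends are
thin functional wrappers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._sampler import sweep_kernel
from .corpus import Corpus, Document

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig", "ModelState", "PosteriorEstimates", "BioLDA",
    "init_assignments", "gibbs_conditional", "gibbs_sweep", "train",
    "estimate_parameters", "top_terms", "map_topics", "as_lda_corpus",
]


@dataclass(frozen=True)
class ModelConfig:
    """Sampler hyperparameters.

    ``alpha=None`` resolves to the common heuristic 50/T. Defaults follow
    field practice for collapsed Gibbs LDA samplers: weak word smoothing
    (β = 0.01), mild journal smoothing (µ = 0.1), 500 sweeps with the
    first 300 discarded when posterior averaging is on.
    """

    n_topics: int = 50
    alpha: float | None = None
    beta: float = 0.01
    mu: float = 0.1
    n_sweeps: int = 500
    burn_in: int = 300
    seed: int = 0
    journal_component_enabled: bool = True
    average_posterior: bool = False

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        a = self.resolved_alpha
        if a <= 0 or self.beta <= 0 or self.mu <= 0:
            raise ValueError("alpha, beta and mu must be positive")
        if not 0 <= self.burn_in < max(self.n_sweeps, 1):
            raise ValueError("burn_in must be < n_sweeps")

    @property
    def resolved_alpha(self) -> float:
        return 50.0 / self.n_topics if self.alpha is None else self.alpha


@dataclass
class ModelState:
    """Flat token arrays, per-token assignments and sufficient statistics.

    Tokens of all documents are concatenated; ``tok_doc[i]`` maps token i
    back to its document, ``bd_flat``/``bd_ptr`` hold the documents'
    bio-term vectors in CSR style. ``z``/``x`` are the per-token topic and
    bio-term assignments; the five count arrays are the collapsed
    sufficient statistics.
    """

    config: ModelConfig
    w: np.ndarray          # (N,) word id per token
    tok_doc: np.ndarray    # (N,) document index per token
    j_doc: np.ndarray      # (D,) journal id per document
    bd_flat: np.ndarray    # concatenated bio-term vectors
    bd_ptr: np.ndarray     # (D+1,) offsets into bd_flat
    z: np.ndarray          # (N,) topic assignment
    x: np.ndarray          # (N,) bio-term assignment
    n_bt: np.ndarray       # (B, T)
    n_wt: np.ndarray       # (V, T)
    n_jt: np.ndarray       # (J, T)
    n_t: np.ndarray        # (T,)
    n_b: np.ndarray        # (B,)

    @property
    def n_tokens(self) -> int:
        return int(self.w.shape[0])

    @property
    def shape(self) -> tuple[int, int, int, int]:
        """(B, V, J, T)"""
        return (self.n_bt.shape[0], self.n_wt.shape[0],
                self.n_jt.shape[0], self.n_bt.shape[1])

    def doc_bioterms(self, d: int) -> np.ndarray:
        return self.bd_flat[self.bd_ptr[d]:self.bd_ptr[d + 1]]

    def token_range(self, d: int) -> tuple[int, int]:
        lo = int(np.searchsorted(self.tok_doc, d, side="left"))
        hi = int(np.searchsorted(self.tok_doc, d, side="right"))
        return lo, hi

    def validate(self) -> None:
        N = self.n_tokens
        if int(self.n_t.sum()) != N or int(self.n_b.sum()) != N:
            raise ValueError("token count not conserved in n_t / n_b")
        if np.any(self.n_bt < 0) or np.any(self.n_wt < 0) or np.any(self.n_jt < 0):
            raise ValueError("negative counts")
        for mat in (self.n_bt, self.n_wt, self.n_jt):
            if not np.array_equal(mat.sum(axis=0), self.n_t):
                raise ValueError("count matrix column sums disagree with n_t")
        for i in range(N):
            if self.x[i] not in self.doc_bioterms(int(self.tok_doc[i])):
                raise ValueError(f"token {i}: x outside its document's b_d")

    def copy(self) -> "ModelState":
        return ModelState(
            self.config,
            self.w.copy(), self.tok_doc.copy(), self.j_doc.copy(),
            self.bd_flat.copy(), self.bd_ptr.copy(),
            self.z.copy(), self.x.copy(),
            self.n_bt.copy(), self.n_wt.copy(), self.n_jt.copy(),
            self.n_t.copy(), self.n_b.copy(),
        )


@dataclass
class PosteriorEstimates:
    """Smoothed probability tables θ (B×T), φ (T×V), ψ (T×J).

    Row semantics: ``theta[b]`` = P(topic | bio-term b); ``phi[t]`` =
    P(word | topic t); ``psi[t]`` = P(journal | topic t). Label lists tie
    rows/columns back to canonical ids when built from a corpus; ``n_b``
    (tokens attributed to each bio-term) supports prominence-weighted
    bio-term ranking in :func:`top_terms`.
    """

    theta: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    bioterm_ids: list[str] | None = None
    word_labels: list[str] | None = None
    journal_labels: list[str] | None = None
    n_b: np.ndarray | None = None
    _bt_index: dict = field(default=None, repr=False)

    @property
    def n_topics(self) -> int:
        return self.theta.shape[1]

    def theta_row(self, bioterm_id: str) -> np.ndarray:
        """θ row for a canonical bio-term id; KeyError if absent."""
        if self.bioterm_ids is None:
            raise KeyError("estimates carry no bio-term labels")
        if self._bt_index is None:
            self._bt_index = {c: i for i, c in enumerate(self.bioterm_ids)}
        return self.theta[self._bt_index[bioterm_id]]

    def has_bioterm(self, bioterm_id: str) -> bool:
        try:
            self.theta_row(bioterm_id)
            return True
        except KeyError:
            return False

    def validate(self) -> None:
        for name, tab in (("theta", self.theta), ("phi", self.phi), ("psi", self.psi)):
            if np.any(tab <= 0):
                raise ValueError(f"{name} has non-positive entries")
            if np.max(np.abs(tab.sum(axis=1) - 1.0)) > 1e-9:
                raise ValueError(f"{name} rows do not sum to 1")

    # ------------------------------------------------------------------
    def save(self, directory: str | Path, config: ModelConfig | None = None) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tcols = [f"topic_{t}" for t in range(self.n_topics)]
        bids = self.bioterm_ids or [str(i) for i in range(self.theta.shape[0])]
        wlabs = self.word_labels or [str(i) for i in range(self.phi.shape[1])]
        jlabs = self.journal_labels or [str(i) for i in range(self.psi.shape[1])]
        pd.DataFrame(self.theta, index=bids, columns=tcols).to_csv(
            directory / "theta.tsv", sep="\t")
        pd.DataFrame(self.phi, index=tcols, columns=wlabs).to_csv(
            directory / "phi.tsv", sep="\t")
        pd.DataFrame(self.psi, index=tcols, columns=jlabs).to_csv(
            directory / "psi.tsv", sep="\t")
        if self.n_b is not None:
            pd.Series(self.n_b, index=bids, name="n_b").to_csv(
                directory / "n_b.tsv", sep="\t")
        if config is not None:
            with open(directory / "config.json", "w") as fh:
                json.dump({k: getattr(config, k) for k in (
                    "n_topics", "alpha", "beta", "mu", "n_sweeps", "burn_in",
                    "seed", "journal_component_enabled", "average_posterior")},
                    fh, indent=2)

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorEstimates":
        directory = Path(directory)
        theta = pd.read_csv(directory / "theta.tsv", sep="\t", index_col=0)
        phi = pd.read_csv(directory / "phi.tsv", sep="\t", index_col=0)
        psi = pd.read_csv(directory / "psi.tsv", sep="\t", index_col=0)
        n_b = None
        if (directory / "n_b.tsv").exists():
            n_b = pd.read_csv(directory / "n_b.tsv", sep="\t", index_col=0)[
                "n_b"].to_numpy()
        return cls(
            theta.to_numpy(), phi.to_numpy(), psi.to_numpy(),
            bioterm_ids=[str(i) for i in theta.index],
            word_labels=[str(c) for c in phi.columns],
            journal_labels=[str(c) for c in psi.columns],
            n_b=n_b,
        )


# ----------------------------------------------------------------------
# state construction and the Gibbs machinery
# ----------------------------------------------------------------------

def _flatten_corpus(corpus: Corpus):
    w = np.concatenate([d.tokens for d in corpus.documents]).astype(np.int32)
    tok_doc = np.concatenate([
        np.full(len(d.tokens), i, dtype=np.int32)
        for i, d in enumerate(corpus.documents)])
    j_doc = np.array([d.journal_id for d in corpus.documents], dtype=np.int32)
    bd_flat = np.concatenate([d.bioterms for d in corpus.documents]).astype(np.int32)
    bd_ptr = np.zeros(corpus.n_docs + 1, dtype=np.int64)
    np.cumsum([len(d.bioterms) for d in corpus.documents], out=bd_ptr[1:])
    return w, tok_doc, j_doc, bd_flat, bd_ptr


def init_assignments(corpus: Corpus, config: ModelConfig,
                     rng: np.random.Generator | None = None) -> ModelState:
    """Uniform random initialization of (x, z) with consistent counts."""
    corpus.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w, tok_doc, j_doc, bd_flat, bd_ptr = _flatten_corpus(corpus)
    N = w.shape[0]
    T = config.n_topics
    B, V, J = corpus.n_bioterms, corpus.n_words, corpus.n_journals
    z = rng.integers(0, T, size=N).astype(np.int32)
    x = np.empty(N, dtype=np.int32)
    for i in range(N):
        bd = bd_flat[bd_ptr[tok_doc[i]]:bd_ptr[tok_doc[i] + 1]]
        x[i] = bd[rng.integers(0, len(bd))]
    state = ModelState(
        config, w, tok_doc, j_doc, bd_flat, bd_ptr, z, x,
        n_bt=np.zeros((B, T), dtype=np.int64),
        n_wt=np.zeros((V, T), dtype=np.int64),
        n_jt=np.zeros((J, T), dtype=np.int64),
        n_t=np.zeros(T, dtype=np.int64),
        n_b=np.zeros(B, dtype=np.int64),
    )
    np.add.at(state.n_bt, (x, z), 1)
    np.add.at(state.n_wt, (w, z), 1)
    np.add.at(state.n_jt, (j_doc[tok_doc], z), 1)
    np.add.at(state.n_t, z, 1)
    np.add.at(state.n_b, x, 1)
    return state


def _decrement(state: ModelState, i: int) -> None:
    wi, zi, xi = int(state.w[i]), int(state.z[i]), int(state.x[i])
    ji = int(state.j_doc[state.tok_doc[i]])
    state.n_bt[xi, zi] -= 1
    state.n_wt[wi, zi] -= 1
    state.n_jt[ji, zi] -= 1
    state.n_t[zi] -= 1
    state.n_b[xi] -= 1


def _increment(state: ModelState, i: int, b: int, t: int) -> None:
    wi = int(state.w[i])
    ji = int(state.j_doc[state.tok_doc[i]])
    state.x[i] = b
    state.z[i] = t
    state.n_bt[b, t] += 1
    state.n_wt[wi, t] += 1
    state.n_jt[ji, t] += 1
    state.n_t[t] += 1
    state.n_b[b] += 1


def _unnormalized_table(state: ModelState, i: int) -> np.ndarray:
    """Raw (b, t) sampling weights for token i, kernel arithmetic order."""
    cfg = state.config
    B, V, J, T = state.shape
    d = int(state.tok_doc[i])
    bd = state.doc_bioterms(d)
    wi = int(state.w[i])
    ji = int(state.j_doc[d])
    alpha = cfg.resolved_alpha
    vbeta = V * cfg.beta
    jmu = J * cfg.mu
    talpha = T * alpha
    tab = np.empty((len(bd), T))
    for k, b in enumerate(bd):
        fb = 1.0 / (state.n_b[b] + talpha)
        for t in range(T):
            p = (state.n_bt[b, t] + alpha) * fb \
                * (state.n_wt[wi, t] + cfg.beta) / (state.n_t[t] + vbeta)
            if cfg.journal_component_enabled:
                p *= (state.n_jt[ji, t] + cfg.mu) / (state.n_t[t] + jmu)
            tab[k, t] = p
    return tab


def gibbs_conditional(state: ModelState, doc_index: int,
                      token_index: int) -> np.ndarray:
    """Joint conditional P(x=b, z=t | rest) for one token.

    ``token_index`` counts within the document. The token's own assignment
    must already be removed from the counts (the "-di" convention); rows
    follow the order of the document's bio-term vector, columns are
    topics. The returned table sums to 1.
    """
    bd = state.doc_bioterms(doc_index)
    if len(bd) == 0:
        raise ValueError(f"document {doc_index} has an empty bio-term vector")
    lo, hi = state.token_range(doc_index)
    i = lo + token_index
    if not lo <= i < hi:
        raise IndexError("token_index out of range for document")
    tab = _unnormalized_table(state, i)
    return tab / tab.sum()


def gibbs_sweep(state: ModelState, rng: np.random.Generator | None = None,
                rand: np.ndarray | None = None, *,
                use_kernel: bool = True) -> ModelState:
    """One in-place sweep: every token re-sampled once, in document order.

    Randomness comes from ``rand`` (one uniform per token) or is drawn
    from ``rng``; both paths — the numba kernel and the pure-Python
    reference (``use_kernel=False``) — consume the same uniforms and
    produce identical states.
    """
    cfg = state.config
    N = state.n_tokens
    if rand is None:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        rand = rng.random(N)
    T = cfg.n_topics
    if use_kernel:
        max_bd = int(np.max(np.diff(state.bd_ptr))) if N else 1
        probs = np.empty(max_bd * T, dtype=np.float64)
        sweep_kernel(state.w, state.tok_doc, state.j_doc,
                     state.bd_flat, state.bd_ptr, state.z, state.x,
                     state.n_bt, state.n_wt, state.n_jt, state.n_t, state.n_b,
                     cfg.resolved_alpha, cfg.beta, cfg.mu,
                     cfg.journal_component_enabled, rand, probs)
        return state
    for i in range(N):
        d = int(state.tok_doc[i])
        _decrement(state, i)
        flat = _unnormalized_table(state, i).ravel()
        total = 0.0
        for m in range(flat.shape[0]):
            total += flat[m]
        u = rand[i] * total
        acc = 0.0
        sel = flat.shape[0] - 1
        for m in range(flat.shape[0]):
            acc += flat[m]
            if u < acc:
                sel = m
                break
        bd = state.doc_bioterms(d)
        _increment(state, i, int(bd[sel // T]), sel % T)
    return state


def estimate_parameters(state: ModelState) -> PosteriorEstimates:
    """Smoothed point estimates θ, φ, ψ from the current counts."""
    cfg = state.config
    B, V, J, T = state.shape
    alpha = cfg.resolved_alpha
    theta = (state.n_bt + alpha) / (state.n_b[:, None] + T * alpha)
    phi = ((state.n_wt + cfg.beta) / (state.n_t + V * cfg.beta)).T
    psi = ((state.n_jt + cfg.mu) / (state.n_t + J * cfg.mu)).T
    return PosteriorEstimates(theta, phi, psi, n_b=state.n_b.copy())


def token_log_likelihood(state: ModelState) -> float:
    """Σ_i ln P(w_i | z_i) (+ journal term if enabled): a mixing diagnostic."""
    cfg = state.config
    B, V, J, T = state.shape
    pw = (state.n_wt[state.w, state.z] + cfg.beta) / (state.n_t[state.z] + V * cfg.beta)
    ll = float(np.log(pw).sum())
    if cfg.journal_component_enabled:
        j = state.j_doc[state.tok_doc]
        pj = (state.n_jt[j, state.z] + cfg.mu) / (state.n_t[state.z] + J * cfg.mu)
        ll += float(np.log(pj).sum())
    return ll


def train(corpus: Corpus, config: ModelConfig,
          ) -> tuple[ModelState, PosteriorEstimates, list[float]]:
    """Initialize, run ``n_sweeps`` Gibbs sweeps, estimate θ/φ/ψ.

    Returns the final state, the estimates (final-sample by default, or
    averaged over post-burn-in sweeps when ``config.average_posterior``)
    and the per-sweep token log-likelihood trace.
    """
    rng = np.random.default_rng(config.seed)
    state = init_assignments(corpus, config, rng)
    loglik: list[float] = []
    acc = None
    n_avg = 0
    for sweep in range(config.n_sweeps):
        gibbs_sweep(state, rand=rng.random(state.n_tokens))
        loglik.append(token_log_likelihood(state))
        if config.average_posterior and sweep >= config.burn_in:
            est = estimate_parameters(state)
            if acc is None:
                acc = est
            else:
                acc.theta += est.theta
                acc.phi += est.phi
                acc.psi += est.psi
            n_avg += 1
    if config.average_posterior and acc is not None:
        acc.theta /= n_avg
        acc.phi /= n_avg
        acc.psi /= n_avg
        est = acc
        est.n_b = state.n_b.copy()
    else:
        est = estimate_parameters(state)
    est.bioterm_ids = [cid for cid, _t in corpus.bioterms]
    est.word_labels = list(corpus.vocabulary)
    est.journal_labels = list(corpus.journals)
    logger.info("train: %d sweeps on %d tokens, final log-likelihood %.1f",
                config.n_sweeps, state.n_tokens, loglik[-1] if loglik else 0.0)
    return state, est, loglik


# ----------------------------------------------------------------------
# summaries
# ----------------------------------------------------------------------

def _ranked(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores, ties broken by lower index."""
    order = np.argsort(-scores, kind="stable")
    return order[:k]


def top_terms(est: PosteriorEstimates, topic: int, k_words: int = 10,
              k_bioterms: int = 10, k_journals: int = 5,
              bioterm_weighting: str = "prominence") -> dict:
    """Top words, bio-terms and journals for one topic.

    Words and journals rank by their φ/ψ row. Bio-terms rank by
    P(b | t) ∝ θ[b,t]·n_b (prominence weighting) so that rare bio-terms
    with flat posteriors do not dominate; pass
    ``bioterm_weighting="raw"`` for raw θ[:, t]. Ties break toward the
    lower id; asking for more items than exist returns everything.
    """
    if not 0 <= topic < est.n_topics:
        raise IndexError(f"topic {topic} out of range")
    phi_row = est.phi[topic]
    psi_row = est.psi[topic]
    if bioterm_weighting == "prominence" and est.n_b is not None:
        bt_scores = est.theta[:, topic] * est.n_b
        tot = bt_scores.sum()
        if tot > 0:
            bt_scores = bt_scores / tot
    elif bioterm_weighting in ("raw", "prominence"):
        bt_scores = est.theta[:, topic]
    else:
        raise ValueError("bioterm_weighting must be 'prominence' or 'raw'")

    def pack(scores, labels, k):
        idx = _ranked(scores, k)
        return [((labels[i] if labels else int(i)), float(scores[i])) for i in idx]

    return {
        "words": pack(phi_row, est.word_labels, k_words),
        "bioterms": pack(bt_scores, est.bioterm_ids, k_bioterms),
        "journals": pack(psi_row, est.journal_labels, k_journals),
    }


def top_words_per_topic(est: PosteriorEstimates, k: int = 20) -> list[list]:
    """Ranked top-k word labels (or ids) for every topic."""
    out = []
    for t in range(est.n_topics):
        idx = _ranked(est.phi[t], k)
        out.append([est.word_labels[i] if est.word_labels else int(i)
                    for i in idx])
    return out


def map_topics(top_words_a: Sequence[Sequence], top_words_b: Sequence[Sequence],
               k: int = 20) -> list[tuple[int, int]]:
    """Map each topic of model A to the B topic sharing most top-k words.

    Returns, per A topic, ``(b_topic, overlap)``; ties break toward the
    lowest B index.
    """
    out = []
    sets_b = [set(wb[:k]) for wb in top_words_b]
    for wa in top_words_a:
        sa = set(wa[:k])
        best_t, best_o = 0, -1
        for tb, sb in enumerate(sets_b):
            o = len(sa & sb)
            if o > best_o:
                best_t, best_o = tb, o
        out.append((best_t, best_o))
    return out


def as_lda_corpus(corpus: Corpus) -> Corpus:
    """Rewrite a corpus so Bio-LDA reduces to plain LDA.

    Every document receives a unique singleton pseudo bio-term, making
    ``n_bt`` the document-topic count matrix; with the journal component
    disabled, the sampler is then the standard collapsed LDA sampler.
    """
    docs = [Document(d.doc_id, d.journal_id, d.tokens.copy(),
                     np.array([i], dtype=np.int32))
            for i, d in enumerate(corpus.documents)]
    pseudo = [(f"__doc_{d.doc_id}", "document") for d in corpus.documents]
    return Corpus(docs, list(corpus.vocabulary), pseudo, list(corpus.journals))


# ----------------------------------------------------------------------
# sklearn-style front end
# ----------------------------------------------------------------------

class BioLDA(BaseEstimator):
    """Entity-conditioned LDA with a collapsed Gibbs sampler.

    Parameters mirror :class:`ModelConfig`; ``fit`` expects a
    :class:`~biolda.corpus.Corpus`. Fitted attributes:

    ``theta_`` : (B, T) topic-given-bio-term table
    ``phi_`` : (T, V) word-given-topic table
    ``psi_`` : (T, J) journal-given-topic table
    ``estimates_`` : the full :class:`PosteriorEstimates`
    ``state_`` : final sampler :class:`ModelState`
    ``loglik_`` : per-sweep token log-likelihood trace

    Example
    -------
    >>> from biolda.synth import generate_corpus
    >>> corpus, truth = generate_corpus(n_topics=3, n_bioterms=6,
    ...     vocab_size=30, n_journals=3, n_docs=100, doc_length=30, seed=0)
    >>> model = BioLDA(n_topics=3, n_sweeps=50, random_state=0).fit(corpus)
    >>> model.phi_.shape
    (3, 30)
    """

    def __init__(self, n_topics: int = 50, alpha: float | None = None,
                 beta: float = 0.01, mu: float = 0.1, n_sweeps: int = 500,
                 burn_in: int = 300, journal_component: bool = True,
                 average_posterior: bool = False,
                 random_state: int | None = None):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.mu = mu
        self.n_sweeps = n_sweeps
        self.burn_in = burn_in
        self.journal_component = journal_component
        self.average_posterior = average_posterior
        self.random_state = random_state

    def _config(self) -> ModelConfig:
        return ModelConfig(
            n_topics=self.n_topics, alpha=self.alpha, beta=self.beta,
            mu=self.mu, n_sweeps=self.n_sweeps, burn_in=self.burn_in,
            seed=0 if self.random_state is None else int(self.random_state),
            journal_component_enabled=self.journal_component,
            average_posterior=self.average_posterior,
        )

    def fit(self, X: Corpus, y=None) -> "BioLDA":
        if not isinstance(X, Corpus):
            raise TypeError("BioLDA.fit expects a biolda.corpus.Corpus")
        config = self._config()
        self.state_, self.estimates_, self.loglik_ = train(X, config)
        self.theta_ = self.estimates_.theta
        self.phi_ = self.estimates_.phi
        self.psi_ = self.estimates_.psi
        self.n_iter_ = config.n_sweeps
        return self

    def transform(self, X: Corpus) -> np.ndarray:
        """Fold documents into topic space: P(t|d) = mean over b∈b_d of θ[b]."""
        if not hasattr(self, "estimates_"):
            raise RuntimeError("BioLDA instance is not fitted")
        rows = np.empty((X.n_docs, self.n_topics))
        for i, d in enumerate(X.documents):
            rows[i] = self.theta_[d.bioterms].mean(axis=0)
        return rows

    def fit_transform(self, X: Corpus, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def top_terms(self, topic: int, **kw) -> dict:
        return top_terms(self.estimates_, topic, **kw)

    def save(self, directory: str | Path) -> None:
        self.estimates_.save(directory, self._config())
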