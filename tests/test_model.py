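"""Gibbs sampler correctness: initialization, conditionals, sweeps,
estimators, summaries, and the plain-LDA reduction."""

import numpy as np
import pytest

from biolda.corpus import Corpus, Document
from biolda.model import (
    BioLDA, ModelConfig, as_lda_corpus, estimate_parameters,
    gibbs_conditional, gibbs_sweep, init_assignments, map_topics,
    top_terms, train, _decrement, _increment,
)
from biolda.synth import generate_corpus

from conftest import brute_force_conditional, recount


def singleton_corpus():
    docs = [Document("d0", 0, np.array([0, 1, 2, 0], dtype=np.int32),
                     np.array([0], dtype=np.int32))]
    return Corpus(docs, ["w0", "w1", "w2"], [("B0", "drug")], ["J0"])


# ----------------------------------------------------------------------
# init_assignments
# ----------------------------------------------------------------------

def test_init_forced_when_T1_and_single_bioterm():
    cfg = ModelConfig(n_topics=1, n_sweeps=2, burn_in=0, seed=0)
    state = init_assignments(singleton_corpus(), cfg)
    assert np.all(state.z == 0)
    assert np.all(state.x == 0)


def test_init_deterministic_under_seed(tiny_corpus):
    cfg = ModelConfig(n_topics=3, n_sweeps=2, burn_in=0, seed=42)
    s1 = init_assignments(tiny_corpus, cfg)
    s2 = init_assignments(tiny_corpus, cfg)
    assert np.array_equal(s1.z, s2.z)
    assert np.array_equal(s1.x, s2.x)
    assert np.array_equal(s1.n_bt, s2.n_bt)


def test_init_counts_match_recount_oracle():
    corpus, _ = generate_corpus(n_docs=30, doc_length=15, seed=5)
    cfg = ModelConfig(n_topics=4, n_sweeps=2, burn_in=0, seed=5)
    state = init_assignments(corpus, cfg)
    n_bt, n_wt, n_jt, n_t, n_b = recount(state)
    assert np.array_equal(state.n_bt, n_bt)
    assert np.array_equal(state.n_wt, n_wt)
    assert np.array_equal(state.n_jt, n_jt)
    assert np.array_equal(state.n_t, n_t)
    assert np.array_equal(state.n_b, n_b)
    state.validate()


# ----------------------------------------------------------------------
# gibbs_conditional
# ----------------------------------------------------------------------

def test_conditional_degenerate_single_cell():
    cfg = ModelConfig(n_topics=1, n_sweeps=2, burn_in=0, seed=0)
    state = init_assignments(singleton_corpus(), cfg)
    _decrement(state, 0)
    tab = gibbs_conditional(state, 0, 0)
    assert tab.shape == (1, 1)
    assert tab[0, 0] == pytest.approx(1.0)
    _increment(state, 0, 0, 0)


def test_conditional_uniform_when_no_counts(tiny_corpus):
    """First token ever: the smoothed conditional is symmetric."""
    cfg = ModelConfig(n_topics=2, n_sweeps=2, burn_in=0, seed=0)
    state = init_assignments(tiny_corpus, cfg)
    # empty all counts except one token, then remove it too
    for i in range(state.n_tokens):
        _decrement(state, i)
    tab = gibbs_conditional(state, 0, 0)  # doc 0 has |b_d|=2, T=2
    assert tab.shape == (2, 2)
    np.testing.assert_allclose(tab, 0.25, atol=1e-12)


@pytest.mark.parametrize("journal_on", [True, False])
def test_conditional_matches_brute_force(tiny_corpus, journal_on):
    cfg = ModelConfig(n_topics=3, n_sweeps=2, burn_in=0, seed=9,
                      journal_component_enabled=journal_on)
    rng = np.random.default_rng(9)
    for trial in range(20):
        state = init_assignments(tiny_corpus, cfg,
                                 np.random.default_rng(trial))
        i = int(rng.integers(0, state.n_tokens))
        d = int(state.tok_doc[i])
        lo, _ = state.token_range(d)
        _decrement(state, i)
        got = gibbs_conditional(state, d, i - lo)
        want = brute_force_conditional(state, i)
        np.testing.assert_allclose(got, want, atol=1e-12)


# ----------------------------------------------------------------------
# gibbs_sweep
# ----------------------------------------------------------------------

def test_sweep_single_token_T1_unchanged():
    docs = [Document("d", 0, np.array([0], dtype=np.int32),
                     np.array([0], dtype=np.int32))]
    c = Corpus(docs, ["w0"], [("B0", "drug")], ["J0"])
    cfg = ModelConfig(n_topics=1, n_sweeps=2, burn_in=0, seed=0)
    state = init_assignments(c, cfg)
    before = (state.z.copy(), state.x.copy())
    gibbs_sweep(state, np.random.default_rng(0))
    assert np.array_equal(state.z, before[0])
    assert np.array_equal(state.x, before[1])


def test_sweep_conserves_counts():
    corpus, _ = generate_corpus(n_docs=40, doc_length=12, seed=2)
    cfg = ModelConfig(n_topics=3, n_sweeps=2, burn_in=0, seed=2)
    state = init_assignments(corpus, cfg)
    n_total = state.n_tokens
    rng = np.random.default_rng(2)
    for _ in range(3):
        gibbs_sweep(state, rng)
        assert int(state.n_t.sum()) == n_total
        assert int(state.n_b.sum()) == n_total
    n_bt, n_wt, n_jt, n_t, n_b = recount(state)
    assert np.array_equal(state.n_bt, n_bt)
    assert np.array_equal(state.n_wt, n_wt)
    assert np.array_equal(state.n_jt, n_jt)


def test_sweep_deterministic_under_seed(tiny_corpus):
    cfg = ModelConfig(n_topics=3, n_sweeps=2, burn_in=0, seed=7)
    s1 = init_assignments(tiny_corpus, cfg)
    s2 = s1.copy()
    gibbs_sweep(s1, np.random.default_rng(11))
    gibbs_sweep(s2, np.random.default_rng(11))
    assert np.array_equal(s1.z, s2.z)
    assert np.array_equal(s1.x, s2.x)


def test_kernel_and_reference_sweep_agree():
    """The numba kernel and the pure-Python sweep consume identical
    uniforms and must produce identical assignments."""
    corpus, _ = generate_corpus(n_docs=20, doc_length=10, seed=3)
    cfg = ModelConfig(n_topics=3, n_sweeps=2, burn_in=0, seed=3)
    s1 = init_assignments(corpus, cfg)
    s2 = s1.copy()
    rand = np.random.default_rng(3).random(s1.n_tokens)
    gibbs_sweep(s1, rand=rand, use_kernel=True)
    gibbs_sweep(s2, rand=rand.copy(), use_kernel=False)
    assert np.array_equal(s1.z, s2.z)
    assert np.array_equal(s1.x, s2.x)
    assert np.array_equal(s1.n_bt, s2.n_bt)


# ----------------------------------------------------------------------
# estimate_parameters
# ----------------------------------------------------------------------

def test_estimates_prior_only_are_uniform(tiny_corpus):
    cfg = ModelConfig(n_topics=2, n_sweeps=2, burn_in=0, seed=0)
    state = init_assignments(tiny_corpus, cfg)
    for i in range(state.n_tokens):
        _decrement(state, i)
    est = estimate_parameters(state)
    np.testing.assert_allclose(est.theta, 1 / 2, atol=1e-12)
    np.testing.assert_allclose(est.phi, 1 / 4, atol=1e-12)
    np.testing.assert_allclose(est.psi, 1 / 2, atol=1e-12)


def test_estimate_hand_arithmetic():
    """2 bio-terms x 2 topics, alpha=1: theta follows directly."""
    docs = [Document("d", 0, np.array([0, 0, 0, 0], dtype=np.int32),
                     np.array([0, 1], dtype=np.int32))]
    c = Corpus(docs, ["w0"], [("B0", "drug"), ("B1", "gene")], ["J0"])
    cfg = ModelConfig(n_topics=2, alpha=1.0, n_sweeps=2, burn_in=0, seed=0)
    state = init_assignments(c, cfg)
    # force n_bt = [[3,1],[0,0]]
    state.z[:] = [0, 0, 0, 1]
    state.x[:] = 0
    n_bt, n_wt, n_jt, n_t, n_b = recount(state)
    state.n_bt, state.n_wt, state.n_jt = n_bt, n_wt, n_jt
    state.n_t, state.n_b = n_t, n_b
    est = estimate_parameters(state)
    np.testing.assert_allclose(est.theta, [[4 / 6, 2 / 6], [1 / 2, 1 / 2]])


def test_estimate_rows_normalized_and_positive():
    corpus, _ = generate_corpus(n_docs=30, doc_length=10, seed=1)
    cfg = ModelConfig(n_topics=4, n_sweeps=5, burn_in=0, seed=1)
    state, est, _ = train(corpus, cfg)
    est.validate()  # rows sum to 1 within 1e-9, all entries > 0


def test_single_topic_closed_form():
    """T=1: theta is the all-ones column; phi row is the smoothed
    empirical word frequency."""
    corpus, _ = generate_corpus(n_topics=1, n_docs=20, doc_length=10, seed=4)
    cfg = ModelConfig(n_topics=1, beta=0.01, n_sweeps=3, burn_in=0, seed=4)
    state, est, _ = train(corpus, cfg)
    np.testing.assert_allclose(est.theta, 1.0)
    counts = np.zeros(corpus.n_words)
    for d in corpus.documents:
        np.add.at(counts, d.tokens, 1)
    expected = (counts + cfg.beta) / (counts.sum() + corpus.n_words * cfg.beta)
    np.testing.assert_allclose(est.phi[0], expected, atol=1e-12)


# ----------------------------------------------------------------------
# train-level behaviour
# ----------------------------------------------------------------------

def test_loglik_trend_improves():
    corpus, _ = generate_corpus(n_docs=100, doc_length=30, seed=6)
    cfg = ModelConfig(n_topics=3, n_sweeps=60, burn_in=0, seed=6)
    _, _, ll = train(corpus, cfg)
    assert np.median(ll[-10:]) >= np.median(ll[:10])


def test_estimator_api_fit_sets_attributes():
    corpus, _ = generate_corpus(n_docs=30, doc_length=10, seed=8)
    model = BioLDA(n_topics=3, n_sweeps=5, burn_in=2, random_state=8)
    assert model.get_params()["n_topics"] == 3
    model.fit(corpus)
    assert model.theta_.shape == (corpus.n_bioterms, 3)
    assert model.phi_.shape == (3, corpus.n_words)
    assert model.psi_.shape == (3, corpus.n_journals)
    emb = model.transform(corpus)
    assert emb.shape == (corpus.n_docs, 3)
    np.testing.assert_allclose(emb.sum(axis=1), 1.0, atol=1e-9)


def test_model_dump_roundtrip(tmp_path):
    corpus, _ = generate_corpus(n_docs=30, doc_length=10, seed=8)
    model = BioLDA(n_topics=3, n_sweeps=5, burn_in=2, random_state=8).fit(corpus)
    model.save(tmp_path / "m")
    from biolda.model import PosteriorEstimates
    est = PosteriorEstimates.load(tmp_path / "m")
    np.testing.assert_allclose(est.theta, model.theta_)
    np.testing.assert_allclose(est.phi, model.phi_)
    assert est.bioterm_ids == [cid for cid, _ in corpus.bioterms]


# ----------------------------------------------------------------------
# top_terms / map_topics
# ----------------------------------------------------------------------

def _toy_estimates():
    from biolda.model import PosteriorEstimates
    theta = np.array([[0.7, 0.3], [0.5, 0.5]])
    phi = np.array([[0.5, 0.3, 0.2], [0.2, 0.3, 0.5]])
    psi = np.array([[0.6, 0.4], [0.4, 0.6]])
    return PosteriorEstimates(theta, phi, psi,
                              bioterm_ids=["B0", "B1"],
                              word_labels=["w0", "w1", "w2"],
                              journal_labels=["J0", "J1"],
                              n_b=np.array([10, 10]))


def test_top_terms_order_and_k():
    est = _toy_estimates()
    tt = top_terms(est, 0, k_words=2)
    assert [w for w, _ in tt["words"]] == ["w0", "w1"]
    # k = V returns a permutation of the whole vocabulary
    tt_all = top_terms(est, 0, k_words=3)
    assert sorted(w for w, _ in tt_all["words"]) == ["w0", "w1", "w2"]
    # k beyond table size is truncated, not an error
    assert len(top_terms(est, 0, k_words=99)["words"]) == 3


def test_top_terms_tie_breaks_to_lower_id():
    est = _toy_estimates()
    est.phi = np.array([[0.4, 0.4, 0.2], [0.2, 0.4, 0.4]])
    tt = top_terms(est, 0, k_words=2)
    assert [w for w, _ in tt["words"]] == ["w0", "w1"]
    tt2 = top_terms(est, 1, k_words=2)
    assert [w for w, _ in tt2["words"]] == ["w1", "w2"]


def test_top_bioterms_prominence_vs_raw():
    est = _toy_estimates()
    est.n_b = np.array([1, 1000])  # B1 dominant in the corpus
    by_prom = [b for b, _ in top_terms(est, 0, k_bioterms=2)["bioterms"]]
    assert by_prom[0] == "B1"
    by_raw = [b for b, _ in top_terms(est, 0, k_bioterms=2,
                                      bioterm_weighting="raw")["bioterms"]]
    assert by_raw[0] == "B0"


def test_map_topics_identity_and_disjoint():
    a = [["w1", "w2", "w3"], ["w4", "w5", "w6"]]
    assert map_topics(a, a, k=3) == [(0, 3), (1, 3)]
    b = [["x1", "x2"], ["x3", "x4"]]
    assert map_topics(a, b, k=3) == [(0, 0), (0, 0)]


def test_map_topics_picks_highest_overlap():
    a = [[f"w{i}" for i in range(20)]]
    b = [[f"w{i}" for i in range(11)] + [f"u{i}" for i in range(9)],   # 11 shared
         [f"w{i}" for i in range(4)] + [f"v{i}" for i in range(16)],   # 4 shared
         [f"z{i}" for i in range(20)]]                                 # 0 shared
    assert map_topics(a, b, k=20) == [(0, 11)]


# ----------------------------------------------------------------------
# LDA reduction
# ----------------------------------------------------------------------

def test_lda_reduction_matches_collapsed_lda(tiny_corpus):
    """Unique pseudo bio-term per document + no journal factor ==
    the standard collapsed-LDA conditional with document-topic counts."""
    lda_corpus = as_lda_corpus(tiny_corpus)
    cfg = ModelConfig(n_topics=3, alpha=0.5, beta=0.01, n_sweeps=2,
                      burn_in=0, seed=13, journal_component_enabled=False)
    state = init_assignments(lda_corpus, cfg)
    T, V = 3, lda_corpus.n_words
    for i in range(state.n_tokens):
        d = int(state.tok_doc[i])
        lo, _ = state.token_range(d)
        _decrement(state, i)
        got = gibbs_conditional(state, d, i - lo).ravel()
        # independent standard collapsed-LDA conditional
        n_dt = np.zeros(T)
        n_wt = np.zeros((V, T))
        n_t = np.zeros(T)
        for k in range(state.n_tokens):
            if k == i:
                continue
            zk = int(state.z[k])
            if int(state.tok_doc[k]) == d:
                n_dt[zk] += 1
            n_wt[int(state.w[k]), zk] += 1
            n_t[zk] += 1
        wi = int(state.w[i])
        want = (n_dt + cfg.alpha) / (n_dt.sum() + T * cfg.alpha) \
            * (n_wt[wi] + cfg.beta) / (n_t + V * cfg.beta)
        want /= want.sum()
        np.testing.assert_allclose(got, want, atol=1e-12)
        _increment(state, i, int(state.doc_bioterms(d)[0]), int(np.argmax(got)))
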