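# Methods

## Model and inference

`biolda` fits an entity-conditioned topic model: each document's extracted
bio-terms **b**_d generate its tokens through latent topics, and each topic
emits both words and the document's journal. The model family is the
author-topic family, with bio-terms in the author role and a second
observed emission (the journal) per token. Three Dirichlet-multinomial
components are involved: θ (B×T, topic given bio-term, concentration α),
φ (T×V, word given topic, concentration β) and ψ (T×J, journal given
topic, concentration µ).

Inference is collapsed Gibbs sampling. The per-token latent pair
(x = bio-term, z = topic) is sampled *jointly* from

    P(x=b, z=t | rest) ∝ (n_bt+α)/(n_b+Tα) · (n_wt+β)/(n_t+Vβ) · (n_jt+µ)/(n_t+Jµ),

all counts excluding the current token. The uniform 1/|**b**_d| factor of
the bio-term draw is constant over outcomes and cancels. The journal factor
is applied once per token (every token of a document carries its journal),
and can be disabled. Assumptions worth stating plainly:

* a document's bio-term set fully explains its tokens — documents with no
  extracted bio-term cannot be generated and are excluded at corpus
  construction (a configurable alternative assigns a shared background
  pseudo bio-term);
* topics are exchangeable and their number T is fixed in advance;
* hyperparameters are fixed, not optimised.

Point estimates are the smoothed conditionals θ̂_bt = (n_bt+α)/(n_b+Tα),
φ̂_tw = (n_wt+β)/(n_t+Vβ), ψ̂_tj = (n_jt+µ)/(n_t+Jµ), taken from the final
sweep by default; averaging over post-burn-in sweeps is available
(`average_posterior=True`) and reduces variance at the cost of blurring
label switching. Strict positivity of the smoothed rows is what keeps all
downstream KL quantities finite.

**Plain-LDA baseline.** With the journal factor off and one unique
singleton pseudo bio-term per document (`as_lda_corpus`), n_bt becomes the
document-topic count matrix and the conditional is exactly the textbook
collapsed-LDA sampler. Topic correspondence between two fitted models is
established by maximal overlap of top-20 word lists (`map_topics`), ties
to the lowest index.

## Parameters that matter

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `n_topics` (T) | 50 | topic count; field-standard default for abstract corpora, 3 in the desk-scale tests |
| `alpha` | 50/T | topic-given-bio-term smoothing; the common heuristic |
| `beta` | 0.01 | word smoothing; weak, favours sparse word profiles |
| `mu` | 0.1 | journal smoothing; journals are fewer than words |
| `n_sweeps` | 500 | Gibbs sweeps; 300 suffices at desk scale |
| `burn_in` | 300 | discarded sweeps when averaging |
| `seed` | 0 | all randomness flows from one numpy Generator |

The sweep kernel is numba-compiled; it consumes one pre-drawn uniform per
token from the caller's Generator, so results are bit-identical to the
pure-Python reference sweep (tested) and independent of compiler version.

## Association measures

Entropy and KL use natural log (one shared base keeps them commensurable;
base 2 via `base=2`). sKL(p,q) = KL(p‖q)+KL(q‖p) over θ̂ rows; smaller =
stronger. The co-occurrence baseline is
Θ = log₂[(N·df_ij+λ)/(df_i·df_j+λ)] with λ=1 guarding zeros: positive for
over-represented pairs, strongly negative for never-co-mentioned pairs —
the regime the topic-model measure is designed to rescue.

## Graph applications — design choices

The spec of "importance" and several tie-breaks were genuinely open; the
package's choices are:

* **Path length** is hop count (edges) with unit weights; sKL enters only
  in ranking. Stage 1 of the near-shortest search computes hop distances
  to the target by breadth-first search (equivalent to Dijkstra under unit
  weights); stage 2 is a depth-first enumeration pruned with
  `hops-so-far + distance-to-target`.
* **Near-shortest bound**: paths with hops strictly below (1+β)·L_min are
  admitted, and the shortest paths (hops = L_min) are always admitted —
  otherwise β = 0 would return nothing. Default β = 0.5, hop cap 4
  (3-hop drug–gene–gene–drug paths are the longest case of interest).
* **Validity threshold** for predicted associations is inclusive:
  sKL ≤ 5. Among multiple connecting paths the one with smallest
  accumulated sKL is shown.
* **Gene importance** for connectivity maps: importance(g) =
  1/(1+sKL(g, disease)); a drug's rank score is the summed importance of
  its targeted genes. Both are logged on the returned object and easy to
  replace.
* **Missing topic profiles** (graph node absent from θ): pairwise sKL is
  replaced by a sentinel of 2× the validity threshold, keeping tables
  total while pushing unknowns to the weak end; every substitution is
  logged.
* **Clustering** of connectivity maps: average-linkage agglomerative
  clustering on Euclidean distances between score rows/columns
  (scipy.cluster.hierarchy); leaf orders are attached, scores unchanged.
* Ranking ties break toward fewer hops, then lexicographic node ids;
  top-term ties toward the lower id — all deterministic.

Bio-term ranking inside a topic uses prominence weighting
P(b|t) ∝ θ̂_bt·n_b rather than raw θ̂_bt, so rare bio-terms with flat
posteriors do not dominate top-term lists (raw ranking available).

## Text processing

Tokenisation lowercases, strips punctuation, removes sklearn's built-in
English stop words and applies the classic Porter (1980) stemmer,
implemented in-package (`biolda.stem`). Bio-term extraction runs on the
*unstemmed* text (gene symbols must not be stemmed): a left-to-right scan
where the longest dictionary match wins and the scan resumes after it.
Matching is case-insensitive except for surface forms of ≤ 3 characters,
which require an exact-case match to limit false positives from short
gene symbols. These are defaults, not reconstructions of any particular
production pipeline.

## Synthetic data

`generate_corpus` draws θ, φ, ψ from symmetric Dirichlets (defaults 0.5,
0.1, 0.5 — small φ concentration gives well-separated word profiles) and
then runs the generative process exactly: journal ~ Uniform(J), b_d a
uniform subset of size 2, tokens via x → z → w. True assignments are kept
for diagnostics, never used to initialise acceptance runs. Default study
condition for recovery experiments: T=3, B=6, V=30, J=3, 500 documents of
50 tokens (25 000 tokens), 300 sweeps — sizes at which best-permutation
total-variation recovery of φ (< 0.1) and θ (< 0.15) is expected for most
seeds while a full run stays in the seconds range on one CPU.

`generate_graph` plants requested type-patterned chains into a random
typed network whose every edge respects the relation/type constraints of
the eight supported relation kinds.

What passing these tests shows — and does not. Recovery on
generative-process data validates the sampler and estimators, not the
model's fit to real literature: real abstracts have Zipfian vocabulary,
bursty word use, correlated bio-term mentions and journals that are not
uniform over documents. Conclusions about real corpora need real corpora.

## Numerical notes and limitations

* Entropy uses the 0·ln 0 := 0 convention; KL requires q > 0 wherever
  p > 0 and raises otherwise (smoothed θ̂ rows always satisfy it); tiny
  negative rounding in KL is clamped to 0.
* Probability-vector validation tolerance is 1e-9 on the row sum.
* Count matrices are int64; conditionals are evaluated in float64.
* Label switching is handled only in evaluation (best permutation), not
  in inference; posterior averaging across sweeps can therefore blur
  topics on long runs.
* Simple-path enumeration (ρ-paths, prediction candidates, near-shortest
  search) is exponential in the worst case; the hop cap keeps it
  tractable on sparse biomedical networks but dense graphs need a lower
  `max_len`.
* The dictionary matcher is a greedy longest-match scan; it does not
  handle nested or crossing entity mentions, abbreviation expansion, or
  disambiguation.
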