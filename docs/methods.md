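# Methods

## Model

The corpus model is standard LDA. A collection of M documents over a
vocabulary of V terms is assumed generated by K latent topics: topic k is a
distribution φ_k over terms, document m a distribution θ_m over topics,
with symmetric Dirichlet priors β on φ and α on θ; each token first draws a
topic z from θ_m, then a term from φ_z. Estimation is by collapsed Gibbs
sampling: Θ and Φ are integrated out analytically and the sampler resamples
one token's assignment at a time from

    P(z_i = k | z_-i, w) ∝ (n_dk + α) · (n_kw + β) / (n_k + Vβ),

where all counts exclude the token being resampled. A sweep visits every
token once, in document order then token order.

Point estimates are the posterior-mean smoothed forms taken from the final
state only — φ_kw = (n_kw + β)/(n_k + Vβ) and θ_mk = (n_mk + α)/(len_m + Kα).
No burn-in discarding or sample averaging is performed: the iteration
budget is a single run length, and the smoothed estimators keep every entry
strictly positive, which the similarity construction and perplexity both
rely on. Hyperparameters are fixed; there is no α/β optimization.

Model fit is compared by training perplexity,
exp(−Σ_d Σ_w log Σ_k θ_dk φ_kw / N) with N the total token count. This is a
relative diagnostic (choice of K, iteration budget), not an absolute
goodness measure; no held-out fold-in inference is implemented.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `n_topics` (K) | 200 | topics per year; deliberately large so that redundant topics exist for the clustering stage to merge |
| `alpha` | 0.25 | document-topic prior (dimensionless concentration) |
| `beta` | 0.01 | topic-word prior; small values give sparse, peaked topics |
| `n_iterations` | 400 | full Gibbs sweeps |
| `random_state` | 0 | seed of the sampler's single PCG64 stream |

The defaults are the operating point used for per-year PubMed-scale corpora
(tens of thousands of abstracts); for the desk-scale synthetic studies in
the tests, K is set to the generator's topic count.

### Determinism and the compiled kernel

The inner loop is compiled with numba. All randomness is drawn from one
seeded `numpy.random.Generator` *outside* the kernel (topic initialization,
then one uniform variate per token per sweep), so a fit is a pure function
of (corpus, config) and is bit-identical across runs and platforms with the
same BLAS-free code path. This also makes the sampler auditable: the unit
tests replay the identical draw sequence through an independent scalar
implementation of the conditional and compare assignments token by token.
After every fit (and optionally every sweep) the count matrices are
re-tallied from the assignments and must match exactly.

## Affinity propagation

The K topic rows of Φ are clustered by affinity propagation with the
canonical message updates

    r(i,k) = s(i,k) − max_{k'≠k} [a(i,k') + s(i,k')]
    a(i,k) = min{0, r(k,k) + Σ_{i'∉{i,k}} max(0, r(i',k))}   (i ≠ k)
    a(k,k) = Σ_{i'≠k} max(0, r(i',k))

damped as new = λ·old + (1−λ)·raw with λ = 0.95 by default. Item k is an
exemplar when r(k,k) + a(k,k) > 0; non-exemplars join the most similar
exemplar, ties to the lowest index. If no diagonal is positive (a knife-edge
degeneracy that arises when the preference exactly ties off-diagonal
similarities), the single best-scoring item becomes the exemplar. n = 1
short-circuits to a trivial single-cluster result. The module is entirely
deterministic — no noise injection is used to break ties.

**Similarity.** The similarity of two topic rows is built from the
reciprocal of their cosine. A raw reciprocal is a *dissimilarity* (larger =
less similar), which would invert the order property a similarity matrix
must satisfy, so the default convention negates it: s(i,j) = −1/cos, with
the cosine clamped below at 1e−12 before inversion so orthogonal vectors map
to a large finite value (smoothed φ rows make exact zeros impossible in
pipeline use). A bounded plain-cosine convention (`similarity="cosine"`) is
also provided. The diagonal preference defaults to the median of the
off-diagonal similarities; `"min"` and explicit values are supported, and
raising the preference never decreases the number of exemplars.

**Convergence.** The loop stops when the exemplar set has been unchanged
for `convergence_window` consecutive iterations, or at `max_iter` (default
1000) with a warning. Two details matter at heavy damping. Messages
equilibrate on a timescale of roughly 1/(1−λ) iterations, and during this
transient an arbitrary exemplar set can appear stable; stability counting
therefore only begins after a burn-in of ⌈5/(1−λ)⌉ iterations. Second, a
window of 50 iterations proved too short at λ = 0.95 — on small instances
it froze mid-equilibration at solutions far from the exemplar-subset
optimum — so the default window is 100, after which solutions on structured
instances match the brute-force optimum exactly.

**Quality guard.** On 8-item instances (noisy two-group probability
vectors, the structure the module serves) the achieved net similarity
Σ_i s(i, exemplar_i) + Σ_k preference_k is compared against exhaustive
enumeration of all exemplar subsets of the same cardinality; the bound is
stated sign-safely as net ≥ optimum − 0.05·|optimum|, since net similarities
are negative under the reciprocal convention.

## Per-year pipeline

Each year is processed independently: fit LDA, build the similarity over
its K topic rows, run affinity propagation, and emit one summary per
cluster holding the exemplar topic's top-`n_words` terms (default 20; ties
in φ broken lexicographically). Topics are *not* aligned across years —
trends are computed on words and categories, which sidesteps the
label-switching problem entirely. A cluster's word list comes from its
exemplar only (exemplars are the clusters' representatives); member topics
contribute to cluster size, which orders the reports (descending size, ties
by exemplar index). Per-year sampler seeds are derived from one master seed
by a fixed affine-mod-2³¹ map, so a multi-year run is reproducible from a
single integer and the serialized outputs are byte-identical across runs.

A fitted model with K > the number of genuinely distinct themes splits
themes into near-duplicate topics and leaves some topics nearly empty.
Clustering then merges the duplicates; the near-empty topics have almost
uniform smoothed rows and attach to whichever exemplar is nearest, which is
noise by construction. Validation therefore checks that the exemplars
represent the planted distinct themes and that every *strongly aligned*
topic (cosine ≥ 0.7 to a planted theme) lands in its theme's cluster, not
the cluster membership of junk topics.

## Preprocessing

Tokens are lowercase alphabetic runs (`[a-z]+` after case folding); pure
numbers and punctuation artifacts disappear. Each surface form is
lemmatized by a small deterministic rule engine (irregular-form table, noun
plural rules, conservative -ing/-ed stripping with Porter-style stem
restoration) that favours returning the input unchanged over over-stemming.
Stop words are checked on both the surface form and the lemma against a
bundled English list (user-overridable; the list's content hash is logged
for provenance). Tokens shorter than `min_len` (default 2) are dropped.
Vocabulary construction keeps terms appearing in at least `min_df`
documents (default 2), assigns dense ids in sorted term order, drops
documents the filter empties, and errors only if nothing survives. Titles
are not included — only the abstract element of each record is read, with
internal markup stripped.

The XML reader accepts any record schema in which a pmid-like and an
abstract-like element can be located by local tag name case-insensitively
(flat `<article><pmid/><abstract/></article>` fixtures and standard
`PubmedArticle`/`MedlineCitation`/`AbstractText` records both parse).
Records missing either field are skipped and counted, never fatal;
malformed XML raises an error naming the file and position.

## Trend analytics

Term categorization is driven by a user-supplied TSV (term → category);
the package ships no ontology and never resolves terms remotely. Unmapped
terms are labelled `uncategorized` and excluded from proportions.
Occurrence tables count, per year and term, the number of cluster summaries
containing the term; a term's "frequency" across the study is its number of
years present. Category proportions divide each year's categorized
word-occurrence counts by the year's categorized total, so rows sum to 1
whenever anything was categorized (all-zero rows are flagged with a
warning, not an error).

Gene extraction intersects summary words with a user lexicon after case
folding — exact symbol match only, since fuzzy matching of abstract tokens
to gene symbols is unverifiable. Enrichment is a local hypergeometric
over-representation test: for a background population of size B (an
integer; gene sets are assumed drawn from it and validated to fit), a set
of size n and a query of size N, the p-value is the upper tail
P(X ≥ overlap) of Hypergeometric(B, n, N), with Benjamini–Hochberg FDR
across sets. This is a plain hypergeometric, not the modified one-less
Fisher score some enrichment services use, so p-values are comparable to
textbook calculations but not to those services' output.

## Synthetic data

The generator emulates exactly the structure the pipeline assumes:

- `make_lda_corpus` draws topic rows from a symmetric Dirichlet, anchors
  each row on a distinct dominant term and sharpens rows by a power
  transform + renormalization until all pairwise cosines fall below a
  threshold (default 0.4). Raw Dirichlet rows at desk-scale V are often too
  similar for recovery to be well-posed in a few hundred sweeps; anchoring
  is required because rows sharing an argmax would collapse onto the same
  point mass under sharpening. Document mixtures are Dirichlet(α), lengths
  Poisson(mean_len) floored at 5, and the truth (Φ*, Θ*) is retained.
- `make_multiyear` shares a configurable number of topic rows bit-identically
  across years and concentrates each year's private topics on a disjoint
  year-specific vocabulary block, so each year has *marker terms* that can
  appear as hotspots only in that year — the oracle for trend tests.
- `make_planted_vectors` produces cluster prototypes on near-disjoint
  support with Dirichlet member noise; the separation parameter sets the
  prototype:noise mixing ratio.

Vocabulary terms are all-consonant strings chosen to be fixed points of the
lemmatizer and disjoint from the stop list, so generated corpora survive
the full XML → preprocessing round trip unchanged.

What the generator does *not* emulate: natural English (no function-word
layer beyond the stop list, no collocations), term burstiness within
documents, vocabulary growth and document-count growth over years, OCR or
encoding noise, and any citation structure. Passing tests therefore
demonstrate correctness of the algorithms under the model's own
assumptions, not robustness to real-corpus pathologies.

## Study sizes

The shipped studies are sized for a single CPU: parameter recovery uses
K = 5, V = 200, M = 400 documents of mean length 60 at three seeds with the
full 400 sweeps (matched mean cosine ≈ 0.98, threshold 0.85 on at least two
seeds); the multiyear pipeline study uses 3 years × 80 documents, 4 topics
of which 2 shared, 150 terms, 150 sweeps; clustering quality uses 30
planted vectors in 3 groups and twenty 8-item brute-force instances. The
headline corpus-scale figures reported for full decade-scale PubMed runs
(tens of thousands of abstracts per year, 200 topics, ~14 clusters per
year) depend on that corpus and are not reproduced here.

## Known limitations

- The lemmatizer is rule-based and English-only; it under-lemmatizes rare
  irregular forms ("used" is kept as-is when the stem would be too short)
  and does no part-of-speech disambiguation.
- Single-chain Gibbs with a fixed budget gives no convergence diagnostics
  beyond perplexity monotonicity checks; label switching across seeds is
  expected and handled downstream by matching, never by the sampler.
- Affinity propagation at heavy damping can require many hundreds of
  iterations; `converged=False` results are returned with a warning rather
  than raised, and should be treated as provisional.
- The `uncategorized` bucket is excluded from proportions, so categories
  covering few hotspot words can make proportion rows volatile year-over-year.
- Enrichment treats the background as a size, not a membership list; if
  query genes can fall outside the background population the p-values are
  conservative approximations.
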