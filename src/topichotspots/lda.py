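"""Latent Dirichlet allocation estimated by collapsed Gibbs sampling.

Each document m carries a distribution θ_m over K topics and each topic k a
distribution φ_k over the V vocabulary terms, with symmetric Dirichlet
priors α (document-topic) and β (topic-word). Θ and Φ are integrated out and
the sampler resamples per-token topic assignments z from the collapsed
conditional; point estimates are the posterior-mean smoothed forms

    φ_kw = (n_kw + β) / (n_k + Vβ),   θ_mk = (n_mk + α) / (len_m + Kα),

taken from the final state. Defaults follow the framework's operating point
for per-year PubMed corpora: K=200, α=0.25, β=0.01, 400 sweeps.

Model fit is compared by training perplexity,
exp(−Σ_d Σ_w log Σ_k θ_dk φ_kw / N); lower is better.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._gibbs import sweep_kernel
from .base import ParamsMixin, check_fitted
from .corpus import Corpus, Vocabulary


@dataclass
class LDAConfig:
    """Sampler configuration; defaults are the framework's operating point."""

    n_topics: int = 200
    alpha: float = 0.25
    beta: float = 0.01
    n_iterations: int = 400
    seed: int = 0

    def __post_init__(self):
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class GibbsState:
    """Per-token assignments z and the count tallies the sampler maintains."""

    tokens: np.ndarray  # (N,) int32 word ids, documents concatenated
    doc_ids: np.ndarray  # (N,) int32 document index per token
    z: np.ndarray  # (N,) int32 topic assignment per token
    n_dk: np.ndarray  # (M, K) document-topic counts
    n_kw: np.ndarray  # (K, V) topic-word counts
    n_k: np.ndarray  # (K,) per-topic totals
    doc_len: np.ndarray  # (M,) document lengths
    rng: np.random.Generator


def _flatten(corpus: Corpus) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tokens = np.concatenate(
        [np.asarray(d.token_ids, dtype=np.int32) for d in corpus.documents]
    )
    doc_len = np.array([len(d.token_ids) for d in corpus.documents], dtype=np.int64)
    doc_ids = np.repeat(np.arange(corpus.M, dtype=np.int32), doc_len)
    return tokens, doc_ids, doc_len


def init_state(corpus: Corpus, config: LDAConfig) -> GibbsState:
    """Assign every token a uniform random topic and tally the counts."""
    if corpus.M == 0:
        raise ValueError("empty corpus")
    K, V = config.n_topics, corpus.V
    tokens, doc_ids, doc_len = _flatten(corpus)
    if tokens.size and tokens.max() >= V:
        raise ValueError("token id out of vocabulary range")
    rng = np.random.default_rng(config.seed)
    z = rng.integers(0, K, size=tokens.shape[0], dtype=np.int32)
    n_dk = np.zeros((corpus.M, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    np.add.at(n_dk, (doc_ids, z), 1)
    np.add.at(n_kw, (z, tokens), 1)
    return GibbsState(
        tokens=tokens,
        doc_ids=doc_ids,
        z=z,
        n_dk=n_dk,
        n_kw=n_kw,
        n_k=n_kw.sum(axis=1),
        doc_len=doc_len,
        rng=rng,
    )


def audit_state(state: GibbsState) -> None:
    """Recount z from scratch and verify every tally; raises on mismatch."""
    M, K = state.n_dk.shape
    V = state.n_kw.shape[1]
    n_dk = np.zeros((M, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    np.add.at(n_dk, (state.doc_ids, state.z), 1)
    np.add.at(n_kw, (state.z, state.tokens), 1)
    if not (
        np.array_equal(n_dk, state.n_dk)
        and np.array_equal(n_kw, state.n_kw)
        and np.array_equal(n_kw.sum(axis=1), state.n_k)
        and np.array_equal(state.n_dk.sum(axis=1), state.doc_len)
    ):
        raise AssertionError("Gibbs state counts inconsistent with assignments")


def gibbs_sweep(state: GibbsState, corpus: Corpus, config: LDAConfig) -> GibbsState:
    """Resample every token once, in document then token order, in place."""
    uniforms = state.rng.random(state.tokens.shape[0])
    sweep_kernel(
        state.tokens,
        state.doc_ids,
        state.z,
        state.n_dk,
        state.n_kw,
        state.n_k,
        float(config.alpha),
        float(config.beta),
        uniforms,
    )
    return state


def estimate_phi_theta(
    state: GibbsState, config: LDAConfig
) -> tuple[np.ndarray, np.ndarray]:
    K = config.n_topics
    V = state.n_kw.shape[1]
    phi = (state.n_kw + config.beta) / (
        state.n_k[:, None] + V * config.beta
    )
    theta = (state.n_dk + config.alpha) / (
        state.doc_len[:, None] + K * config.alpha
    )
    return phi, theta


class GibbsLDA(ParamsMixin):
    """Collapsed-Gibbs LDA estimator.

    Parameters
    ----------
    n_topics : int
        Number of topics K.
    alpha, beta : float
        Symmetric Dirichlet priors on θ (document-topic) and φ (topic-word).
    n_iterations : int
        Full Gibbs sweeps over the corpus.
    random_state : int
        Seed for the sampler's generator; fits are bit-reproducible.
    audit_every : int
        If > 0, recount-audit the state every that many sweeps (0 = only at
        the end of fit).

    Attributes
    ----------
    phi_ : ndarray of shape (K, V)
        Topic-word distributions; rows sum to 1, all entries > 0.
    theta_ : ndarray of shape (M, K)
        Document-topic distributions; rows sum to 1.
    state_ : GibbsState
        Final sampler state (assignments and counts).
    vocabulary_ : Vocabulary
        The corpus vocabulary the model indexes into.
    """

    def __init__(
        self,
        n_topics: int = 200,
        alpha: float = 0.25,
        beta: float = 0.01,
        n_iterations: int = 400,
        random_state: int = 0,
        audit_every: int = 0,
    ):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.n_iterations = n_iterations
        self.random_state = random_state
        self.audit_every = audit_every

    def _config(self) -> LDAConfig:
        return LDAConfig(
            n_topics=self.n_topics,
            alpha=self.alpha,
            beta=self.beta,
            n_iterations=self.n_iterations,
            seed=self.random_state,
        )

    def fit(self, corpus: Corpus, y=None) -> "GibbsLDA":
        config = self._config()
        state = init_state(corpus, config)
        for it in range(config.n_iterations):
            gibbs_sweep(state, corpus, config)
            if self.audit_every and (it + 1) % self.audit_every == 0:
                audit_state(state)
        audit_state(state)
        self.phi_, self.theta_ = estimate_phi_theta(state, config)
        self.state_ = state
        self.vocabulary_ = corpus.vocabulary
        self.n_iter_ = config.n_iterations
        return self

    def perplexity(self, corpus: Corpus) -> float:
        check_fitted(self, "phi_")
        return perplexity(self.phi_, self.theta_, corpus)

    def top_words(self, topic: int, n: int = 20) -> list[tuple[str, float]]:
        check_fitted(self, "phi_")
        return top_words(self.phi_, self.vocabulary_, topic, n)


def fit_lda(corpus: Corpus, config: LDAConfig | None = None) -> GibbsLDA:
    """Thin functional wrapper over :class:`GibbsLDA`."""
    config = config or LDAConfig()
    model = GibbsLDA(
        n_topics=config.n_topics,
        alpha=config.alpha,
        beta=config.beta,
        n_iterations=config.n_iterations,
        random_state=config.seed,
    )
    return model.fit(corpus)


def perplexity(phi: np.ndarray, theta: np.ndarray, corpus: Corpus) -> float:
    """Training perplexity exp(−Σ log p(w|d) / N) under the mixture θφ."""
    V = phi.shape[1]
    log_lik = 0.0
    n_tokens = 0
    for m, doc in enumerate(corpus.documents):
        ids = np.asarray(doc.token_ids)
        if ids.size and ids.max() >= V:
            raise ValueError("token id outside model vocabulary")
        p = theta[m] @ phi[:, ids]
        log_lik += float(np.log(p).sum())
        n_tokens += ids.size
    if n_tokens == 0:
        raise ValueError("empty corpus")
    return float(np.exp(-log_lik / n_tokens))


def top_words(
    phi: np.ndarray, vocabulary: Vocabulary, topic: int, n: int = 20
) -> list[tuple[str, float]]:
    """The n highest-weight terms of one topic, ties broken lexicographically."""
    if not 0 <= topic < phi.shape[0]:
        raise IndexError(f"topic {topic} out of range")
    if n < 1:
        raise ValueError("n must be >= 1")
    V = phi.shape[1]
    if n > V:
        warnings.warn(f"requested {n} words but vocabulary has {V}", stacklevel=2)
        n = V
    row = phi[topic]
    ranked = sorted(
        ((vocabulary.term(w), float(row[w])) for w in range(V)),
        key=lambda tw: (-tw[1], tw[0]),
    )
    return ranked[:n]


def corpus_hash(corpus: Corpus) -> str:
    h = hashlib.sha256()
    for doc in corpus.documents:
        h.update(doc.pmid.encode())
        h.update(np.asarray(doc.token_ids, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]


def save_model(model: GibbsLDA, out_dir: str | Path, corpus: Corpus | None = None):
    """Write phi/theta as TSV matrices plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "phi.tsv", model.phi_, fmt="%.10e", delimiter="\t")
    np.savetxt(out / "theta.tsv", model.theta_, fmt="%.10e", delimiter="\t")
    sidecar = {
        "K": model.n_topics,
        "V": int(model.phi_.shape[1]),
        "alpha": model.alpha,
        "beta": model.beta,
        "iterations": model.n_iterations,
        "seed": model.random_state,
        "corpus_hash": corpus_hash(corpus) if corpus is not None else None,
    }
    (out / "model.json").write_text(json.dumps(sidecar, indent=2), encoding="utf-8")
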