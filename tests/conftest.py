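import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from topichotspots import (
    APConfig,
    Corpus,
    Document,
    GibbsLDA,
    LDAConfig,
    Vocabulary,
    load_stopwords,
    make_lda_corpus,
    make_multiyear,
    run_pipeline,
)

RECOVERY_SEEDS = (11, 12, 13)


def matched_mean_cosine(true_phi: np.ndarray, est_phi: np.ndarray) -> float:
    """Mean cosine between true and estimated topic rows under the optimal
    one-to-one (Hungarian) topic matching."""
    A = true_phi / np.linalg.norm(true_phi, axis=1, keepdims=True)
    B = est_phi / np.linalg.norm(est_phi, axis=1, keepdims=True)
    C = A @ B.T
    r, c = linear_sum_assignment(-C)
    return float(C[r, c].mean())


def tiny_corpus(token_ids: list[list[int]], n_terms: int) -> Corpus:
    """Hand-built corpus over terms t0..t{n-1} for closed-form checks."""
    vocab = Vocabulary([f"t{i}" for i in range(n_terms)])
    docs = [
        Document(
            pmid=f"P{m}",
            year=2000,
            raw_text="",
            tokens=[f"t{i}" for i in ids],
            token_ids=list(ids),
        )
        for m, ids in enumerate(token_ids)
    ]
    return Corpus(documents=docs, vocabulary=vocab, year=2000)


@pytest.fixture(scope="session")
def stopwords():
    return load_stopwords()


@pytest.fixture(scope="session")
def recovery_runs():
    """Parameter-recovery study: corpora drawn from known Φ* and fitted for
    1 and for 400 sweeps, at three seeds."""
    runs = {}
    for seed in RECOVERY_SEEDS:
        corpus, truth = make_lda_corpus(
            K=5, V=200, M=400, mean_len=60.0, seed=seed
        )
        long_fit = GibbsLDA(
            n_topics=5, n_iterations=400, random_state=seed
        ).fit(corpus)
        short_fit = GibbsLDA(
            n_topics=5, n_iterations=1, random_state=seed
        ).fit(corpus)
        runs[seed] = dict(
            corpus=corpus, truth=truth, long=long_fit, short=short_fit
        )
    return runs


@pytest.fixture(scope="session")
def multiyear_family():
    return make_multiyear(
        [2014, 2015, 2016], n_topics=4, n_shared=2, V=150, M=80,
        mean_len=40.0, seed=5,
    )


@pytest.fixture(scope="session")
def multiyear_results(multiyear_family):
    corpora = {y: c for y, (c, _t) in multiyear_family.items()}
    return run_pipeline(
        corpora,
        LDAConfig(n_topics=4, n_iterations=150),
        APConfig(),
        n_words=20,
        master_seed=5,
    )
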