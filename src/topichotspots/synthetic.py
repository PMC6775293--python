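"""Synthetic corpora with retained ground truth.

Generates exactly the structure the framework assumes: corpora drawn from
the LDA generative process (topic-word rows Φ*, document-topic rows Θ*,
both kept for parameter-recovery checks), multi-year families of corpora
with shared and year-specific topics (so a planted term is a hotspot only in
its planted year), and planted-cluster probability vectors for exercising
affinity propagation against known labels.

Vocabulary terms are synthetic all-consonant strings ("qbbcd", ...), chosen
to be fixed points of the lemmatizer and disjoint from the stop list so that
corpora survive a full round trip through the XML reader and preprocessing
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from .corpus import Corpus, Document, Vocabulary
from .lemmatize import lemmatize

_ALPHABET = "bcdfghklmnpqrtvw"  # no vowels, no 's': lemmatizer fixed points


@dataclass
class SyntheticTruth:
    """Generator ground truth retained for recovery and clustering oracles."""

    true_phi: np.ndarray
    true_theta: np.ndarray
    params: dict
    terms: list[str]
    labels: np.ndarray | None = None
    marker_terms: dict = field(default_factory=dict)


def make_terms(V: int) -> list[str]:
    """V distinct alphabetic terms that preprocessing maps to themselves."""
    width = max(3, int(np.ceil(np.log(max(V, 2)) / np.log(len(_ALPHABET)))))
    terms = []
    for i in range(V):
        digits = []
        x = i
        for _ in range(width):
            digits.append(_ALPHABET[x % len(_ALPHABET)])
            x //= len(_ALPHABET)
        term = "q" + "".join(reversed(digits))
        assert lemmatize(term) == term
        terms.append(term)
    return terms


def _separate_rows(phi: np.ndarray, max_cosine: float, max_rounds: int = 60):
    """Sharpen Dirichlet rows (power transform + renormalize) until all
    pairwise cosines drop below ``max_cosine``; keeps rows strictly positive.

    Each row is first anchored on a distinct dominant term (otherwise two
    rows sharing an argmax would converge to the same point mass under the
    power transform and never separate)."""
    K = phi.shape[0]
    used: set[int] = set()
    for k in range(K):
        for w in np.argsort(-phi[k]):
            if int(w) not in used:
                used.add(int(w))
                phi[k, w] = max(phi[k, w], 1.5 * phi[k].max())
                break
    phi = phi / phi.sum(axis=1, keepdims=True)
    for _ in range(max_rounds):
        norm = phi / np.linalg.norm(phi, axis=1, keepdims=True)
        cos = norm @ norm.T
        np.fill_diagonal(cos, 0.0)
        if cos.max() <= max_cosine:
            break
        phi = phi ** 1.3
        phi /= phi.sum(axis=1, keepdims=True)
    return phi


def _sample_docs(
    rng: np.random.Generator,
    phi: np.ndarray,
    M: int,
    mean_len: float,
    alpha: float,
    year: int | str,
    pmid_prefix: str,
    terms: list[str],
) -> tuple[list[Document], np.ndarray]:
    K, V = phi.shape
    theta = rng.dirichlet(np.full(K, alpha), size=M)
    documents = []
    for m in range(M):
        length = max(5, int(rng.poisson(mean_len)))
        zs = rng.choice(K, size=length, p=theta[m])
        ids = np.empty(length, dtype=np.int64)
        for k in np.unique(zs):
            mask = zs == k
            ids[mask] = rng.choice(V, size=int(mask.sum()), p=phi[k])
        token_ids = [int(w) for w in ids]
        documents.append(
            Document(
                pmid=f"{pmid_prefix}{m:05d}",
                year=year if isinstance(year, int) else 0,
                raw_text=" ".join(terms[w] for w in token_ids),
                tokens=[terms[w] for w in token_ids],
                token_ids=token_ids,
            )
        )
    return documents, theta


def _vocab_with_df(terms: list[str], documents: list[Document]) -> Vocabulary:
    df = np.zeros(len(terms), dtype=int)
    for doc in documents:
        for w in set(doc.token_ids):
            df[w] += 1
    return Vocabulary(terms, df.tolist())


def make_lda_corpus(
    K: int = 5,
    V: int = 200,
    M: int = 400,
    mean_len: float = 60.0,
    alpha: float = 0.25,
    beta: float = 0.01,
    seed: int = 0,
    max_topic_cosine: float = 0.4,
    year: int | str = "pooled",
    true_phi: np.ndarray | None = None,
) -> tuple[Corpus, SyntheticTruth]:
    """Draw a corpus from the LDA generative process.

    Topic rows are symmetric-Dirichlet draws sharpened until pairwise
    cosines fall below ``max_topic_cosine`` (well-separated truth makes
    recovery well-posed at small V); document mixtures are Dirichlet(α);
    lengths are Poisson(mean_len) floored at 5. ``true_phi`` overrides the
    topic rows (e.g. planted topic groups from make_planted_vectors).
    """
    if V < K:
        raise ValueError("V must be >= K for separable topics")
    rng = np.random.default_rng(seed)
    terms = make_terms(V)
    if true_phi is not None:
        phi = np.asarray(true_phi, dtype=float)
        if phi.shape != (K, V):
            raise ValueError("true_phi must have shape (K, V)")
        phi = phi / phi.sum(axis=1, keepdims=True)
    else:
        conc = max(beta * V, 0.05) * 50.0 / V
        phi = rng.dirichlet(np.full(V, conc), size=K)
        phi = _separate_rows(phi, max_topic_cosine)
    documents, theta = _sample_docs(
        rng, phi, M, mean_len, alpha, year, "SYN", terms
    )
    corpus = Corpus(
        documents=documents, vocabulary=_vocab_with_df(terms, documents),
        year=year,
    )
    truth = SyntheticTruth(
        true_phi=phi,
        true_theta=theta,
        params=dict(K=K, V=V, M=M, mean_len=mean_len, alpha=alpha, beta=beta,
                    seed=seed, max_topic_cosine=max_topic_cosine),
        terms=terms,
    )
    return corpus, truth


def make_multiyear(
    years: list[int],
    n_topics: int = 4,
    n_shared: int = 2,
    V: int = 150,
    M: int = 80,
    mean_len: float = 40.0,
    alpha: float = 0.25,
    seed: int = 0,
) -> dict[int, tuple[Corpus, SyntheticTruth]]:
    """One corpus per year over a shared vocabulary.

    ``n_shared`` topic rows are bit-identical across years; the remaining
    rows are year-specific and concentrated on a disjoint year-private
    vocabulary block, so each year has planted marker terms that can appear
    as hotspots only in that year (``truth.marker_terms``).
    """
    if not years:
        raise ValueError("years must be non-empty")
    if not 0 <= n_shared <= n_topics:
        raise ValueError("n_shared must be within [0, n_topics]")
    n_unique = n_topics - n_shared
    master = np.random.SeedSequence(seed)
    shared_seed, *year_seeds = master.spawn(len(years) + 1)

    terms = make_terms(V)
    shared_block = V // 2
    unique_span = (V - shared_block) // max(len(years), 1)
    if n_unique and unique_span < n_unique:
        raise ValueError("V too small for the requested year-specific topics")

    rng_shared = np.random.default_rng(shared_seed)
    shared_phi = np.zeros((n_shared, V))
    if n_shared:
        shared_phi[:, :shared_block] = _separate_rows(
            rng_shared.dirichlet(np.full(shared_block, 0.2), size=n_shared),
            0.4,
        )

    out: dict[int, tuple[Corpus, SyntheticTruth]] = {}
    for yi, (year, yseed) in enumerate(zip(years, year_seeds)):
        rng = np.random.default_rng(yseed)
        lo = shared_block + yi * unique_span
        hi = lo + unique_span
        phi = np.zeros((n_topics, V))
        phi[:n_shared] = shared_phi
        markers = []
        if n_unique:
            block = _separate_rows(
                rng.dirichlet(np.full(hi - lo, 0.2), size=n_unique), 0.4
            )
            phi[n_shared:, lo:hi] = block
            markers = [terms[lo + int(row.argmax())] for row in block]
        documents, theta = _sample_docs(
            rng, phi, M, mean_len, alpha, year, f"Y{year}N", terms
        )
        corpus = Corpus(
            documents=documents,
            vocabulary=_vocab_with_df(terms, documents),
            year=year,
        )
        truth = SyntheticTruth(
            true_phi=phi,
            true_theta=theta,
            params=dict(year=year, n_topics=n_topics, n_shared=n_shared, V=V,
                        M=M, mean_len=mean_len, alpha=alpha, seed=seed),
            terms=terms,
            marker_terms={year: markers},
        )
        out[year] = (corpus, truth)
    return out


def make_planted_vectors(
    n_clusters: int,
    per_cluster: int,
    V: int = 60,
    separation: float = 50.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted-cluster probability vectors for AP tests.

    Cluster prototypes are Dirichlet draws on near-disjoint vocabulary
    blocks; each member is a convex mix (separation : 1) of its prototype
    with fresh Dirichlet noise, so large ``separation`` gives within-cluster
    cosine near 1 and between-cluster cosine near 0. Returns (vectors,
    labels)."""
    if separation <= 0:
        raise ValueError("separation must be > 0")
    rng = np.random.default_rng(seed)
    block = V // n_clusters
    vectors = []
    labels = []
    for c in range(n_clusters):
        proto = np.full(V, 1e-12)
        lo = c * block
        proto[lo : lo + block] = rng.dirichlet(np.ones(block))
        proto /= proto.sum()
        for _ in range(per_cluster):
            noise = rng.dirichlet(np.ones(V))
            member = (separation * proto + noise) / (separation + 1.0)
            vectors.append(member / member.sum())
            labels.append(c)
    return np.asarray(vectors), np.asarray(labels)


def write_pubmed_xml(documents: list[Document], path: str | Path) -> None:
    """Emit documents as a flat PubMed-style XML file (<article> records with
    <pmid> and <abstract>), so the XML reader can be exercised end to end."""
    root = etree.Element("articles")
    for doc in documents:
        rec = etree.SubElement(root, "article")
        etree.SubElement(rec, "pmid").text = doc.pmid
        etree.SubElement(rec, "abstract").text = doc.raw_text
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")
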