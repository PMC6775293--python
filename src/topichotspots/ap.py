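"""Affinity propagation clustering of topic-word distributions.

Items exchange two messages over a similarity matrix S: the responsibility
r(i,k), how well item k would serve as exemplar for i given other candidate
exemplars, and the availability a(i,k), how appropriate it is for i to pick
k given the support k receives. Updates follow the canonical message
definitions

    r(i,k) = s(i,k) − max_{k'≠k} [a(i,k') + s(i,k')]
    a(i,k) = min{0, r(k,k) + Σ_{i'∉{i,k}} max(0, r(i',k))}   (i ≠ k)
    a(k,k) = Σ_{i'≠k} max(0, r(i',k))

damped as new = λ·old + (1−λ)·raw to suppress oscillation. The diagonal of S
(the "preference") controls how many exemplars emerge; the default is the
median of the off-diagonal similarities.

For topic rows (strictly positive distributions) the similarity is built
from the reciprocal of cosine similarity, negated so that larger s means
more similar: s(i,j) = −1 / cos(x_i, x_j). A plain-cosine convention is also
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base import ParamsMixin, check_fitted

_EPS = 1e-12


@dataclass
class APConfig:
    damping: float = 0.95
    max_iter: int = 1000
    convergence_window: int = 100
    preference_strategy: str | float = "median"

    def __post_init__(self):
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must be in (0, 1)")
        if self.max_iter < 1 or self.convergence_window < 1:
            raise ValueError("max_iter and convergence_window must be >= 1")


@dataclass
class SimilarityMatrix:
    S: np.ndarray
    preference: np.ndarray = field(init=False)

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2 or self.S.shape[0] != self.S.shape[1]:
            raise ValueError("S must be square")
        if not np.all(np.isfinite(self.S)):
            raise ValueError("S contains non-finite entries")
        self.preference = self.S.diagonal().copy()

    @property
    def n(self) -> int:
        return self.S.shape[0]


@dataclass
class APResult:
    exemplars: list[int]
    labels: np.ndarray
    iterations_run: int
    converged: bool

    def clusters(self) -> dict[int, list[int]]:
        """exemplar index -> sorted member indices (exemplar included)."""
        out: dict[int, list[int]] = {k: [] for k in self.exemplars}
        for i, lab in enumerate(self.labels):
            out[int(lab)].append(i)
        return out


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("zero-norm vector")
    return float(x @ y / (nx * ny))


def build_similarity(
    items: np.ndarray,
    preference_strategy: str | float = "median",
    similarity: str = "neg-reciprocal",
) -> SimilarityMatrix:
    """Pairwise similarity of item vectors with the preference on the diagonal.

    ``neg-reciprocal`` (default): s(i,j) = −1/max(cos, 1e−12), so larger s is
    more similar and near-orthogonal pairs are clamped at −1e12.
    ``cosine``: s(i,j) = cos(x_i, x_j).
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 item vectors")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite item vectors")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-norm vector")
    cos = (X / norms[:, None]) @ (X / norms[:, None]).T
    np.clip(cos, -1.0, 1.0, out=cos)
    if similarity == "neg-reciprocal":
        S = -1.0 / np.maximum(cos, _EPS)
    elif similarity == "cosine":
        S = cos.copy()
    else:
        raise ValueError(f"unknown similarity convention {similarity!r}")

    off = S[~np.eye(S.shape[0], dtype=bool)]
    if preference_strategy == "median":
        pref = float(np.median(off))
    elif preference_strategy == "min":
        pref = float(off.min())
    elif isinstance(preference_strategy, (int, float)):
        pref = float(preference_strategy)
    else:
        raise ValueError(f"unknown preference strategy {preference_strategy!r}")
    np.fill_diagonal(S, pref)
    return SimilarityMatrix(S)


def update_responsibility(
    S: np.ndarray, A: np.ndarray, R_prev: np.ndarray, damping: float
) -> np.ndarray:
    """r(i,k) = s(i,k) − max_{k'≠k}[a(i,k') + s(i,k')], damped."""
    n = S.shape[0]
    if n < 2:
        raise ValueError("responsibility update needs n >= 2")
    AS = A + S
    idx = np.arange(n)
    first_arg = AS.argmax(axis=1)
    first = AS[idx, first_arg]
    AS_wo = AS.copy()
    AS_wo[idx, first_arg] = -np.inf
    second = AS_wo.max(axis=1)
    raw = S - first[:, None]
    raw[idx, first_arg] = S[idx, first_arg] - second
    return damping * R_prev + (1.0 - damping) * raw


def update_availability(
    R: np.ndarray, A_prev: np.ndarray, damping: float
) -> np.ndarray:
    """a(i,k) = min{0, r(k,k) + Σ_{i'∉{i,k}} max(0, r(i',k))}, damped;
    a(k,k) = Σ_{i'≠k} max(0, r(i',k))."""
    n = R.shape[0]
    if n < 2:
        raise ValueError("availability update needs n >= 2")
    Rp = np.maximum(R, 0.0)
    np.fill_diagonal(Rp, R.diagonal())
    colsum = Rp.sum(axis=0)
    raw = np.minimum(colsum[None, :] - Rp, 0.0)
    np.fill_diagonal(raw, colsum - R.diagonal())
    return damping * A_prev + (1.0 - damping) * raw


def extract_exemplars(
    R: np.ndarray, A: np.ndarray, S: np.ndarray
) -> tuple[list[int], np.ndarray]:
    """Exemplars are items with r(k,k)+a(k,k) > 0; others join the most
    similar exemplar (ties to the lowest index). If no diagonal is positive
    the single best-scoring item becomes the exemplar."""
    crit = R.diagonal() + A.diagonal()
    exemplars = np.flatnonzero(crit > 0.0)
    if exemplars.size == 0:
        exemplars = np.array([int(crit.argmax())])
    labels = exemplars[np.argmax(S[:, exemplars], axis=1)]
    labels[exemplars] = exemplars
    return [int(k) for k in exemplars], labels.astype(np.int64)


def affinity_propagation(
    S: SimilarityMatrix | np.ndarray, config: APConfig | None = None
) -> APResult:
    """Iterate message passing until the exemplar set is stable.

    Convergence is declared when the exemplar set is unchanged for
    ``convergence_window`` consecutive iterations; otherwise the loop stops
    at ``max_iter`` with ``converged=False``. Deterministic: no randomness.
    """
    config = config or APConfig()
    mat = S.S if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    n = mat.shape[0]
    if n == 1:
        return APResult([0], np.zeros(1, dtype=np.int64), 0, True)

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    # With heavy damping, messages equilibrate on a timescale of roughly
    # 1/(1-λ) iterations; a transiently stable exemplar set during that
    # burn-in must not be mistaken for convergence.
    burn_in = int(np.ceil(5.0 / (1.0 - config.damping)))
    last: tuple[int, ...] | None = None
    stable = 0
    it = 0
    for it in range(1, config.max_iter + 1):
        R = update_responsibility(mat, A, R, config.damping)
        A = update_availability(R, A, config.damping)
        if not (np.all(np.isfinite(R)) and np.all(np.isfinite(A))):
            raise FloatingPointError("AP messages diverged to non-finite values")
        # A stable empty set after burn-in is the degenerate "no diagonal
        # went positive" case; extract_exemplars falls back to the single
        # best-scoring item.
        current = tuple(np.flatnonzero(R.diagonal() + A.diagonal() > 0.0))
        if it > burn_in and current == last:
            stable += 1
            if stable >= config.convergence_window:
                exemplars, labels = extract_exemplars(R, A, mat)
                return APResult(exemplars, labels, it, True)
        else:
            stable = 0
        last = current

    import warnings

    warnings.warn(
        f"affinity propagation did not converge in {config.max_iter} iterations",
        stacklevel=2,
    )
    exemplars, labels = extract_exemplars(R, A, mat)
    return APResult(exemplars, labels, it, False)


class AffinityPropagation(ParamsMixin):
    """Exemplar clustering estimator over item vectors or a precomputed S.

    Parameters
    ----------
    damping : float
        Message damping λ ∈ (0,1); new = λ·old + (1−λ)·raw.
    max_iter, convergence_window : int
        Iteration budget and the run of stable exemplar sets that declares
        convergence.
    preference : 'median' | 'min' | float
        Diagonal of S; larger values yield more exemplars.
    similarity : 'neg-reciprocal' | 'cosine' | 'precomputed'
        How fit(X) builds S from the rows of X; 'precomputed' takes X as S.

    Attributes
    ----------
    exemplars_ : list of exemplar item indices (sorted).
    labels_ : per-item exemplar assignment.
    n_iter_ : iterations run; converged_ : bool.
    """

    def __init__(
        self,
        damping: float = 0.95,
        max_iter: int = 1000,
        convergence_window: int = 100,
        preference: str | float = "median",
        similarity: str = "neg-reciprocal",
    ):
        self.damping = damping
        self.max_iter = max_iter
        self.convergence_window = convergence_window
        self.preference = preference
        self.similarity = similarity

    def fit(self, X: np.ndarray, y=None) -> "AffinityPropagation":
        config = APConfig(
            damping=self.damping,
            max_iter=self.max_iter,
            convergence_window=self.convergence_window,
            preference_strategy=self.preference,
        )
        X = np.asarray(X, dtype=float)
        if self.similarity == "precomputed":
            sim = SimilarityMatrix(X)
        elif X.shape[0] == 1:
            sim = None
        else:
            sim = build_similarity(X, self.preference, self.similarity)
        result = affinity_propagation(
            sim if sim is not None else np.zeros((1, 1)), config
        )
        self.similarity_matrix_ = sim
        self.result_ = result
        self.exemplars_ = result.exemplars
        self.labels_ = result.labels
        self.n_iter_ = result.iterations_run
        self.converged_ = result.converged
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_fitted(self, "labels_")
        return self.labels_
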