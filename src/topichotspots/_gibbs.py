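"""Compiled inner loop of the collapsed Gibbs sampler.

The kernel consumes one pre-drawn uniform variate per token, so all
randomness lives in the caller's seeded generator and a sweep is a pure,
bit-reproducible function of (state, uniforms).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_kernel(tokens, doc_ids, z, n_dk, n_kw, n_k, alpha, beta, uniforms):
    """One full sweep: resample every token's topic from the collapsed
    conditional P(z=k | rest) ∝ (n_dk+α)(n_kw+β)/(n_k+Vβ), own count excluded.
    """
    K, V = n_kw.shape
    vbeta = V * beta
    cum = np.empty(K, dtype=np.float64)
    for t in range(tokens.shape[0]):
        d = doc_ids[t]
        w = tokens[t]
        k_old = z[t]
        n_dk[d, k_old] -= 1
        n_kw[k_old, w] -= 1
        n_k[k_old] -= 1
        total = 0.0
        for k in range(K):
            total += (n_dk[d, k] + alpha) * (n_kw[k, w] + beta) / (n_k[k] + vbeta)
            cum[k] = total
        u = uniforms[t] * total
        k_new = 0
        while k_new < K - 1 and cum[k_new] <= u:
            k_new += 1
        z[t] = k_new
        n_dk[d, k_new] += 1
        n_kw[k_new, w] += 1
        n_k[k_new] += 1
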