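"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's forward-backward and closed-form
code paths: the HMM oracle enumerates all haplotype-copying path pairs, and
the binomial oracle sums probability mass term by term.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = -1


def enumerate_hmm_dosages(g, H, pos, ne, err, recomb_rate, min_switch):
    """Posterior dosages/variances by summing over every ordered pair of
    haplotype-copying paths.

    g : (M,) genotypes with MISSING at unobserved sites
    H : (K, M) reference haplotypes
    """
    H = np.asarray(H, dtype=np.int8)
    K, M = H.shape
    gaps = np.diff(np.asarray(pos, dtype=float)) * recomb_rate * 1e-8
    theta = np.maximum(1.0 - np.exp(-4.0 * ne * gaps / K), min_switch)
    stay = 1.0 - theta + theta / K
    move = theta / K

    paths = np.array(list(itertools.product(range(K), repeat=M)), dtype=np.int64)
    if M > 1:
        same = paths[:, 1:] == paths[:, :-1]
        w = np.where(same, stay, move).prod(axis=1) / K
    else:
        w = np.full(len(paths), 1.0 / K)
    A = H[paths, np.arange(M)].astype(np.int8)  # (P, M) copied alleles

    e, c = err, 1.0 - err
    em = np.array(
        [
            [c * c, c * e, e * e],
            [2 * c * e, c * c + e * e, 2 * c * e],
            [e * e, c * e, c * c],
        ]
    )
    W = np.outer(w, w)
    for j in range(M):
        if g[j] == MISSING:
            continue
        S = A[:, j][:, None] + A[None, :, j]
        W = W * em[g[j]][S]
    Z = W.sum()
    row = W.sum(axis=1)
    col = W.sum(axis=0)
    ds = np.empty(M)
    var = np.empty(M)
    for j in range(M):
        a = A[:, j].astype(float)
        e1 = row @ a / Z
        e2 = col @ a / Z
        e12 = a @ W @ a / Z
        ds[j] = e1 + e2
        var[j] = e1 * (1 - e1) + e2 * (1 - e2) + 2 * (e12 - e1 * e2)
    return ds, var


def binomial_tail_sum(k: int, n: int, p: float) -> float:
    """P(X <= k) for X ~ Binomial(n, p) by direct mass summation."""
    return sum(
        math.comb(n, j) * p**j * (1.0 - p) ** (n - j) for j in range(k + 1)
    )
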