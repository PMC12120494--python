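"""Independent brute-force oracles used to cross-check the vectorised metrics.

Everything here is written as literal loops over pair enumerations, straight
from the metric definitions, and deliberately shares no code with the
package implementation.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def _pack_desc(X: np.ndarray) -> np.ndarray:
    rows = sorted(range(X.shape[0]), key=lambda i: -X[i].sum())
    X = X[rows, :]
    cols = sorted(range(X.shape[1]), key=lambda j: -X[:, j].sum())
    return X[:, cols]


def brute_nodf(X: np.ndarray) -> tuple[float, float, float]:
    """(overall, row component, col component) of binary NODF by literal pairs."""
    B = (np.asarray(X) > 0).astype(int)
    B = B[B.sum(axis=1) > 0, :]
    B = _pack_desc(B)

    def axis_terms(M):
        terms = []
        for i, j in combinations(range(M.shape[0]), 2):  # i above j
            mt_i, mt_j = M[i].sum(), M[j].sum()
            if mt_i > mt_j > 0:
                overlap = sum(1 for c in range(M.shape[1]) if M[i, c] and M[j, c])
                terms.append(100.0 * overlap / mt_j)
            else:
                terms.append(0.0)
        return terms

    rows = axis_terms(B)
    cols = axis_terms(B.T)
    overall = sum(rows + cols) / len(rows + cols)
    return overall, sum(rows) / len(rows), sum(cols) / len(cols)


def brute_wnodf(X: np.ndarray) -> tuple[float, float, float]:
    """(overall, row component, col component) of WNODF by literal pairs."""
    X = np.asarray(X)
    X = X[X.sum(axis=1) > 0, :]
    X = _pack_desc(X)

    def axis_terms(M):
        terms = []
        for i, j in combinations(range(M.shape[0]), 2):  # i above j
            tot_i, tot_j = M[i].sum(), M[j].sum()
            fill_j = sum(1 for c in M[j] if c > 0)
            if tot_i > tot_j and fill_j > 0:
                count = sum(
                    1 for c in range(M.shape[1]) if M[j, c] > 0 and M[i, c] > M[j, c]
                )
                terms.append(100.0 * count / fill_j)
            else:
                terms.append(0.0)
        return terms

    rows = axis_terms(X)
    cols = axis_terms(X.T)
    overall = sum(rows + cols) / len(rows + cols)
    return overall, sum(rows) / len(rows), sum(cols) / len(cols)


def brute_rarefaction(x: np.ndarray, m: int) -> float:
    """E[S(m)] by exhaustive enumeration over all subsamples of size m.

    Averages the richness of every one of the C(n, m) equally likely
    subsamples of individuals; feasible only for tiny n.
    """
    individuals = np.concatenate([[i] * int(c) for i, c in enumerate(x)])
    n = len(individuals)
    total = 0
    for subset in combinations(range(n), m):
        total += len({individuals[k] for k in subset})
    return total / comb(n, m)


def random_matrix(rng: np.random.Generator, max_dim: int = 6, weighted: bool = False):
    """A random small community matrix with at least one non-empty row."""
    while True:
        r = rng.integers(2, max_dim + 1)
        c = rng.integers(2, max_dim + 1)
        if weighted:
            X = rng.poisson(1.2, size=(r, c))
        else:
            X = (rng.random((r, c)) < 0.45).astype(int)
        if (X.sum(axis=1) > 0).sum() >= 2 and X.sum() > 0:
            return X
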