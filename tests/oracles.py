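"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written from first principles, separately from the
package implementation it checks: a Gotoh affine-gap local aligner, a
subset-enumeration maximal-clique finder with a repeated-merge
supercluster step, and a vectorised grid evaluation of the Cox partial
log-likelihood.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> float:
    return float(_B62[a][b])


def gotoh_local_score(
    a: str, b: str, open_: float = -11.0, extend: float = -1.0
) -> float:
    """Optimal Smith-Waterman score with affine gaps where a gap of
    length k scores open + (k-1)*extend.  Plain three-state DP."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend)
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = diag + blosum62(a[i - 1], b[j - 1])
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def brute_maximal_cliques(nodes: list, edges: set) -> set:
    """All maximal cliques of size >= 2 by subset enumeration."""
    def is_clique(sub) -> bool:
        return all(frozenset(p) in edges for p in combinations(sub, 2))

    cliques = set()
    for r in range(2, len(nodes) + 1):
        for sub in combinations(nodes, r):
            if not is_clique(sub):
                continue
            if any(
                is_clique(tuple(sorted(set(sub) | {v})))
                for v in nodes
                if v not in sub
            ):
                continue  # extendable, not maximal
            cliques.add(frozenset(sub))
    return cliques


def brute_merge_overlapping(clusters: set) -> set:
    """Repeatedly merge any two clusters sharing a member until none do."""
    out = [set(c) for c in clusters]
    changed = True
    while changed:
        changed = False
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                if out[i] & out[j]:
                    out[i] |= out[j]
                    del out[j]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(c) for c in out}


def cox_loglik_grid(
    times: np.ndarray, x: np.ndarray, betas: np.ndarray
) -> np.ndarray:
    """Breslow log partial likelihood on a grid of beta values for
    all-events data (vectorised; intended for tie-free times)."""
    order = np.argsort(times)
    x = np.asarray(x, dtype=float)[order]
    e = np.exp(np.outer(betas, x))                      # (B, n)
    risk = np.cumsum(e[:, ::-1], axis=1)[:, ::-1]       # suffix sums
    return (betas[:, None] * x[None, :] - np.log(risk)).sum(axis=1)


def grid_max_beta(times, x, lo=-6.0, hi=6.0, step=1e-4) -> float:
    betas = np.arange(lo, hi + step, step)
    ll = cox_loglik_grid(np.asarray(times, float), np.asarray(x, float), betas)
    return float(betas[int(np.argmax(ll))])
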