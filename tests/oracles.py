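"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity from first principles (closed forms,
exhaustive enumeration, dense linear algebra) through a code path
disjoint from the package's implementation, so agreement is evidence
rather than tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import betainc


def welch_oracle(x, y):
    """Textbook Welch t-test: statistic for mean(y)-mean(x), df, 2-sided p.

    The p-value goes through the regularized incomplete beta function
    rather than a t-distribution object: for T ~ t_df,
    P(|T| > t) = I_{df/(df+t^2)}(df/2, 1/2).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (y.mean() - x.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, df, p


def _floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[adj > 0] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    return dist


def _path_counts(adj: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """sigma[s, v] = number of shortest s-v paths (0 if unreachable)."""
    n = adj.shape[0]
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = sorted(
            (v for v in range(n) if np.isfinite(dist[s, v])), key=lambda v: dist[s, v]
        )
        for v in order:
            if v == s:
                continue
            for u in range(n):
                if adj[u, v] and dist[s, u] == dist[s, v] - 1:
                    sigma[s, v] += sigma[s, u]
    return sigma


def centrality_oracle(adj: np.ndarray) -> dict[str, np.ndarray]:
    """Brute-force degree / betweenness / closeness / eigenvector.

    Betweenness applies the definitional pair-sum
    sum_{s<t, v not in {s,t}} sigma_st(v)/sigma_st, normalized by
    (n-1)(n-2)/2. Closeness is (k-1)/sum(d) within each component of
    size k. Eigenvector is the dense-eigendecomposition Perron vector
    per component, max-normalized; singleton components score 0.
    """
    n = adj.shape[0]
    adj = np.asarray(adj, float)
    degree = adj.sum(axis=1)
    dist = _floyd_warshall(adj)
    sigma = _path_counts(adj, dist)

    betweenness = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    betweenness[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    if n > 2:
        betweenness /= (n - 1) * (n - 2) / 2.0

    closeness = np.zeros(n)
    for v in range(n):
        reach = np.isfinite(dist[v]) & (np.arange(n) != v)
        total = dist[v, reach].sum()
        if total > 0:
            closeness[v] = reach.sum() / total

    eigenvector = np.zeros(n)
    seen: set[int] = set()
    for v in range(n):
        if v in seen:
            continue
        comp = sorted(np.flatnonzero(np.isfinite(dist[v])))
        seen.update(comp)
        if len(comp) == 1:
            continue
        sub = adj[np.ix_(comp, comp)]
        w, vecs = np.linalg.eigh(sub)
        vec = np.abs(vecs[:, np.argmax(w)])
        eigenvector[comp] = vec / vec.max()

    return {
        "degree": degree,
        "betweenness": betweenness,
        "closeness": closeness,
        "eigenvector": eigenvector,
    }


def hypergeom_tail_by_enumeration(N: int, K: int, n: int) -> dict[int, float]:
    """P(X >= k) for every k by enumerating all n-subsets of the universe.

    Universe = {0..N-1}, gene set = {0..K-1}; returns a dict k -> tail
    probability computed as an exact fraction of subset counts.
    """
    marked = set(range(K))
    tally: dict[int, int] = {}
    total = 0
    for combo in itertools.combinations(range(N), n):
        k = len(marked.intersection(combo))
        tally[k] = tally.get(k, 0) + 1
        total += 1
    out = {}
    acc = 0.0
    for k in range(min(n, K), -1, -1):
        acc += tally.get(k, 0) / total
        out[k] = acc
    return out
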