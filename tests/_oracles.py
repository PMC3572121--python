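"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and self-contained (direct formula
evaluation, exhaustive enumeration, dense linear algebra) so it shares no
code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


# --- logistic regression: Newton-Raphson IRLS from scratch -----------------

def _logit_ll(y, X, beta):
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def irls_logit(y: np.ndarray, X: np.ndarray, tol: float = 1e-12, maxiter: int = 200):
    """Newton-Raphson maximum likelihood for logistic regression (step-halved)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    beta = np.zeros(X.shape[1])
    ll = _logit_ll(y, X, beta)
    for _ in range(maxiter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        W = np.clip(p * (1 - p), 1e-12, None)
        grad = X.T @ (y - p)
        H = (X.T * W) @ X
        step = np.linalg.solve(H, grad)
        scale = 1.0
        while scale > 1e-8:
            cand = beta + scale * step
            ll_new = _logit_ll(y, X, cand)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2
        beta = beta + scale * step
        if np.max(np.abs(scale * step)) < tol:
            break
        ll = _logit_ll(y, X, beta)
    return beta


# --- SAR likelihood and fit oracles ----------------------------------------

def mvn_sar_loglik(beta, rho, sigma2, y, X, W_list):
    """Exact density of y ~ N(X beta, sigma^2 (A'A)^-1) via scipy's MVN."""
    n = len(y)
    A = np.eye(n)
    for r, W in zip(np.atleast_1d(rho), W_list):
        A = A - r * W
    cov = sigma2 * np.linalg.inv(A.T @ A)
    return float(stats.multivariate_normal(mean=np.asarray(X) @ np.atleast_1d(beta),
                                           cov=cov).logpdf(np.asarray(y)))


def grid_search_sar(y, X, W, lo=-0.99, hi=0.99, resolution=1e-3):
    """Exhaustive profile-likelihood grid search over rho for a single W."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    best = (-np.inf, None)
    for rho in np.arange(lo, hi + resolution / 2, resolution):
        A = np.eye(n) - rho * W
        sign, ld = np.linalg.slogdet(A)
        if sign <= 0:
            continue
        Ay, AX = A @ y, A @ X
        beta, *_ = np.linalg.lstsq(AX, Ay, rcond=None)
        resid = Ay - AX @ beta
        s2 = resid @ resid / n
        ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1) + ld
        if ll > best[0]:
            best = (ll, rho)
    return best[1], best[0]


# --- egocentric network metrics by exhaustive path enumeration -------------

def _all_simple_paths(adj: dict[int, set], s: int, t: int):
    """All simple s->t paths via DFS on an adjacency-set dict."""
    stack = [(s, [s])]
    while stack:
        v, path = stack.pop()
        if v == t:
            yield path
            continue
        for w in adj[v]:
            if w not in path:
                stack.append((w, path + [w]))


def brute_force_metrics(edges: list[tuple[int, int]], nodes: list[int]) -> dict:
    """Degree, betweenness, closeness, eigenvector, transitivity by brute force.

    Assumes a connected undirected simple graph. Betweenness uses the
    fractional shortest-path count with endpoints excluded; closeness is
    1/(total shortest-path distance); eigenvector centrality comes from
    power iteration scaled to max 1; transitivity is the fraction of
    neighbour pairs that are themselves adjacent (NaN for degree <= 1).
    """
    nodes = list(nodes)
    adj: dict[int, set] = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    degree = {v: len(adj[v]) for v in nodes}

    # shortest-path structure from exhaustive simple-path enumeration
    dist: dict[tuple, int] = {}
    sp_paths: dict[tuple, list] = {}
    for s, t in itertools.combinations(nodes, 2):
        paths = list(_all_simple_paths(adj, s, t))
        d = min(len(p) - 1 for p in paths)
        shortest = [p for p in paths if len(p) - 1 == d]
        dist[(s, t)] = dist[(t, s)] = d
        sp_paths[(s, t)] = shortest

    betweenness = {v: 0.0 for v in nodes}
    for (s, t), paths in sp_paths.items():
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            if through:
                betweenness[v] += through / len(paths)

    closeness = {v: 1.0 / sum(dist[(v, u)] for u in nodes if u != v) for v in nodes}

    A = np.zeros((len(nodes), len(nodes)))
    pos = {v: i for i, v in enumerate(nodes)}
    for u, v in edges:
        A[pos[u], pos[v]] = A[pos[v], pos[u]] = 1.0
    # power iteration on A + I: same eigenvectors, avoids period-2
    # oscillation on bipartite graphs
    A = A + np.eye(len(nodes))
    x = np.ones(len(nodes))
    for _ in range(10000):
        x_new = A @ x
        x_new = x_new / np.linalg.norm(x_new)
        if np.max(np.abs(x_new - x)) < 1e-14:
            x = x_new
            break
        x = x_new
    x = np.abs(x) / np.max(np.abs(x))
    eigenvector = {v: float(x[pos[v]]) for v in nodes}

    transitivity = {}
    for v in nodes:
        k = degree[v]
        if k <= 1:
            transitivity[v] = float("nan")
        else:
            pairs = list(itertools.combinations(sorted(adj[v]), 2))
            closed = sum(1 for a, b in pairs if b in adj[a])
            transitivity[v] = closed / len(pairs)

    return {
        "degree": {v: float(degree[v]) for v in nodes},
        "betweenness": betweenness,
        "closeness": closeness,
        "eigenvector": eigenvector,
        "transitivity": transitivity,
    }
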