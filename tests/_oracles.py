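"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's estimation code paths: DAG
scoring is done by per-node penalized regressions optimized with
scipy's Powell search over exhaustively enumerated structures,
shortest paths by depth-first enumeration, OLS by explicit normal
equations, and BH by its textbook formula.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# OLS via normal equations
# ---------------------------------------------------------------------------

def ols_oracle(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(beta, se, two-sided p) from (X'X)^-1 X'y with classical SEs."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * sigma2)
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return beta, se, p


# ---------------------------------------------------------------------------
# exhaustive DAG enumeration and scoring
# ---------------------------------------------------------------------------

def all_dags(p: int) -> List[Tuple[Tuple[int, int], ...]]:
    """Every labelled DAG on p nodes as a tuple of (parent, child) edges."""
    pairs = [(i, j) for i in range(p) for j in range(p) if i != j]
    out = []
    for mask in range(2 ** len(pairs)):
        edges = tuple(pairs[k] for k in range(len(pairs)) if mask >> k & 1)
        if _is_acyclic(edges, p):
            out.append(edges)
    return out


def _is_acyclic(edges: Sequence[Tuple[int, int]], p: int) -> bool:
    children: Dict[int, List[int]] = {i: [] for i in range(p)}
    indeg = [0] * p
    for u, v in edges:
        children[u].append(v)
        indeg[v] += 1
    frontier = [i for i in range(p) if indeg[i] == 0]
    seen = 0
    while frontier:
        u = frontier.pop()
        seen += 1
        for v in children[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                frontier.append(v)
    return seen == p


def _pen(t: float, mu: float, penalty: str, gamma: float) -> float:
    t = abs(t)
    if penalty == "l1":
        return mu * t
    if t <= gamma * mu:
        return mu * t - t * t / (2.0 * gamma)
    return 0.5 * gamma * mu * mu


def fit_structure_score(
    X: np.ndarray,
    edges: Sequence[Tuple[int, int]],
    lam: float,
    penalty: str = "mcp",
    gamma: float = 2.0,
) -> float:
    """Penalized profiled-Gaussian score of one structure.

    Per node with parents S: minimize
    (n/2) log(RSS/n * 2 pi e scale) + n sum pen(|beta|) over beta in R^|S|
    by Powell search started at the OLS solution.  Nodes without
    parents contribute their marginal-variance term.
    """
    n, p = X.shape
    mu = lam / math.sqrt(n)
    parents: Dict[int, List[int]] = {j: [] for j in range(p)}
    for u, v in edges:
        parents[v].append(u)
    total = 0.0
    for j in range(p):
        y = X[:, j]
        S = parents[j]
        if not S:
            rss = float(y @ y - n * y.mean() ** 2)
            rss = float(((y - y.mean()) ** 2).sum())
            total += 0.5 * n * (1.0 + math.log(2.0 * math.pi * rss / n))
            continue
        Xs = X[:, S]

        def obj(beta: np.ndarray) -> float:
            r = y - Xs @ beta
            rss = float(r @ r)
            return 0.5 * n * (1.0 + math.log(2.0 * math.pi * rss / n)) + n * sum(
                _pen(b, mu, penalty, gamma) for b in beta
            )

        beta0 = np.linalg.lstsq(Xs, y, rcond=None)[0]
        starts = [beta0, np.zeros(len(S))]
        best = math.inf
        for b0 in starts:
            res = optimize.minimize(
                obj, b0, method="Powell",
                options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 2000},
            )
            best = min(best, float(res.fun))
        total += best
    return total


def exhaustive_best_score(
    X: np.ndarray,
    lam: float,
    penalty: str = "mcp",
    gamma: float = 2.0,
    dags: Optional[List[Tuple[Tuple[int, int], ...]]] = None,
) -> float:
    """Global optimum of the penalized score over all DAG structures."""
    if dags is None:
        dags = all_dags(X.shape[1])
    return min(fit_structure_score(X, e, lam, penalty, gamma) for e in dags)


# ---------------------------------------------------------------------------
# path enumeration
# ---------------------------------------------------------------------------

def enumerate_all_paths(
    edges: Sequence[Tuple[str, str]], source: str, target: str
) -> List[List[str]]:
    """All simple directed paths, by depth-first search."""
    children: Dict[str, List[str]] = {}
    for u, v in edges:
        children.setdefault(u, []).append(v)
    out: List[List[str]] = []

    def walk(node: str, trail: List[str]) -> None:
        if node == target:
            out.append(list(trail))
            return
        for nxt in sorted(children.get(node, [])):
            if nxt not in trail:
                trail.append(nxt)
                walk(nxt, trail)
                trail.pop()

    walk(source, [source])
    return out


def shortest_paths_oracle(
    edges: Sequence[Tuple[str, str]], source: str, target: str
) -> List[List[str]]:
    paths = enumerate_all_paths(edges, source, target)
    if not paths:
        return []
    k = min(len(p) for p in paths)
    return sorted(p for p in paths if len(p) == k)


def subpath_oracle(short: Sequence[str], long: Sequence[str]) -> bool:
    s, l = list(short), list(long)
    return any(l[i : i + len(s)] == s for i in range(len(l) - len(s) + 1))


def extract_candidates_oracle(
    edges: Sequence[Tuple[str, str]],
    sources: Sequence[str],
    targets: Sequence[str],
    min_nodes: int = 3,
) -> List[Tuple[str, ...]]:
    pool = set()
    for s in sources:
        for t in targets:
            if s == t:
                continue
            for p in shortest_paths_oracle(edges, s, t):
                if len(p) >= min_nodes:
                    pool.add(tuple(p))
    kept = [
        p
        for p in pool
        if not any(len(q) > len(p) and subpath_oracle(p, q) for q in pool)
    ]
    return sorted(kept, key=lambda p: (len(p), p))


# ---------------------------------------------------------------------------
# BH by definition
# ---------------------------------------------------------------------------

def bh_oracle(pvals: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return adj
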