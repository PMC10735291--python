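"""Independent brute-force oracles used by the tests.

These deliberately re-derive results by enumeration or per-base expansion,
never by calling the code paths they check.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# Chain lifting: explicit per-base map
# ---------------------------------------------------------------------------

def chain_base_map(chain) -> dict[int, int]:
    """Expand a chain into an explicit target-base -> query-base table
    (query coordinate on the chain's stated strand)."""
    table = {}
    tpos, qpos = chain.target_start, chain.query_start
    for size, dt, dq in chain.blocks:
        for k in range(size):
            table[tpos + k] = qpos + k
        tpos += size + dt
        qpos += size + dq
    return table


def brute_lift(chain, start: int, end: int) -> tuple[int, list[int]]:
    """(aligned bases, sorted forward-strand query positions) by table lookup."""
    table = chain_base_map(chain)
    hits = [table[t] for t in range(start, end) if t in table]
    if chain.query_strand == "-":
        hits = [chain.query_size - 1 - q for q in hits]
    return len(hits), sorted(hits)


# ---------------------------------------------------------------------------
# Global alignment with free end gaps: exhaustive enumeration
# ---------------------------------------------------------------------------

def _score_alignment(cols: list[tuple[str, str]], match, mismatch,
                     gap_open, gap_extend) -> float:
    """Affine score of one explicit alignment; terminal gap runs are free."""
    n = len(cols)
    # which gap columns are terminal for the gapped sequence
    a_res = [i for i, (a, _) in enumerate(cols) if a != "-"]
    b_res = [i for i, (_, b) in enumerate(cols) if b != "-"]
    score = 0.0
    prev_gap = None  # 'a' or 'b' for an open internal run
    for i, (a, b) in enumerate(cols):
        if a != "-" and b != "-":
            score += match if a == b else mismatch
            prev_gap = None
        elif a == "-":
            end = not a_res or i < a_res[0] or i > a_res[-1]
            if not end:
                score += gap_extend if prev_gap == "a" else gap_open
            prev_gap = "a"
        else:
            end = not b_res or i < b_res[0] or i > b_res[-1]
            if not end:
                score += gap_extend if prev_gap == "b" else gap_open
            prev_gap = "b"
    return score


def best_alignment_score(seq_a: str, seq_b: str, match=1.0, mismatch=-1.0,
                         gap_open=-4.0, gap_extend=-1.0) -> float:
    """Maximum score over every possible global alignment (free end gaps)."""
    best = -np.inf
    stack = [(0, 0, [])]
    while stack:
        i, j, cols = stack.pop()
        if i == len(seq_a) and j == len(seq_b):
            best = max(best, _score_alignment(cols, match, mismatch,
                                              gap_open, gap_extend))
            continue
        if i < len(seq_a) and j < len(seq_b):
            stack.append((i + 1, j + 1, cols + [(seq_a[i], seq_b[j])]))
        if i < len(seq_a):
            stack.append((i + 1, j, cols + [(seq_a[i], "-")]))
        if j < len(seq_b):
            stack.append((i, j + 1, cols + [("-", seq_b[j])]))
    return best


# ---------------------------------------------------------------------------
# Neighbor joining: topology enumeration + least squares
# ---------------------------------------------------------------------------

def _enumerate_edge_sets(n: int) -> list[list[tuple[int, int]]]:
    """All unrooted binary topologies on leaves 0..n-1 (edge lists).

    Internal node ids start at n so they never collide with leaf ids.
    """
    trees = [([(0, n), (1, n), (2, n)], n + 1)]
    for leaf in range(3, n):
        nxt_trees = []
        for edges, nxt in trees:
            for k, (u, v) in enumerate(edges):
                e2 = edges[:k] + edges[k + 1:] + [
                    (u, nxt), (v, nxt), (leaf, nxt)]
                nxt_trees.append((e2, nxt + 1))
        trees = nxt_trees
    return [e for e, _ in trees]


def edge_splits(edges: list[tuple[int, int]], n: int) -> frozenset:
    """Non-trivial splits (as frozensets of the smaller leaf side)."""
    adj: dict[int, set[int]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    def side(start, banned):
        seen, stack, out = {banned, start}, [start], set()
        while stack:
            x = stack.pop()
            if x < n:
                out.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    splits = set()
    for u, v in edges:
        s = side(v, u)
        if 1 < len(s) < n - 1:
            comp = frozenset(range(n)) - s
            splits.add(min(s, comp, key=lambda x: (len(x), sorted(x))))
    return frozenset(splits)


@lru_cache(maxsize=None)
def topology_catalog(n: int):
    """All topologies on n leaves with path-incidence matrices and splits.

    The incidence matrix A has one row per leaf pair (combinations order)
    and one column per edge; A @ branch_lengths gives path distances.
    """
    catalog = []
    pairs = list(combinations(range(n), 2))
    for edges in _enumerate_edge_sets(n):
        adj: dict[int, list[tuple[int, int]]] = {}
        for idx, (u, v) in enumerate(edges):
            adj.setdefault(u, []).append((v, idx))
            adj.setdefault(v, []).append((u, idx))
        # BFS from each leaf recording edge paths
        A = np.zeros((len(pairs), len(edges)))
        paths: dict[int, dict[int, set[int]]] = {}
        for leaf in range(n):
            seen = {leaf}
            frontier = [(leaf, set())]
            reach: dict[int, set[int]] = {}
            while frontier:
                node, used = frontier.pop()
                for nxt, eidx in adj[node]:
                    if nxt in seen:
                        continue
                    seen.add(nxt)
                    nu = used | {eidx}
                    if nxt < n:
                        reach[nxt] = nu
                    frontier.append((nxt, nu))
            paths[leaf] = reach
        for r, (i, j) in enumerate(pairs):
            for eidx in paths[i][j]:
                A[r, eidx] = 1.0
        catalog.append((A, edge_splits(edges, n)))
    return catalog


def ls_best_splits(D: np.ndarray) -> frozenset:
    """Splits of the least-squares best topology for a distance matrix."""
    n = D.shape[0]
    d = np.array([D[i, j] for i, j in combinations(range(n), 2)])
    best = None
    for A, splits in topology_catalog(n):
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        rss = float(((A @ x - d) ** 2).sum())
        if best is None or rss < best[0] - 1e-12:
            best = (rss, splits)
    return best[1]


def random_additive_matrix(n: int, rng: np.random.Generator):
    """(distance matrix, generating splits) from a random binary topology
    with uniform branch lengths."""
    all_top = _enumerate_edge_sets(n)
    edges = all_top[int(rng.integers(0, len(all_top)))]
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in zip(edges, lengths):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    D = np.zeros((n, n))
    for leaf in range(n):
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for other in range(n):
            D[leaf, other] = dist[other]
    D = (D + D.T) / 2.0  # exact symmetry despite fp summation order
    return D, edge_splits(edges, n)
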