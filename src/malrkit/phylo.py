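"""Consensus-sequence phylogeny: free-end-gap alignment, Jukes-Cantor
distances, and neighbor-joining.

The tree is driven by *pairwise* corrected distances, not a multiple
alignment: every pair of LTR consensus models is globally aligned with
zero-cost terminal gaps (so length differences between models are not
penalised), the observed mismatch fraction p over internal, gap-free columns
is corrected with the Jukes-Cantor transform d = -(3/4) ln(1 - 4p/3), and
the classic neighbor-joining algorithm builds an unrooted tree from the
matrix.  An optional transition/transversion weighting biases the aligner;
the correction itself always treats all mismatches equally, as the JC model
assumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import Align

log = logging.getLogger(__name__)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

#: central-quantile half-widths of a normal distribution
Z75 = 1.1503493803760079
Z95 = 1.959963984540054
Z99 = 2.5758293035489004


@dataclass
class AlignParams:
    """Scoring for global alignment with free end gaps (affine penalties)."""

    match: float = 1.0
    mismatch: float = -1.0
    transition: float | None = None  # e.g. -0.5 to halve transition penalty
    gap_open: float = -4.0
    gap_extend: float = -1.0


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if params.transition is not None:
        alphabet = "ACGTN"
        m = np.zeros((5, 5))
        for i, a in enumerate(alphabet):
            for j, b in enumerate(alphabet):
                if "N" in (a, b):
                    m[i, j] = 0.0
                elif a == b:
                    m[i, j] = params.match
                elif ({a, b} <= _PURINES) or ({a, b} <= _PYRIMIDINES):
                    m[i, j] = params.transition
                else:
                    m[i, j] = params.mismatch
        aligner.substitution_matrix = Align.substitution_matrices.Array(
            alphabet=alphabet, dims=2, data=m
        )
    else:
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    aligner.end_gap_score = 0.0  # free end gaps on both sequences
    return aligner


@dataclass
class PairwiseAlignment:
    """A scored pairwise alignment plus per-column classification.

    ``columns`` holds one code per aligned column: ``M`` match, ``S``
    transition, ``V`` transversion, ``N`` ambiguous comparison, ``G``
    internal gap, ``E`` end gap (terminal run of columns where either
    sequence is gapped -- free under the scoring, excluded from distances).
    """

    seq_a: str
    seq_b: str
    aligned_a: str
    aligned_b: str
    score: float
    params: AlignParams
    columns: str = field(init=False)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        n = len(self.aligned_a)
        lead = 0
        while lead < n and ("-" in (self.aligned_a[lead], self.aligned_b[lead])):
            lead += 1
        trail = n
        while trail > lead and ("-" in (self.aligned_a[trail - 1],
                                        self.aligned_b[trail - 1])):
            trail -= 1
        codes = []
        for i in range(n):
            a, b = self.aligned_a[i], self.aligned_b[i]
            if "-" in (a, b):
                codes.append("E" if (i < lead or i >= trail) else "G")
            elif "N" in (a, b):
                codes.append("N")
            elif a == b:
                codes.append("M")
            elif {a, b} <= _PURINES or {a, b} <= _PYRIMIDINES:
                codes.append("S")
            else:
                codes.append("V")
        self.columns = "".join(codes)

    @property
    def n_compared(self) -> int:
        """Internal columns with a residue in both sequences."""
        return sum(self.columns.count(c) for c in "MSV")

    @property
    def n_mismatch(self) -> int:
        return self.columns.count("S") + self.columns.count("V")

    @property
    def p_distance(self) -> float:
        if self.n_compared == 0:
            raise ValueError("no comparable columns in alignment")
        return self.n_mismatch / self.n_compared


def global_align_free_end_gaps(
    seq_a: str, seq_b: str, params: AlignParams | None = None
) -> PairwiseAlignment:
    """Optimal global alignment with zero-cost terminal gaps.

    Ties are broken deterministically by taking the aligner's first
    reported path (highroad).
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    params = params or AlignParams()
    aligner = _make_aligner(params)
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    return PairwiseAlignment(
        seq_a=seq_a, seq_b=seq_b,
        aligned_a=str(aln[0]), aligned_b=str(aln[1]),
        score=float(aln.score), params=params,
    )


# ---------------------------------------------------------------------------
# Jukes-Cantor correction
# ---------------------------------------------------------------------------

@dataclass
class JCDistance:
    distance: float
    p: float
    n_compared: int
    saturated: bool


def jc_from_p(p: float) -> float:
    """Closed-form Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("p must be nonnegative")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def jc_distance(alignment: PairwiseAlignment) -> JCDistance:
    """JC-corrected distance from an alignment's internal gap-free columns."""
    p = alignment.p_distance  # raises on zero comparable columns
    saturated = p >= 0.75
    return JCDistance(
        distance=jc_from_p(p), p=p,
        n_compared=alignment.n_compared, saturated=saturated,
    )


def distance_matrix(
    seqs: dict[str, str], params: AlignParams | None = None
) -> pd.DataFrame:
    """Symmetric JC distance matrix over named consensus sequences.

    Saturated pairs (p >= 0.75) get ``inf`` entries; downstream tree
    building refuses them unless explicitly allowed.
    """
    names = list(seqs)
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jc_distance(
                global_align_free_end_gaps(seqs[names[i]], seqs[names[j]], params)
            )
            mat[i, j] = mat[j, i] = d.distance
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: pd.DataFrame, allow_saturated: bool = False) -> str:
    """Classic neighbor-joining; returns an unrooted Newick string.

    Q-matrix pair selection with ties broken by lexicographic order of the
    clusters' smallest leaf labels; standard branch-length formulas with
    negative lengths clamped to zero (logged).  The result is written as a
    trifurcating root, the conventional rendering of an unrooted tree.
    """
    names = list(dm.index)
    if list(dm.columns) != names:
        raise ValueError("distance matrix must have matching index/columns")
    if len(names) < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    D = dm.to_numpy(dtype=float).copy()
    if not np.allclose(D, D.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if np.isinf(D).any() or np.isnan(D).any():
        if not allow_saturated:
            raise ValueError(
                "matrix contains saturated/undefined distances; "
                "pass allow_saturated=True to cap them"
            )
        cap = 2.0 * np.nanmax(D[np.isfinite(D)])
        D = np.where(np.isfinite(D), D, cap)

    def clamp(x: float) -> float:
        if x < 0:
            log.info("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    nodes = [(n, n) for n in names]  # (newick fragment, min leaf label)
    active = list(range(len(names)))
    newick_of = {i: nodes[i] for i in active}

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] <= qmin + 1e-12:
                    key = tuple(sorted((newick_of[active[a]][1],
                                        newick_of[active[b]][1])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        bi = clamp(0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2)))
        bj = clamp(dij - bi)
        frag_i, key_i = newick_of[i]
        frag_j, key_j = newick_of[j]
        new_idx = D.shape[0]
        new_row = np.zeros(new_idx + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        for c in range(m):
            if c in (a, b):
                continue
            k = active[c]
            D[new_idx, k] = D[k, new_idx] = 0.5 * (sub[a, c] + sub[b, c] - dij)
        newick_of[new_idx] = (
            f"({frag_i}:{bi:.10g},{frag_j}:{bj:.10g})", min(key_i, key_j)
        )
        active = [k for k in active if k not in (i, j)] + [new_idx]
        del new_row

    (x, y, z) = active
    dxy, dxz, dyz = D[x, y], D[x, z], D[y, z]
    bx = clamp(0.5 * (dxy + dxz - dyz))
    by = clamp(0.5 * (dxy + dyz - dxz))
    bz = clamp(0.5 * (dxz + dyz - dxy))
    parts = sorted(
        [(newick_of[x], bx), (newick_of[y], by), (newick_of[z], bz)],
        key=lambda t: t[0][1],
    )
    inner = ",".join(f"{frag}:{b:.10g}" for (frag, _), b in parts)
    return f"({inner});"


def tree_splits(newick: str) -> set[frozenset[str]]:
    """Non-trivial splits (smaller-side leaf sets) of an unrooted tree."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = frozenset(t.label for t in tree.taxon_namespace)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(leaves) - 1:
            other = leaves - side
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


@dataclass
class CladeReport:
    is_split: bool
    sister: tuple[str, ...] | None


def clade_check(newick: str, taxa_subset: Sequence[str]) -> CladeReport:
    """Does the taxon subset form a split of the unrooted tree?

    A subset is a clade on some rooting iff it is one side of an edge
    bipartition.  When it is, the reported sister is the leaf set of the
    smallest subtree adjacent to the split on the far side (ties broken
    lexicographically).
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaf_labels = {t.label for t in tree.taxon_namespace}
    subset = frozenset(taxa_subset)
    unknown = subset - leaf_labels
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if subset == leaf_labels:
        return CladeReport(True, None)

    # adjacency over nodes, collapsing the artificial root if it is binary
    adj: dict[int, set[int]] = {}
    label: dict[int, str] = {}
    nodes = list(tree.preorder_node_iter())
    idx = {id(n): k for k, n in enumerate(nodes)}
    for n in nodes:
        k = idx[id(n)]
        adj.setdefault(k, set())
        if n.is_leaf():
            label[k] = n.taxon.label
        for ch in n.child_nodes():
            adj[k].add(idx[id(ch)])
            adj.setdefault(idx[id(ch)], set()).add(k)
    root = idx[id(tree.seed_node)]
    if len(adj[root]) == 2:  # suppress binary root: unrooted tree
        a, b = adj[root]
        adj[a].discard(root)
        adj[b].discard(root)
        adj[a].add(b)
        adj[b].add(a)
        del adj[root]

    def side_leaves(start: int, banned: int) -> frozenset[str]:
        seen, stack, out = {banned, start}, [start], []
        while stack:
            u = stack.pop()
            if u in label:
                out.append(label[u])
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return frozenset(out)

    for u in adj:
        for v in adj[u]:
            if u > v:
                continue
            side = side_leaves(v, u)
            far = None
            if side == subset:
                far = u
            elif leaf_labels - side == subset:
                far = v
            if far is None:
                continue
            # the split edge is (u, v); `far` sits on the complement side
            near = v if far == u else u
            branches = [side_leaves(w, far) for w in adj[far] if w != near]
            if not branches:
                sister = None
            else:
                sister = tuple(sorted(
                    min(branches, key=lambda s: (len(s), sorted(s)))
                ))
            return CladeReport(True, sister)
    return CladeReport(False, None)
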