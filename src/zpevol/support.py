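"""Bipartition machinery and branch support across replicate trees.

The central objects are *bipartitions*: the splits of the tip set induced by
removing internal branches of an unrooted tree.  Replicate trees estimated
from replicate alignments of the same sequences are combined into a
majority-rule consensus whose branches carry two support measures:

* **BRP** (branch recovery proportion): the fraction of replicate trees that
  contain the branch's bipartition exactly.  Analogous to a bootstrap
  proportion, but replication is over alignments rather than resampled
  columns.
* **TBE** (transfer bootstrap expectation): ``mean(1 - delta/(p-1))`` over
  replicate trees, where ``delta`` is the transfer distance — the minimum
  number of tips that must be moved to turn some branch of the replicate
  tree into the reference bipartition — and ``p`` is the size of the
  bipartition's smaller side.  TBE is gentler on branches destabilized by a
  few rogue taxa and always satisfies ``TBE >= BRP``.

Also provided: normalized and branch-length-weighted Robinson–Foulds
distances, Pearson concordance of branch-length vectors, and a
neighbor-joining fallback so the pipeline can run end to end when no
externally estimated trees are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .trees import Node, Tree


class InputError(ValueError):
    """Inconsistent inputs (e.g. tip-set mismatch between trees)."""


@dataclass(frozen=True)
class Bipartition:
    """Canonical form of an unrooted split.

    ``side`` is the half of the tip set that excludes the reference tip
    (the lexicographically smallest label in ``universe``), which makes the
    representation unique; ``p`` is the size of the smaller half.
    """

    side: FrozenSet[str]
    universe: FrozenSet[str]

    @property
    def n_tips(self) -> int:
        return len(self.universe)

    @property
    def p(self) -> int:
        return min(len(self.side), self.n_tips - len(self.side))

    def smaller_side(self) -> FrozenSet[str]:
        if len(self.side) * 2 <= self.n_tips:
            return self.side
        return self.universe - self.side

    def __repr__(self) -> str:  # pragma: no cover
        return f"Bipartition({sorted(self.side)}|rest, n={self.n_tips})"


def make_bipartition(one_side: Iterable[str], universe: Iterable[str]) -> Bipartition:
    """Build the canonical bipartition separating ``one_side`` from the rest."""
    side = frozenset(one_side)
    uni = frozenset(universe)
    if not side < uni or len(side) < 2 or len(uni - side) < 2:
        raise ValueError("bipartition sides must be proper, non-trivial subsets")
    ref = min(uni)
    return Bipartition(uni - side if ref in side else side, uni)


def _canonical(tips_below: FrozenSet[str], all_tips: FrozenSet[str], ref: str) -> FrozenSet[str]:
    return all_tips - tips_below if ref in tips_below else tips_below


def bipartitions(tree: Tree) -> FrozenSet[Bipartition]:
    """Non-trivial bipartitions of ``tree`` viewed as unrooted.

    A fully resolved unrooted tree with *n* tips has exactly ``n - 3``.
    """
    all_tips = frozenset(tree.tip_names())
    n = len(all_tips)
    if n < 4:
        return frozenset()
    ref = min(all_tips)
    below: Dict[Node, FrozenSet[str]] = {}
    out = set()
    for nd in tree.postorder():
        if nd.is_tip:
            below[nd] = frozenset([nd.name])
        else:
            below[nd] = frozenset().union(*(below[c] for c in nd.children))
        if nd is tree.root:
            continue
        s = below[nd]
        if 2 <= len(s) <= n - 2:
            out.add(Bipartition(_canonical(s, all_tips, ref), all_tips))
    return frozenset(out)


def _check_same_tips(trees: Sequence[Tree]) -> FrozenSet[str]:
    tip_sets = [frozenset(t.tip_names()) for t in trees]
    first = tip_sets[0]
    for s in tip_sets[1:]:
        if s != first:
            raise InputError(
                "tip-set mismatch between trees: "
                f"{sorted(first ^ s)[:5]} differ"
            )
    return first


# ---------------------------------------------------------------------------
# Majority-rule consensus with BRP / TBE
# ---------------------------------------------------------------------------

@dataclass
class SupportedBranch:
    bipartition: Bipartition
    brp: float
    tbe: Optional[float] = None


@dataclass
class SupportedTree:
    tree: Tree
    branches: List[SupportedBranch] = field(default_factory=list)

    def support_table(self) -> List[dict]:
        rows = []
        for i, b in enumerate(self.branches):
            rows.append(
                {
                    "branch": i,
                    "smaller_side": ";".join(sorted(b.bipartition.smaller_side())),
                    "brp": b.brp,
                    "tbe": b.tbe,
                }
            )
        return rows


def majority_rule_consensus(trees: Sequence[Tree], compute_tbe: bool = True) -> SupportedTree:
    """Majority-rule consensus of replicate trees with BRP (and TBE) support.

    Retains exactly the bipartitions occurring in strictly more than half of
    the input trees (such splits are guaranteed pairwise compatible);
    branches failing the threshold collapse into polytomies.
    """
    if len(trees) < 2:
        raise InputError("consensus needs at least two trees")
    all_tips = _check_same_tips(trees)
    n = len(all_tips)
    k = len(trees)
    counts: Dict[Bipartition, int] = {}
    for t in trees:
        for bp in bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1
    kept = {bp: c / k for bp, c in counts.items() if c * 2 > k}

    # Build the consensus topology by nesting the kept clades.  Each kept
    # bipartition is represented by its canonical side (the half without the
    # reference tip), which behaves like a clade in the tree rooted at the
    # reference tip's edge.
    ref = min(all_tips)
    root = Node()
    clade_of: Dict[Node, set] = {root: set(all_tips)}
    node_for: Dict[FrozenSet[str], Node] = {}
    tip_nodes = {nm: Node(name=nm) for nm in all_tips}
    for s in sorted(kept, key=lambda bp: -len(bp.side)):
        nd = Node()
        node_for[s.side] = nd
        clade_of[nd] = set(s.side)
    # attach internal nodes then tips, each under the smallest containing clade
    internals = sorted(node_for.items(), key=lambda kv: -len(kv[0]))
    placed: List[Node] = [root]

    def host_for(tipset: set) -> Node:
        best = root
        for nd in placed:
            c = clade_of[nd]
            if tipset <= c and len(c) < len(clade_of[best]):
                if nd is not root and tipset == c:
                    continue
                best = nd
        return best

    for side, nd in internals:
        host = host_for(set(side))
        host.add_child(nd)
        placed.append(nd)
    for nm in sorted(all_tips):
        if nm == ref:
            continue
        host = host_for({nm})
        host.add_child(tip_nodes[nm])
    root.add_child(tip_nodes[ref])

    consensus = Tree(root)
    branches = []
    for side, nd in node_for.items():
        bp = Bipartition(side, all_tips)
        brp = kept[bp]
        t = tbe(bp, trees) if compute_tbe else None
        nd.annotations["BRP"] = brp
        if t is not None:
            nd.annotations["TBE"] = t
        nd.label = f"{brp:.3f}|{t:.3f}" if t is not None else f"{brp:.3f}"
        branches.append(SupportedBranch(bp, brp, t))
    branches.sort(key=lambda b: sorted(b.bipartition.smaller_side()))
    return SupportedTree(consensus, branches)


# ---------------------------------------------------------------------------
# Transfer distance / TBE
# ---------------------------------------------------------------------------

def transfer_index(bp: Bipartition, tree: Tree) -> int:
    """Minimum number of tips to move so that ``tree`` displays ``bp``.

    Minimized over *all* branches of the tree, trivial ones included, so the
    result is 0 iff the bipartition occurs in the tree and never exceeds
    ``p - 1``.
    """
    all_tips = frozenset(tree.tip_names())
    n = len(all_tips)
    if bp.universe != all_tips:
        raise InputError("bipartition tip set does not match the tree")
    b_set = bp.side
    nb = len(b_set)
    best = n
    size: Dict[Node, int] = {}
    inb: Dict[Node, int] = {}
    for nd in tree.postorder():
        if nd.is_tip:
            size[nd] = 1
            inb[nd] = 1 if nd.name in b_set else 0
        else:
            size[nd] = sum(size[c] for c in nd.children)
            inb[nd] = sum(inb[c] for c in nd.children)
        if nd is tree.root:
            continue
        s, c = size[nd], inb[nd]
        d1 = nb + s - 2 * c            # |B Δ E|
        d2 = n - s - nb + 2 * c        # |B Δ (T-E)|
        best = min(best, d1, d2)
    return best


def tbe(bp: Bipartition, trees: Sequence[Tree]) -> float:
    """Transfer bootstrap expectation of a branch over replicate trees."""
    p = bp.p
    if p < 2:
        raise ValueError("TBE is undefined for trivial branches (p < 2)")
    scores = []
    for t in trees:
        delta = transfer_index(bp, t)
        if p == 2:
            scores.append(1.0 if delta == 0 else 0.0)
        else:
            scores.append(1.0 - delta / (p - 1))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Robinson–Foulds distances
# ---------------------------------------------------------------------------

def rf_normalized(t1: Tree, t2: Tree) -> float:
    """Robinson–Foulds distance scaled to [0, 1].

    The symmetric difference of the two bipartition sets divided by its
    maximum attainable value given each tree's resolution (the total number
    of non-trivial bipartitions in both trees); 0 for topologically
    identical trees, 1 for trees sharing no internal branch.
    """
    _check_same_tips([t1, t2])
    s1, s2 = bipartitions(t1), bipartitions(t2)
    denom = len(s1) + len(s2)
    if denom == 0:
        return 0.0
    return len(s1 ^ s2) / denom


def _split_lengths(tree: Tree) -> Dict[Bipartition, float]:
    all_tips = frozenset(tree.tip_names())
    n = len(all_tips)
    ref = min(all_tips)
    below: Dict[Node, FrozenSet[str]] = {}
    out: Dict[Bipartition, float] = {}
    for nd in tree.postorder():
        below[nd] = (
            frozenset([nd.name])
            if nd.is_tip
            else frozenset().union(*(below[c] for c in nd.children))
        )
        if nd is tree.root:
            continue
        s = below[nd]
        if 2 <= len(s) <= n - 2:
            if nd.length is None:
                raise InputError("missing branch length on an internal branch")
            bp = Bipartition(_canonical(s, all_tips, ref), all_tips)
            out[bp] = out.get(bp, 0.0) + nd.length
    return out


def rf_weighted(t1: Tree, t2: Tree) -> float:
    """Branch-length-weighted Robinson–Foulds distance in [0, 1].

    ``sum(|l1 - l2|) / sum(l1 + l2)`` over the union of non-trivial
    bipartitions, with absent splits contributing length 0.  Identical
    trees give 0; trees with disjoint split sets give 1.
    """
    _check_same_tips([t1, t2])
    l1, l2 = _split_lengths(t1), _split_lengths(t2)
    num = den = 0.0
    for bp in set(l1) | set(l2):
        a, b = l1.get(bp, 0.0), l2.get(bp, 0.0)
        num += abs(a - b)
        den += a + b
    if den == 0:
        return 0.0
    return num / den


# ---------------------------------------------------------------------------
# Branch-length concordance
# ---------------------------------------------------------------------------

def branch_length_concordance(length_vectors: Sequence[Sequence[float]]) -> np.ndarray:
    """Pairwise Pearson correlation of replicate branch-length vectors.

    Vectors must align branch-for-branch on one fixed topology.  Pairs
    involving a zero-variance vector are undefined and reported as NaN.
    """
    vecs = [np.asarray(v, dtype=float) for v in length_vectors]
    if len(vecs) < 2:
        raise InputError("need at least two branch-length vectors")
    m = len(vecs[0])
    if m < 3 or any(len(v) != m for v in vecs):
        raise InputError("vectors must share a common length >= 3")
    k = len(vecs)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = vecs[i], vecs[j]
            if vi.std() == 0 or vj.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(vi, vj)[0, 1])
            out[i, j] = out[j, i] = r
    return out


# ---------------------------------------------------------------------------
# Neighbor joining fallback
# ---------------------------------------------------------------------------

_MISSING = set("-.X?")


def p_distance_matrix(rows: Sequence[Tuple[str, str]]) -> Tuple[List[str], np.ndarray]:
    """Pairwise p-distances, excluding sites missing in either sequence."""
    names = [nm for nm, _ in rows]
    seqs = [s.upper() for _, s in rows]
    k = len(names)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            diffs = comparable = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in _MISSING or b in _MISSING:
                    continue
                comparable += 1
                if a != b:
                    diffs += 1
            if comparable == 0:
                raise InputError(
                    f"no comparable sites between {names[i]} and {names[j]}"
                )
            d[i, j] = d[j, i] = diffs / comparable
    return names, d


def nj_tree(rows: Sequence[Tuple[str, str]]) -> Tree:
    """Neighbor-joining tree from an alignment's p-distance matrix.

    Deterministic: ties in the Q criterion are broken by the
    lexicographically smallest pair of cluster labels (a cluster is labeled
    by its smallest member tip).  Negative branch lengths are clamped to 0.
    The result is unrooted (basal trifurcation).
    """
    if len(rows) < 4:
        raise InputError("neighbor joining needs at least four sequences")
    names, dmat = p_distance_matrix(rows)
    nodes: List[Node] = [Node(name=nm) for nm in names]
    labels = list(names)
    d = dmat.copy()
    active = list(range(len(names)))
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                key = (q, min(labels[i], labels[j]), max(labels[i], labels[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_idx = d.shape[0]
        newrow = np.zeros((1, d.shape[1]))
        d = np.vstack([d, newrow])
        d = np.hstack([d, np.zeros((d.shape[0], 1))])
        for m in active:
            if m in (i, j):
                continue
            d[new_idx, m] = d[m, new_idx] = 0.5 * (d[i, m] + d[j, m] - d[i, j])
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [m for m in active if m not in (i, j)] + [new_idx]
    i, j, k = active
    root = Node()
    nodes[i].length = max(0.5 * (d[i, j] + d[i, k] - d[j, k]), 0.0)
    nodes[j].length = max(0.5 * (d[i, j] + d[j, k] - d[i, k]), 0.0)
    nodes[k].length = max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0)
    for nd in (nodes[i], nodes[j], nodes[k]):
        root.add_child(nd)
    return Tree(root)
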