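"""Root placement for unrooted trees: minimal ancestor deviation and midpoint.

MAD rooting evaluates every branch as a candidate root location.  For a
candidate root point r on a branch, each tip pair (b, c) contributes the
relative deviation ``|2*d(a, b)/d(b, c) - 1|`` where ``a`` is the pair's
ancestor relative to r (the root point itself for pairs spanning r, their
ordinary most recent common ancestor otherwise).  The candidate's score is
the root-mean-square of these deviations, and the position rho along the
branch is obtained in closed form as the minimizer of the quadratic part of
the objective.  The branch with the globally smallest score hosts the root.

A clocklike (ultrametric) tree scores exactly 0 at its true root.  Unlike
midpoint rooting, MAD discounts isolated rate-accelerated lineages because
every tip pair votes, not just the single most distant pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Tuple

import numpy as np

from .trees import Node, Tree, TreeError, _reroot_at


class RootingError(TreeError):
    """Tree cannot be rooted (e.g. all branch lengths zero)."""


@dataclass
class RootCandidate:
    """A candidate root position on one branch.

    ``branch`` is the tip set below the branch's child-side endpoint (in
    the arbitrary input orientation); ``rho`` the relative position of the
    root point along the branch measured from that child endpoint;
    ``deviation`` the RMS relative ancestor deviation at that position.
    """

    branch: FrozenSet[str]
    rho: float
    deviation: float

    @property
    def smaller_side(self) -> FrozenSet[str]:
        return self.branch


def _prepare(tree: Tree) -> Tree:
    tree.validate()
    if tree.n_tips < 2:
        raise RootingError("rooting needs at least two tips")
    total = sum((nd.length or 0.0) for nd in tree.preorder() if nd is not tree.root)
    if total <= 0:
        raise RootingError("all branch lengths are zero")
    return tree


def mad_root(tree: Tree, tie_tol: float = 1e-12) -> Tuple[Tree, RootCandidate, List[RootCandidate]]:
    """Root a tree by Minimal Ancestor Deviation.

    Returns the rooted tree, the winning candidate, and the full per-branch
    candidate list (the deviation landscape, sorted by deviation) so root
    ambiguity is visible.  Ties within ``tie_tol`` of the minimum are broken
    by the lexicographically smallest sorted tip set below the branch.
    """
    _prepare(tree)
    tip_names, tipdist = tree.tip_distance_matrix()
    node_tip = tree.node_tip_distances()

    skipped_pairs = 0
    candidates: List[RootCandidate] = []
    below: Dict[Node, FrozenSet[str]] = {}
    for nd in tree.postorder():
        below[nd] = (
            frozenset([nd.name])
            if nd.is_tip
            else frozenset().union(*(below[c] for c in nd.children))
        )
    all_tips = frozenset(tip_names)

    for nd in tree.preorder():
        if nd is tree.root:
            continue
        length = nd.length or 0.0
        b_side = sorted(below[nd])
        c_side = sorted(all_tips - below[nd])
        if not c_side:
            continue
        d_i = node_tip[nd]          # child endpoint
        d_j = node_tip[nd.parent]   # parent endpoint

        # closed-form rho for the spanning pairs' quadratic
        s_inv2 = 0.0
        s_lin = 0.0
        sq_same = 0.0
        n_pairs = 0
        for b in b_side:
            for c in c_side:
                dbc = d_i[b] + length + d_j[c]
                if dbc <= 0:
                    skipped_pairs += 1
                    continue
                n_pairs += 1
                s_inv2 += 1.0 / dbc**2
                s_lin += (dbc - 2.0 * d_i[b]) / dbc**2
        # same-side pairs: ancestor is the ordinary MRCA; independent of rho
        for side, d_end in ((b_side, d_i), (c_side, d_j)):
            for x in range(len(side)):
                for y in range(x + 1, len(side)):
                    b, c = side[x], side[y]
                    dbc = tipdist[b][c]
                    if dbc <= 0:
                        skipped_pairs += 1
                        continue
                    n_pairs += 1
                    d_anc_b = 0.5 * (dbc + d_end[b] - d_end[c])
                    sq_same += (2.0 * d_anc_b / dbc - 1.0) ** 2
        if n_pairs == 0:
            continue
        if length > 0 and s_inv2 > 0:
            x = s_lin / (2.0 * s_inv2)       # distance from child endpoint
            rho = min(max(x / length, 0.0), 1.0)
        else:
            rho = 0.0
        sq_span = 0.0
        for b in b_side:
            for c in c_side:
                dbc = d_i[b] + length + d_j[c]
                if dbc <= 0:
                    continue
                r = 2.0 * (d_i[b] + rho * length) / dbc - 1.0
                sq_span += r * r
        dev = float(np.sqrt((sq_span + sq_same) / n_pairs))
        candidates.append(RootCandidate(frozenset(b_side), rho, dev))

    if skipped_pairs:
        warnings.warn(
            f"{skipped_pairs} tip pair(s) at zero distance skipped in MAD scoring",
            stacklevel=2,
        )
    if not candidates:
        raise RootingError("no valid root candidate")
    candidates.sort(key=lambda c: (c.deviation, sorted(c.branch)))
    best_dev = candidates[0].deviation
    ties = [c for c in candidates if c.deviation <= best_dev + tie_tol]
    best = min(ties, key=lambda c: sorted(c.branch))
    rooted = _root_at_candidate(tree, best)
    return rooted, best, candidates


def _root_at_candidate(tree: Tree, cand: RootCandidate) -> Tree:
    t = tree.copy()
    target = None
    for nd in t.preorder():
        if nd is t.root:
            continue
        names = frozenset(x.name for x in Tree(nd).tips())
        if names == cand.branch:
            target = nd
            break
    if target is None:  # pragma: no cover - internal consistency
        raise RootingError("candidate branch disappeared from tree")
    return _reroot_at(t, target, cand.rho * (target.length or 0.0))


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest tip-to-tip path."""
    _prepare(tree)
    names, dist = tree.tip_distance_matrix()
    best = None
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            key = (-dist[a][b], a, b)
            if best is None or key < best:
                best = key
    dmax, a, b = -best[0], best[1], best[2]
    if dmax <= 0:
        raise RootingError("all tip-to-tip distances are zero")
    half = dmax / 2.0

    # walk the a -> b path and find the edge containing the midpoint
    parent_map = {tree.root: None}
    for nd in tree.preorder():
        for c in nd.children:
            parent_map[c] = nd
    tips = {t.name: t for t in tree.tips()}

    def path_to_root(nd: Node) -> List[Node]:
        out = [nd]
        while parent_map[out[-1]] is not None:
            out.append(parent_map[out[-1]])
        return out

    pa, pb = path_to_root(tips[a]), path_to_root(tips[b])
    sa, sb = set(pa), set(pb)
    lca = next(nd for nd in pa if nd in sb)
    path = pa[: pa.index(lca) + 1] + list(reversed(pb[: pb.index(lca)]))
    # walk from a toward b
    walked = 0.0
    for idx in range(len(path) - 1):
        cur, nxt = path[idx], path[idx + 1]
        child = cur if parent_map[cur] is nxt else nxt  # edge's child-side node
        step = child.length or 0.0
        if walked + step >= half - 1e-15:
            offset = half - walked  # distance from `cur` along this edge
            dist_from_child = offset if child is cur else step - offset
            t = tree.copy()
            target = _find_matching_edge(t, tree, child)
            return _reroot_at(t, target, min(max(dist_from_child, 0.0), step))
        walked += step
    raise RootingError("midpoint not found on path")  # pragma: no cover


def _find_matching_edge(copy_tree: Tree, orig_tree: Tree, orig_node: Node) -> Node:
    wanted = frozenset(x.name for x in Tree(orig_node).tips())
    for nd in copy_tree.preorder():
        if nd is copy_tree.root:
            continue
        if frozenset(x.name for x in Tree(nd).tips()) == wanted:
            return nd
    raise RootingError("edge not found in copy")  # pragma: no cover


@dataclass
class RootComparison:
    mad_branch: FrozenSet[str]
    midpoint_branch: FrozenSet[str]
    same_branch: bool
    mad_deviation: float


def root_comparison(tree: Tree) -> RootComparison:
    """Run MAD and midpoint rooting and report whether they agree.

    Branches are identified by the tip set of the smaller root child, which
    is invariant to the input tree's internal orientation.
    """
    mad_tree, best, _ = mad_root(tree)
    mid_tree = midpoint_root(tree)

    def root_branch(t: Tree) -> FrozenSet[str]:
        sides = [frozenset(x.name for x in Tree(c).tips()) for c in t.root.children]
        return min(sides, key=lambda s: (len(s), sorted(s)))

    mb = root_branch(mad_tree)
    pb = root_branch(mid_tree)
    return RootComparison(mb, pb, mb == pb, best.deviation)
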