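"""Shared fixtures and independent oracle helpers.

The oracle helpers deliberately avoid the package's own tree machinery:
they work on plain adjacency dictionaries built directly from parent/child
links, so they provide an independent route to the same quantities.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, List, Set, Tuple

import numpy as np
import pytest

from zpevol.trees import Node, Tree, unroot
from zpevol.synthetic import SyntheticSpec, make_fixture_bundle


# ---------------------------------------------------------------------------
# Random tree construction
# ---------------------------------------------------------------------------

def random_resolved_tree(
    names: List[str],
    rng: np.random.Generator,
    min_len: float = 0.05,
    max_len: float = 1.0,
) -> Tree:
    """Random fully resolved unrooted tree with uniform branch lengths."""
    nodes = [Node(name=names[0]), Node(name=names[1])]
    root = Node(children=nodes)
    edges = list(nodes)
    for nm in names[2:]:
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        parent.remove_child(target)
        mid = Node()
        mid.add_child(target)
        tip = Node(name=nm)
        mid.add_child(tip)
        parent.add_child(mid)
        edges.extend([tip, mid])
    t = Tree(root)
    for nd in t.preorder():
        if nd is not root:
            nd.length = float(rng.uniform(min_len, max_len))
    return unroot(t)


def random_rooted_topology(names: List[str], rng: np.random.Generator) -> Tree:
    """Random rooted binary topology (no branch lengths)."""
    nodes = [Node(name=names[0]), Node(name=names[1])]
    root = Node(children=nodes)
    edges = list(nodes)
    for nm in names[2:]:
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        parent.remove_child(target)
        mid = Node()
        mid.add_child(target)
        tip = Node(name=nm)
        mid.add_child(tip)
        parent.add_child(mid)
        edges.extend([tip, mid])
    return Tree(root)


def random_ultrametric_tree(
    names: List[str], rng: np.random.Generator, depth: float = 1.0
) -> Tree:
    """Random rooted binary tree in which every tip is exactly ``depth``
    from the root (a perfect molecular clock)."""
    t = random_rooted_topology(names, rng)

    def assign(nd: Node, height: float) -> None:
        for c in nd.children:
            if c.is_tip:
                c.length = height
            else:
                child_height = height * float(rng.uniform(0.3, 0.8))
                c.length = height - child_height
                assign(c, child_height)

    assign(t.root, depth)
    return t


# ---------------------------------------------------------------------------
# Independent split/graph oracles
# ---------------------------------------------------------------------------

def tree_to_adjacency(tree: Tree) -> Dict[int, List[Tuple[int, float]]]:
    """Plain undirected weighted graph (node ids) from a Tree."""
    ids: Dict[Node, int] = {}
    adj: Dict[int, List[Tuple[int, float]]] = {}
    for nd in tree.preorder():
        ids[nd] = len(ids)
        adj[ids[nd]] = []
    for nd in tree.preorder():
        for c in nd.children:
            w = c.length or 0.0
            adj[ids[nd]].append((ids[c], w))
            adj[ids[c]].append((ids[nd], w))
    return adj


def brute_force_splits(tree: Tree) -> Set[FrozenSet[str]]:
    """All non-trivial splits, computed by deleting each edge of the
    undirected graph and collecting one component's tips."""
    name_of: Dict[int, str] = {}
    ids: Dict[Node, int] = {}
    for nd in tree.preorder():
        ids[nd] = len(ids)
        if nd.is_tip:
            name_of[ids[nd]] = nd.name
    edges = []
    for nd in tree.preorder():
        for c in nd.children:
            edges.append((ids[nd], ids[c]))
    adj: Dict[int, Set[int]] = {i: set() for i in ids.values()}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    all_tips = frozenset(name_of.values())
    n = len(all_tips)
    ref = min(all_tips)
    out: Set[FrozenSet[str]] = set()
    for a, b in edges:
        # component containing b after removing edge (a, b)
        seen = {b}
        stack = [b]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if (x, y) in ((a, b), (b, a)) or (y, x) in ((a, b), (b, a)):
                    continue
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(name_of[i] for i in seen if i in name_of)
        if 2 <= len(side) <= n - 2:
            out.add(side if ref not in side else all_tips - side)
    return out


def brute_force_transfer_index(side: FrozenSet[str], tree: Tree) -> int:
    """Exhaustive minimum hamming distance between the bipartition and the
    2-coloring induced by every branch (trivial branches included)."""
    all_tips = frozenset(t.name for t in tree.tips())
    n = len(all_tips)
    best = n
    ids: Dict[Node, int] = {}
    name_of: Dict[int, str] = {}
    for nd in tree.preorder():
        ids[nd] = len(ids)
        if nd.is_tip:
            name_of[ids[nd]] = nd.name
    adj: Dict[int, Set[int]] = {i: set() for i in ids.values()}
    edges = []
    for nd in tree.preorder():
        for c in nd.children:
            edges.append((ids[nd], ids[c]))
            adj[ids[nd]].add(ids[c])
            adj[ids[c]].add(ids[nd])
    for a, b in edges:
        seen = {b}
        stack = [b]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if (x, y) in ((a, b), (b, a)):
                    continue
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        e_side = frozenset(name_of[i] for i in seen if i in name_of)
        d1 = len(side ^ e_side)
        d2 = len(side ^ (all_tips - e_side))
        best = min(best, d1, d2)
    return best


def brute_force_fitch(tree: Tree, tip_labels: Dict[str, str]) -> int:
    """Exhaustive minimum-change count over all internal labelings."""
    states = sorted(set(tip_labels.values()))
    internals = [nd for nd in tree.preorder() if not nd.is_tip]
    best = None
    for combo in itertools.product(states, repeat=len(internals)):
        lab = dict(zip((id(nd) for nd in internals), combo))
        changes = 0
        for nd in tree.preorder():
            for c in nd.children:
                s_p = lab[id(nd)]
                s_c = tip_labels[c.name] if c.is_tip else lab[id(c)]
                if s_p != s_c:
                    changes += 1
        if best is None or changes < best:
            best = changes
    return best


def mad_oracle_deviation(tree: Tree, side: FrozenSet[str], rho: float) -> float:
    """RMS relative ancestor deviation for a root placed at position
    ``rho`` (measured from the child endpoint) on the branch whose
    child-side tip set is ``side`` — computed purely from BFS distances on
    an augmented graph with an explicit root node."""
    ids: Dict[Node, int] = {}
    name_of: Dict[int, str] = {}
    for nd in tree.preorder():
        ids[nd] = len(ids)
        if nd.is_tip:
            name_of[ids[nd]] = nd.name
    target = None
    for nd in tree.preorder():
        if nd is tree.root:
            continue
        tipset = frozenset(t.name for t in Tree(nd).tips())
        if tipset == side:
            target = nd
            break
    assert target is not None
    adj: Dict[int, List[Tuple[int, float]]] = {i: [] for i in ids.values()}
    for nd in tree.preorder():
        for c in nd.children:
            if c is target:
                continue
            w = c.length or 0.0
            adj[ids[nd]].append((ids[c], w))
            adj[ids[c]].append((ids[nd], w))
    # insert the root point on the target edge
    root_id = len(ids)
    adj[root_id] = []
    L = target.length or 0.0
    a, b = ids[target], ids[target.parent]
    adj[root_id].append((a, rho * L))
    adj[a].append((root_id, rho * L))
    adj[root_id].append((b, (1 - rho) * L))
    adj[b].append((root_id, (1 - rho) * L))

    def bfs(src: int) -> Dict[int, float]:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        return dist

    d_root = bfs(root_id)
    tips = sorted(name_of.items())
    sq = []
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            bi, bn = tips[i]
            cj, cn = tips[j]
            dbc = bfs(bi)[cj]
            if dbc <= 0:
                continue
            d_anc_b = 0.5 * (dbc + d_root[bi] - d_root[cj])
            sq.append((2.0 * d_anc_b / dbc - 1.0) ** 2)
    return float(np.sqrt(np.mean(sq)))


# ---------------------------------------------------------------------------
# Shared bundles (expensive; session scope)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default synthetic bundle, written to disk once per session."""
    out = tmp_path_factory.mktemp("bundle")
    spec = SyntheticSpec(seed=11)
    return make_fixture_bundle(spec, str(out))
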