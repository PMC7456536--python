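"""Lightweight phylogenetic tree container and Newick I/O.

Trees are stored as mutable node hierarchies.  A tree whose root has two
children is treated as rooted; an unrooted tree is represented with a basal
trifurcation (or higher multifurcation).  Branch lengths are expected in
substitutions per site and must be non-negative.

Newick parsing is delegated to dendropy; serialization is done here so that
support labels (e.g. ``BRP|TBE``) and per-tip annotation comments can be
written in a controlled format.
"""

from __future__ import annotations

from typing import Callable, Dict, FrozenSet, Iterator, List, Optional, Tuple

import dendropy


class TreeError(ValueError):
    """Malformed tree or invalid tree operation."""


class NewickError(TreeError):
    """Unparseable or inconsistent Newick input."""


class Node:
    __slots__ = ("name", "length", "children", "parent", "label", "annotations")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        children: Optional[List["Node"]] = None,
        label: Optional[str] = None,
    ):
        self.name = name
        self.length = length
        self.children: List[Node] = []
        self.parent: Optional[Node] = None
        self.label = label
        self.annotations: Dict[str, float] = {}
        if children:
            for c in children:
                self.add_child(c)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name or self.label or '*'})"


class Tree:
    """A rooted or unrooted phylogenetic tree over uniquely named tips."""

    def __init__(self, root: Node):
        self.root = root

    # ---- traversal -------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return iter(reversed(out))

    def tips(self) -> List[Node]:
        return [nd for nd in self.preorder() if nd.is_tip]

    def tip_names(self) -> List[str]:
        return [nd.name for nd in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    # ---- bookkeeping -----------------------------------------------------
    def validate(self) -> None:
        names = self.tip_names()
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        if any(n is None for n in names):
            raise TreeError("unnamed tip")
        for nd in self.preorder():
            if nd.length is not None and nd.length < 0:
                raise TreeError(f"negative branch length on {nd!r}")

    def copy(self) -> "Tree":
        def _copy(nd: Node) -> Node:
            new = Node(name=nd.name, length=nd.length, label=nd.label)
            new.annotations = dict(nd.annotations)
            for c in nd.children:
                new.add_child(_copy(c))
            return new

        return Tree(_copy(self.root))

    # ---- geometry --------------------------------------------------------
    def tip_distance_matrix(self) -> Tuple[List[str], Dict[str, Dict[str, float]]]:
        """All pairwise path-length distances between tips."""
        names = sorted(self.tip_names())
        adj: Dict[Node, List[Tuple[Node, float]]] = {}
        for nd in self.preorder():
            for c in nd.children:
                w = c.length if c.length is not None else 0.0
                adj.setdefault(nd, []).append((c, w))
                adj.setdefault(c, []).append((nd, w))
        by_name = {t.name: t for t in self.tips()}
        dist: Dict[str, Dict[str, float]] = {n: {} for n in names}
        for src_name in names:
            src = by_name[src_name]
            seen = {src: 0.0}
            stack = [src]
            while stack:
                nd = stack.pop()
                for nb, w in adj.get(nd, []):
                    if nb not in seen:
                        seen[nb] = seen[nd] + w
                        stack.append(nb)
            for t in names:
                dist[src_name][t] = seen[by_name[t]]
        return names, dist

    def node_tip_distances(self) -> Dict[Node, Dict[str, float]]:
        """Path length from every node to every tip."""
        down: Dict[Node, Dict[str, float]] = {}
        for nd in self.postorder():
            if nd.is_tip:
                down[nd] = {nd.name: 0.0}
            else:
                d: Dict[str, float] = {}
                for c in nd.children:
                    w = c.length or 0.0
                    for t, x in down[c].items():
                        d[t] = x + w
                down[nd] = d
        full: Dict[Node, Dict[str, float]] = {self.root: dict(down[self.root])}
        for nd in self.preorder():
            if nd is self.root:
                continue
            w = nd.length or 0.0
            d = dict(down[nd])
            up = full[nd.parent]
            for t, x in up.items():
                if t not in d:
                    d[t] = x + w
            full[nd] = d
        return full

    # ---- serialization ---------------------------------------------------
    def to_newick(
        self,
        label_for: Optional[Callable[[Node], Optional[str]]] = None,
        annotations: bool = False,
        precision: int = 10,
    ) -> str:
        def fmt_len(nd: Node) -> str:
            if nd.length is None:
                return ""
            return f":{nd.length:.{precision}g}"

        def fmt_comment(nd: Node) -> str:
            if not annotations or not nd.annotations:
                return ""
            inner = ",".join(f"{k}={v:.6g}" for k, v in sorted(nd.annotations.items()))
            return f"[&{inner}]"

        def rec(nd: Node) -> str:
            if nd.is_tip:
                return f"{_quote(nd.name)}{fmt_comment(nd)}{fmt_len(nd)}"
            inner = ",".join(rec(c) for c in nd.children)
            if label_for is not None:
                lab = label_for(nd) or ""
            else:
                lab = nd.label or ""
            return f"({inner}){_quote(lab) if lab else ''}{fmt_comment(nd)}{fmt_len(nd)}"

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree(n_tips={self.n_tips}, rooted={self.is_rooted})"


def _quote(label: str) -> str:
    if label and any(ch in label for ch in "(),:;[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Newick I/O (parsing via dendropy)
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Internal node labels are preserved as support annotations
    (``Node.label``); ``[&key=value]`` comments become float annotations
    where they parse as numbers.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            extract_comment_metadata=True,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except (dendropy.utility.error.DataParseError, Exception) as exc:
        if isinstance(exc, (ValueError, dendropy.utility.error.DataParseError)) or (
            "dendropy" in type(exc).__module__
        ):
            raise NewickError(f"invalid Newick: {exc}") from exc
        raise

    def convert(dnode: dendropy.Node) -> Node:
        name = dnode.taxon.label if dnode.taxon is not None else None
        nd = Node(
            name=name if not dnode.child_nodes() else None,
            length=dnode.edge.length,
            label=dnode.label if dnode.child_nodes() else None,
        )
        if dnode.child_nodes() and name and nd.label is None:
            nd.label = name
        for a in dnode.annotations:
            try:
                nd.annotations[a.name] = float(a.value)
            except (TypeError, ValueError):
                pass
        for ch in dnode.child_nodes():
            nd.add_child(convert(ch))
        return nd

    tree = Tree(convert(dtree.seed_node))
    tree.validate()
    return tree


def read_newick(path) -> Tree:
    """Read a single tree from a Newick file."""
    with open(path) as fh:
        text = fh.read().strip()
    if not text:
        raise NewickError(f"empty Newick file: {path}")
    return parse_newick(text)


def read_newick_trees(path) -> List[Tree]:
    """Read every tree in a multi-tree Newick file (one per ';')."""
    with open(path) as fh:
        text = fh.read()
    chunks = [c.strip() for c in text.split(";") if c.strip()]
    return [parse_newick(c + ";") for c in chunks]


def write_newick(tree: Tree, path, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(**kwargs) + "\n")


# ---------------------------------------------------------------------------
# Rerooting
# ---------------------------------------------------------------------------

def unroot(tree: Tree) -> Tree:
    """Collapse a two-child root into a basal multifurcation (copy)."""
    t = tree.copy()
    if len(t.root.children) == 2 and not all(c.is_tip for c in t.root.children):
        a, b = t.root.children
        dissolve = a if not a.is_tip else b
        other = b if dissolve is a else a
        t.root.remove_child(dissolve)
        for c in list(dissolve.children):
            dissolve.remove_child(c)
            t.root.add_child(c)
        other.length = (other.length or 0.0) + (dissolve.length or 0.0)
    return t


def root_on_edge(tree: Tree, child_tips: FrozenSet[str], dist_from_child: float) -> Tree:
    """Return a copy rooted on the edge above the clade whose tip set is
    ``child_tips``, at ``dist_from_child`` along the branch (measured from
    the child-side endpoint)."""
    t = tree.copy()
    target = None
    for nd in t.preorder():
        if nd is t.root:
            continue
        below = frozenset(x.name for x in Tree(nd).tips())
        if below == child_tips:
            target = nd
            break
    if target is None:
        raise TreeError("edge not found for requested tip set")
    return _reroot_at(t, target, dist_from_child)


def _reroot_at(t: Tree, child: Node, dist_from_child: float) -> Tree:
    length = child.length or 0.0
    if not (-1e-12 <= dist_from_child <= length + 1e-12):
        raise TreeError("root position outside the branch")
    dist_from_child = min(max(dist_from_child, 0.0), length)
    parent = child.parent
    parent.remove_child(child)
    new_root = Node()
    child.length = dist_from_child
    new_root.add_child(child)
    flipped = _flip_to(parent)
    flipped.length = length - dist_from_child
    new_root.add_child(flipped)
    out = Tree(new_root)
    _suppress_unary_nodes(out)
    return out


def _flip_to(node: Node) -> Node:
    """Reverse parent links so that ``node`` becomes a subtree root."""
    if node.parent is None:
        return node
    parent = node.parent
    parent.remove_child(node)
    up = _flip_to(parent)
    up.length = node.length
    node.add_child(up)
    node.parent = None
    return node


def _suppress_unary_nodes(tree: Tree) -> None:
    """Merge away degree-2 artifacts left by rerooting (the old root)."""
    changed = True
    while changed:
        changed = False
        for nd in list(tree.preorder()):
            if nd is tree.root or nd.is_tip or len(nd.children) != 1:
                continue
            only = nd.children[0]
            nd.remove_child(only)
            only.length = (only.length or 0.0) + (nd.length or 0.0)
            parent = nd.parent
            idx = parent.children.index(nd)
            parent.remove_child(nd)
            only.parent = parent
            parent.children.insert(idx, only)
            changed = True
            break


def is_binary_unrooted(tree: Tree) -> bool:
    """True if the tree is fully resolved when viewed as unrooted."""
    for nd in tree.preorder():
        k = len(nd.children)
        if nd is tree.root:
            if k not in (2, 3):
                return False
        elif not nd.is_tip and k != 2:
            return False
    return True
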