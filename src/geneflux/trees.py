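"""Rooted species trees: Newick I/O, least-squares midpoint rooting, depth geometry.

Branch lengths are in nucleotide substitutions per site throughout. Trees are
small (tens of leaves), so all algorithms favour clarity over asymptotics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "TreeNode",
    "RootedTree",
    "NewickError",
    "parse_newick",
    "write_newick",
    "midpoint_root_ls",
    "branch_midpoint_depth",
    "mean_root_to_leaf_depth",
]


class NewickError(ValueError):
    """Malformed Newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: Optional[float] = None  # branch above this node; None only at root
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)


class RootedTree:
    """A rooted tree with unique leaf labels and non-negative branch lengths.

    Edges are identified by their child node's post-order index (the root,
    which has no edge above it, is excluded from the edge index space).
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[TreeNode]:
        """Non-root nodes in post-order; the edge id of a node is its index here."""
        return [n for n in self.postorder() if n.parent is not None]

    # -- geometry ----------------------------------------------------------

    def node_depths(self) -> dict[int, float]:
        """Distance from the root to each node, keyed by id(node)."""
        depths = {id(self.root): 0.0}
        for node in self.preorder():
            if node.parent is not None:
                depths[id(node)] = depths[id(node.parent)] + node.length
        return depths

    def total_length(self) -> float:
        return sum(n.length for n in self.edges())

    def leaf_distance_matrix(self) -> dict[tuple[str, str], float]:
        """Pairwise leaf-to-leaf path lengths (unordered label pairs)."""
        depths = self.node_depths()
        leaves_under: dict[int, list[tuple[str, float]]] = {}
        dist: dict[tuple[str, str], float] = {}
        for node in self.postorder():
            if node.is_leaf:
                leaves_under[id(node)] = [(node.name, 0.0)]
            else:
                groups = []
                for child in node.children:
                    sub = [(lab, d + child.length) for lab, d in leaves_under.pop(id(child))]
                    groups.append(sub)
                merged = []
                for i in range(len(groups)):
                    for j in range(i + 1, len(groups)):
                        for la, da in groups[i]:
                            for lb, db in groups[j]:
                                key = (la, lb) if la < lb else (lb, la)
                                dist[key] = da + db
                    merged.extend(groups[i])
                leaves_under[id(node)] = merged
        del depths
        return dist

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        for node in self.postorder():
            if node.parent is None:
                continue
            if node.length is None:
                raise ValueError(f"missing branch length above node {node.name!r}")
            if not (node.length >= 0.0) or node.length != node.length or node.length == float("inf"):
                raise ValueError(f"invalid branch length {node.length!r} above node {node.name!r}")

    def copy(self) -> "RootedTree":
        return parse_newick(write_newick(self))


# -- Newick parsing --------------------------------------------------------

_TOKEN = re.compile(r"\s*([(),;:]|[^\s(),;:\[\]]+)")


def _strip_comments(text: str) -> str:
    # Newick comments in [...] carry no information we use; strip them while
    # keeping character offsets meaningful enough for error messages.
    return re.sub(r"\[[^\]]*\]", "", text)


def parse_newick(text: str) -> RootedTree:
    """Parse a Newick string into a :class:`RootedTree`.

    Branch lengths are required on every non-root node. Internal node labels
    (e.g. bootstrap values) are tolerated and discarded.
    """
    text = _strip_comments(text)
    pos = 0
    n = len(text)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def peek() -> str:
        skip_ws()
        return text[pos] if pos < n else ""

    def read_label() -> str:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] in "'\"":
            quote = text[pos]
            end = text.find(quote, pos + 1)
            if end < 0:
                raise NewickError("unterminated quoted label", pos)
            label = text[pos + 1 : end]
            pos = end + 1
            return label
        m = re.match(r"[^\s(),;:\[\]]+", text[pos:])
        if not m:
            return ""
        pos += m.end()
        return m.group(0)

    def read_length(node: TreeNode) -> None:
        nonlocal pos
        if peek() == ":":
            pos += 1
            skip_ws()
            m = re.match(r"[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?", text[pos:])
            if not m:
                raise NewickError("expected branch length after ':'", pos)
            node.length = float(m.group(0))
            pos += m.end()

    def read_clade() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if peek() == "(":
            pos += 1
            while True:
                node.add_child(read_clade())
                ch = peek()
                if ch == ",":
                    pos += 1
                    continue
                if ch == ")":
                    pos += 1
                    break
                raise NewickError("expected ',' or ')'", pos)
            label = read_label()  # internal label: discard content, keep leaves only
            if label and node.is_leaf:
                node.name = label
        else:
            label = read_label()
            if not label:
                raise NewickError("expected a leaf label", pos)
            node.name = label
        read_length(node)
        return node

    root = read_clade()
    if peek() != ";":
        raise NewickError("expected ';' at end of tree", pos)
    pos += 1
    skip_ws()
    if pos != n:
        raise NewickError("trailing characters after ';'", pos)
    root.length = None  # a length on the root edge has no parent to attach to
    stack = [root]
    while stack:
        cur = stack.pop()
        if cur.parent is not None and cur.length is None:
            raise NewickError(f"missing branch length for node {cur.name or '(internal)'}", pos)
        stack.extend(cur.children)
    return RootedTree(root)


def _format_length(x: float) -> str:
    return repr(float(x))


def write_newick(tree: RootedTree) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            core = _quote(node.name)
        else:
            core = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.parent is not None:
            core += ":" + _format_length(node.length)
        return core

    def _quote(label: str) -> str:
        if re.search(r"[\s(),;:\[\]]", label):
            return "'" + label + "'"
        return label

    return fmt(tree.root) + ";"


# -- rooting ---------------------------------------------------------------


def _unrooted_adjacency(tree: RootedTree) -> tuple[list[object], dict[int, list[tuple[object, float]]]]:
    """Undirected weighted graph over tree nodes; degree-2 roots are elided."""
    adj: dict[int, list[tuple[object, float]]] = {}
    nodes: list[object] = []

    def add(a: TreeNode, b: TreeNode, w: float) -> None:
        adj.setdefault(id(a), []).append((b, w))
        adj.setdefault(id(b), []).append((a, w))

    for node in tree.postorder():
        nodes.append(node)
        for child in node.children:
            add(node, child, child.length)

    root = tree.root
    if len(root.children) == 2:
        # the root is a rooting artifact: merge its two incident edges
        a, b = root.children
        w = a.length + b.length
        adj[id(a)] = [(x, d) for x, d in adj[id(a)] if x is not root] + [(b, w)]
        adj[id(b)] = [(x, d) for x, d in adj[id(b)] if x is not root] + [(a, w)]
        del adj[id(root)]
        nodes.remove(root)
    return nodes, adj


def midpoint_root_ls(tree: RootedTree) -> RootedTree:
    """Re-root at the point minimizing the variance of root-to-leaf distances.

    The candidate root may fall anywhere along any edge (the edge is split).
    On each edge the variance is a quadratic in the root position, so the
    optimum is found in closed form per edge and the global minimum taken;
    ties break toward the edge encountered first.
    """
    nodes, adj = _unrooted_adjacency(tree)
    leaves = [n for n in nodes if n.is_leaf]
    if len(leaves) < 2:
        raise ValueError("need at least 2 leaves to root")
    if all(w == 0.0 for nbrs in adj.values() for _, w in nbrs):
        raise ValueError("all branch lengths are zero; root position undefined")

    # distances from every node to every leaf, by BFS from each leaf
    dist_to_leaf: dict[int, dict[int, float]] = {id(n): {} for n in nodes}
    for leaf in leaves:
        seen = {id(leaf): 0.0}
        stack = [leaf]
        while stack:
            cur = stack.pop()
            for nxt, w in adj[id(cur)]:
                if id(nxt) not in seen:
                    seen[id(nxt)] = seen[id(cur)] + w
                    stack.append(nxt)
        for node in nodes:
            dist_to_leaf[id(node)][id(leaf)] = seen[id(node)]

    nleaf = len(leaves)
    best: Optional[tuple[float, TreeNode, TreeNode, float]] = None  # (var, a, b, x from a)
    seen_edges: set[frozenset[int]] = set()
    for a in nodes:
        for b, w in adj[id(a)]:
            key = frozenset((id(a), id(b)))
            if key in seen_edges:
                continue
            seen_edges.add(key)
            # Classify leaves by which endpoint they are reached through.
            # Root at distance x from `a` along the edge (0 <= x <= w):
            # leaves on a's side are at d_a + x, leaves on b's side at d_b + (w - x).
            da = dist_to_leaf[id(a)]
            db = dist_to_leaf[id(b)]
            coeff = []  # (sign, intercept): distance = intercept + sign * x
            for leaf in leaves:
                if da[id(leaf)] <= db[id(leaf)] - w + 1e-15:  # through a
                    coeff.append((1.0, da[id(leaf)]))
                else:
                    coeff.append((-1.0, db[id(leaf)] + w))
            s = sum(c[0] for c in coeff)
            t0 = sum(c[1] for c in coeff)
            sum_sq = lambda x: sum((c[1] + c[0] * x) ** 2 for c in coeff)
            mean = lambda x: (t0 + s * x) / nleaf
            var = lambda x: sum_sq(x) / nleaf - mean(x) ** 2
            # d var/dx = 2/n [ sum(sign*(i + sign x)) ] - 2 mean * s/n ; solve linear
            a2 = nleaf - s * s / nleaf  # coefficient of x^2 (times 1/n), >= 0
            b1 = sum(c[0] * c[1] for c in coeff) - s * t0 / nleaf
            if a2 > 1e-300:
                x_star = -b1 / a2
            else:
                x_star = 0.0
            x_star = min(max(x_star, 0.0), w)
            v = var(x_star)
            if best is None or v < best[0] - 1e-15:
                best = (v, a, b, x_star)

    _, a, b, x = best
    return _reroot_at_point(nodes, adj, a, b, x)


def _reroot_at_point(nodes, adj, a: TreeNode, b: TreeNode, x: float) -> RootedTree:
    """Build a new rooted tree with the root x along the (a, b) edge from a."""
    w = next(wt for nb, wt in adj[id(a)] if nb is b)

    def build(node: TreeNode, came_from: Optional[TreeNode], came_weight: float) -> TreeNode:
        fresh = TreeNode(name=node.name, length=came_weight)
        for nxt, wt in adj[id(node)]:
            if nxt is came_from:
                continue
            fresh.add_child(build(nxt, node, wt))
        return fresh

    root = TreeNode()
    if x <= 0.0:
        # root exactly at node a
        ra = build(a, None, None)
        root = ra
        root.length = None
        # need children on both sides; build() from a already spans everything
        return RootedTree(root)
    if x >= w:
        rb = build(b, None, None)
        rb.length = None
        return RootedTree(rb)
    left = build(a, b, x)
    right = build(b, a, w - x)
    root.add_child(left)
    root.add_child(right)
    return RootedTree(root)


# -- depth geometry --------------------------------------------------------


def branch_midpoint_depth(tree: RootedTree, edge_id: int) -> float:
    """Root-to-parent distance plus half the edge's own length."""
    edges = tree.edges()
    if not (0 <= edge_id < len(edges)):
        raise KeyError(f"unknown edge id {edge_id} (tree has {len(edges)} edges)")
    node = edges[edge_id]
    depths = tree.node_depths()
    return depths[id(node.parent)] + node.length / 2.0


def mean_root_to_leaf_depth(tree: RootedTree) -> float:
    depths = tree.node_depths()
    leaf_depths = [depths[id(n)] for n in tree.leaves()]
    return sum(leaf_depths) / len(leaf_depths)
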