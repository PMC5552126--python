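"""Rooted binary time-trees with node heights.

Leaves sit at height 0 (time before present); every parent is strictly
older than its children.  Branch durations are implied by height
differences.  This is the object the MCMC proposals act on, so it is kept
deliberately small: mutable nodes, explicit post-order lists, cheap deep
copies.  Newick parsing of externally supplied trees goes through dendropy
(see :mod:`cognatree.classification`); the writers here emit plain Newick
and the NEXUS tree-log dialect with a translate block.
"""

from __future__ import annotations

from .errors import ModelError

HEIGHT_TOL = 1e-9


class Node:
    __slots__ = ("parent", "children", "height", "label", "index", "pid")

    def __init__(self, label: str | None = None, height: float = 0.0):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.height = height
        self.label = label
        self.index = -1   # position in the current post-order (volatile)
        self.pid = -1     # persistent id, survives topology moves and copies

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)


class PhyloTree:
    """A rooted, strictly bifurcating tree over labelled leaves."""

    def __init__(self, root: Node):
        self.root = root
        self.reindex()
        if any(n.pid < 0 for n in self.postorder):
            for i, node in enumerate(self.postorder):
                node.pid = i

    # -- bookkeeping -------------------------------------------------------
    def reindex(self) -> None:
        """Rebuild the post-order node list and leaf table."""
        post: list[Node] = []

        def walk(node: Node) -> None:
            for c in node.children:
                walk(c)
            post.append(node)

        walk(self.root)
        self.postorder = post
        for i, node in enumerate(post):
            node.index = i
        self.leaves = [n for n in post if n.is_leaf]
        self.leaf_labels = [n.label for n in self.leaves]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder if not n.is_leaf]

    def validate(self) -> None:
        for node in self.postorder:
            if node.is_leaf:
                if abs(node.height) > HEIGHT_TOL:
                    raise ModelError(f"leaf {node.label} not at height 0")
            else:
                if len(node.children) != 2:
                    raise ModelError("tree is not strictly bifurcating")
                for c in node.children:
                    if not node.height > c.height:
                        raise ModelError(
                            f"parent height {node.height} not above child "
                            f"height {c.height}")

    def duration(self, node: Node) -> float:
        """Length of the branch above *node* (0 for the root)."""
        return 0.0 if node.parent is None else node.parent.height - node.height

    def total_length(self) -> float:
        return sum(self.duration(n) for n in self.postorder if n.parent)

    def clade_leafset(self, node: Node) -> frozenset:
        out = []

        def walk(n: Node) -> None:
            if n.is_leaf:
                out.append(n.label)
            else:
                for c in n.children:
                    walk(c)

        walk(node)
        return frozenset(out)

    def clades(self) -> dict[frozenset, Node]:
        """Leaf set -> node, for every internal node."""
        sets: dict[int, frozenset] = {}
        out: dict[frozenset, Node] = {}
        for node in self.postorder:
            if node.is_leaf:
                sets[node.index] = frozenset([node.label])
            else:
                s = frozenset().union(*(sets[c.index] for c in node.children))
                sets[node.index] = s
                out[s] = node
        return out

    def mrca(self, labels) -> Node:
        """Most recent common ancestor of the given leaf labels."""
        want = set(labels)
        found: dict[int, set] = {}
        for node in self.postorder:
            if node.is_leaf:
                found[node.index] = {node.label} & want
            else:
                found[node.index] = set().union(
                    *(found[c.index] for c in node.children))
            if found[node.index] == want:
                return node
        raise ModelError(f"labels {sorted(want)} not all present in tree")

    def is_monophyletic(self, labels) -> bool:
        want = frozenset(labels)
        if not want <= set(self.leaf_labels):
            return False
        if len(want) <= 1 or want == frozenset(self.leaf_labels):
            return True
        node = self.mrca(want)
        return self.clade_leafset(node) == want

    # -- copy --------------------------------------------------------------
    def copy(self) -> "PhyloTree":
        mapping: dict[int, Node] = {}
        for node in self.postorder:
            clone = Node(node.label, node.height)
            clone.pid = node.pid
            mapping[node.index] = clone
            for c in node.children:
                clone.add_child(mapping[c.index])
        return PhyloTree(mapping[self.root.index])

    # -- serialisation -----------------------------------------------------
    def to_newick(self, fmt: str = "%.17g",
                  translate: dict[str, str] | None = None) -> str:
        def render(node: Node) -> str:
            if node.is_leaf:
                name = translate[node.label] if translate else node.label
            else:
                name = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.parent is None:
                return name
            return name + ":" + (fmt % self.duration(node))

        return render(self.root) + ";"

    def patristic_distance(self, a: str, b: str) -> float:
        node = self.mrca({a, b})
        return 2.0 * node.height  # leaves at height 0


def from_parent_lists(labels: list[str], merges: list[tuple[int, int, float]]) -> PhyloTree:
    """Build a tree from leaf labels and a merge schedule.

    *merges* is a list of ``(i, j, height)`` joining the current lineages at
    positions ``i`` and ``j`` (coalescent-style construction, used by the
    Yule simulator and the constrained-start builder).
    """
    lineages: list[Node] = [Node(lbl, 0.0) for lbl in labels]
    for i, j, height in merges:
        a, b = lineages[i], lineages[j]
        parent = Node(None, height)
        parent.add_child(a)
        parent.add_child(b)
        hi, lo = max(i, j), min(i, j)
        lineages.pop(hi)
        lineages.pop(lo)
        lineages.append(parent)
    if len(lineages) != 1:
        raise ModelError("merge schedule did not reduce to a single root")
    return PhyloTree(lineages[0])
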