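"""Lightweight rooted-representation phylogenetic trees.

Trees are stored as node objects with parent/child links and branch lengths.
An unrooted tree is represented rooted at an arbitrary (usually trifurcating)
internal node; all algorithms that care (bipartitions, path distances,
subfamily assignment) work on the unrooted interpretation.

Newick input is parsed with dendropy; a trailing ``#<k>`` on a label marks
the branch above that node as foreground (the codeml convention for
branch-site models).
"""

from __future__ import annotations

import itertools
import re
from typing import Iterable, Iterator

import dendropy

_FOREGROUND_RE = re.compile(r"\s*#\s*(\d+)\s*$")


class Node:
    __slots__ = ("name", "length", "children", "parent", "foreground")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)  # branch above this node
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.foreground = False

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.name or ''} {kind} l={self.length:g}>"


class Tree:
    """A tree rooted for bookkeeping; semantically unrooted unless stated."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal -------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    def find_leaf(self, name: str) -> Node:
        for n in self.leaves:
            if n.name == name:
                return n
        raise KeyError(f"leaf {name!r} not in tree")

    # -- construction ----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )

        def convert(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            foreground = False
            if label is not None:
                m = _FOREGROUND_RE.search(label)
                if m:
                    foreground = True
                    label = label[: m.start()] or None
            node = Node(label, dnode.edge.length or 0.0)
            node.foreground = foreground
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            tag = "#1" if node.foreground else ""
            if node.is_leaf:
                return f"{node.name}{tag}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = node.name or ""
            if node is self.root:
                return f"({inner}){label}{tag}"
            return f"({inner}){label}{tag}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def copy(self) -> "Tree":
        return Tree.from_newick(self.to_newick())

    # -- unrooted structure ----------------------------------------------
    def mark_foreground(self, branch_ids: Iterable[str]) -> None:
        """Mark branches above the named nodes as foreground.

        Branch ids are leaf names or internal-node labels.
        """
        wanted = set(branch_ids)
        found = set()
        for node in self.postorder():
            if node.name in wanted:
                node.foreground = True
                found.add(node.name)
        missing = wanted - found
        if missing:
            raise KeyError(f"branch ids not in tree: {sorted(missing)}")

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    def bipartitions(self) -> list[tuple[frozenset, Node]]:
        """(leaf-set below the branch, child node) for every internal branch.

        Trivial bipartitions (single leaves and the full set) are included;
        callers filter as needed.
        """
        below: dict[Node, frozenset] = {}
        result = []
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.name])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
            if node is not self.root:
                result.append((below[node], node))
        return result

    def path_distances(self, weighted: bool = True) -> dict[tuple[str, str], float]:
        """All pairwise leaf distances (branch-length sums, or edge counts)."""
        # distances from every node down to its descendant leaves
        down: dict[Node, dict[str, float]] = {}
        for node in self.postorder():
            if node.is_leaf:
                down[node] = {node.name: 0.0}
            else:
                acc: dict[str, float] = {}
                for c in node.children:
                    step = c.length if weighted else 1.0
                    for leaf, d in down[c].items():
                        acc[leaf] = d + step
                down[node] = acc
        out: dict[tuple[str, str], float] = {}
        for node in self.postorder():
            if node.is_leaf:
                continue
            kids = node.children
            for c1, c2 in itertools.combinations(kids, 2):
                s1 = c1.length if weighted else 1.0
                s2 = c2.length if weighted else 1.0
                for l1, d1 in down[c1].items():
                    for l2, d2 in down[c2].items():
                        key = (l1, l2) if l1 < l2 else (l2, l1)
                        out[key] = d1 + s1 + d2 + s2
        return out

    def extract_subtree(self, leaf_names: Iterable[str]) -> "Tree":
        """Induced subtree on the given leaves, degree-2 nodes suppressed."""
        keep = set(leaf_names)
        missing = keep - set(self.leaf_names)
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")

        def prune(node: Node) -> Node | None:
            if node.is_leaf:
                if node.name in keep:
                    new = Node(node.name, node.length)
                    return new
                return None
            kept = [prune(c) for c in node.children]
            kept = [k for k in kept if k is not None]
            if not kept:
                return None
            if len(kept) == 1:  # suppress degree-2: fold branch lengths
                kept[0].length += node.length
                return kept[0]
            new = Node(node.name, node.length)
            for k in kept:
                new.add_child(k)
            return new

        sub = prune(self.root)
        if sub is None:
            raise ValueError("no requested leaves found")
        sub.length = 0.0
        return Tree(sub)

    def __repr__(self):  # pragma: no cover
        return f"<Tree {len(self.leaf_names)} leaves>"
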