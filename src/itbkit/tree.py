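"""Phylogenetic tree structure, Newick I/O, and outgroup rooting.

Trees are lightweight mutable nodes; an edge's length and (for internal
edges) integer bootstrap support are stored on the child node.  Newick text
is parsed with dendropy and serialised by a small controlled writer (lengths
to six decimals, supports as internal node labels) so that round-trips are
byte-stable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import dendropy


@dataclass
class TreeNode:
    label: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PhyloTree:
    """A tree plus run metadata (e.g. dropped bootstrap replicates)."""

    root: TreeNode
    meta: dict = field(default_factory=dict)

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.root.leaves()]

    def copy(self) -> "PhyloTree":
        return PhyloTree(root=copy.deepcopy(self.root), meta=dict(self.meta))


def _node_newick(node: TreeNode, with_lengths: bool) -> str:
    if node.is_leaf:
        s = node.label or ""
    else:
        inner = ",".join(_node_newick(c, with_lengths) for c in node.children)
        s = f"({inner})"
        if node.support is not None:
            s += str(node.support)
        elif node.label:
            s += node.label
    if with_lengths:
        s += f":{node.length:.6f}"
    return s


def write_newick(tree: PhyloTree, with_lengths: bool = True) -> str:
    """Serialise to Newick; internal supports become internal node labels."""
    root = tree.root
    if root.is_leaf:
        return (root.label or "") + ";"
    inner = ",".join(_node_newick(c, with_lengths) for c in root.children)
    label = str(root.support) if root.support is not None else (root.label or "")
    return f"({inner}){label};"


def parse_newick(text: str) -> PhyloTree:
    """Parse Newick text; integer internal labels are read as supports."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        node = TreeNode(length=float(dnode.edge.length or 0.0))
        if dnode.is_leaf():
            node.label = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            raw = dnode.label
            if raw is not None:
                try:
                    node.support = int(raw)
                except ValueError:
                    node.label = raw
            node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return PhyloTree(root=convert(dtree.seed_node))


def bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial splits, each canonicalised as the side excluding a
    reference leaf (the lexicographically smallest label)."""
    all_leaves = frozenset(tree.leaf_labels())
    ref = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        below = frozenset(leaf.label for leaf in node.leaves())
        side = below if ref not in below else all_leaves - below
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(side)
    return splits


def leaf_path_lengths(tree: PhyloTree) -> dict[tuple[str, str], float]:
    """Sum of branch lengths between every leaf pair."""
    dists: dict[tuple[str, str], float] = {}

    def recurse(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.label: 0.0}
        per_child = []
        for child in node.children:
            sub = recurse(child)
            per_child.append({k: v + child.length for k, v in sub.items()})
        for i in range(len(per_child)):
            for j in range(i + 1, len(per_child)):
                for la, da in per_child[i].items():
                    for lb, db in per_child[j].items():
                        key = (la, lb) if la < lb else (lb, la)
                        dists[key] = da + db
        merged: dict[str, float] = {}
        for sub in per_child:
            merged.update(sub)
        return merged

    recurse(tree.root)
    return dists


def root_with_outgroup(tree: PhyloTree, outgroup_id: str) -> PhyloTree:
    """Root at the midpoint of the outgroup's pendant edge.

    Leaf-to-leaf path lengths are preserved.  For a two-leaf tree the whole
    tree is a single edge, which the new root splits in half.
    """
    tree = tree.copy()
    parents: dict[int, TreeNode] = {}
    for node in tree.root.walk():
        for child in node.children:
            parents[id(child)] = node
    target = None
    for leaf in tree.root.leaves():
        if leaf.label == outgroup_id:
            target = leaf
            break
    if target is None:
        raise ValueError(f"outgroup {outgroup_id!r} is not a leaf of the tree")

    leaves = tree.root.leaves()
    if len(leaves) == 2:
        other = next(l for l in leaves if l is not target)
        total = sum(c.length for c in tree.root.children)
        target.length = total / 2.0
        other.length = total / 2.0
        new_root = TreeNode(children=[target, other])
        return PhyloTree(root=new_root, meta=dict(tree.meta))

    # Path from the outgroup up to the old root.
    path = [target]
    while id(path[-1]) in parents:
        path.append(parents[id(path[-1])])

    half = target.length / 2.0
    target.length = half
    new_root = TreeNode(children=[target])

    # Reverse the path: each former parent is re-hung beneath its former child.
    prev_attach = new_root
    carry_length = half
    carry_support = None  # pendant-edge split is trivial
    for i in range(1, len(path)):
        node = path[i]
        below = path[i - 1]
        node.children = [c for c in node.children if c is not below]
        next_length, next_support = node.length, node.support
        node.length, node.support = carry_length, carry_support
        prev_attach.children.append(node)
        prev_attach = node
        carry_length, carry_support = next_length, next_support

    # Suppress a degree-one remnant of the old root.
    def suppress(node: TreeNode) -> None:
        for child in list(node.children):
            suppress(child)
        if len(node.children) == 1 and node is not new_root:
            only = node.children[0]
            only.length += node.length
            if only.support is None:
                only.support = node.support
            parent = next(p for p in new_root.walk() if node in p.children)
            idx = parent.children.index(node)
            parent.children[idx] = only

    suppress(new_root)
    return PhyloTree(root=new_root, meta=dict(tree.meta))


def ascii_tree(tree: PhyloTree) -> str:
    """Minimal indented text rendering for logs and reports."""
    lines: list[str] = []

    def recurse(node: TreeNode, depth: int) -> None:
        tag = node.label if node.is_leaf else (
            f"[{node.support}]" if node.support is not None else "*"
        )
        lines.append("  " * depth + f"{tag}:{node.length:.4f}")
        for child in node.children:
            recurse(child, depth + 1)

    recurse(tree.root, 0)
    return "\n".join(lines)
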