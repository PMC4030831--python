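"""Distance-based phylogenetics for protein alignments.

The procedure mirrors classical protein phylogenetics practice: observed
proportions of differing sites (p-distances, with pairwise deletion of gap
columns) are corrected for multiple hits with the Kimura protein transform

    d = -ln(1 - p - 0.2 p^2),

trees are built by Saitou-Nei neighbor joining, clade stability is assessed
by bootstrap resampling of alignment columns (default 100 replicates,
display threshold 90), trees are rooted on an outgroup's pendant edge, and
family-level groups are read off the rooted, support-collapsed tree.

The correction saturates: it is undefined for p >= p_max ~= 0.854102 (the
positive root of 0.2 p^2 + p = 1).  Saturated pairs raise SaturationError at
the point estimate and cause the replicate to be dropped (and counted)
during bootstrapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP, MultipleAlignment
from .tree import PhyloTree, TreeNode, bipartitions

P_MAX = (-1.0 + math.sqrt(1.8)) / 0.4  # ~0.8541019662496845


class SaturationError(ValueError):
    """p-distance beyond the domain of the Kimura protein correction."""


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # square, symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("nonzero diagonal")
        if np.any(v < 0):
            raise ValueError("negative distances")

    def to_tsv(self) -> str:
        lines = ["\t".join(("",) + self.ids)]
        for i, name in enumerate(self.ids):
            lines.append(name + "\t" + "\t".join(f"{x:.6f}" for x in self.values[i]))
        return "\n".join(lines) + "\n"

    def to_phylip(self) -> str:
        lines = [f" {len(self.ids)}"]
        for i, name in enumerate(self.ids):
            lines.append(f"{name:<10}" + " ".join(f"{x:.6f}" for x in self.values[i]))
        return "\n".join(lines) + "\n"


def p_distance(row_i: str, row_j: str) -> float:
    """Differing columns / mutually non-gap columns."""
    if len(row_i) != len(row_j):
        raise ValueError("rows differ in length")
    diff = comparable = 0
    for a, b in zip(row_i, row_j):
        if a != GAP and b != GAP:
            comparable += 1
            if a != b:
                diff += 1
    if comparable == 0:
        raise ValueError("no mutually non-gap columns")
    return diff / comparable


def kimura_correct(p: float) -> float:
    """Kimura multiple-hit correction for protein p-distances."""
    if p < 0:
        raise ValueError("p-distance cannot be negative")
    if p >= P_MAX:
        raise SaturationError(
            f"p = {p:.6f} is at or beyond saturation (p_max = {P_MAX:.6f})"
        )
    return -math.log(1.0 - p - 0.2 * p * p)


def _encode(msa: MultipleAlignment) -> np.ndarray:
    """Rows as an int matrix; gaps become -1."""
    arr = np.frombuffer("".join(msa.rows).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(msa.n_rows, msa.n_columns).astype(np.int16)
    arr[arr == ord(GAP)] = -1
    return arr


def _distances_from_codes(codes: np.ndarray, ids: tuple[str, ...]) -> DistanceMatrix:
    n = codes.shape[0]
    values = np.zeros((n, n))
    nongap = codes >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            p = float((codes[i][both] != codes[j][both]).sum()) / comparable
            d = kimura_correct(p)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=ids, values=values)


def kimura_distance_matrix(msa: MultipleAlignment) -> DistanceMatrix:
    """Kimura-corrected pairwise distances with pairwise gap deletion."""
    return _distances_from_codes(_encode(msa), msa.ids())


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The Q-criterion minimiser is chosen as the lowest (i, j) index pair on
    ties; negative branch lengths are clamped to zero with the deficit moved
    to the sister edge.  Returns an unrooted tree (root of degree 3, or a
    two-leaf tree for n = 2).
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("neighbor joining needs at least two taxa")
    nodes: list[TreeNode] = [TreeNode(label=name) for name in dm.ids]
    d = dm.values.astype(float).copy()

    if n == 2:
        half = d[0, 1] / 2.0
        nodes[0].length = half
        nodes[1].length = half
        return PhyloTree(root=TreeNode(children=nodes))

    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_id = n
    node_of: dict[int, TreeNode] = {i: nodes[i] for i in range(n)}

    def get(i: int, j: int) -> float:
        return dist[(i, j)] if i <= j else dist[(j, i)]

    def put(i: int, j: int, value: float) -> None:
        key = (i, j) if i <= j else (j, i)
        dist[key] = value

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and best is None):
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        child_i, child_j = node_of[i], node_of[j]
        child_i.length = li
        child_j.length = lj
        parent = TreeNode(children=[child_i, child_j])
        u = next_id
        next_id += 1
        node_of[u] = parent
        for k in active:
            if k in (i, j):
                continue
            put(u, k, 0.5 * (get(i, k) + get(j, k) - dij))
        active = [k for k in active if k not in (i, j)] + [u]

    # Final star of three: closed-form pendant lengths.
    i, j, k = active
    li = max(0.0, 0.5 * (get(i, j) + get(i, k) - get(j, k)))
    lj = max(0.0, 0.5 * (get(i, j) + get(j, k) - get(i, k)))
    lk = max(0.0, 0.5 * (get(i, k) + get(j, k) - get(i, j)))
    for idx, length in ((i, li), (j, lj), (k, lk)):
        node_of[idx].length = length
    root = TreeNode(children=[node_of[i], node_of[j], node_of[k]])
    return PhyloTree(root=root)


def nj_tree_from_alignment(msa: MultipleAlignment) -> PhyloTree:
    return neighbor_joining(kimura_distance_matrix(msa))


def bootstrap_support(
    msa: MultipleAlignment, n_replicates: int = 100, seed: int = 0
) -> PhyloTree:
    """Annotate the point-estimate NJ tree with bootstrap clade support.

    Each replicate resamples alignment columns with replacement (as many
    draws as columns), reruns the distance + NJ pipeline, and records the
    replicate's bipartitions.  Replicate r uses seed + r, so runs with the
    same seed are exactly reproducible.  A replicate whose distances saturate
    is dropped and counted (``tree.meta['dropped_replicates']``); supports
    are percentages over the replicates that produced a tree.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    codes = _encode(msa)
    ids = msa.ids()
    point_tree = neighbor_joining(_distances_from_codes(codes, ids))
    target_splits = bipartitions(point_tree)
    counts = {split: 0 for split in target_splits}
    n_cols = codes.shape[1]
    dropped = 0
    completed = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        cols = rng.integers(0, n_cols, size=n_cols)
        try:
            dm = _distances_from_codes(codes[:, cols], ids)
        except SaturationError:
            dropped += 1
            continue
        completed += 1
        rep_splits = bipartitions(neighbor_joining(dm))
        for split in target_splits & rep_splits:
            counts[split] += 1
    if completed == 0:
        raise SaturationError("every bootstrap replicate saturated")
    supports = {
        split: int(round(100.0 * c / completed)) for split, c in counts.items()
    }
    all_leaves = frozenset(ids)
    ref = min(all_leaves)
    for node in point_tree.root.walk():
        if node is point_tree.root or node.is_leaf:
            continue
        below = frozenset(leaf.label for leaf in node.leaves())
        side = below if ref not in below else all_leaves - below
        if side in supports:
            node.support = supports[side]
    point_tree.meta["dropped_replicates"] = dropped
    point_tree.meta["completed_replicates"] = completed
    return point_tree


@dataclass(frozen=True)
class FamilyPartition:
    """Disjoint family groups read off a support-collapsed rooted tree."""

    groups: tuple[frozenset[str], ...]
    support_threshold: int
    resolved: dict[str, bool] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in self.groups:
            if seen & group:
                raise ValueError("family groups are not disjoint")
            seen |= group

    def as_sorted_sets(self) -> list[list[str]]:
        return sorted([sorted(g) for g in self.groups])


def collapse_low_support(tree: PhyloTree, threshold: int) -> PhyloTree:
    """Collapse internal edges with support below the threshold to polytomies.

    Edges without a support value (e.g. on a point-estimate tree that has not
    been bootstrapped) are left intact.
    """
    tree = tree.copy()

    def recurse(node: TreeNode) -> None:
        changed = True
        while changed:
            changed = False
            new_children: list[TreeNode] = []
            for child in node.children:
                if (
                    not child.is_leaf
                    and child.support is not None
                    and child.support < threshold
                ):
                    for grand in child.children:
                        grand.length += child.length
                    new_children.extend(child.children)
                    changed = True
                else:
                    new_children.append(child)
            node.children = new_children
        for child in node.children:
            recurse(child)

    recurse(tree.root)
    return tree


def family_groups(
    tree: PhyloTree, labels: dict[str, str], support_threshold: int = 90
) -> FamilyPartition:
    """Partition families using the well-supported structure of a rooted tree.

    Internal edges below the support threshold are collapsed first, the
    outgroup (labels mapping to "OUTGROUP") is removed, and the children of
    the ingroup root are merged whenever their family sets intersect; each
    resulting component is one group.  With a fully collapsed tree this
    degenerates to one group per family; with one family present it returns
    a single group.
    """
    for leaf in tree.root.leaves():
        if leaf.label not in labels:
            raise ValueError(f"unlabelled leaf {leaf.label!r}")
    collapsed = collapse_low_support(tree, support_threshold)

    def prune_outgroup(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            return None if labels[node.label] == "OUTGROUP" else node
        kept = [c for c in (prune_outgroup(child) for child in node.children) if c]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length += node.length
            return kept[0]
        node.children = kept
        return node

    ingroup = prune_outgroup(collapsed.root)
    if ingroup is None:
        raise ValueError("no ingroup leaves remain after removing the outgroup")

    families_present = sorted({labels[l.label] for l in ingroup.leaves()}) if not ingroup.is_leaf else [labels[ingroup.label]]

    # Monophyly per family in the collapsed ingroup tree.
    resolved: dict[str, bool] = {}
    if ingroup.is_leaf:
        resolved[labels[ingroup.label]] = True
    else:
        for fam in families_present:
            fam_leaves = {l.label for l in ingroup.leaves() if labels[l.label] == fam}
            mono = False
            for node in ingroup.walk():
                below = {l.label for l in node.leaves()}
                if below == fam_leaves:
                    mono = True
                    break
            resolved[fam] = mono

    if ingroup.is_leaf:
        return FamilyPartition(
            groups=(frozenset([labels[ingroup.label]]),),
            support_threshold=support_threshold,
            resolved=resolved,
        )

    # Merge top-level subtrees sharing any family.
    components: list[set[str]] = []
    for child in ingroup.children:
        fams = {labels[l.label] for l in child.leaves()}
        merged = set(fams)
        rest = []
        for comp in components:
            if comp & merged:
                merged |= comp
            else:
                rest.append(comp)
        rest.append(merged)
        components = rest
    groups = tuple(sorted((frozenset(c) for c in components), key=sorted))
    return FamilyPartition(
        groups=groups, support_threshold=support_threshold, resolved=resolved
    )
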