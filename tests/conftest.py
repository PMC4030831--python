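"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import random

import numpy as np
import pytest

from itbkit.records import ProteinRecord
from itbkit.alignment import MultipleAlignment
from itbkit.tree import PhyloTree, TreeNode, leaf_path_lengths


def make_msa(rows: dict[str, str], families: dict[str, str] | None = None) -> MultipleAlignment:
    """Build an alignment from {id: gapped_row}."""
    families = families or {}
    records = tuple(
        ProteinRecord(id=name, sequence=row.replace("-", ""), family=families.get(name))
        for name, row in rows.items()
    )
    return MultipleAlignment(records=records, rows=tuple(rows.values()))


def random_binary_tree(labels: list[str], rng: random.Random,
                       min_len: float = 0.1, max_len: float = 1.0) -> PhyloTree:
    """A random binary tree with random edge lengths over the given leaves."""
    nodes = [TreeNode(label=l, length=round(rng.uniform(min_len, max_len), 3))
             for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        parent = TreeNode(length=round(rng.uniform(min_len, max_len), 3),
                          children=[a, b])
        nodes.append(parent)
    root = TreeNode(children=nodes)
    return PhyloTree(root=root)


def additive_matrix_from_tree(tree: PhyloTree) -> tuple[tuple[str, ...], np.ndarray]:
    """Exact leaf-to-leaf path-length matrix of a tree (the additive oracle)."""
    paths = leaf_path_lengths(tree)
    ids = tuple(sorted(tree.leaf_labels()))
    n = len(ids)
    d = np.zeros((n, n))
    for (a, b), v in paths.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v
    return ids, d


def brute_force_global_alignments(a: str, b: str):
    """Enumerate every global alignment of two short sequences."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ra, rb in brute_force_global_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in brute_force_global_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)
    if a and b:
        for ra, rb in brute_force_global_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)


def score_alignment(row_a: str, row_b: str, score, gap_open: float, gap_extend: float) -> float:
    """Score a finished alignment: substitution scores minus affine gap costs.

    Scored independently of any DP internals: each maximal gap run of length
    L in either row costs gap_open + (L-1)*gap_extend.
    """
    total = 0.0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            total += score(ca, cb)
    for row in (row_a, row_b):
        run = 0
        for ch in row:
            if ch == "-":
                run += 1
            else:
                if run:
                    total -= gap_open + (run - 1) * gap_extend
                run = 0
        if run:
            total -= gap_open + (run - 1) * gap_extend
    return total


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
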