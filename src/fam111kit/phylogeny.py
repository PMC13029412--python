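"""UPGMA tree construction, Newick serialization, and taxon-clade concordance.

UPGMA (unweighted pair-group method with arithmetic mean) repeatedly merges
the two closest clusters, placing the merged node at half the merge distance,
and averages distances to the remainder weighted by cluster size.  The result
is ultrametric: every leaf sits at height 0 and all root-to-leaf path lengths
equal the root height.  The same routine serves as the guide tree for
progressive alignment and as the family phylogeny.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import Phylo


@dataclass
class TreeNode:
    """A node of a rooted, ultrametric binary tree.

    Leaves carry a label and height 0; internal nodes carry two children and
    a nonnegative height.  Branch lengths are derived quantities:
    ``parent.height - child.height``.
    """

    label: str | None = None
    children: tuple["TreeNode", ...] = ()
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def walk(self) -> Iterator["TreeNode"]:
        """Post-order traversal."""
        for c in self.children:
            yield from c.walk()
        yield self

    def min_leaf_label(self) -> str:
        return min(self.leaf_labels())


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.d < 0):
            raise ValueError("distance matrix must be nonnegative")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=list(frame.index), d=frame.to_numpy())


def upgma(D: DistanceMatrix) -> TreeNode:
    """Build the UPGMA tree for a distance matrix.

    Merge order ties are broken on the lexicographically smallest pair of
    cluster minimum-member labels, making the output independent of input
    taxon order.  New-cluster distances are size-weighted arithmetic means.
    """
    n = len(D.ids)
    if n < 2:
        raise ValueError("UPGMA needs at least two taxa")
    nodes = [TreeNode(label=tid, height=0.0) for tid in D.ids]
    sizes = [1] * n
    minlab = list(D.ids)
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D.d[i, j])
    active = list(range(n))
    next_idx = n
    store: dict[int, TreeNode] = {i: nodes[i] for i in range(n)}
    size_of = {i: 1 for i in range(n)}
    lab_of = {i: minlab[i] for i in range(n)}

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 1:
        best = None
        best_key = None
        for a_pos in range(len(active)):
            for b_pos in range(a_pos + 1, len(active)):
                i, j = active[a_pos], active[b_pos]
                dij = get(i, j)
                key = (dij, tuple(sorted((lab_of[i], lab_of[j]))))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best
        dij = get(i, j)
        ci, cj = store[i], store[j]
        children = tuple(sorted((ci, cj), key=lambda c: c.min_leaf_label()))
        merged = TreeNode(label=None, children=children, height=dij / 2.0)
        k = next_idx
        next_idx += 1
        store[k] = merged
        size_of[k] = size_of[i] + size_of[j]
        lab_of[k] = min(lab_of[i], lab_of[j])
        for m in active:
            if m in (i, j):
                continue
            dm = (size_of[i] * get(i, m) + size_of[j] * get(j, m)) / (
                size_of[i] + size_of[j]
            )
            dist[(min(k, m), max(k, m))] = dm
        active = [m for m in active if m not in (i, j)] + [k]
    return store[active[0]]


def _fmt_branch(x: float, precision: int) -> str:
    s = f"{x:.{precision}f}".rstrip("0").rstrip(".")
    return s if s not in ("", "-0") else "0"


def to_newick(tree: TreeNode, precision: int = 6) -> str:
    """Serialize a tree as Newick with branch lengths, canonical child order.

    Children are ordered by their smallest descendant label so that
    isomorphic trees serialize identically.
    """

    def render(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.label
        else:
            kids = sorted(node.children, key=lambda c: c.min_leaf_label())
            body = "(" + ",".join(render(c, node.height) for c in kids) + ")"
        if parent_height is None:
            return body
        return f"{body}:{_fmt_branch(parent_height - node.height, precision)}"

    return render(tree, None) + ";"


def from_newick(text: str) -> TreeNode:
    """Parse a Newick string into a TreeNode, heights from branch lengths."""
    clade = Phylo.read(io.StringIO(text), "newick").root

    def convert(c) -> TreeNode:
        if not c.clades:
            return TreeNode(label=c.name, height=0.0)
        children = tuple(convert(x) for x in c.clades)
        height = max(
            child.height + (x.branch_length or 0.0)
            for child, x in zip(children, c.clades)
        )
        return TreeNode(label=None, children=children, height=height)

    return convert(clade)


def write_newick(tree: TreeNode, path, precision: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree, precision) + "\n")


def clade_concordance(
    tree: TreeNode, class_of: Mapping[str, object]
) -> pd.DataFrame:
    """Monophyly report: for each class, is its smallest containing clade pure?

    ``class_of`` maps leaf label to a class label (or to a TaxonomyRecord,
    whose ``class_label`` is used).  Returns one row per class with the size
    of the smallest clade containing all of the class's leaves and whether
    that clade contains no other class's leaf.
    """

    def label_of(x) -> str:
        return getattr(x, "class_label", x)

    leaves = tree.leaf_labels()
    missing = [l for l in leaves if l not in class_of]
    if missing:
        raise KeyError(f"leaves without class labels: {missing}")
    members: dict[str, set[str]] = {}
    for leaf in leaves:
        members.setdefault(label_of(class_of[leaf]), set()).add(leaf)

    leafsets: list[frozenset] = [
        frozenset(node.leaf_labels()) for node in tree.walk()
    ]
    rows = []
    for cls in sorted(members):
        want = members[cls]
        containing = [s for s in leafsets if want <= s]
        smallest = min(containing, key=len)
        rows.append(
            {
                "class_label": cls,
                "n_members": len(want),
                "smallest_clade_size": len(smallest),
                "is_monophyletic": len(smallest) == len(want),
            }
        )
    return pd.DataFrame(rows)
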