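"""Cell-type hierarchy: pseudo-bulk profiles, Ward clustering, tree queries.

The hierarchy is a rooted, strictly binary tree whose leaves are cell-type
labels and whose internal nodes are numbered classification points. It is
built by summing raw counts over all cells of each type (pseudo-bulk),
normalizing each profile to 10,000 total counts (TP10K), and agglomeratively
clustering the profiles with Ward's method.

Node numbering is deterministic: breadth-first from the root (which is node
1), with the left child being the subtree containing the alphabetically
first leaf label. This guarantees identical trees and numbering across runs
and platforms for identical input profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .containers import LabeledReference

__all__ = [
    "PseudobulkProfiles",
    "CellTypeHierarchy",
    "aggregate_pseudobulk",
    "tp10k",
    "build_hierarchy",
]

TP10K_TARGET = 10_000.0


@dataclass
class PseudobulkProfiles:
    """Cell-types x genes profile table (raw or TP10K-normalized sums)."""

    profiles: pd.DataFrame  # index: cell-type labels, columns: gene ids
    total_counts_per_type: pd.Series

    @property
    def cell_types(self) -> list:
        return list(self.profiles.index)


def aggregate_pseudobulk(ref: LabeledReference) -> PseudobulkProfiles:
    """Sum gene counts across all barcodes per cell type.

    Produces one profile row per distinct label, rows sorted by label so the
    output is invariant to cell order.
    """
    labels = pd.Series(ref.labels)
    types = sorted(labels.unique())
    onehot = np.zeros((len(types), ref.matrix.n_cells))
    for i, t in enumerate(types):
        onehot[i, labels.values == t] = 1.0
    sums = onehot @ ref.matrix.counts  # types x genes, dense
    sums = np.asarray(sums)
    profiles = pd.DataFrame(sums, index=types, columns=ref.matrix.gene_ids)
    totals = pd.Series(sums.sum(axis=1).astype(np.int64), index=types)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"cell types with all-zero profiles: {bad}")
    return PseudobulkProfiles(profiles, totals)


def tp10k(pb: PseudobulkProfiles) -> PseudobulkProfiles:
    """Scale each profile row to sum to 10,000 (idempotent)."""
    sums = pb.profiles.sum(axis=1)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"profiles with nonpositive row sums: {bad}")
    scaled = pb.profiles.div(sums, axis=0) * TP10K_TARGET
    return PseudobulkProfiles(scaled, pb.total_counts_per_type)


@dataclass
class CellTypeHierarchy:
    """Strictly binary rooted tree over cell-type labels.

    ``children`` maps each internal node id to its (left, right) child ids;
    ``leaf_labels`` maps leaf node ids to cell-type labels. Node ids are
    breadth-first integers starting at 1 (the root).
    """

    children: dict
    leaf_labels: dict
    _parent: dict = field(init=False, repr=False, compare=False)
    _label_to_leaf: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        self._parent = {}
        for node, (a, b) in self.children.items():
            self._parent[a] = node
            self._parent[b] = node
        self._label_to_leaf = {lab: nid for nid, lab in self.leaf_labels.items()}
        if len(self._label_to_leaf) != len(self.leaf_labels):
            raise ValueError("duplicate leaf labels in hierarchy")

    # -- structure -----------------------------------------------------
    @property
    def root(self) -> int:
        return 1

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.children) + len(self.leaf_labels)

    @property
    def labels(self) -> list:
        return sorted(self._label_to_leaf)

    @property
    def internal_nodes(self) -> list:
        return sorted(self.children)

    def is_leaf(self, node: int) -> bool:
        return node in self.leaf_labels

    def parent(self, node: int):
        return self._parent.get(node)

    def leaf_for_label(self, label) -> int:
        try:
            return self._label_to_leaf[label]
        except KeyError:
            raise KeyError(
                f"unknown cell-type label {label!r}; known labels: {self.labels}"
            ) from None

    def leaves_under(self, node: int) -> list:
        """Sorted cell-type labels in the subtree rooted at ``node``."""
        if self.is_leaf(node):
            return [self.leaf_labels[node]]
        a, b = self.children[node]
        return sorted(self.leaves_under(a) + self.leaves_under(b))

    def depth(self, node: int) -> int:
        d = 0
        while node != self.root:
            node = self._parent[node]
            d += 1
        return d

    def lineage(self, label) -> list:
        """Root-first node path from the root to the leaf carrying ``label``."""
        node = self.leaf_for_label(label)
        path = [node]
        while node != self.root:
            node = self._parent[node]
            path.append(node)
        return path[::-1]

    def label_similarity(self, a, b) -> float:
        """Shared lineage-prefix length over the shorter lineage's length.

        Symmetric, in (0, 1]; equals 1 iff one lineage is a prefix of the
        other (the root is always shared, so the score is strictly positive).
        """
        la, lb = self.lineage(a), self.lineage(b)
        shared = 0
        for x, y in zip(la, lb):
            if x != y:
                break
            shared += 1
        return shared / min(len(la), len(lb))

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        obj = {
            "format": "census-hierarchy-v1",
            "children": {str(k): list(v) for k, v in self.children.items()},
            "leaf_labels": {str(k): v for k, v in self.leaf_labels.items()},
        }
        return json.dumps(obj, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CellTypeHierarchy":
        obj = json.loads(text)
        return cls(
            children={int(k): tuple(v) for k, v in obj["children"].items()},
            leaf_labels={int(k): v for k, v in obj["leaf_labels"].items()},
        )

    def to_newick(self) -> str:
        def esc(s):
            s = str(s)
            if any(c in s for c in " ()[]:;,'"):
                return "'" + s.replace("'", "''") + "'"
            return s

        def rec(node):
            if self.is_leaf(node):
                return esc(self.leaf_labels[node])
            a, b = self.children[node]
            return f"({rec(a)},{rec(b)}){node}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "CellTypeHierarchy":
        import io as _io

        from skbio import TreeNode

        tree = TreeNode.read(_io.StringIO(text))
        children: dict = {}
        leaf_labels: dict = {}
        # internal node names carry the original numbering; leaves get fresh
        # ids below all internal ids
        next_leaf_id = [0]
        internal_ids = []

        def collect(node):
            if node.is_tip():
                return
            internal_ids.append(int(node.name) if node.name else None)
            for ch in node.children:
                collect(ch)

        collect(tree)
        max_internal = max(i for i in internal_ids if i is not None)
        next_leaf_id[0] = max_internal + 1

        def build(node):
            if node.is_tip():
                # skbio strips quoting; underscores stand for spaces unless quoted
                nid = next_leaf_id[0]
                next_leaf_id[0] += 1
                leaf_labels[nid] = node.name
                return nid
            kids = [build(ch) for ch in node.children]
            if len(kids) != 2:
                raise ValueError("hierarchy must be strictly binary")
            nid = int(node.name)
            children[nid] = tuple(kids)
            return nid

        build(tree)
        h = cls(children=children, leaf_labels=leaf_labels)
        # renumber leaves to match canonical BFS ids
        return _renumber(h)


def _renumber(h: CellTypeHierarchy) -> CellTypeHierarchy:
    """Assign canonical BFS ids (root=1, alphabetical-first leaf on the left)."""
    new_children: dict = {}
    new_leaves: dict = {}
    # order children so the left subtree holds the alphabetically first label
    def first_label(node):
        if h.is_leaf(node):
            return h.leaf_labels[node]
        a, b = h.children[node]
        return min(first_label(a), first_label(b))

    mapping = {}
    queue = [_find_root(h)]
    next_id = 1
    order: dict = {}
    while queue:
        node = queue.pop(0)
        mapping[node] = next_id
        next_id += 1
        if not h.is_leaf(node):
            a, b = h.children[node]
            if first_label(b) < first_label(a):
                a, b = b, a
            order[node] = (a, b)
            queue.extend([a, b])
    for node, (a, b) in order.items():
        new_children[mapping[node]] = (mapping[a], mapping[b])
    for node, lab in h.leaf_labels.items():
        new_leaves[mapping[node]] = lab
    return CellTypeHierarchy(children=new_children, leaf_labels=new_leaves)


def _find_root(h: CellTypeHierarchy) -> int:
    nodes = set(h.children) | set(h.leaf_labels)
    non_root = {c for pair in h.children.values() for c in pair}
    (root,) = nodes - non_root
    return root


def build_hierarchy(
    pb: PseudobulkProfiles, *, log_transform: bool = False
) -> CellTypeHierarchy:
    """Ward-linkage binary tree over TP10K pseudo-bulk profiles.

    Parameters
    ----------
    pb
        Pseudo-bulk profiles; TP10K normalization is (re-)applied first, so
        passing raw sums is fine (tp10k is idempotent).
    log_transform
        If True, cluster log1p-transformed TP10K rows instead of raw TP10K.
    """
    pb = tp10k(pb)
    X = pb.profiles.values
    labels = list(pb.profiles.index)
    if len(labels) < 2:
        raise ValueError(
            f"need at least 2 cell types to build a hierarchy, got {len(labels)}"
        )
    if log_transform:
        X = np.log1p(X)
    Z = sch.linkage(X, method="ward")  # Euclidean distance
    tree = sch.to_tree(Z)

    children: dict = {}
    leaf_labels: dict = {}
    counter = [0]

    def build(node):
        counter[0] += 1
        nid = counter[0]
        if node.is_leaf():
            leaf_labels[nid] = labels[node.id]
        else:
            a = build(node.left)
            b = build(node.right)
            children[nid] = (a, b)
        return nid

    build(tree)
    return _renumber(CellTypeHierarchy(children=children, leaf_labels=leaf_labels))
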