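"""Rough clustering of the candidate database.

Pairwise uncorrected p-distances are computed from a trimmed global MSA
with pairwise gap deletion, a UPGMA (average-linkage) ultrametric tree is
built, and the tree is cut into clades by the accumulated-branch-length
rule: leaves whose tree path length is below a threshold (default 0.3)
belong to the same cluster.  On an ultrametric tree the path length
between two leaves is twice the height of their most recent common
ancestor, so the cut is realized exactly by taking maximal clades whose
node height is below ``threshold / 2``.

The distance measure is deliberately the minimal assumption — the
proportion of differing residues over mutually ungapped columns — and is
configurable by passing any :class:`DistanceMatrix` to :func:`upgma`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import SerializationError, UndefinedDistanceError, ValidationError
from .io_core import GAP, Msa

DEFAULT_PATH_LENGTH_THRESHOLD = 0.3


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # (n, n), symmetric, zero diagonal

    def __post_init__(self):
        n = len(self.labels)
        if n < 1:
            raise ValidationError("distance matrix needs >= 1 label")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        d = np.asarray(self.d, dtype=float)
        if d.shape != (n, n):
            raise ValidationError(f"matrix shape {d.shape} != ({n}, {n})")
        if np.isnan(d).any():
            raise ValidationError("NaN in distance matrix")
        if (d < 0).any():
            raise ValidationError("negative distance")
        if np.abs(np.diag(d)).max(initial=0.0) > 1e-12:
            raise ValidationError("non-zero diagonal")
        if np.abs(d - d.T).max(initial=0.0) > 1e-12:
            raise ValidationError("asymmetric distance matrix")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class TreeNode:
    """Node of an ultrametric tree; leaves have height 0 and a label."""

    height: float
    label: Optional[str] = None
    children: tuple["TreeNode", ...] = ()
    n_leaves: int = 1

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


@dataclass
class UpgmaTree:
    root: TreeNode

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.label for lf in self.root.leaves()]

    def leaf_pair_path_lengths(self) -> dict[tuple[str, str], float]:
        """Path length between every leaf pair: 2x the MRCA height."""
        out: dict[tuple[str, str], float] = {}

        def visit(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.label]
            groups = [visit(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            key = (a, b) if a <= b else (b, a)
                            out[key] = 2.0 * node.height
            return [x for g in groups for x in g]

        visit(self.root)
        return out


@dataclass(frozen=True)
class ClusterAssignment:
    threshold: float
    mapping: dict[str, int]  # label -> 0-based cluster index

    @property
    def n_clusters(self) -> int:
        return len(set(self.mapping.values())) if self.mapping else 0

    def clusters(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for label, idx in self.mapping.items():
            out.setdefault(idx, []).append(label)
        return [out[i] for i in sorted(out)]


# ---------------------------------------------------------------------------

def p_distance(msa: Msa) -> DistanceMatrix:
    """Uncorrected p-distance with pairwise gap deletion.

    d[i][j] = mismatches / comparable, where comparable columns are those
    where neither row carries a gap; X mismatches every residue,
    including another X.  A pair with zero comparable columns raises
    :class:`UndefinedDistanceError` rather than guessing.
    """
    if len(msa.rows) < 2:
        raise ValidationError("p_distance needs >= 2 alignment rows")
    labels = tuple(msa.ids)
    arr = np.frombuffer(
        "".join(s for _, s in msa.rows).encode("ascii"), dtype="S1"
    ).reshape(len(labels), msa.width)
    gap = arr == GAP.encode()
    unknown = arr == b"X"
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ~gap[i] & ~gap[j]
            n_comp = int(comparable.sum())
            if n_comp == 0:
                raise UndefinedDistanceError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            diff = (arr[i] != arr[j]) | unknown[i] | unknown[j]
            d[i, j] = d[j, i] = int((diff & comparable).sum()) / n_comp
    return DistanceMatrix(labels, d)


def upgma(dm: DistanceMatrix) -> UpgmaTree:
    """Unweighted pair-group (average-linkage) agglomeration.

    Repeatedly merges the active cluster pair with minimal average
    distance; the new node's height is half that distance and distances
    to the merged cluster are size-weighted averages.  Ties are broken by
    the lexicographically smallest (i, j) in cluster creation order, so
    the result is deterministic.
    """
    n = dm.n
    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, label=dm.labels[i]) for i in range(n)
    }
    if n == 1:
        return UpgmaTree(nodes[0])
    # Working distance table indexed by cluster creation order.
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = dm.d[i, j]
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        best = min(dist[key] for key in dist)
        i, j = min(key for key in dist if dist[key] == best)
        height = best / 2.0
        merged = TreeNode(
            height=height,
            children=(nodes[i], nodes[j]),
            n_leaves=sizes[i] + sizes[j],
        )
        nodes[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)]
        for k in active:
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(k, next_id), max(k, next_id))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        dist = {
            (a, b): v for (a, b), v in dist.items()
            if a not in (i, j) and b not in (i, j)
        }
        active.append(next_id)
        next_id += 1
    return UpgmaTree(nodes[active[0]])


def cut_clusters(tree: UpgmaTree,
                 threshold: float = DEFAULT_PATH_LENGTH_THRESHOLD
                 ) -> ClusterAssignment:
    """Partition leaves into maximal clades of pairwise path length < threshold.

    Every within-cluster leaf pair is separated by accumulated branch
    length strictly below ``threshold`` (as printed: strict inequality),
    and merging any two clusters would violate that bound for some pair.
    ``threshold <= 0`` yields every leaf as a singleton (documented, not
    an error).  Cluster indices follow first appearance in leaf order.
    """
    mapping: dict[str, int] = {}
    counter = 0

    def assign_clade(node: TreeNode):
        nonlocal counter
        for lf in node.leaves():
            mapping[lf.label] = counter
        counter += 1

    def visit(node: TreeNode):
        if node.is_leaf or 2.0 * node.height < threshold:
            assign_clade(node)
        else:
            for c in node.children:
                visit(c)

    visit(tree.root)
    return ClusterAssignment(threshold=threshold, mapping=mapping)


def write_newick(tree: UpgmaTree) -> str:
    """Serialize with branch lengths (parent height minus child height).

    A single leaf serializes as ``A:0.0;`` (root branch length zero).
    Non-monotone heights (a child higher than its parent) raise
    :class:`SerializationError`.
    """

    def render(node: TreeNode, parent_height: float) -> str:
        bl = parent_height - node.height
        if bl < 0:
            raise SerializationError(
                f"negative branch length {bl} (child height {node.height} "
                f"above parent height {parent_height})"
            )
        if node.is_leaf:
            return f"{node.label}:{bl:.10g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{bl:.10g}"

    root = tree.root
    if root.is_leaf:
        return f"{root.label}:0.0;"
    inner = ",".join(render(c, root.height) for c in root.children)
    return f"({inner});"
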