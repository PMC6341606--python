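"""Independent oracles used only by the test suite.

Each oracle is implemented from first principles, deliberately not
sharing code with the implementation it checks: a regex translation of
the motif grammar, a brute-force UPGMA, and a transitive-closure
clustering over leaf path lengths.
"""

from __future__ import annotations

import itertools
import re

import numpy as np

from paofam.motif_engine import ElementKind, MotifPattern
from paofam.rough_cluster import UpgmaTree

FULL_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"


def pattern_to_regex(pattern: MotifPattern) -> str:
    """Translate a parsed motif into a standard regular expression."""
    parts = []
    for el in pattern.elements:
        if el.kind is ElementKind.ANY:
            core = f"[{FULL_ALPHABET}]"
        elif el.kind is ElementKind.LITERAL:
            core = next(iter(el.residues))
        else:
            core = "[" + "".join(sorted(el.residues)) + "]"
        if (el.min_repeat, el.max_repeat) != (1, 1):
            core += f"{{{el.min_repeat},{el.max_repeat}}}"
        parts.append(core)
    return "".join(parts)


def regex_match_starts(residues: str, pattern: MotifPattern) -> list[int]:
    """1-based start positions where the pattern matches, via regex
    lookahead (so overlapping starts are all reported)."""
    rx = re.compile("(?=(" + pattern_to_regex(pattern) + "))")
    return [m.start() + 1 for m in rx.finditer(residues)]


def brute_force_upgma(labels: list[str], d: np.ndarray
                      ) -> dict[frozenset, float]:
    """UPGMA by direct recomputation of every average from the original
    matrix: returns {frozenset(leaf labels): merge height} per internal
    node.  Ties broken by cluster creation order, as documented."""
    index = {lab: i for i, lab in enumerate(labels)}
    clusters: list[frozenset] = [frozenset([lab]) for lab in labels]
    heights: dict[frozenset, float] = {}

    def avg(a: frozenset, b: frozenset) -> float:
        return float(np.mean([d[index[x], index[y]] for x in a for y in b]))

    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            dist = avg(clusters[i], clusters[j])
            if best is None or dist < best[0] - 1e-15:
                best = (dist, i, j)
        dist, i, j = best
        merged = clusters[i] | clusters[j]
        heights[merged] = dist / 2.0
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights


def tree_merge_heights(tree: UpgmaTree) -> dict[frozenset, float]:
    out: dict[frozenset, float] = {}

    def visit(node):
        if node.is_leaf:
            return frozenset([node.label])
        leaves = frozenset()
        for c in node.children:
            leaves |= visit(c)
        out[leaves] = node.height
        return leaves

    visit(tree.root)
    return out


def transitive_closure_clusters(tree: UpgmaTree, threshold: float
                                ) -> list[set[str]]:
    """Connected components of the relation 'leaf path length < threshold'."""
    paths = tree.leaf_pair_path_lengths()
    labels = tree.leaf_labels
    parent = {lab: lab for lab in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), plen in paths.items():
        if plen < threshold:
            parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for lab in labels:
        groups.setdefault(find(lab), set()).add(lab)
    return list(groups.values())
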