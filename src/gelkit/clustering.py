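"""Dendrograms from similarity matrices by agglomerative clustering.

Similarities s (percent) are flipped to dissimilarities d = 100 - s and
clusters are merged bottom-up, always joining the pair at minimum d; ties
are broken deterministically toward the pair whose member lane indices are
smallest. Inter-cluster distances are updated by the Lance-Williams
formulas for the six supported linkages:

    upgma     size-weighted average (UPGMA / average linkage)
    upgmc     centroid (can produce inversions, which are flagged)
    single    minimum
    complete  maximum
    mean      unweighted average of the two merged clusters (WPGMA)
    ward      Ward variance update

Ward and the centroid method are applied to d directly rather than to a
squared-Euclidean embedding — band-metric similarities are not Euclidean,
so this is a documented convention, not an approximation.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError
from .similarity import SimilarityMatrix

LINKAGES = ("upgma", "upgmc", "single", "complete", "mean", "ward")


@dataclasses.dataclass(frozen=True)
class ClusterNode:
    """Binary merge-tree node. Leaves carry a lane id (and optional info);
    internal nodes carry the merge height (dissimilarity d and the
    equivalent similarity 100 - d)."""

    members: tuple                       # lane indices, sorted
    lane_id: str | None = None           # leaves only
    left: "ClusterNode | None" = None
    right: "ClusterNode | None" = None
    merge_d: float = 0.0
    info: dict = dataclasses.field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def merge_similarity(self) -> float:
        return 100.0 - self.merge_d


@dataclasses.dataclass(frozen=True)
class ClusterTree:
    root: ClusterNode
    linkage: str
    lane_ids: tuple
    has_inversions: bool = False

    def leaves(self) -> list[ClusterNode]:
        out: list[ClusterNode] = []

        def walk(n: ClusterNode) -> None:
            if n.is_leaf:
                out.append(n)
            else:
                walk(n.left)
                walk(n.right)

        walk(self.root)
        return out

    def cophenetic(self) -> np.ndarray:
        """n x n matrix of the dissimilarity at which each pair first merges."""
        n = len(self.lane_ids)
        D = np.zeros((n, n))

        def walk(node: ClusterNode) -> None:
            if node.is_leaf:
                return
            for i in node.left.members:
                for j in node.right.members:
                    D[i, j] = D[j, i] = node.merge_d
            walk(node.left)
            walk(node.right)

        walk(self.root)
        return D

    def cophenetic_map(self) -> dict:
        """Cophenetic dissimilarities keyed by sorted lane-id pairs —
        index-order independent, for comparing trees across serializations."""
        out: dict = {}

        def walk(node: ClusterNode) -> list[str]:
            if node.is_leaf:
                return [node.lane_id]
            l, r = walk(node.left), walk(node.right)
            for a in l:
                for b in r:
                    out[tuple(sorted((a, b)))] = node.merge_d
            return l + r

        walk(self.root)
        return out


def _update(linkage: str, d_ik: float, d_jk: float, d_ij: float,
            ni: int, nj: int, nk: int) -> float:
    if linkage == "single":
        return min(d_ik, d_jk)
    if linkage == "complete":
        return max(d_ik, d_jk)
    if linkage == "upgma":
        return (ni * d_ik + nj * d_jk) / (ni + nj)
    if linkage == "mean":  # WPGMA
        return 0.5 * (d_ik + d_jk)
    if linkage == "upgmc":  # centroid
        s = ni + nj
        return (ni * d_ik + nj * d_jk) / s - ni * nj * d_ij / (s * s)
    if linkage == "ward":
        s = ni + nj + nk
        return ((ni + nk) * d_ik + (nj + nk) * d_jk - nk * d_ij) / s
    raise DomainError(f"unknown linkage {linkage!r}")


def cluster(matrix: SimilarityMatrix, linkage: str = "upgma") -> ClusterTree:
    """Agglomerate a similarity matrix into a binary merge tree.

    The default linkage is UPGMA. Ties at the minimum distance merge the
    pair with the lexicographically smallest sorted member-index tuple, so
    trees are reproducible.
    """
    if linkage not in LINKAGES:
        raise DomainError(f"linkage must be one of {LINKAGES}")
    n = len(matrix.lane_ids)
    if n < 2:
        raise DomainError("need >= 2 lanes to cluster")
    D = 100.0 - matrix.values.astype(float)
    nodes: dict[int, ClusterNode] = {
        i: ClusterNode(members=(i,), lane_id=str(matrix.lane_ids[i]))
        for i in range(n)
    }
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]
    active = list(range(n))
    next_id = n
    last_height = -np.inf
    inversions = False
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (i, j) if i < j else (j, i)
                d = dist[key]
                tie_key = tuple(sorted(nodes[i].members + nodes[j].members))
                if best is None or (d, tie_key) < (best[0], best[1]):
                    best = (d, tie_key, i, j)
        d, _, i, j = best
        if d < last_height - 1e-12:
            inversions = True
        last_height = max(last_height, d)
        merged = ClusterNode(
            members=tuple(sorted(nodes[i].members + nodes[j].members)),
            left=nodes[i], right=nodes[j], merge_d=float(d))
        ni, nj = len(nodes[i].members), len(nodes[j].members)
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            nk = len(nodes[k].members)
            dist[(min(next_id, k), max(next_id, k))] = _update(
                linkage, dik, djk, d, ni, nj, nk)
        nodes[next_id] = merged
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    tree = ClusterTree(root=nodes[active[0]], linkage=linkage,
                       lane_ids=matrix.lane_ids, has_inversions=inversions)
    return tree


# ---------------------------------------------------------------------------
# Newick serialization
# ---------------------------------------------------------------------------

_NEEDS_QUOTE = set(" ()[]{}:;,'\"\t\n")


def _quote(label: str) -> str:
    if any(c in _NEEDS_QUOTE for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: ClusterTree, branch_scale: str = "dissimilarity") -> str:
    """Serialize the merge tree as Newick with ultrametric branch lengths.

    Node heights are half the merge dissimilarity (leaves at height 0), so
    a pair merging at similarity 80 yields ``(A:10.0,B:10.0);``. On the
    'similarity' scale lengths are the same magnitudes read off the
    100-to-0 similarity axis; both scales carry identical information.
    """
    if branch_scale not in ("similarity", "dissimilarity"):
        raise DomainError("branch_scale must be 'similarity' or 'dissimilarity'")

    def height(node: ClusterNode) -> float:
        return 0.0 if node.is_leaf else node.merge_d / 2.0

    def write(node: ClusterNode, parent_h: float) -> str:
        bl = parent_h - height(node)
        if node.is_leaf:
            return f"{_quote(node.lane_id)}:{bl:.10g}"
        inner = ",".join(write(c, height(node))
                         for c in (node.left, node.right))
        return f"({inner}):{bl:.10g}"

    root_h = height(tree.root)
    if tree.root.is_leaf:
        return f"{_quote(tree.root.lane_id)}:0;"
    inner = ",".join(write(c, root_h) for c in (tree.root.left, tree.root.right))
    return f"({inner});"


def from_newick(text: str, linkage: str = "upgma") -> ClusterTree:
    """Parse a Newick string produced by :func:`to_newick` back into a
    ClusterTree (topology + merge heights)."""
    s = text.strip()
    if not s.endswith(";"):
        raise DomainError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_label() -> str:
        nonlocal pos
        if pos >= len(s):
            return ""
        if s[pos] == "'":
            pos += 1
            out = []
            while True:
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                    else:
                        pos += 1
                        break
                else:
                    out.append(s[pos])
                    pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        return s[start:pos]

    def parse_length() -> float:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            return float(s[start:pos])
        return 0.0

    def parse_node():
        """Returns (children-or-label, branch_length)."""
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            children = [parse_node()]
            while s[pos] == ",":
                pos += 1
                children.append(parse_node())
            if s[pos] != ")":
                raise DomainError("unbalanced parentheses in Newick")
            pos += 1
            parse_label()  # internal labels ignored
            return children, parse_length()
        return parse_label(), parse_length()

    raw, _ = parse_node()

    leaf_ids: list[str] = []
    counter = [0]

    def build(node):
        sub, bl = node
        if isinstance(sub, str):
            idx = counter[0]
            counter[0] += 1
            leaf_ids.append(sub)
            return ClusterNode(members=(idx,), lane_id=sub), 0.0
        built = [build(c) for c in sub]
        if len(built) != 2:
            raise DomainError("only binary trees are supported")
        (l, hl), (r, hr) = built
        h = max(hl + sub[0][1], hr + sub[1][1])
        node_obj = ClusterNode(
            members=tuple(sorted(l.members + r.members)),
            left=l, right=r, merge_d=2.0 * h)
        return node_obj, h

    if isinstance(raw, str):
        root = ClusterNode(members=(0,), lane_id=raw)
        return ClusterTree(root=root, linkage=linkage, lane_ids=(raw,))
    root, _h = build((raw, 0.0))
    return ClusterTree(root=root, linkage=linkage, lane_ids=tuple(leaf_ids))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_dendrogram(tree: ClusterTree, out_path,
                      annotations: Sequence[str] = (),
                      leaf_info: dict | None = None,
                      figsize: tuple = (8.0, 5.0)) -> None:
    """Draw the dendrogram on a 0-100 similarity axis and save it.

    ``annotations`` selects keys of ``leaf_info[lane_id]`` to print beside
    each leaf label; unknown keys are skipped with a warning. Rendering is
    deterministic: the same tree produces byte-identical SVG.
    """
    import logging

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    leaves = tree.leaves()
    ypos = {id(l): float(k) for k, l in enumerate(leaves)}

    with matplotlib.rc_context({"svg.hashsalt": "gelkit"}):
        fig, ax = plt.subplots(figsize=figsize)

        def draw(node: ClusterNode) -> float:
            if node.is_leaf:
                return ypos[id(node)]
            yl, yr = draw(node.left), draw(node.right)
            s = node.merge_similarity
            sl = 100.0 if node.left.is_leaf else node.left.merge_similarity
            sr = 100.0 if node.right.is_leaf else node.right.merge_similarity
            ax.plot([sl, s], [yl, yl], color="k", lw=1)
            ax.plot([sr, s], [yr, yr], color="k", lw=1)
            ax.plot([s, s], [yl, yr], color="k", lw=1)
            return 0.5 * (yl + yr)

        draw(tree.root)
        info = leaf_info or {}
        known_keys = {k for d in info.values() for k in d}
        for key in annotations:
            if key not in known_keys:
                logging.getLogger(__name__).warning(
                    "unknown annotation key %r skipped", key)
        keys = [k for k in annotations if k in known_keys]
        for k, leaf in enumerate(leaves):
            label = leaf.lane_id
            extra = " ".join(str(info.get(leaf.lane_id, {}).get(key, ""))
                             for key in keys)
            if extra.strip():
                label = f"{label}  [{extra.strip()}]"
            ax.text(101, k, label, va="center", fontsize=8)
        ax.set_xlim(0, 130)
        ax.set_xticks(range(0, 101, 20))
        ax.set_xlabel("similarity (%)")
        ax.set_yticks([])
        ax.invert_xaxis()
        ax.spines[["top", "right", "left"]].set_visible(False)
        fig.savefig(out_path, metadata={"Date": None}
                    if str(out_path).endswith(".svg") else None)
        plt.close(fig)
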