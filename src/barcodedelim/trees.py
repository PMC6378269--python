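"""Rooted trees for delimitation: newick I/O, ultrametricity checks, and
bundled UPGMA / neighbor-joining builders.

Trees are :class:`dendropy.Tree` objects throughout.  The bundled distance
tree builders exist so the tree-based delimiters can be exercised without an
external ML or Bayesian tree; user-supplied newick trees are first-class
inputs.  All trees handed to downstream code are rooted and binary —
polytomies (including the basal trifurcation of unrooted newick) are resolved
with zero-length edges.
"""

from __future__ import annotations

import io
import math
from pathlib import Path

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .errors import TreeError


def _force_binary(tree: dendropy.Tree) -> dendropy.Tree:
    tree.suppress_unifurcations()
    tree.resolve_polytomies(update_bipartitions=False)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            edge.length = 0.0
    return tree


def parse_newick(text: str, require_lengths: bool = True) -> dendropy.Tree:
    """Parse a newick string into a rooted binary tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed newick: {exc}") from exc
    if tree.seed_node is None or not tree.leaf_nodes():
        raise TreeError("newick string contains no tips")
    if require_lengths:
        missing = [
            e for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node and e.length is None
        ]
        if missing:
            raise TreeError(
                f"{len(missing)} edges lack branch lengths (required downstream)"
            )
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate tip labels")
    return _force_binary(tree)


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    text = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def check_tip_alignment_consistency(tree: dendropy.Tree, ids) -> None:
    """Raise unless tree tips and alignment/matrix ids coincide exactly."""
    tips, idset = set(tip_labels(tree)), set(ids)
    if tips != idset:
        raise TreeError(
            f"tree tips and sample ids differ: only-tree={sorted(tips - idset)[:5]}, "
            f"only-ids={sorted(idset - tips)[:5]}"
        )


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Path length from the root to each node."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def node_heights(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Height of each node above its deepest descendant tip."""
    heights: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            heights[node] = max(
                heights[c] + (c.edge.length or 0.0) for c in node.child_nodes()
            )
    return heights


def is_ultrametric(
    tree: dendropy.Tree, rel_tolerance: float = 1e-6
) -> tuple[bool, float]:
    """Whether all root-to-tip paths agree within ``rel_tolerance`` of the
    tree height; also returns the maximum absolute tip-depth deviation."""
    depths = node_depths(tree)
    tip_depths = [depths[leaf] for leaf in tree.leaf_node_iter()]
    height = max(tip_depths)
    dev = max(tip_depths) - min(tip_depths)
    if height == 0.0:
        return True, 0.0
    return dev <= rel_tolerance * height, dev


def upgma_tree(m: DistanceMatrix) -> dendropy.Tree:
    """UPGMA agglomeration of a distance matrix (always ultrametric).

    Node height is half the merge distance.  Ties are broken by the
    lexicographically smallest (min-label, max-label) cluster pair, so the
    construction is deterministic for a given matrix.
    """
    if m.n < 2:
        raise TreeError("UPGMA needs at least 2 ids")
    if np.isnan(m.d).any():
        raise TreeError("distance matrix has undefined entries; resolve them first")

    # active clusters: key -> (sorted member labels, size, newick fragment, height)
    clusters: dict[str, tuple[list[str], int, str, float]] = {
        sid: ([sid], 1, sid, 0.0) for sid in m.ids
    }
    dist: dict[tuple[str, str], float] = {}
    for i in range(m.n):
        for j in range(i + 1, m.n):
            a, b = sorted((m.ids[i], m.ids[j]))
            dist[(a, b)] = float(m.d[m.ids.index(a), m.ids.index(b)])

    while len(clusters) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (ka, kb), dmin = best
        la, na, fa, ha = clusters.pop(ka)
        lb, nb, fb, hb = clusters.pop(kb)
        h = dmin / 2.0
        frag = f"({fa}:{h - ha!r},{fb}:{h - hb!r})"
        new_key = min(ka, kb)
        # average-linkage update against every remaining cluster
        for kc in list(clusters):
            pa = tuple(sorted((ka, kc)))
            pb = tuple(sorted((kb, kc)))
            dnew = (na * dist.pop(pa) + nb * dist.pop(pb)) / (na + nb)
            dist[tuple(sorted((new_key, kc)))] = dnew
        dist.pop((ka, kb), None)
        clusters[new_key] = (sorted(la + lb), na + nb, frag, h)

    (_, _, frag, _h) = next(iter(clusters.values()))
    return parse_newick(frag + ";")


def nj_tree(m: DistanceMatrix, root: str = "midpoint") -> dendropy.Tree:
    """Saitou–Nei neighbor joining, rooted for downstream delimitation.

    Negative branch lengths are clamped to 0.  ``root`` is either
    ``"midpoint"`` or a tip label to use as outgroup.
    """
    if m.n < 3:
        raise TreeError("NJ needs at least 3 ids")
    if np.isnan(m.d).any():
        raise TreeError("distance matrix has undefined entries; resolve them first")
    buf = io.StringIO()
    buf.write("," + ",".join(m.ids) + "\n")
    for i, sid in enumerate(m.ids):
        buf.write(sid + "," + ",".join(repr(float(m.d[i, j])) for j in range(m.n)) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    n_clamped = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            n_clamped += 1
    if n_clamped:
        import warnings

        warnings.warn(f"NJ produced {n_clamped} negative branch lengths; clamped to 0")
    if root == "midpoint":
        tree.reroot_at_midpoint(update_bipartitions=False)
    else:
        og = [l for l in tree.leaf_node_iter() if l.taxon.label == root]
        if not og:
            raise TreeError(f"outgroup tip {root!r} not in tree")
        edge = og[0].edge
        tree.reroot_at_edge(edge, length1=edge.length / 2, length2=edge.length / 2,
                            update_bipartitions=False)
    tree.is_rooted = True
    return _force_binary(tree)


def distance_matrix_from_tree(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic (path-length) distances between tips — handy as an oracle:
    UPGMA on distances from an ultrametric tree reconstructs that tree."""
    from .distances import DistanceModelConfig

    labels = tip_labels(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(tuple(labels), d, DistanceModelConfig(model="p"))


def tree_height(tree: dendropy.Tree) -> float:
    return max(node_depths(tree)[leaf] for leaf in tree.leaf_node_iter())
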