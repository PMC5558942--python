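"""Phylogeny input.

Trees come in as Newick; branch lengths are frequently absent from
supertrees assembled from the literature, in which case every edge is
assigned a default length (1 by convention, turning shared path length
into a shared-branch count).
"""

from __future__ import annotations

from pathlib import Path

import dendropy


class TreeError(ValueError):
    """Fatal problem with a phylogeny."""


def _check_and_default(tree: dendropy.Tree, default_branch_length: float) -> dendropy.Tree:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = sorted({x for x in labels if labels.count(x) > 1})
    if dupes:
        raise TreeError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = default_branch_length
        elif edge.length < 0:
            raise TreeError(f"negative branch length {edge.length}")
    return tree


def read_newick(path, default_branch_length: float = 1.0) -> dendropy.Tree:
    """Parse a rooted Newick tree; missing branch lengths get the default.

    Raises :class:`TreeError` on malformed input or duplicate tip labels.
    """
    if default_branch_length <= 0:
        raise ValueError("default_branch_length must be > 0")
    path = Path(path)
    if not path.exists():
        raise TreeError(f"tree file not found: {path}")
    return parse_newick(path.read_text(), default_branch_length)


def parse_newick(newick: str, default_branch_length: float = 1.0) -> dendropy.Tree:
    """Parse a Newick string (see :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # noqa: BLE001 - dendropy raises several types
        raise TreeError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    return _check_and_default(tree, default_branch_length)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in tree traversal order (stable for a fixed input)."""
    return [lf.taxon.label for lf in tree.leaf_node_iter()]
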