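"""Shared tree utilities on top of dendropy.

All trees in this package are rooted dendropy ``Tree`` objects whose leaves
carry genome identifiers as taxon labels and whose internal nodes carry plain
string labels (species trees) or support values (gene trees).  Helpers here
cover parsing, deterministic serialization (used for tie-breaking), leaf/genome
mapping and exhaustive enumeration of small rooted topologies.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "parse_newick",
    "to_newick",
    "canonical_newick",
    "genome_of_label",
    "leaf_labels",
    "internal_nodes",
    "is_binary",
    "label_internal_nodes",
    "enumerate_rooted_topologies",
    "tree_from_nested",
]

_COPY_SUFFIX = re.compile(r"_copy\d+$")


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a rooted newick string; internal labels kept as node labels."""
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
        rooting="force-rooted",
    )


def to_newick(tree: dendropy.Tree, *, lengths: bool = True) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_edge_lengths=not lengths,
        unquoted_underscores=True,
    ).strip()


def _canon(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label if node.taxon else (node.label or "")
    parts = sorted(_canon(c) for c in node.child_nodes())
    return "(" + ",".join(parts) + ")"


def canonical_newick(tree: dendropy.Tree) -> str:
    """Topology-only newick with children sorted; deterministic tie-break key."""
    return _canon(tree.seed_node) + ";"


def genome_of_label(label: str) -> str:
    """Genome id behind a gene-tree leaf label (``gid_copyN`` or bare ``gid``)."""
    return _COPY_SUFFIX.sub("", label)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def internal_nodes(tree: dendropy.Tree) -> list[dendropy.Node]:
    return [n for n in tree.preorder_node_iter() if not n.is_leaf()]


def is_binary(tree: dendropy.Tree) -> bool:
    return all(len(n.child_nodes()) == 2 for n in internal_nodes(tree))


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "n") -> dendropy.Tree:
    """Assign labels ``n1..nk`` (preorder) to unlabeled internal nodes, in place."""
    k = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            k += 1
            node.label = f"{prefix}{k}"
    return tree


def enumerate_rooted_topologies(labels: Iterable[str]) -> Iterator[tuple]:
    """Yield every rooted binary topology on ``labels`` as nested tuples.

    The count is (2n-3)!! for n labels; intended for exhaustive sweeps on
    n <= 7.  Leaves appear as bare strings, internal nodes as 2-tuples.
    """
    labels = list(labels)
    if not labels:
        return
    if len(labels) == 1:
        yield labels[0]
        return

    def _grow(shape, leaf):
        # insert `leaf` on every edge of `shape`, including above the root
        yield (shape, leaf)
        if isinstance(shape, tuple):
            left, right = shape
            for sub in _grow(left, leaf):
                yield (sub, right)
            for sub in _grow(right, leaf):
                yield (left, sub)

    shapes: list = [labels[0]]
    for leaf in labels[1:]:
        shapes = [grown for shape in shapes for grown in _grow(shape, leaf)]
    yield from shapes


def tree_from_nested(shape, *, label_internals: bool = True) -> dendropy.Tree:
    """Build a dendropy tree from nested tuples of leaf-label strings."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def _build(s) -> dendropy.Node:
        node = dendropy.Node()
        if isinstance(s, tuple):
            for child in s:
                node.add_child(_build(child))
        else:
            node.taxon = taxa.require_taxon(label=str(s))
        return node

    tree.seed_node = _build(shape)
    tree.is_rooted = True
    if label_internals:
        label_internal_nodes(tree)
    return tree
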