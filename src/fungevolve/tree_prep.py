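"""Pre-reconciliation tree conditioning.

Families outside the 4..1000 sequence range are dropped, weakly supported
gene-tree branches (SH-like < 0.90, or bootstrap < 50 on the species tree) are
collapsed into polytomies, and the species phylogeny can be pruned down to the
taxa present in a gene family.  Thresholds are strict less-than; family-size
bounds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import dendropy

from .trees import leaf_labels

__all__ = [
    "MIN_FAMILY_SIZE",
    "MAX_FAMILY_SIZE",
    "GeneFamily",
    "SpeciesPhylogeny",
    "filter_family_size",
    "collapse_low_support",
    "prune_species_tree",
]

MIN_FAMILY_SIZE = 4
MAX_FAMILY_SIZE = 1000

_SCALE_MAX = {"sh": 1.0, "bootstrap": 100.0}


@dataclass
class GeneFamily:
    """A gene family: its tree, EC number and optional alignment metadata.

    ``alignment_length`` is carried as metadata when upstream trimmed
    alignment lengths are available; families shorter than 150 residues can be
    flagged by the caller but no alignment work happens here.
    """

    family_id: str
    tree: dendropy.Tree
    ec_number: Optional[str] = None
    support_scale: str = "sh"
    alignment_length: Optional[int] = None

    @property
    def size(self) -> int:
        return len(leaf_labels(self.tree))


@dataclass
class SpeciesPhylogeny:
    """Bifurcating and consensus renderings of one species phylogeny.

    The consensus tree is the bifurcating tree with poorly supported branches
    collapsed, so the two must share a leaf set; per-leaf lineage annotations
    (e.g. Pezizomycotina, Saccharomycotina, Agaricomycetes) ride along for the
    summary statistics.
    """

    bifurcating: dendropy.Tree
    consensus: dendropy.Tree
    lineages: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(leaf_labels(self.bifurcating)) != set(leaf_labels(self.consensus)):
            raise ValueError("bifurcating and consensus trees differ in leaf sets")


def filter_family_size(
    families: Mapping[str, int] | Iterable[tuple[str, int]],
    min_size: int = MIN_FAMILY_SIZE,
    max_size: int = MAX_FAMILY_SIZE,
) -> list[str]:
    """Family ids whose sequence count n satisfies ``min_size <= n <= max_size``."""
    items = families.items() if isinstance(families, Mapping) else families
    return [fid for fid, n in items if min_size <= n <= max_size]


def _branch_support(node: dendropy.Node) -> Optional[float]:
    if node.label is None or node.label == "":
        return None
    try:
        return float(node.label)
    except ValueError:
        return None  # a name, not a support value


def collapse_low_support(
    tree: dendropy.Tree,
    threshold: float,
    scale: str = "sh",
) -> dendropy.Tree:
    """Contract internal branches with support strictly below ``threshold``.

    Supports are read from internal node labels.  ``scale`` declares the
    support convention ("sh" on [0, 1] or "bootstrap" on [0, 100]) and is
    validated against the observed values rather than sniffed.  Branches with
    support exactly at the threshold, or without a numeric support, are kept.
    Returns a collapsed copy; the input is untouched.  Idempotent.
    """
    if scale not in _SCALE_MAX:
        raise ValueError(f"unknown support scale: {scale!r}")
    if not 0 <= threshold <= _SCALE_MAX[scale]:
        raise ValueError(f"threshold {threshold} outside the {scale} scale")
    out = tree.clone(depth=1)
    to_collapse = []
    for node in out.preorder_internal_node_iter(exclude_seed_node=True):
        support = _branch_support(node)
        if support is None:
            continue
        if support > _SCALE_MAX[scale]:
            raise ValueError(
                f"support {support} exceeds the {scale} scale maximum "
                f"{_SCALE_MAX[scale]}"
            )
        if support < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out


def prune_species_tree(
    species_tree: dendropy.Tree,
    taxa: Iterable[str],
) -> dendropy.Tree:
    """Induced subtree on ``taxa``; internal labels preserved, unary nodes gone."""
    wanted = set(taxa)
    present = set(leaf_labels(species_tree))
    unknown = sorted(wanted - present)
    if unknown:
        raise ValueError(f"taxa absent from the species tree: {unknown}")
    if len(wanted) < 2:
        raise ValueError("pruning needs at least two retained taxa")
    out = species_tree.clone(depth=1)
    out.retain_taxa_with_labels(sorted(wanted))
    # dendropy can leave the seed node unifurcating after pruning; a root with
    # one child is not a meaningful rooted tree, so hoist the child while
    # keeping the deeper surviving label.
    while len(out.seed_node.child_nodes()) == 1:
        child = out.seed_node.child_nodes()[0]
        grandchildren = list(child.child_nodes())
        if not grandchildren:
            break  # degenerate single-leaf tree
        if out.seed_node.label is None:
            out.seed_node.label = child.label
        out.seed_node.remove_child(child)
        for grandchild in grandchildren:
            out.seed_node.add_child(grandchild)
    return out
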