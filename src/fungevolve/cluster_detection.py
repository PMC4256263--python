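"""Metabolic gene-cluster calling from gene order and pathway adjacency.

Two ECgenes on the same scaffold form a clustered pair when (i) at most six
annotated genes lie between them in the published gene order and (ii) some EC
number of one is a nearest-neighbor reaction of some EC number of the other in
at least one pathway.  Pair ranges are then joined transitively -- overlapping
ranges, or ranges separated by at most six intervening genes, merge into one
cluster.  Intervening counts use ordinal positions, so non-EC genes count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .ec_annotation import GeneRecord

__all__ = [
    "MAX_INTERVENING",
    "GeneCluster",
    "build_ec_adjacency",
    "find_clustered_pairs",
    "merge_pairs_to_clusters",
    "call_clusters",
    "cluster_summary",
]

MAX_INTERVENING = 6


@dataclass(frozen=True)
class GeneCluster:
    """A maximal merged run of clustered ECgenes on one scaffold."""

    genome_id: str
    scaffold_id: str
    members: tuple[GeneRecord, ...]  # ordered by ordinal
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a gene cluster needs at least two members")
        scaffolds = {g.scaffold_id for g in self.members}
        if scaffolds != {self.scaffold_id}:
            raise ValueError("cluster members must share one scaffold")

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.members)


def build_ec_adjacency(
    pathway_definitions: Iterable[tuple[str, str, str]],
) -> nx.Graph:
    """Union of nearest-neighbor EC edges over pathways.

    ``pathway_definitions`` yields ``(pathway_id, ec_a, ec_b)`` rows, one per
    directly connected reaction pair (no intermediate reaction) within one
    pathway.  Edges carry the set of supporting pathway ids under the
    ``pathways`` attribute.  Self-pairs are malformed and rejected.
    """
    graph = nx.Graph()
    for row in pathway_definitions:
        try:
            pathway_id, ec_a, ec_b = row
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed pathway row: {row!r}") from exc
        if not ec_a or not ec_b:
            raise ValueError(f"malformed pathway {pathway_id!r}: empty EC in {row!r}")
        if ec_a == ec_b:
            raise ValueError(
                f"malformed pathway {pathway_id!r}: self-edge on EC {ec_a!r}"
            )
        if graph.has_edge(ec_a, ec_b):
            graph.edges[ec_a, ec_b]["pathways"].add(pathway_id)
        else:
            graph.add_edge(ec_a, ec_b, pathways={pathway_id})
    return graph


def _ec_adjacent(a: GeneRecord, b: GeneRecord, graph: nx.Graph) -> bool:
    return any(
        graph.has_edge(ec_a, ec_b) for ec_a in a.ec_set for ec_b in b.ec_set
    )


def find_clustered_pairs(
    genes_on_scaffold: Sequence[GeneRecord],
    graph: nx.Graph,
    max_intervening: int = MAX_INTERVENING,
) -> list[tuple[GeneRecord, GeneRecord]]:
    """All ECgene pairs within the intervening-gene window that are EC-adjacent.

    The intervening count between ordinals ``i < j`` is ``j - i - 1`` and
    counts every annotated gene, EC-bearing or not; the window is inclusive at
    ``max_intervening``.  Genes may be passed in any order.
    """
    ecgenes = sorted(
        (g for g in genes_on_scaffold if g.is_ecgene), key=lambda g: g.ordinal
    )
    scaffolds = {g.scaffold_id for g in ecgenes}
    if len(scaffolds) > 1:
        raise ValueError(f"genes span multiple scaffolds: {sorted(scaffolds)}")
    pairs: list[tuple[GeneRecord, GeneRecord]] = []
    for a, b in combinations(ecgenes, 2):
        if b.ordinal - a.ordinal - 1 > max_intervening:
            continue
        if _ec_adjacent(a, b, graph):
            pairs.append((a, b))
    return pairs


def merge_pairs_to_clusters(
    pairs: Sequence[tuple[GeneRecord, GeneRecord]],
    max_intervening: int = MAX_INTERVENING,
) -> list[GeneCluster]:
    """Join overlapping pair ranges, and ranges within the intervening window.

    Each pair spans ``[min ordinal, max ordinal]``.  Ranges merge transitively
    when they overlap or when at most ``max_intervening`` genes separate them.
    Cluster members are the union of the pair genes (intervening non-EC genes
    are not members).  Output is sorted by span; input order is irrelevant.
    """
    if not pairs:
        return []
    ranges = sorted(
        (
            (min(a.ordinal, b.ordinal), max(a.ordinal, b.ordinal), (a, b))
            for a, b in pairs
        ),
        key=lambda r: (r[0], r[1]),
    )
    clusters: list[GeneCluster] = []
    cur_lo, cur_hi, cur_genes = ranges[0][0], ranges[0][1], set(ranges[0][2])
    for lo, hi, genes in ranges[1:]:
        if lo - cur_hi - 1 <= max_intervening:  # overlap gives a negative gap
            cur_hi = max(cur_hi, hi)
            cur_genes.update(genes)
        else:
            clusters.append(_make_cluster(cur_genes))
            cur_lo, cur_hi, cur_genes = lo, hi, set(genes)
    clusters.append(_make_cluster(cur_genes))
    return clusters


def _make_cluster(genes: set[GeneRecord]) -> GeneCluster:
    members = tuple(sorted(genes, key=lambda g: g.ordinal))
    return GeneCluster(
        genome_id=members[0].genome_id,
        scaffold_id=members[0].scaffold_id,
        members=members,
        span=(members[0].ordinal, members[-1].ordinal),
    )


def call_clusters(
    genes: Sequence[GeneRecord],
    graph: nx.Graph,
    max_intervening: int = MAX_INTERVENING,
) -> list[GeneCluster]:
    """Cluster calling across all genomes and scaffolds of a gene table."""
    by_scaffold: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_scaffold.setdefault((g.genome_id, g.scaffold_id), []).append(g)
    clusters: list[GeneCluster] = []
    for key in sorted(by_scaffold):
        pairs = find_clustered_pairs(by_scaffold[key], graph, max_intervening)
        clusters.extend(merge_pairs_to_clusters(pairs, max_intervening))
    return clusters


def cluster_summary(
    genes: Sequence[GeneRecord],
    clusters: Sequence[GeneCluster],
) -> pd.DataFrame:
    """Per-genome clustering summary.

    Columns: ``n_ecgenes``, ``n_clustered_ecgenes``, ``pct_clustered``,
    ``n_clusters`` and ``undefined`` (True where a genome has no ECgenes, in
    which case the percentage is reported as 0 rather than NaN).  A totals row
    labeled ``__all__`` is appended.
    """
    genomes = sorted({g.genome_id for g in genes})
    clustered_ids: dict[str, set[str]] = {g: set() for g in genomes}
    n_clusters: dict[str, int] = {g: 0 for g in genomes}
    for cluster in clusters:
        clustered_ids.setdefault(cluster.genome_id, set()).update(cluster.member_ids)
        n_clusters[cluster.genome_id] = n_clusters.get(cluster.genome_id, 0) + 1
    rows = []
    for genome in genomes:
        n_ec = sum(1 for g in genes if g.genome_id == genome and g.is_ecgene)
        n_clu = len(clustered_ids[genome])
        rows.append(
            {
                "genome_id": genome,
                "n_ecgenes": n_ec,
                "n_clustered_ecgenes": n_clu,
                "pct_clustered": 100.0 * n_clu / n_ec if n_ec else 0.0,
                "n_clusters": n_clusters[genome],
                "undefined": n_ec == 0,
            }
        )
    total_ec = sum(r["n_ecgenes"] for r in rows)
    total_clu = sum(r["n_clustered_ecgenes"] for r in rows)
    rows.append(
        {
            "genome_id": "__all__",
            "n_ecgenes": total_ec,
            "n_clustered_ecgenes": total_clu,
            "pct_clustered": 100.0 * total_clu / total_ec if total_ec else 0.0,
            "n_clusters": sum(r["n_clusters"] for r in rows),
            "undefined": total_ec == 0,
        }
    )
    return pd.DataFrame(rows).set_index("genome_id")
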