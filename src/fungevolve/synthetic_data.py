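"""Forward simulation with planted ground truth.

Everything downstream of the external annotation and tree-building tools is
exercised on synthetic inputs: an ultrametric random species tree, gene
families evolved branch-wise with planted duplication/transfer/loss events,
genome layouts with planted metabolic gene clusters consistent with a
synthetic pathway graph, and similarity-hit tables with a planted KO truth
plus optional decoy noise.

The gene-family model is a discrete branch-wise scheme rather than a
continuous-time birth-death process: on each species-tree branch of length
``b`` a gene lineage draws ``Poisson(rate * b)`` duplications and transfers
and survives the branch with probability ``exp(-loss_rate * b)``, the
standard reading of per-lineage event rates on a time-calibrated tree.  Transfer recipients are drawn
uniformly from branches whose time spans overlap the donor branch on the
ultrametric species tree and that are neither ancestors nor descendants of
the donor; transfers from the root branch cannot occur (the root branch has
zero length).  A duplicate copy created on a branch experiences no further
events on that same branch (it starts evolving at the branch's lower end).
Only the event vocabulary matters downstream, so this simple, fully
reproducible scheme is used instead of a Gillespie simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import networkx as nx
import numpy as np

from .cluster_detection import build_ec_adjacency
from .ec_annotation import GeneRecord, SimilarityHit
from .trees import label_internal_nodes, leaf_labels

__all__ = [
    "NoiseConfig",
    "SimulationConfig",
    "PlantedEvent",
    "PlantedCluster",
    "SimulationTruth",
    "genome_labels",
    "simulate_species_tree",
    "simulate_gene_family",
    "replay_leaf_count",
    "simulate_pathways",
    "make_ko_ec_map",
    "plant_genome_layout",
    "simulate_hit_table",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Hit-table perturbation parameters.

    ``identity_jitter`` is the s.d. of Gaussian noise on the true hit's
    percent identity (around 90%); ``decoy_rate`` is the expected number of
    decoy hits per gene (wrong KO, low identity, poor e-value);
    ``low_identity_fraction`` is the fraction of genes whose true hit falls
    below the 80% identity tier so that assignment must go through the
    e-value-gap fallback.
    """

    identity_jitter: float = 2.0
    decoy_rate: float = 0.0
    low_identity_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.identity_jitter < 0 or self.decoy_rate < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0 <= self.low_identity_fraction <= 1:
            raise ValueError("low_identity_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """One synthetic study: genomes, evolutionary rates and planted layout."""

    n_taxa: int = 12
    dup_rate: float = 0.1
    transfer_rate: float = 0.05
    loss_rate: float = 0.05
    n_families: int = 50
    seed: int = 0
    cluster_spec: tuple[tuple[int, int], ...] = ()
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    genes_per_genome: int = 60
    n_scattered_ecgenes: int = 4

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        for name in ("dup_rate", "transfer_rate", "loss_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for n_genes, gap in self.cluster_spec:
            if n_genes < 2 or gap < 0:
                raise ValueError("cluster_spec entries need n_genes >= 2, gap >= 0")


@dataclass(frozen=True)
class PlantedEvent:
    """One planted evolutionary event on the species tree.

    ``branch`` names the species branch (by its lower node) where the event
    happened; for transfers ``donor``/``recipient`` are set and ``branch``
    equals the donor.  ``lineage`` is the gene lineage the event acted on and
    ``child_lineage`` the lineage a duplication or transfer created.
    """

    kind: str  # duplication | transfer | loss
    branch: str
    lineage: int
    donor: Optional[str] = None
    recipient: Optional[str] = None
    child_lineage: Optional[int] = None


@dataclass(frozen=True)
class PlantedCluster:
    genome_id: str
    scaffold_id: str
    gene_ids: tuple[str, ...]
    intervening_gap: int


@dataclass
class SimulationTruth:
    """Planted ground truth: events per family, clusters, per-gene KO."""

    events: dict[str, list[PlantedEvent]] = field(default_factory=dict)
    clusters: list[PlantedCluster] = field(default_factory=list)
    true_ko: dict[str, str] = field(default_factory=dict)

    def transfer_pairs(self, family_id: str) -> set[tuple[str, str]]:
        return {
            (e.donor, e.recipient)
            for e in self.events.get(family_id, [])
            if e.kind == "transfer"
        }


def genome_labels(n_taxa: int) -> list[str]:
    return [f"g{i:02d}" for i in range(1, n_taxa + 1)]


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Random rooted binary ultrametric species tree with labeled internals.

    Coalescent-style: leaves start at age 0 and random pairs join at strictly
    increasing ages.  Leaves are ``g01..gNN``, internal nodes ``n1..n(N-1)``
    in join order (the root gets the last label).  Deterministic per seed.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    lineages: list[tuple[dendropy.Node, float]] = []
    for label in genome_labels(n_taxa):
        node = dendropy.Node()
        node.taxon = taxa.require_taxon(label=label)
        lineages.append((node, 0.0))
    age = 0.0
    join = 0
    while len(lineages) > 1:
        k = len(lineages)
        age += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        join += 1
        parent = dendropy.Node()
        parent.label = f"n{join}"
        for child, child_age in (lineages[i], lineages[j]):
            parent.add_child(child)
            child.edge.length = age - child_age
        lineages = [
            lin for t, lin in enumerate(lineages) if t not in (i, j)
        ] + [(parent, age)]
    tree.seed_node = lineages[0][0]
    tree.is_rooted = True
    return tree


def _node_ages(tree: dendropy.Tree) -> dict[int, float]:
    ages: dict[int, float] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            ages[id(nd)] = 0.0
        else:
            ages[id(nd)] = max(
                ages[id(c)] + (c.edge.length or 1.0) for c in nd.child_nodes()
            )
    return ages


def _node_name(nd: dendropy.Node) -> str:
    return nd.taxon.label if nd.taxon else nd.label


# ---------------------------------------------------------------------------
# gene families


def simulate_gene_family(
    species_tree: dendropy.Tree,
    dup_rate: float,
    transfer_rate: float,
    loss_rate: float,
    seed: int,
) -> tuple[Optional[dendropy.Tree], list[PlantedEvent]]:
    """Evolve one gene family along the species tree.

    Returns the rooted binary gene tree (leaves ``genome_copyN`` with N in
    simulation order) and the list of planted events.  A family whose copies
    are all lost returns ``(None, events)``.
    """
    for rate, name in (
        (dup_rate, "dup_rate"),
        (transfer_rate, "transfer_rate"),
        (loss_rate, "loss_rate"),
    ):
        if rate < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    ages = _node_ages(species_tree)
    nodes = sorted(
        species_tree.preorder_node_iter(), key=lambda nd: _node_name(nd)
    )
    root = species_tree.seed_node
    span: dict[int, tuple[float, float]] = {}  # node id -> (low, high) branch ages
    for nd in species_tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        span[id(nd)] = (ages[id(nd)], ages[id(nd.parent_node)])
    anc_ids: dict[int, set[int]] = {}
    for nd in species_tree.preorder_node_iter():
        own = {id(nd)}
        if nd.parent_node is not None:
            own |= anc_ids[id(nd.parent_node)]
        anc_ids[id(nd)] = own

    def _transfer_targets(donor: dendropy.Node) -> list[dendropy.Node]:
        lo_d, hi_d = span[id(donor)]
        out = []
        for cand in nodes:
            if cand is root or cand is donor:
                continue
            if id(cand) in anc_ids[id(donor)] or id(donor) in anc_ids[id(cand)]:
                continue
            lo, hi = span[id(cand)]
            if lo < hi_d and lo_d < hi:
                out.append(cand)
        return out

    events: list[PlantedEvent] = []
    copy_counter: dict[str, int] = {}
    next_lineage = [0]

    def _new_lineage() -> int:
        next_lineage[0] += 1
        return next_lineage[0]

    def _at_node(v: dendropy.Node, lineage: int) -> Optional[dendropy.Node]:
        if v.is_leaf():
            genome = v.taxon.label
            copy_counter[genome] = copy_counter.get(genome, 0) + 1
            leaf = dendropy.Node()
            leaf.label = f"{genome}_copy{copy_counter[genome]}"
            return leaf
        alive = [
            sub
            for c in v.child_nodes()
            if (sub := _enter_branch(c, lineage)) is not None
        ]
        if not alive:
            return None
        if len(alive) == 1:
            return alive[0]
        node = dendropy.Node()
        for sub in alive:
            node.add_child(sub)
        return node

    def _enter_branch(v: dendropy.Node, lineage: int) -> Optional[dendropy.Node]:
        lo, hi = span[id(v)]
        blen = hi - lo
        if loss_rate > 0 and rng.random() >= math.exp(-loss_rate * blen):
            events.append(PlantedEvent("loss", _node_name(v), lineage))
            return None
        kinds = ["D"] * rng.poisson(dup_rate * blen) + [
            "T"
        ] * rng.poisson(transfer_rate * blen)
        rng.shuffle(kinds)
        return _chain(v, lineage, kinds)

    def _chain(
        v: dendropy.Node, lineage: int, kinds: list[str]
    ) -> Optional[dendropy.Node]:
        if not kinds:
            return _at_node(v, lineage)
        kind, rest = kinds[0], kinds[1:]
        if kind == "D":
            child_lin = _new_lineage()
            events.append(
                PlantedEvent(
                    "duplication", _node_name(v), lineage, child_lineage=child_lin
                )
            )
            cont = _chain(v, lineage, rest)
            copy = _at_node(v, child_lin)
        else:
            targets = _transfer_targets(v)
            if not targets:
                return _chain(v, lineage, rest)
            r = targets[int(rng.integers(len(targets)))]
            child_lin = _new_lineage()
            events.append(
                PlantedEvent(
                    "transfer",
                    _node_name(v),
                    lineage,
                    donor=_node_name(v),
                    recipient=_node_name(r),
                    child_lineage=child_lin,
                )
            )
            cont = _chain(v, lineage, rest)
            copy = _enter_branch(r, child_lin)
        if cont is None:
            return copy
        if copy is None:
            return cont
        node = dendropy.Node()
        node.add_child(cont)
        node.add_child(copy)
        return node

    root_lineage = _new_lineage()
    gene_root = _at_node(root, root_lineage)
    if gene_root is None:
        return None, events
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = gene_root
    tree.is_rooted = True
    for leaf in tree.leaf_node_iter():
        leaf.taxon = taxa.require_taxon(label=leaf.label)
        leaf.label = None
    return tree, events


def replay_leaf_count(
    species_tree: dendropy.Tree, events: Sequence[PlantedEvent]
) -> int:
    """Leaf count implied by replaying a planted event list.

    Independent of the generator's recursion: each gene lineage is born at
    the species root (the founding lineage) or at the branch its duplication
    or transfer created it on, and contributes one gene copy for every
    species leaf reachable from its birth point without crossing a branch on
    which that lineage was lost.
    """
    by_name = {_node_name(nd): nd for nd in species_tree.preorder_node_iter()}
    root = species_tree.seed_node
    births: dict[int, dendropy.Node] = {1: root}  # lineage 1 founds the family
    for e in events:
        if e.child_lineage is not None:
            birth = by_name[e.recipient if e.kind == "transfer" else e.branch]
            births[e.child_lineage] = birth
    losses = {(e.lineage, e.branch) for e in events if e.kind == "loss"}

    def _count(lineage: int, nd: dendropy.Node, entering_branch: bool) -> int:
        if entering_branch and (lineage, _node_name(nd)) in losses:
            return 0
        if nd.is_leaf():
            return 1
        return sum(_count(lineage, c, True) for c in nd.child_nodes())

    total = 0
    for lineage, birth in births.items():
        # the founding lineage starts at the root node itself; all others
        # start on (and can be lost on) their birth branch
        total += _count(lineage, birth, entering_branch=birth is not root)
    return total


# ---------------------------------------------------------------------------
# pathways, layouts, hit tables


def simulate_pathways(
    n_pathways: int = 3, chain_length: int = 6, seed: int = 0
) -> tuple[list[tuple[str, str, str]], nx.Graph]:
    """Synthetic linear pathways and their nearest-neighbor EC graph.

    Pathway ``p`` is a chain of ``chain_length`` reactions with EC numbers
    ``1.2.p.j``; consecutive reactions are nearest neighbors.  With more than
    one pathway, a shared EC links each pathway's first reaction to the
    previous pathway's last, mimicking overlapping KEGG maps.
    """
    if n_pathways < 1 or chain_length < 2:
        raise ValueError("need n_pathways >= 1 and chain_length >= 2")
    definitions: list[tuple[str, str, str]] = []
    for p in range(1, n_pathways + 1):
        ecs = [f"1.2.{p}.{j}" for j in range(1, chain_length + 1)]
        pid = f"map{p:05d}"
        for a, b in zip(ecs, ecs[1:]):
            definitions.append((pid, a, b))
    return definitions, build_ec_adjacency(definitions)


def make_ko_ec_map(
    pathway_graph: nx.Graph, n_non_enzyme_kos: int = 0
) -> dict[str, frozenset[str]]:
    """One KO per EC (``K00001``...) plus optional KOs with no EC."""
    mapping: dict[str, frozenset[str]] = {}
    for i, ec in enumerate(sorted(pathway_graph.nodes), start=1):
        mapping[f"K{i:05d}"] = frozenset([ec])
    for j in range(1, n_non_enzyme_kos + 1):
        mapping[f"K9{j:04d}"] = frozenset()
    return mapping


def _ko_of_ec(pathway_graph: nx.Graph) -> dict[str, str]:
    return {
        ec: f"K{i:05d}" for i, ec in enumerate(sorted(pathway_graph.nodes), start=1)
    }


def _find_ec_path(graph: nx.Graph, length: int, rng: np.random.Generator) -> list[str]:
    """A simple path of ``length`` nodes, or raise if the graph has none."""
    nodes = sorted(graph.nodes)
    order = list(rng.permutation(len(nodes)))

    def _dfs(path: list[str]) -> Optional[list[str]]:
        if len(path) == length:
            return path
        for nb in sorted(graph.neighbors(path[-1])):
            if nb not in path:
                found = _dfs(path + [nb])
                if found:
                    return found
        return None

    for k in order:
        found = _dfs([nodes[k]])
        if found:
            return found
    raise ValueError(
        f"pathway graph has no chain of {length} adjacent EC numbers"
    )


# planted features are separated by at least this many positions so that
# nothing outside a planted cluster can fall within the 6-gene window
_PAD = 8


def plant_genome_layout(
    config: SimulationConfig,
    pathway_graph: nx.Graph,
    seed: int,
) -> tuple[list[GeneRecord], SimulationTruth]:
    """Gene-order tables with planted clusters and scattered ECgenes.

    Every genome gets one scaffold.  For each ``(n_genes, gap)`` entry of
    ``config.cluster_spec`` a run of ``n_genes`` genes whose ECs form a path
    in the pathway graph is planted with ``gap`` intervening non-EC genes
    between consecutive members.  ``n_scattered_ecgenes`` additional single
    ECgenes are placed at least 8 positions away from any other ECgene.
    Remaining positions are filler genes with KOs that map to no EC.
    """
    rng = np.random.default_rng(seed)
    ko_of_ec = _ko_of_ec(pathway_graph)
    records: list[GeneRecord] = []
    truth = SimulationTruth()
    for genome in genome_labels(config.n_taxa):
        scaffold = "sc1"
        planted: dict[int, tuple[str, str]] = {}  # ordinal -> (ec, ko)
        cursor = int(rng.integers(0, 3))
        for ci, (n_genes, gap) in enumerate(config.cluster_spec, start=1):
            path = _find_ec_path(pathway_graph, n_genes, rng)
            ordinals = [cursor + k * (gap + 1) for k in range(n_genes)]
            gene_ids = tuple(
                f"{genome}:c{ci}:{k + 1}" for k in range(n_genes)
            )
            for pos, ec, gid in zip(ordinals, path, gene_ids):
                planted[pos] = (ec, ko_of_ec[ec], gid)
            truth.clusters.append(
                PlantedCluster(genome, scaffold, gene_ids, intervening_gap=gap)
            )
            cursor = ordinals[-1] + _PAD + 1
        for _ in range(config.n_scattered_ecgenes):
            ec = sorted(pathway_graph.nodes)[
                int(rng.integers(len(pathway_graph.nodes)))
            ]
            planted[cursor] = (ec, ko_of_ec[ec], None)
            cursor += _PAD
        total = max(config.genes_per_genome, cursor + 1)
        filler_i = 0
        for pos in range(total):
            if pos in planted:
                ec, ko, gid = planted[pos]
                gene_id = gid if gid else f"{genome}:e{pos}"
                rec = GeneRecord(
                    gene_id=gene_id,
                    genome_id=genome,
                    scaffold_id=scaffold,
                    ordinal=pos,
                    strand="+" if rng.random() < 0.5 else "-",
                    ko=ko,
                    ec_set=frozenset([ec]),
                )
            else:
                filler_i += 1
                rec = GeneRecord(
                    gene_id=f"{genome}:f{filler_i}",
                    genome_id=genome,
                    scaffold_id=scaffold,
                    ordinal=pos,
                    strand="+" if rng.random() < 0.5 else "-",
                    ko=f"K9{(filler_i % 50) + 1:04d}",
                    ec_set=frozenset(),
                )
            truth.true_ko[rec.gene_id] = rec.ko
            records.append(rec)
    return records, truth


def simulate_hit_table(
    gene_records: Sequence[GeneRecord],
    noise: NoiseConfig,
    seed: int,
) -> list[SimilarityHit]:
    """Similarity hits whose best hit encodes each gene's true KO.

    In noise-free mode every gene's single hit has >80% identity, <=10%
    length difference and a tiny e-value, so the high-identity tier recovers
    the planted KO exactly.  ``low_identity_fraction`` genes instead get a
    sub-threshold true hit (exercising the e-value fallback) and
    ``decoy_rate`` adds wrong-KO hits whose e-values sit beyond the 1e-50
    truncation gap.
    """
    rng = np.random.default_rng(seed)
    kos = sorted({g.ko for g in gene_records if g.ko})
    hits: list[SimilarityHit] = []
    for gene in gene_records:
        if gene.ko is None:
            continue
        qlen = int(rng.integers(200, 600))
        low_tier = rng.random() < noise.low_identity_fraction
        if low_tier:
            pident = float(rng.uniform(50.0, 75.0))
        else:
            pident = float(
                np.clip(90.0 + noise.identity_jitter * rng.standard_normal(), 80.5, 100.0)
            )
        slen = int(round(qlen * float(rng.uniform(0.95, 1.05))))
        evalue = float(10.0 ** -rng.uniform(100.0, 200.0))
        hits.append(
            SimilarityHit(
                query_id=gene.gene_id,
                subject_id=f"ref|{gene.ko}|1",
                subject_ko=gene.ko,
                percent_identity=round(pident, 1),
                query_length=qlen,
                subject_length=slen,
                evalue=evalue,
            )
        )
        for d in range(rng.poisson(noise.decoy_rate)):
            wrong = kos[int(rng.integers(len(kos)))]
            if wrong == gene.ko and len(kos) > 1:
                wrong = kos[(kos.index(wrong) + 1) % len(kos)]
            hits.append(
                SimilarityHit(
                    query_id=gene.gene_id,
                    subject_id=f"ref|{wrong}|d{d}",
                    subject_ko=wrong,
                    percent_identity=round(float(rng.uniform(35.0, 70.0)), 1),
                    query_length=qlen,
                    subject_length=int(rng.integers(150, 700)),
                    evalue=float(10.0 ** -rng.uniform(3.0, 40.0)),
                )
            )
    return hits
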