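"""Gene-tree / species-tree reconciliation under DTL+ILS event parsimony.

A rooted binary gene tree is mapped into a rooted species tree while labeling
every internal gene node with one of four events -- speciation, duplication,
transfer or ILS -- and charging losses for lineages that disappear from
species branches.  The optimum minimizes

    total = dup_cost * #dup + transfer_cost * #transfer
          + loss_cost * #loss + ils_cost * #ILS

by dynamic programming over (gene node x species node).  The model is undated:
a transfer may land on any species branch that is neither an ancestor nor a
descendant of the donor branch, with no global time-consistency constraint.
Transfers to or from the root branch are impossible (the root is comparable to
every branch).

Incomplete lineage sorting is confined to species-tree polytomies: within one
consensus polytomy, gene lineages may branch in any order at ``ils_cost``
(default 0) per branching, provided sibling lineages claim disjoint subsets of
the polytomy's children -- overlapping claims require a duplication, because
ILS cannot create extra gene copies.  Conflict spanning resolved species
branches is never labeled ILS.  Loss accounting at a polytomy follows the best
binary resolution: a lineage that enters the polytomy from above but survives
in only a subset of its children is charged a single loss.

Co-optimal reconciliations are resolved deterministically: fewer transfers,
then fewer duplications, then a fixed traversal order over species nodes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from . import trees as _t
from .tree_prep import prune_species_tree

__all__ = [
    "CostScheme",
    "ReconciliationResult",
    "HGTEventKey",
    "HGTDedupResult",
    "reconcile_dtl",
    "root_by_event_parsimony",
    "resolve_polytomies",
    "bruteforce_min_cost",
    "dedupe_hgt_events",
]

_INF = (math.inf, 0, 0)
_ZERO = (0.0, 0, 0)

# events
SPECIATION = "speciation"
DUPLICATION = "duplication"
TRANSFER = "transfer"
ILS = "ils"

_MAX_POLYTOMY_CLAIM = 14  # subset DP guard


@dataclass(frozen=True)
class CostScheme:
    """Event costs for the parsimony reconciliation.

    Defaults follow the scheme used throughout this package: duplication 1.5,
    loss 1, ILS 0 and transfer 6 with species-tree pruning enabled.  Transfer
    costs {2, 4, 6, 8, 10, 12} form the evaluation grid; 6 is the default.
    """

    dup_cost: float = 1.5
    transfer_cost: float = 6.0
    loss_cost: float = 1.0
    ils_cost: float = 0.0
    prune: bool = True

    def __post_init__(self) -> None:
        for name in ("dup_cost", "transfer_cost", "loss_cost", "ils_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.transfer_cost <= 0:
            raise ValueError("transfer_cost must be > 0")


@dataclass(frozen=True)
class HGTEventKey:
    """Identity of a unique HGT event: EC number plus donor/recipient nodes."""

    ec_number: Optional[str]
    donor: str
    recipient: str

    def __post_init__(self) -> None:
        if self.donor == self.recipient:
            raise ValueError("HGT donor and recipient must differ")


@dataclass
class ReconciliationResult:
    """Per-node event labels, transfer edges, loss count and total cost."""

    mapping: dict[str, str]  # gene node id -> species node label
    events: dict[str, str]  # internal gene node id -> event name
    transfer_edges: list[tuple[str, str]]  # (donor, recipient) species labels
    n_losses: int
    total_cost: float
    costs: CostScheme

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events.values() if e == DUPLICATION)

    @property
    def n_transfers(self) -> int:
        return sum(1 for e in self.events.values() if e == TRANSFER)

    @property
    def n_ils(self) -> int:
        return sum(1 for e in self.events.values() if e == ILS)

    @property
    def n_speciations(self) -> int:
        return sum(1 for e in self.events.values() if e == SPECIATION)

    @property
    def has_duplication(self) -> bool:
        return self.n_duplications > 0

    @property
    def has_transfer(self) -> bool:
        return self.n_transfers > 0


@dataclass
class HGTDedupResult:
    """Unique (EC, donor, recipient) transfer identities and per-node tallies."""

    unique_events: frozenset[HGTEventKey]
    recipient_counts: Counter = field(default_factory=Counter)
    donor_counts: Counter = field(default_factory=Counter)

    @property
    def n_unique(self) -> int:
        return len(self.unique_events)


# ---------------------------------------------------------------------------
# species / gene tree indexing


class _SpeciesIndex:
    """Postorder-indexed view of a rooted species tree."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        self.n = len(nodes)
        self.idx = {id(nd): i for i, nd in enumerate(nodes)}
        self.labels: list[str] = []
        self.children: list[list[int]] = []
        self.parent = [-1] * self.n
        self.is_leaf = [False] * self.n
        self.leaf_idx: dict[str, int] = {}
        auto = 0
        for i, nd in enumerate(nodes):
            kids = [self.idx[id(c)] for c in nd.child_nodes()]
            self.children.append(kids)
            for k in kids:
                self.parent[k] = i
            if nd.is_leaf():
                self.is_leaf[i] = True
                label = nd.taxon.label if nd.taxon else (nd.label or f"leaf{i}")
                self.labels.append(label)
                self.leaf_idx[label] = i
            else:
                if nd.label:
                    label = nd.label
                else:
                    auto += 1
                    label = f"_n{auto}"
                self.labels.append(label)
        self.root = self.n - 1
        # ancestor-or-equal matrix
        anc = np.zeros((self.n, self.n), dtype=bool)
        for i in range(self.n):
            anc[i, i] = True
            for k in self.children[i]:
                anc[i] |= anc[k]
        self.anc = anc
        self.comparable = anc | anc.T
        # genomes below each node
        self.genomes_below: list[frozenset[str]] = [frozenset()] * self.n
        for i in range(self.n):
            if self.is_leaf[i]:
                self.genomes_below[i] = frozenset([self.labels[i]])
            else:
                acc: set[str] = set()
                for k in self.children[i]:
                    acc |= self.genomes_below[k]
                self.genomes_below[i] = frozenset(acc)

    def is_polytomy(self, s: int) -> bool:
        return len(self.children[s]) > 2


class _GeneIndex:
    """Postorder-indexed view of a rooted binary gene tree."""

    def __init__(self, tree: dendropy.Tree, sp: _SpeciesIndex):
        nodes = list(tree.postorder_node_iter())
        self.n = len(nodes)
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        self.children: list[tuple[int, ...]] = []
        self.is_leaf = [False] * self.n
        self.sigma = [-1] * self.n  # species leaf index for gene leaves
        self.ids: list[str] = []
        self.genomes: list[frozenset[str]] = []
        internal_counter = 0
        for i, nd in enumerate(nodes):
            kids = tuple(idx[id(c)] for c in nd.child_nodes())
            if kids and len(kids) != 2:
                raise ValueError(
                    "gene tree must be binary; resolve polytomies first"
                )
            self.children.append(kids)
            if not kids:
                self.is_leaf[i] = True
                label = nd.taxon.label if nd.taxon else (nd.label or "")
                genome = _t.genome_of_label(label)
                if genome not in sp.leaf_idx:
                    raise ValueError(
                        f"gene-tree leaf {label!r} maps to genome {genome!r} "
                        "absent from the species tree"
                    )
                self.sigma[i] = sp.leaf_idx[genome]
                self.ids.append(label or f"leaf{i}")
                self.genomes.append(frozenset([genome]))
            else:
                internal_counter += 1
                self.ids.append(f"g{internal_counter}")
                self.genomes.append(self.genomes[kids[0]] | self.genomes[kids[1]])
        self.root = self.n - 1


# ---------------------------------------------------------------------------
# DP core


def _add(a: tuple, b: tuple) -> tuple:
    return (a[0] + b[0], a[1] + b[1], a[2] + b[2])


def _submasks_ascending(mask: int) -> list[int]:
    subs = []
    sub = mask
    while sub:
        subs.append(sub)
        sub = (sub - 1) & mask
    subs.reverse()
    return subs


class _DP:
    def __init__(self, gi: _GeneIndex, sp: _SpeciesIndex, costs: CostScheme):
        self.gi = gi
        self.sp = sp
        self.costs = costs
        self.loss_t = (costs.loss_cost, 0, 0)
        self.dup_t = (costs.dup_cost, 0, 1)
        self.tr_t = (costs.transfer_cost, 1, 0)
        self.ils_t = (costs.ils_cost, 0, 0)
        n_g, n_s = gi.n, sp.n
        self.C = [[_INF] * n_s for _ in range(n_g)]
        self.IN = [[_INF] * n_s for _ in range(n_g)]
        self.RECV = [[_INF] * n_s for _ in range(n_g)]
        self.OUT = [[_INF] * n_s for _ in range(n_g)]
        self.ENTER = [[_INF] * n_s for _ in range(n_g)]
        # P[g][s]: mask -> tuple, for polytomy s and masks with >=2 bits
        self.P: list[dict[int, dict[int, tuple]]] = [dict() for _ in range(n_g)]
        self._psh: list[dict[tuple[int, int], tuple]] = [dict() for _ in range(n_g)]
        self._rel_mask: list[dict[int, int]] = [dict() for _ in range(n_g)]

    # -- polytomy helpers ---------------------------------------------------

    def rel_mask(self, g: int, s: int) -> int:
        cache = self._rel_mask[g]
        if s not in cache:
            mask = 0
            for pos, child in enumerate(self.sp.children[s]):
                if self.sp.genomes_below[child] & self.gi.genomes[g]:
                    mask |= 1 << pos
            cache[s] = mask
        return cache[s]

    def pget(self, g: int, s: int, mask: int) -> tuple:
        """Cost of gene node g inside polytomy region s claiming ``mask``."""
        if mask == 0:
            return _INF
        if mask & (mask - 1) == 0:  # single child claimed
            child = self.sp.children[s][mask.bit_length() - 1]
            return self.IN[g][child]
        return self.P[g].get(s, {}).get(mask, _INF)

    def psh(self, g: int, s: int, mask: int) -> tuple:
        """Claim ``mask`` but possibly survive only in a subset (one loss)."""
        key = (s, mask)
        cache = self._psh[g]
        if key not in cache:
            best = _INF
            for sub in _submasks_ascending(mask):
                val = self.pget(g, s, sub)
                if sub != mask:
                    val = _add(val, self.loss_t)
                if val < best:
                    best = val
            cache[key] = best
        return cache[key]

    # -- option generators (shared by the DP fill and the traceback) --------

    def options_P(self, g: int, s: int, mask: int):
        """Branching options for internal gene g inside polytomy s, claim mask."""
        a, b = self.gi.children[g]
        out = []
        for sub in _submasks_ascending(mask):
            comp = mask ^ sub
            if comp == 0:
                continue
            val = _add(self.ils_t, _add(self.pget(a, s, sub), self.pget(b, s, comp)))
            out.append((val, (ILS, sub)))
        out.append(
            (
                _add(self.dup_t, _add(self.psh(a, s, mask), self.psh(b, s, mask))),
                (DUPLICATION, None),
            )
        )
        out.append(
            (
                _add(self.tr_t, _add(self.psh(a, s, mask), self.OUT[b][s])),
                (TRANSFER, b),
            )
        )
        out.append(
            (
                _add(self.tr_t, _add(self.psh(b, s, mask), self.OUT[a][s])),
                (TRANSFER, a),
            )
        )
        return out

    def options_C(self, g: int, s: int):
        """Event options for internal gene g mapped exactly to species s."""
        a, b = self.gi.children[g]
        sp = self.sp
        out = []
        kids = sp.children[s]
        if len(kids) == 2:
            u, v = kids
            out.append(
                (_add(self.IN[a][u], self.IN[b][v]), (SPECIATION, (u, v)))
            )
            out.append(
                (_add(self.IN[a][v], self.IN[b][u]), (SPECIATION, (v, u)))
            )
        out.append(
            (
                _add(self.dup_t, _add(self.IN[a][s], self.IN[b][s])),
                (DUPLICATION, None),
            )
        )
        out.append(
            (_add(self.tr_t, _add(self.IN[a][s], self.OUT[b][s])), (TRANSFER, b))
        )
        out.append(
            (_add(self.tr_t, _add(self.IN[b][s], self.OUT[a][s])), (TRANSFER, a))
        )
        return out

    def options_ENTER(self, g: int, s: int):
        """Entry from above into polytomy region s: claim + one loss if partial."""
        full = (1 << len(self.sp.children[s])) - 1
        rel = self.rel_mask(g, s)
        out = []
        if rel == 0:
            return out
        for mask in _submasks_ascending(rel):
            val = self.pget(g, s, mask)
            charged = mask != full
            if charged:
                val = _add(val, self.loss_t)
            out.append((val, (mask, charged)))
        return out

    # -- forward fill -------------------------------------------------------

    def run(self) -> tuple:
        gi, sp = self.gi, self.sp
        for g in range(gi.n):
            for s in range(sp.n):
                poly = sp.is_polytomy(s)
                if poly and not gi.is_leaf[g]:
                    rel = self.rel_mask(g, s)
                    if rel.bit_count() > _MAX_POLYTOMY_CLAIM:
                        raise ValueError(
                            f"polytomy at {sp.labels[s]!r} too large for the "
                            f"claim DP ({rel.bit_count()} occupied children)"
                        )
                    table: dict[int, tuple] = {}
                    for mask in _submasks_ascending(rel):
                        if mask.bit_count() < 2:
                            continue
                        table[mask] = min(v for v, _ in self.options_P(g, s, mask))
                    if table:
                        self.P[g][s] = table
                # C
                if gi.is_leaf[g]:
                    self.C[g][s] = _ZERO if s == gi.sigma[g] else _INF
                else:
                    self.C[g][s] = min(v for v, _ in self.options_C(g, s))
                # ENTER (polytomy only)
                if poly:
                    opts = self.options_ENTER(g, s)
                    self.ENTER[g][s] = min((v for v, _ in opts), default=_INF)
                # IN
                if poly:
                    self.IN[g][s] = min(self.C[g][s], self.ENTER[g][s])
                else:
                    best = self.C[g][s]
                    for c in sp.children[s]:
                        cand = _add(self.IN[g][c], self.loss_t)
                        if cand < best:
                            best = cand
                    self.IN[g][s] = best
                # RECV: free entry for transfers / origination
                if poly:
                    free = min(
                        (
                            self.pget(g, s, mask)
                            for mask in _submasks_ascending(self.rel_mask(g, s))
                        ),
                        default=_INF,
                    )
                    self.RECV[g][s] = min(self.IN[g][s], free)
                else:
                    self.RECV[g][s] = self.IN[g][s]
            # OUT: best incomparable landing site
            comp = sp.comparable
            for s in range(sp.n):
                best = _INF
                row = comp[s]
                for s2 in range(sp.n):
                    if not row[s2] and self.RECV[g][s2] < best:
                        best = self.RECV[g][s2]
                self.OUT[g][s] = best
        root = gi.root
        best = _INF
        best_s = -1
        for s in range(sp.n):
            if self.RECV[root][s] < best:
                best = self.RECV[root][s]
                best_s = s
        return best, best_s


class _Trace:
    """Deterministic traceback over the filled DP tables."""

    def __init__(self, dp: _DP):
        self.dp = dp
        self.mapping: dict[str, str] = {}
        self.events: dict[str, str] = {}
        self.transfer_edges: list[tuple[str, str]] = []
        self.n_losses = 0

    def _recipient(self, g: int, s: int) -> int:
        dp = self.dp
        target = dp.OUT[g][s]
        row = dp.sp.comparable[s]
        for s2 in range(dp.sp.n):
            if not row[s2] and dp.RECV[g][s2] == target:
                return s2
        raise AssertionError("transfer recipient not found in traceback")

    def recv(self, g: int, s: int) -> None:
        dp = self.dp
        val = dp.RECV[g][s]
        if val == dp.IN[g][s]:
            self.in_(g, s)
            return
        for mask in _submasks_ascending(dp.rel_mask(g, s)):
            if dp.pget(g, s, mask) == val:
                self.p(g, s, mask)
                return
        raise AssertionError("RECV traceback failed")

    def in_(self, g: int, s: int) -> None:
        dp = self.dp
        val = dp.IN[g][s]
        if val == dp.C[g][s]:
            self.c(g, s)
            return
        if dp.sp.is_polytomy(s):
            if val == dp.ENTER[g][s]:
                for v, (mask, charged) in dp.options_ENTER(g, s):
                    if v == val:
                        if charged:
                            self.n_losses += 1
                        self.p(g, s, mask)
                        return
            raise AssertionError("IN traceback failed at polytomy")
        for c in dp.sp.children[s]:
            if _add(dp.IN[g][c], dp.loss_t) == val:
                self.n_losses += 1
                self.in_(g, c)
                return
        raise AssertionError("IN traceback failed")

    def p(self, g: int, s: int, mask: int) -> None:
        dp = self.dp
        if mask & (mask - 1) == 0:
            child = dp.sp.children[s][mask.bit_length() - 1]
            self.in_(g, child)
            return
        val = dp.P[g][s][mask]
        gid = dp.gi.ids[g]
        a, b = dp.gi.children[g]
        for v, (kind, payload) in dp.options_P(g, s, mask):
            if v != val:
                continue
            self.mapping[gid] = dp.sp.labels[s]
            if kind == ILS:
                self.events[gid] = ILS
                sub = payload
                self.p(a, s, sub)
                self.p(b, s, mask ^ sub)
            elif kind == DUPLICATION:
                self.events[gid] = DUPLICATION
                self.psh(a, s, mask)
                self.psh(b, s, mask)
            else:  # transfer out of the region
                self.events[gid] = TRANSFER
                moved = payload
                kept = b if moved == a else a
                r = self._recipient(moved, s)
                self.transfer_edges.append((dp.sp.labels[s], dp.sp.labels[r]))
                self.psh(kept, s, mask)
                self.recv(moved, r)
            return
        raise AssertionError("P traceback failed")

    def psh(self, g: int, s: int, mask: int) -> None:
        dp = self.dp
        val = dp.psh(g, s, mask)
        for sub in _submasks_ascending(mask):
            cand = dp.pget(g, s, sub)
            if sub != mask:
                cand = _add(cand, dp.loss_t)
            if cand == val:
                if sub != mask:
                    self.n_losses += 1
                self.p(g, s, sub)
                return
        raise AssertionError("PSH traceback failed")

    def c(self, g: int, s: int) -> None:
        dp = self.dp
        gid = dp.gi.ids[g]
        if dp.gi.is_leaf[g]:
            self.mapping[gid] = dp.sp.labels[s]
            return
        val = dp.C[g][s]
        a, b = dp.gi.children[g]
        for v, (kind, payload) in dp.options_C(g, s):
            if v != val:
                continue
            self.mapping[gid] = dp.sp.labels[s]
            if kind == SPECIATION:
                self.events[gid] = SPECIATION
                u, v_side = payload
                self.in_(a, u)
                self.in_(b, v_side)
            elif kind == DUPLICATION:
                self.events[gid] = DUPLICATION
                self.in_(a, s)
                self.in_(b, s)
            else:
                self.events[gid] = TRANSFER
                moved = payload
                kept = b if moved == a else a
                r = self._recipient(moved, s)
                self.transfer_edges.append((dp.sp.labels[s], dp.sp.labels[r]))
                self.in_(kept, s)
                self.recv(moved, r)
            return
        raise AssertionError("C traceback failed")


def reconcile_dtl(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    costs: CostScheme = CostScheme(),
) -> ReconciliationResult:
    """Minimum-cost DTL+ILS reconciliation of a rooted binary gene tree.

    With ``costs.prune`` the species tree is first restricted to the genomes
    present in the gene tree (internal labels preserved); otherwise every gene
    leaf must already map to a species leaf.  ILS branching is available only
    at species-tree polytomies.  Returns the tie-broken optimum (fewer
    transfers, then fewer duplications, then first option in a fixed
    deterministic traversal).
    """
    genomes = sorted({_t.genome_of_label(l) for l in _t.leaf_labels(gene_tree)})
    sp_tree = species_tree
    sp_leaves = set(_t.leaf_labels(species_tree))
    missing = [g for g in genomes if g not in sp_leaves]
    if missing:
        raise ValueError(f"genomes absent from the species tree: {missing}")
    if costs.prune and len(genomes) == 1:
        # whole family inside one genome: duplications only
        return _single_genome_result(gene_tree, genomes[0], costs)
    if costs.prune and set(genomes) != sp_leaves:
        sp_tree = prune_species_tree(species_tree, genomes)
    sp = _SpeciesIndex(sp_tree)
    gi = _GeneIndex(gene_tree, sp)
    dp = _DP(gi, sp, costs)
    best, best_s = dp.run()
    if not math.isfinite(best[0]):
        raise RuntimeError("reconciliation found no finite-cost scenario")
    tr = _Trace(dp)
    tr.recv(gi.root, best_s)
    total, n_tr, n_dup = best
    # internal consistency: the DP cost decomposes over the traced events
    recon = (
        costs.dup_cost * n_dup
        + costs.transfer_cost * n_tr
        + costs.loss_cost * tr.n_losses
        + costs.ils_cost * sum(1 for e in tr.events.values() if e == ILS)
    )
    if not math.isclose(recon, total, rel_tol=1e-9, abs_tol=1e-9):
        raise AssertionError(
            f"traceback events ({recon}) do not reproduce the DP cost ({total})"
        )
    return ReconciliationResult(
        mapping=tr.mapping,
        events=tr.events,
        transfer_edges=tr.transfer_edges,
        n_losses=tr.n_losses,
        total_cost=total,
        costs=costs,
    )


def _single_genome_result(
    gene_tree: dendropy.Tree, genome: str, costs: CostScheme
) -> ReconciliationResult:
    mapping: dict[str, str] = {}
    events: dict[str, str] = {}
    k = 0
    n_internal = 0
    for nd in gene_tree.postorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon else (nd.label or "")
            mapping[label] = genome
        else:
            k += 1
            gid = f"g{k}"
            mapping[gid] = genome
            events[gid] = DUPLICATION
            n_internal += 1
    return ReconciliationResult(
        mapping=mapping,
        events=events,
        transfer_edges=[],
        n_losses=0,
        total_cost=costs.dup_cost * n_internal,
        costs=costs,
    )


# ---------------------------------------------------------------------------
# rooting and polytomy resolution


def root_by_event_parsimony(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    costs: CostScheme = CostScheme(),
) -> dendropy.Tree:
    """Root an unrooted gene tree on the branch minimizing reconciliation cost.

    Every branch is tried as the root position; ties are broken by the
    smallest canonical newick string of the rooted tree.  The input tree's
    current root placement is treated as arbitrary.
    """
    n_leaves = len(_t.leaf_labels(gene_tree))
    if n_leaves < 3:
        raise ValueError("rooting needs at least three leaves")
    base = gene_tree.clone(depth=1)
    base.is_rooted = True
    n_edges = sum(1 for _ in base.preorder_edge_iter())
    best: tuple | None = None
    best_tree: dendropy.Tree | None = None
    for i in range(n_edges):
        cand = base.clone(depth=1)
        edge = list(cand.preorder_edge_iter())[i]
        if edge.tail_node is None:
            continue  # the virtual root edge is not a branch
        cand.reroot_at_edge(edge, update_bipartitions=False)
        cand.suppress_unifurcations()
        if not _t.is_binary(cand):
            continue
        res = reconcile_dtl(cand, species_tree, costs)
        key = (
            res.total_cost,
            res.n_transfers,
            res.n_duplications,
            _t.canonical_newick(cand),
        )
        if best is None or key < best:
            best = key
            best_tree = cand
    if best_tree is None:
        raise RuntimeError("no valid rooting found")
    return best_tree


def _to_nested(node: dendropy.Node):
    if node.is_leaf():
        return node.taxon.label if node.taxon else node.label
    return tuple(_to_nested(c) for c in node.child_nodes())


def _nested_polytomies(shape, path=()) -> list[tuple]:
    found = []
    if isinstance(shape, tuple):
        if len(shape) > 2:
            found.append(path)
        for i, child in enumerate(shape):
            found.extend(_nested_polytomies(child, path + (i,)))
    return found


def _replace_at(shape, path, new):
    if not path:
        return new
    i = path[0]
    return tuple(
        _replace_at(c, path[1:], new) if j == i else c for j, c in enumerate(shape)
    )


def _get_at(shape, path):
    for i in path:
        shape = shape[i]
    return shape


def _caterpillar(shape):
    if not isinstance(shape, tuple):
        return shape
    kids = [_caterpillar(c) for c in shape]
    while len(kids) > 2:
        kids = [(kids[0], kids[1])] + kids[2:]
    return tuple(kids) if len(kids) == 2 else kids[0]


def _score_shape(shape, species_tree, costs) -> tuple:
    tree = _t.tree_from_nested(_caterpillar(shape), label_internals=False)
    res = reconcile_dtl(tree, species_tree, costs)
    return (res.total_cost, res.n_transfers, res.n_duplications)


def resolve_polytomies(
    gene_tree: dendropy.Tree,
    bifurcating_species_tree: dendropy.Tree,
    costs: CostScheme = CostScheme(),
    exact_max_degree: int = 6,
) -> dendropy.Tree:
    """Resolve gene-tree polytomies against the bifurcating species tree.

    Each polytomy (deepest first) is replaced by the binary arrangement of its
    child subtrees that minimizes the reconciliation cost of the whole tree:
    exhaustively for degree <= ``exact_max_degree``, by greedy agglomerative
    pairing above that.  While one polytomy is being scored, any other still
    unresolved polytomy is temporarily resolved pectinately.  An already
    binary tree is returned unchanged.  Branch supports and lengths are not
    preserved on the resolved tree (resolution happens after support-based
    collapsing, which consumes them).
    """
    if _t.is_binary(gene_tree):
        return gene_tree
    if not _t.is_binary(bifurcating_species_tree):
        raise ValueError("the reference species tree must be bifurcating")
    shape = _to_nested(gene_tree.seed_node)
    # deepest-first: resolve inner polytomies before the ones above them
    while True:
        spots = _nested_polytomies(shape)
        if not spots:
            break
        path = max(spots, key=len)
        kids = list(_get_at(shape, path))
        if len(kids) <= exact_max_degree:
            best = None
            placeholders = list(range(len(kids)))
            for topo in _t.enumerate_rooted_topologies(placeholders):
                cand = _fill_placeholders(topo, kids)
                full = _replace_at(shape, path, cand)
                score = _score_shape(full, bifurcating_species_tree, costs)
                tree_key = _t.canonical_newick(
                    _t.tree_from_nested(_caterpillar(full), label_internals=False)
                )
                key = score + (tree_key,)
                if best is None or key < best[0]:
                    best = (key, cand)
            shape = _replace_at(shape, path, best[1])
        else:
            while len(kids) > 2:
                best = None
                for i in range(len(kids)):
                    for j in range(i + 1, len(kids)):
                        merged = (
                            [(kids[i], kids[j])]
                            + [k for t, k in enumerate(kids) if t not in (i, j)]
                        )
                        full = _replace_at(shape, path, tuple(merged))
                        score = _score_shape(
                            full, bifurcating_species_tree, costs
                        )
                        if best is None or score < best[0]:
                            best = (score, merged)
                kids = best[1]
            shape = _replace_at(shape, path, tuple(kids))
    return _t.tree_from_nested(shape, label_internals=False)


def _fill_placeholders(topo, kids):
    if isinstance(topo, tuple):
        return tuple(_fill_placeholders(t, kids) for t in topo)
    return kids[topo]


# ---------------------------------------------------------------------------
# brute-force oracle


def bruteforce_min_cost(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    costs: CostScheme = CostScheme(),
) -> float:
    """Exhaustive minimum reconciliation cost on small binary instances.

    Enumerates every assignment of internal gene nodes to species branches;
    for a fixed assignment the cheapest consistent event labeling and loss
    count are determined locally per node (speciation vs duplication, transfer
    recipient at the moved child's own branch), so the scan covers the full
    scenario space without the DP recurrences.  Covers the binary DTL core:
    refuses multifurcating species trees, gene trees with more than 6 leaves
    and species trees with more than 5 taxa.
    """
    if not _t.is_binary(species_tree):
        raise ValueError("the brute-force oracle requires a binary species tree")
    sp = _SpeciesIndex(species_tree)
    if (sp.n + 1) // 2 > 5:
        raise ValueError("brute-force oracle limited to species trees of <= 5 taxa")
    sp_for_run = species_tree
    if costs.prune:
        genomes = sorted({_t.genome_of_label(l) for l in _t.leaf_labels(gene_tree)})
        if set(genomes) != set(sp.leaf_idx):
            sp_for_run = prune_species_tree(species_tree, genomes)
            sp = _SpeciesIndex(sp_for_run)
    gi = _GeneIndex(gene_tree, sp)
    if (gi.n + 1) // 2 > 6:
        raise ValueError("brute-force oracle limited to gene trees of <= 6 leaves")

    n = sp.n
    anc = sp.anc
    comp = sp.comparable
    # losses along a descent from branch b to branch t (b ancestor-or-equal t):
    # one per species node passed through strictly above t
    nloss = np.full((n, n), -1, dtype=np.int64)
    for b in range(n):
        for t in range(n):
            if anc[b, t]:
                nloss[b, t] = int(np.sum(anc[b] & anc[:, t])) - 1
    dup_c, tr_c, loss_c = costs.dup_cost, costs.transfer_cost, costs.loss_cost

    internals = [g for g in range(gi.n) if not gi.is_leaf[g]]
    pos_of = {g: i for i, g in enumerate(internals)}
    tensors = []
    child_refs = []
    for g in internals:
        a, b = gi.children[g]
        T = np.full((n, n, n), np.inf)
        for s in range(n):
            kids = sp.children[s]
            for x in range(n):
                for y in range(n):
                    best = math.inf
                    if kids:
                        u, v = kids
                        for cu, cv in ((u, v), (v, u)):
                            if anc[cu, x] and anc[cv, y]:
                                cand = loss_c * (nloss[cu, x] + nloss[cv, y])
                                if cand < best:
                                    best = cand
                    if anc[s, x] and anc[s, y]:
                        cand = dup_c + loss_c * (nloss[s, x] + nloss[s, y])
                        if cand < best:
                            best = cand
                    if anc[s, x] and not comp[s, y]:
                        cand = tr_c + loss_c * nloss[s, x]
                        if cand < best:
                            best = cand
                    if anc[s, y] and not comp[s, x]:
                        cand = tr_c + loss_c * nloss[s, y]
                        if cand < best:
                            best = cand
                    T[s, x, y] = best
        tensors.append(T)
        refs = []
        for c in (a, b):
            if gi.is_leaf[c]:
                refs.append(("leaf", gi.sigma[c]))
            else:
                refs.append(("node", pos_of[c]))
        child_refs.append(refs)

    m = len(internals)
    assigns = np.array(list(product(range(n), repeat=m)), dtype=np.int64)
    total = np.zeros(len(assigns))
    for gpos in range(m):
        T = tensors[gpos]
        (ka, va), (kb, vb) = child_refs[gpos]
        xa = assigns[:, va] if ka == "node" else np.full(len(assigns), va)
        xb = assigns[:, vb] if kb == "node" else np.full(len(assigns), vb)
        total += T[assigns[:, gpos], xa, xb]
    return float(total.min())


# ---------------------------------------------------------------------------
# unique-HGT deduplication


def dedupe_hgt_events(
    families: Iterable[tuple[Optional[str], object]],
) -> HGTDedupResult:
    """Collapse transfers observed across families into unique HGT identities.

    ``families`` yields ``(ec_number, transfer_edges)`` pairs, where
    ``transfer_edges`` is a sequence of (donor, recipient) species-node labels
    or a :class:`ReconciliationResult`.  Transfers recorded by several gene
    families count once when they share the EC number and both endpoint nodes;
    a different EC, donor or recipient makes a distinct event.  Per-node
    recipient/donor tallies of the unique events are also returned.
    """
    keys: set[HGTEventKey] = set()
    for ec, edges in families:
        if isinstance(edges, ReconciliationResult):
            edges = edges.transfer_edges
        for donor, recipient in edges:
            keys.add(HGTEventKey(ec_number=ec, donor=donor, recipient=recipient))
    recip = Counter(k.recipient for k in keys)
    donor = Counter(k.donor for k in keys)
    return HGTDedupResult(
        unique_events=frozenset(keys),
        recipient_counts=recip,
        donor_counts=donor,
    )
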