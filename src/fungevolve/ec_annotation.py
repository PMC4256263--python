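"""KO/EC assignment from similarity-search hit tables.

Genes are annotated with KEGG Orthology (KO) terms from tabular protein
similarity hits against a KO-labeled reference, then mapped to Enzyme
Commission (EC) numbers through a KO->EC table.  Two tiers apply:

* Tier 1 -- a hit with >80% sequence identity (strict) and at most 10% length
  difference assigns its KO directly; among qualifying hits the lowest e-value
  wins.
* Tier 2 -- otherwise the hit list is truncated at the first large e-value
  increase (default 1e-50) and the KO is taken from the retained hits, by
  majority vote (default) or from the single best hit.

A gene whose KO maps to one or more EC numbers is an "ECgene"; genes with no
hits or with KOs outside the mapping table get an empty EC set.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "SimilarityHit",
    "GeneRecord",
    "truncate_hits_by_evalue_gap",
    "assign_ko",
    "annotate_genome",
    "DEFAULT_GAP_THRESHOLD",
    "IDENTITY_THRESHOLD",
    "MAX_LENGTH_DIFF",
]

DEFAULT_GAP_THRESHOLD = 1e-50
IDENTITY_THRESHOLD = 80.0  # strict: identity must exceed this
MAX_LENGTH_DIFF = 0.10  # relative to the longer sequence

_TINY = 5e-324  # smallest positive subnormal; stands in for e-value 0 in ratio mode


@dataclass(frozen=True)
class SimilarityHit:
    """One tabular similarity hit (outfmt-6-like plus subject KO and length)."""

    query_id: str
    subject_id: str
    subject_ko: str
    percent_identity: float
    query_length: int
    subject_length: int
    evalue: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent_identity out of range: {self.percent_identity}")
        if self.query_length <= 0 or self.subject_length <= 0:
            raise ValueError("sequence lengths must be positive")
        if self.evalue < 0:
            raise ValueError(f"negative e-value: {self.evalue}")

    @property
    def length_diff(self) -> float:
        longer = max(self.query_length, self.subject_length)
        return abs(self.query_length - self.subject_length) / longer

    @property
    def is_high_identity(self) -> bool:
        return (
            self.percent_identity > IDENTITY_THRESHOLD
            and self.length_diff <= MAX_LENGTH_DIFF
        )


@dataclass(frozen=True)
class GeneRecord:
    """One gene in published gene order, with its KO/EC annotation."""

    gene_id: str
    genome_id: str
    scaffold_id: str
    ordinal: int  # 0-based position along the scaffold
    strand: str = "unknown"
    ko: Optional[str] = None
    ec_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-", "unknown"}:
            raise ValueError(f"bad strand: {self.strand!r}")
        object.__setattr__(self, "ec_set", frozenset(self.ec_set))

    @property
    def is_ecgene(self) -> bool:
        return bool(self.ec_set)


def _sorted_hits(hits: Sequence[SimilarityHit]) -> list[SimilarityHit]:
    # ascending e-value; ties by descending identity, then subject id
    return sorted(hits, key=lambda h: (h.evalue, -h.percent_identity, h.subject_id))


def truncate_hits_by_evalue_gap(
    hits: Sequence[SimilarityHit],
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    mode: str = "additive",
) -> list[SimilarityHit]:
    """Drop every hit from the first large e-value increase onward.

    Hits are sorted by ascending e-value (ties: descending identity, then
    subject id).  Scanning consecutive pairs, the first pair whose increase
    meets the threshold truncates the list: in ``additive`` mode when
    ``e[i+1] - e[i] >= gap_threshold``, in ``ratio`` mode when the fold change
    reaches ``1 / gap_threshold`` (e-values of exactly 0 are treated as the
    smallest positive float for the ratio).  Without such a gap all hits are
    retained; an empty input returns an empty list.
    """
    if mode not in {"additive", "ratio"}:
        raise ValueError(f"unknown gap mode: {mode!r}")
    ordered = _sorted_hits(hits)
    if len(ordered) < 2:
        return ordered
    queries = {h.query_id for h in ordered}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    fold = 1.0 / gap_threshold
    for i in range(len(ordered) - 1):
        lo, hi = ordered[i].evalue, ordered[i + 1].evalue
        if mode == "additive":
            gapped = hi - lo >= gap_threshold
        else:
            gapped = hi / max(lo, _TINY) >= fold
        if gapped:
            return ordered[: i + 1]
    return ordered


def assign_ko(
    hits: Sequence[SimilarityHit],
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    gap_mode: str = "additive",
    tier2: str = "majority",
) -> Optional[str]:
    """Two-tier KO assignment for all hits of a single query.

    Tier 1 takes the lowest-e-value hit among those with >80% identity and
    <=10% length difference.  Failing that, tier 2 truncates the hit list at
    the first e-value gap and assigns either the majority KO among retained
    hits (``tier2="majority"``, ties broken by the KO of the single
    lowest-e-value hit, then lexicographically) or the KO of the single best
    retained hit (``tier2="best"``).  Returns ``None`` for an empty hit list.
    """
    if tier2 not in {"majority", "best"}:
        raise ValueError(f"unknown tier2 policy: {tier2!r}")
    if not hits:
        return None
    high = [h for h in hits if h.is_high_identity]
    if high:
        return _sorted_hits(high)[0].subject_ko
    retained = truncate_hits_by_evalue_gap(hits, gap_threshold, gap_mode)
    if not retained:
        return None
    if tier2 == "best":
        return retained[0].subject_ko
    votes = Counter(h.subject_ko for h in retained)
    top = max(votes.values())
    tied = sorted(ko for ko, n in votes.items() if n == top)
    if len(tied) == 1:
        return tied[0]
    best_ko = retained[0].subject_ko  # retained is already deterministically sorted
    return best_ko if best_ko in tied else tied[0]


def annotate_genome(
    hit_table: Iterable[SimilarityHit],
    ko_to_ec_map: Mapping[str, Iterable[str]],
    gene_table: Sequence[GeneRecord],
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    gap_mode: str = "additive",
    tier2: str = "majority",
) -> list[GeneRecord]:
    """Assign a KO and EC set to every gene; returns new records.

    Genes without hits keep ``ko=None`` and an empty EC set.  A KO missing
    from ``ko_to_ec_map`` triggers a warning and an empty EC set (the gene is
    then not an ECgene).
    """
    by_query: dict[str, list[SimilarityHit]] = defaultdict(list)
    for hit in hit_table:
        by_query[hit.query_id].append(hit)

    annotated: list[GeneRecord] = []
    missing: set[str] = set()
    for gene in gene_table:
        ko = assign_ko(by_query.get(gene.gene_id, []), gap_threshold, gap_mode, tier2)
        if ko is None:
            ecs: frozenset[str] = frozenset()
        elif ko in ko_to_ec_map:
            ecs = frozenset(ko_to_ec_map[ko])
        else:
            missing.add(ko)
            ecs = frozenset()
        annotated.append(
            GeneRecord(
                gene_id=gene.gene_id,
                genome_id=gene.genome_id,
                scaffold_id=gene.scaffold_id,
                ordinal=gene.ordinal,
                strand=gene.strand,
                ko=ko,
                ec_set=ecs,
            )
        )
    if missing:
        warnings.warn(
            f"{len(missing)} KO term(s) absent from the KO->EC map: "
            f"{sorted(missing)[:5]}...",
            stacklevel=2,
        )
    return annotated
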