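"""Per-genome summaries and enrichment tests.

Percentages of clustered, duplicated and transferred ECgenes are tabulated
per genome and rolled up per lineage; over/underrepresentation of metabolic
categories in ECgene subsets (clustered / duplicated / transferred) is tested
with two-sided Fisher's exact tests, corrected with Benjamini-Hochberg across
each invocation batch.  Duplication/transfer percentages use as denominator
only the ECgenes whose families passed the reconciliation pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .cluster_detection import GeneCluster
from .ec_annotation import GeneRecord

__all__ = [
    "METABOLIC_CATEGORIES",
    "GeneFlags",
    "EnrichmentResult",
    "per_genome_summary",
    "lineage_rollup",
    "fisher_exact_2x2",
    "bh_adjust",
    "category_enrichment",
    "clustering_association",
]

#: The 12 overlapping higher-order metabolic categories used for enrichment.
METABOLIC_CATEGORIES = (
    "carbohydrate",
    "energy",
    "lipid",
    "nucleotide",
    "amino acid",
    "glycan",
    "cofactor/vitamin",
    "terpenoid/polyketide",
    "other secondary metabolite",
    "xenobiotics",
    "biosynthesis of secondary metabolites",
    "microbial metabolism in diverse environments",
)


@dataclass(frozen=True)
class GeneFlags:
    """Reconciliation outcome for one ECgene's family.

    Present only for genes whose family passed the reconciliation pipeline;
    all leaves of a family inherit the family-level flags.
    """

    duplicated: bool
    transferred: bool


@dataclass
class EnrichmentResult:
    lineage: str
    category: str
    subset: str  # clustered | duplicated | transferred
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    p_adj: float
    direction: str = "none"  # over | under | none

    def finalize(self, alpha: float) -> None:
        if self.p_adj <= alpha and math.isfinite(self.odds_ratio):
            if self.odds_ratio > 1:
                self.direction = "over"
            elif self.odds_ratio < 1:
                self.direction = "under"
            else:
                self.direction = "none"
        else:
            self.direction = "none"


def per_genome_summary(
    gene_records: Sequence[GeneRecord],
    clusters: Sequence[GeneCluster],
    flags: Mapping[str, GeneFlags],
) -> pd.DataFrame:
    """Per-genome ECgene, clustering, duplication and transfer percentages.

    ``pct_clustered`` is over all ECgenes of the genome; ``pct_gd`` and
    ``pct_hgt`` are over the genome's ECgenes present in ``flags`` (i.e. that
    passed reconciliation).  Genomes with a zero denominator get 0 and a
    raised ``undefined_*`` flag rather than NaN.
    """
    clustered_ids: set[str] = set()
    for c in clusters:
        clustered_ids.update(c.member_ids)
    rows = []
    for genome in sorted({g.genome_id for g in gene_records}):
        ecgenes = [
            g for g in gene_records if g.genome_id == genome and g.is_ecgene
        ]
        n_ec = len(ecgenes)
        n_clu = sum(1 for g in ecgenes if g.gene_id in clustered_ids)
        passed = [g for g in ecgenes if g.gene_id in flags]
        n_passed = len(passed)
        n_gd = sum(1 for g in passed if flags[g.gene_id].duplicated)
        n_hgt = sum(1 for g in passed if flags[g.gene_id].transferred)
        rows.append(
            {
                "genome_id": genome,
                "n_ecgenes": n_ec,
                "n_clustered": n_clu,
                "pct_clustered": 100.0 * n_clu / n_ec if n_ec else 0.0,
                "n_passed": n_passed,
                "pct_gd": 100.0 * n_gd / n_passed if n_passed else 0.0,
                "pct_hgt": 100.0 * n_hgt / n_passed if n_passed else 0.0,
                "undefined_clustering": n_ec == 0,
                "undefined_events": n_passed == 0,
            }
        )
    return pd.DataFrame(rows).set_index("genome_id")


def lineage_rollup(
    summary: pd.DataFrame, lineage_map: Mapping[str, str]
) -> pd.DataFrame:
    """Lineage means of the per-genome percentage columns."""
    df = summary.copy()
    df["lineage"] = [lineage_map.get(g, "unassigned") for g in df.index]
    cols = ["n_ecgenes", "pct_clustered", "pct_gd", "pct_hgt"]
    return df.groupby("lineage")[cols].mean()


def fisher_exact_2x2(
    table: Sequence[Sequence[int]],
) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)`` with the sample odds ratio ``(a*d)/(b*c)``
    (``inf`` when ``b*c == 0`` and ``a*d > 0``; ``nan`` for a degenerate
    margin).  The two-sided p sums the hypergeometric probabilities of all
    tables with the observed margins whose point probability does not exceed
    the observed one (with a small relative slack for float safety).
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError(f"table entries must be non-negative integers: {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    else:
        odds = (a * d) / (b * c)
    _, p = _st.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _one_test(
    lineage: str,
    category: str,
    subset: str,
    status_in: int,
    status_out: int,
    rest_in: int,
    rest_out: int,
) -> EnrichmentResult:
    table = ((status_in, status_out), (rest_in, rest_out))
    total = status_in + status_out + rest_in + rest_out
    if total == 0:
        return EnrichmentResult(lineage, category, subset, table, math.nan, 1.0, 1.0)
    odds, p = fisher_exact_2x2(table)
    return EnrichmentResult(lineage, category, subset, table, odds, p, p)


def category_enrichment(
    membership: Mapping[str, set[str]],
    status: Mapping[str, bool],
    lineages: Mapping[str, str],
    subset: str = "clustered",
    alpha: float = 0.05,
    categories: Optional[Sequence[str]] = None,
) -> list[EnrichmentResult]:
    """Category over/underrepresentation within an ECgene subset, per lineage.

    For each (lineage, category) the 2x2 table crosses subset status with
    category membership over that lineage's ECgenes.  BH correction spans all
    tests of this invocation (one subset x all lineages x all categories);
    directions are called at ``p_adj <= alpha``.  Genes must appear in all
    three input mappings.
    """
    cats = tuple(categories) if categories is not None else METABOLIC_CATEGORIES
    genes = sorted(status)
    out: list[EnrichmentResult] = []
    for lineage in sorted(set(lineages.values())):
        in_lineage = [g for g in genes if lineages[g] == lineage]
        for cat in cats:
            a = sum(1 for g in in_lineage if status[g] and cat in membership[g])
            b = sum(1 for g in in_lineage if status[g] and cat not in membership[g])
            c = sum(1 for g in in_lineage if not status[g] and cat in membership[g])
            d = sum(
                1 for g in in_lineage if not status[g] and cat not in membership[g]
            )
            out.append(_one_test(lineage, cat, subset, a, b, c, d))
    _apply_bh(out, alpha)
    return out


def clustering_association(
    flags: Mapping[str, bool],
    clustering: Mapping[str, bool],
    lineages: Optional[Mapping[str, str]] = None,
    subset: str = "transferred",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Association between gene clustering and an event flag (GD or HGT).

    One 2x2 table (clustered x flagged) per lineage plus a global ``all``
    stratum; Fisher + BH across the batch.  ``flags`` and ``clustering`` must
    cover the same genes.
    """
    genes = sorted(flags)
    strata: dict[str, list[str]] = {"all": genes}
    if lineages is not None:
        for g in genes:
            strata.setdefault(lineages.get(g, "unassigned"), []).append(g)
    out: list[EnrichmentResult] = []
    for name in sorted(strata):
        sub = strata[name]
        a = sum(1 for g in sub if clustering[g] and flags[g])
        b = sum(1 for g in sub if clustering[g] and not flags[g])
        c = sum(1 for g in sub if not clustering[g] and flags[g])
        d = sum(1 for g in sub if not clustering[g] and not flags[g])
        res = _one_test(name, "clustered", subset, a, b, c, d)
        out.append(res)
    _apply_bh(out, alpha)
    return out


def _apply_bh(results: list[EnrichmentResult], alpha: float) -> None:
    if not results:
        return
    adj = bh_adjust([r.p for r in results])
    for r, padj in zip(results, adj):
        r.p_adj = float(padj)
        r.finalize(alpha)
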