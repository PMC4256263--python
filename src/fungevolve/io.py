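"""TSV/newick readers and writers for the pipeline's tabular interfaces."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cluster_detection import GeneCluster
from .ec_annotation import GeneRecord, SimilarityHit

__all__ = [
    "read_gene_table",
    "write_gene_table",
    "read_hit_table",
    "write_hit_table",
    "read_ko_ec_map",
    "write_ko_ec_map",
    "read_pathway_definitions",
    "write_pathway_definitions",
    "write_clusters",
    "read_flags",
    "write_flags",
]

_GENE_COLS = ["gene_id", "genome_id", "scaffold_id", "ordinal", "strand", "ko", "ec_list"]
_HIT_COLS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "query_length",
    "subject_length",
    "evalue",
    "subject_ko",
]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        ecs = frozenset(e for e in str(row.ec_list).split(";") if e)
        out.append(
            GeneRecord(
                gene_id=row.gene_id,
                genome_id=row.genome_id,
                scaffold_id=row.scaffold_id,
                ordinal=int(row.ordinal),
                strand=row.strand or "unknown",
                ko=row.ko or None,
                ec_set=ecs,
            )
        )
    return out


def write_gene_table(records: Sequence[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "genome_id": g.genome_id,
            "scaffold_id": g.scaffold_id,
            "ordinal": g.ordinal,
            "strand": g.strand,
            "ko": g.ko or "",
            "ec_list": ";".join(sorted(g.ec_set)),
        }
        for g in records
    ]
    pd.DataFrame(rows, columns=_GENE_COLS).to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> list[SimilarityHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        SimilarityHit(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            subject_ko=str(r.subject_ko),
            percent_identity=float(r.percent_identity),
            query_length=int(r.query_length),
            subject_length=int(r.subject_length),
            evalue=float(r.evalue),
        )
        for r in df.itertuples(index=False)
    ]


def write_hit_table(hits: Sequence[SimilarityHit], path: str | Path) -> None:
    rows = [
        {
            "query_id": h.query_id,
            "subject_id": h.subject_id,
            "percent_identity": h.percent_identity,
            "query_length": h.query_length,
            "subject_length": h.subject_length,
            "evalue": h.evalue,
            "subject_ko": h.subject_ko,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=_HIT_COLS).to_csv(path, sep="\t", index=False)


def read_ko_ec_map(path: str | Path) -> dict[str, frozenset[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.ko, set())
        if row.ec:
            out[row.ko].add(row.ec)
    return {k: frozenset(v) for k, v in out.items()}


def write_ko_ec_map(mapping: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = []
    for ko in sorted(mapping):
        ecs = sorted(mapping[ko])
        if not ecs:
            rows.append({"ko": ko, "ec": ""})
        for ec in ecs:
            rows.append({"ko": ko, "ec": ec})
    pd.DataFrame(rows, columns=["ko", "ec"]).to_csv(path, sep="\t", index=False)


def read_pathway_definitions(path: str | Path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["pathway_id", "ec_a", "ec_b"]
    if list(df.columns) != expected:
        raise ValueError(
            f"pathway file {path} must have columns {expected}, got {list(df.columns)}"
        )
    return [tuple(r) for r in df.itertuples(index=False)]


def write_pathway_definitions(
    definitions: Sequence[tuple[str, str, str]], path: str | Path
) -> None:
    pd.DataFrame(definitions, columns=["pathway_id", "ec_a", "ec_b"]).to_csv(
        path, sep="\t", index=False
    )


def write_clusters(clusters: Sequence[GeneCluster], path: str | Path) -> None:
    rows = [
        {
            "genome_id": c.genome_id,
            "scaffold_id": c.scaffold_id,
            "span_start": c.span[0],
            "span_end": c.span[1],
            "member_gene_ids": ";".join(c.member_ids),
        }
        for c in clusters
    ]
    pd.DataFrame(
        rows,
        columns=["genome_id", "scaffold_id", "span_start", "span_end", "member_gene_ids"],
    ).to_csv(path, sep="\t", index=False)


def read_flags(path: str | Path) -> dict[str, tuple[bool, bool]]:
    """gene_id -> (duplicated, transferred) for genes that passed reconciliation."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.gene_id): (bool(r.duplicated), bool(r.transferred))
        for r in df.itertuples(index=False)
    }


def write_flags(flags: Mapping[str, tuple[bool, bool]], path: str | Path) -> None:
    rows = [
        {"gene_id": g, "duplicated": int(d), "transferred": int(t)}
        for g, (d, t) in sorted(flags.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "duplicated", "transferred"]).to_csv(
        path, sep="\t", index=False
    )
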