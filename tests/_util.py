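"""Small shared helpers for the test suite."""

from fungevolve.ec_annotation import GeneRecord, SimilarityHit


def mk_hit(
    query="q1",
    ko="K00001",
    ident=90.0,
    qlen=300,
    slen=300,
    evalue=1e-100,
    subject=None,
):
    return SimilarityHit(
        query_id=query,
        subject_id=subject or f"s|{ko}|{evalue}",
        subject_ko=ko,
        percent_identity=ident,
        query_length=qlen,
        subject_length=slen,
        evalue=evalue,
    )


def mk_gene(gene_id, ordinal, ecs=(), genome="g01", scaffold="sc1", ko=None):
    return GeneRecord(
        gene_id=gene_id,
        genome_id=genome,
        scaffold_id=scaffold,
        ordinal=ordinal,
        ko=ko,
        ec_set=frozenset(ecs),
    )
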