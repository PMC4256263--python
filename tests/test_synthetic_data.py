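"""Generators: determinism, event bookkeeping, planted layouts, hit tables."""

import pytest

from fungevolve.cluster_detection import call_clusters
from fungevolve.ec_annotation import annotate_genome
from fungevolve.reconciliation import CostScheme, reconcile_dtl
from fungevolve.synthetic_data import (
    NoiseConfig,
    SimulationConfig,
    make_ko_ec_map,
    plant_genome_layout,
    replay_leaf_count,
    simulate_gene_family,
    simulate_hit_table,
    simulate_pathways,
    simulate_species_tree,
)
from fungevolve.trees import canonical_newick, leaf_labels, to_newick


@pytest.fixture(scope="module")
def pathway_graph():
    return simulate_pathways(n_pathways=3, chain_length=6, seed=0)[1]


class TestSpeciesTree:
    def test_two_taxa_single_topology(self):
        tree = simulate_species_tree(2, seed=1)
        assert canonical_newick(tree) == "(g01,g02);"

    def test_deterministic_per_seed(self):
        assert to_newick(simulate_species_tree(8, 7)) == to_newick(
            simulate_species_tree(8, 7)
        )
        assert to_newick(simulate_species_tree(8, 7)) != to_newick(
            simulate_species_tree(8, 8)
        )

    def test_binary_node_count_and_labels(self):
        tree = simulate_species_tree(8, 7)
        leaves = leaf_labels(tree)
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(leaves) == 8
        assert len(internal) == 7
        assert len({n.label for n in internal}) == 7  # unique internal labels

    def test_ultrametric_depths(self):
        tree = simulate_species_tree(6, 3)
        depths = {
            round(leaf.distance_from_root(), 9) for leaf in tree.leaf_node_iter()
        }
        assert len(depths) == 1

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, seed=0)


class TestGeneFamily:
    def test_no_events_reproduces_species_tree(self):
        species = simulate_species_tree(6, 5)
        gene, events = simulate_gene_family(species, 0, 0, 0, seed=9)
        assert events == []
        assert sorted(leaf_labels(gene)) == [
            f"g{i:02d}_copy1" for i in range(1, 7)
        ]
        assert reconcile_dtl(gene, species).total_cost == 0.0

    def test_duplications_are_recorded_per_extra_copy(self):
        species = simulate_species_tree(5, 2)
        for seed in range(10):
            gene, events = simulate_gene_family(species, 0.5, 0, 0, seed=seed)
            genomes = [l.rsplit("_copy", 1)[0] for l in leaf_labels(gene)]
            multi = {g for g in genomes if genomes.count(g) > 1}
            if multi:
                assert any(e.kind == "duplication" for e in events)

    @pytest.mark.parametrize("rates", [(0.3, 0.2, 0.15), (0.0, 0.5, 0.0), (0.6, 0.0, 0.3)])
    def test_replay_reproduces_leaf_counts(self, rates):
        species = simulate_species_tree(8, 7)
        dup, tr, loss = rates
        for seed in range(15):
            gene, events = simulate_gene_family(species, dup, tr, loss, seed=seed)
            observed = 0 if gene is None else len(leaf_labels(gene))
            assert observed == replay_leaf_count(species, events)

    def test_transfers_never_link_ancestor_to_descendant(self):
        species = simulate_species_tree(10, 4)
        anc = {}
        for nd in species.preorder_node_iter():
            name = nd.taxon.label if nd.taxon else nd.label
            parent = nd.parent_node
            pname = (
                (parent.taxon.label if parent.taxon else parent.label)
                if parent
                else None
            )
            anc[name] = anc.get(pname, set()) | {name} if pname else {name}
        for seed in range(10):
            _, events = simulate_gene_family(species, 0, 0.5, 0, seed=seed)
            for e in events:
                if e.kind == "transfer":
                    assert e.donor not in anc[e.recipient]
                    assert e.recipient not in anc[e.donor]

    def test_deterministic_per_seed(self):
        species = simulate_species_tree(6, 1)
        a, ev_a = simulate_gene_family(species, 0.3, 0.3, 0.1, seed=4)
        b, ev_b = simulate_gene_family(species, 0.3, 0.3, 0.1, seed=4)
        assert to_newick(a) == to_newick(b)
        assert ev_a == ev_b


class TestGenomeLayout:
    def test_planted_cluster_members_form_a_pathway_path(self, pathway_graph):
        config = SimulationConfig(n_taxa=2, cluster_spec=((3, 0),), seed=1)
        records, truth = plant_genome_layout(config, pathway_graph, seed=1)
        planted = truth.clusters[0]
        members = [r for r in records if r.gene_id in planted.gene_ids]
        members.sort(key=lambda r: r.ordinal)
        ecs = [next(iter(r.ec_set)) for r in members]
        assert all(
            pathway_graph.has_edge(a, b) for a, b in zip(ecs, ecs[1:])
        )
        assert [m.ordinal for m in members] == [
            members[0].ordinal + k for k in range(3)
        ]

    def test_wide_gap_cluster_is_not_callable(self, pathway_graph):
        config = SimulationConfig(
            n_taxa=2, cluster_spec=((2, 7),), seed=2, n_scattered_ecgenes=0
        )
        records, _ = plant_genome_layout(config, pathway_graph, seed=2)
        assert call_clusters(records, pathway_graph) == []

    def test_empty_spec_plants_no_callable_pairs(self, pathway_graph):
        config = SimulationConfig(
            n_taxa=3, cluster_spec=(), seed=3, n_scattered_ecgenes=5
        )
        records, truth = plant_genome_layout(config, pathway_graph, seed=3)
        assert truth.clusters == []
        assert call_clusters(records, pathway_graph) == []

    def test_impossible_cluster_spec_rejected(self, pathway_graph):
        # longest simple path in the synthetic graph is bounded by its size
        config = SimulationConfig(n_taxa=2, cluster_spec=((99, 0),), seed=1)
        with pytest.raises(ValueError, match="chain"):
            plant_genome_layout(config, pathway_graph, seed=1)

    def test_cluster_members_share_scaffold(self, pathway_graph):
        config = SimulationConfig(n_taxa=2, cluster_spec=((3, 1), (2, 2)), seed=4)
        records, truth = plant_genome_layout(config, pathway_graph, seed=4)
        by_id = {r.gene_id: r for r in records}
        for cluster in truth.clusters:
            scaffolds = {by_id[g].scaffold_id for g in cluster.gene_ids}
            assert len(scaffolds) == 1


class TestHitTables:
    def test_noise_free_recovery_is_exact(self, pathway_graph):
        config = SimulationConfig(n_taxa=3, cluster_spec=((3, 0),), seed=5)
        records, truth = plant_genome_layout(config, pathway_graph, seed=5)
        hits = simulate_hit_table(records, NoiseConfig(), seed=5)
        annotated = annotate_genome(
            hits, make_ko_ec_map(pathway_graph, n_non_enzyme_kos=60), records
        )
        assert all(g.ko == truth.true_ko[g.gene_id] for g in annotated)

    def test_noisy_recovery_survives_decoys(self, pathway_graph):
        config = SimulationConfig(
            n_taxa=3,
            cluster_spec=((3, 1),),
            seed=9,
            noise=NoiseConfig(decoy_rate=1.5, low_identity_fraction=0.25),
        )
        records, truth = plant_genome_layout(config, pathway_graph, seed=9)
        hits = simulate_hit_table(records, config.noise, seed=9)
        annotated = annotate_genome(
            hits, make_ko_ec_map(pathway_graph, n_non_enzyme_kos=60), records
        )
        assert all(g.ko == truth.true_ko[g.gene_id] for g in annotated)

    def test_low_identity_gene_exercises_tier2(self, pathway_graph):
        config = SimulationConfig(
            n_taxa=2, seed=6, noise=NoiseConfig(low_identity_fraction=1.0)
        )
        records, _ = plant_genome_layout(config, pathway_graph, seed=6)
        hits = simulate_hit_table(records, config.noise, seed=6)
        assert all(h.percent_identity <= 80.0 for h in hits)

    def test_same_seed_identical_tables(self, pathway_graph):
        config = SimulationConfig(n_taxa=2, seed=7, noise=NoiseConfig(decoy_rate=1.0))
        records, _ = plant_genome_layout(config, pathway_graph, seed=7)
        a = simulate_hit_table(records, config.noise, seed=7)
        b = simulate_hit_table(records, config.noise, seed=7)
        assert a == b


class TestConfigValidation:
    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(dup_rate=-0.1)

    def test_cluster_spec_validated(self):
        with pytest.raises(ValueError):
            SimulationConfig(cluster_spec=((1, 0),))
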