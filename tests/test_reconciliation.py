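"""DTL+ILS reconciliation: DP vs oracle, events, rooting, polytomies, dedup."""

import numpy as np
import pytest

from fungevolve.reconciliation import (
    CostScheme,
    HGTEventKey,
    bruteforce_min_cost,
    dedupe_hgt_events,
    reconcile_dtl,
    resolve_polytomies,
    root_by_event_parsimony,
)
from fungevolve.trees import (
    canonical_newick,
    enumerate_rooted_topologies,
    parse_newick,
    tree_from_nested,
)


def random_instance(rng, n_species_min=3, n_species_max=5, n_gene_max=6):
    """One random (gene tree, species tree, costs) problem for the oracle."""
    n_sp = int(rng.integers(n_species_min, n_species_max + 1))
    labels = [chr(65 + i) for i in range(n_sp)]
    topos = list(enumerate_rooted_topologies(labels))
    species = tree_from_nested(topos[int(rng.integers(len(topos)))])
    n_g = int(rng.integers(3, n_gene_max + 1))
    leaves = [labels[int(rng.integers(n_sp))] + f"_copy{i}" for i in range(n_g)]
    items = list(leaves)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), 2, replace=False))
        items = [x for t, x in enumerate(items) if t not in (i, j)] + [
            (items[i], items[j])
        ]
    gene = tree_from_nested(items[0], label_internals=False)
    # quarter-integer costs keep every scenario cost exactly representable
    costs = CostScheme(
        dup_cost=float(rng.integers(1, 13)) / 4,
        transfer_cost=float(rng.integers(1, 49)) / 4,
        loss_cost=float(rng.integers(0, 9)) / 4,
        prune=False,
    )
    return gene, species, costs


class TestAgainstBruteForce:
    def test_spec_oracle_values(self, species_abc):
        congruent = parse_newick("((A,B),C);")
        assert bruteforce_min_cost(congruent, species_abc) == 0.0
        conflicting = parse_newick("((A,C),B);")
        assert bruteforce_min_cost(conflicting, species_abc) == 4.5

    def test_random_instances_match(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            gene, species, costs = random_instance(rng)
            dp = reconcile_dtl(gene, species, costs).total_cost
            brute = bruteforce_min_cost(gene, species, costs)
            assert dp == pytest.approx(brute, abs=1e-9)

    def test_oracle_refuses_oversized_input(self):
        big_sp = tree_from_nested(
            next(enumerate_rooted_topologies(list("ABCDEF")))
        )
        gene = parse_newick("((A,B),C);")
        with pytest.raises(ValueError, match="5 taxa"):
            bruteforce_min_cost(gene, big_sp)

    def test_oracle_refuses_polytomous_species_tree(self, species_polytomy):
        with pytest.raises(ValueError, match="binary"):
            bruteforce_min_cost(parse_newick("((A,B),C);"), species_polytomy)


class TestEventInference:
    def test_congruent_tree_costs_zero(self, species_abc):
        res = reconcile_dtl(parse_newick("((A,B),C);"), species_abc)
        assert res.total_cost == 0.0
        assert set(res.events.values()) == {"speciation"}
        assert res.n_losses == 0

    def test_high_transfer_cost_prefers_duplication_and_loss(self, species_abc):
        res = reconcile_dtl(
            parse_newick("((A,C),B);"), species_abc, CostScheme(transfer_cost=6)
        )
        assert res.total_cost == pytest.approx(4.5)
        assert res.n_duplications == 1
        assert res.n_losses == 3
        assert not res.has_transfer

    def test_low_transfer_cost_infers_the_transfer(self, species_abc):
        res = reconcile_dtl(
            parse_newick("((A,C),B);"), species_abc, CostScheme(transfer_cost=2)
        )
        assert res.total_cost == pytest.approx(2.0)
        assert res.n_transfers == 1
        assert res.has_transfer
        assert res.transfer_edges == [("A", "C")]

    @pytest.mark.parametrize("t_cost, expect_transfer", [(2, True), (4, True), (6, False), (8, False), (10, False), (12, False)])
    def test_switchpoint_grid(self, species_abc, t_cost, expect_transfer):
        res = reconcile_dtl(
            parse_newick("((A,C),B);"), species_abc, CostScheme(transfer_cost=t_cost)
        )
        assert res.has_transfer is expect_transfer

    def test_transfer_monotone_in_cost(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            gene, species, _ = random_instance(rng)
            prev_cost, prev_tr = -1.0, None
            for t in (1.0, 2.0, 4.0, 6.0, 9.0, 14.0):
                res = reconcile_dtl(
                    gene, species, CostScheme(transfer_cost=t, prune=False)
                )
                assert res.total_cost >= prev_cost - 1e-12
                if prev_tr is not None:
                    assert res.n_transfers <= prev_tr
                prev_cost, prev_tr = res.total_cost, res.n_transfers

    def test_deterministic_output(self, species_abcd):
        gene = parse_newick("(((A_copy1,C_copy1),(B_copy1,D_copy1)),A_copy2);")
        a = reconcile_dtl(gene, species_abcd)
        b = reconcile_dtl(gene, species_abcd)
        assert a.mapping == b.mapping
        assert a.events == b.events
        assert a.transfer_edges == b.transfer_edges

    def test_leaves_map_to_their_genomes(self, species_abcd):
        gene = parse_newick("((A_copy1,B_copy1),(C_copy1,D_copy1));")
        res = reconcile_dtl(gene, species_abcd)
        assert res.mapping["A_copy1"] == "A"
        assert res.mapping["D_copy1"] == "D"

    def test_unknown_genome_without_prune_errors(self, species_abc):
        with pytest.raises(ValueError, match="absent"):
            reconcile_dtl(
                parse_newick("((A,Z),B);"), species_abc, CostScheme(prune=False)
            )

    def test_single_genome_family_is_pure_duplication(self, species_abcd):
        gene = parse_newick("((A_copy1,A_copy2),A_copy3);")
        res = reconcile_dtl(gene, species_abcd)
        assert res.total_cost == pytest.approx(3.0)
        assert res.n_duplications == 2
        assert not res.has_transfer


class TestIlsAtPolytomies:
    @pytest.mark.parametrize(
        "gene_nwk", ["((A,B),C);", "((A,C),B);", "((B,C),A);"]
    )
    def test_any_resolution_of_a_polytomy_is_free(self, species_polytomy, gene_nwk):
        res = reconcile_dtl(parse_newick(gene_nwk), species_polytomy)
        assert res.total_cost == 0.0
        assert set(res.events.values()) == {"ils"}
        assert res.n_losses == 0

    def test_disjoint_claims_across_four_children(self):
        species = parse_newick("(A,B,C,D)R;")
        res = reconcile_dtl(parse_newick("((A,B),(C,D));"), species)
        assert res.total_cost == 0.0
        assert set(res.events.values()) == {"ils"}

    def test_overlapping_claims_need_a_duplication(self, species_polytomy):
        gene = parse_newick("((A_copy1,B_copy1),(A_copy2,C_copy1));")
        res = reconcile_dtl(gene, species_polytomy)
        assert res.n_duplications == 1
        assert res.total_cost == pytest.approx(3.5)  # dup + two partial claims

    def test_conflict_outside_the_polytomy_is_not_ils(self):
        # ((A,B),C,D): only the root is unresolved; conflict within (A,B)
        # against E-placement cannot be explained as ILS
        species = parse_newick("((A,B)n1,C,D)R;")
        res = reconcile_dtl(parse_newick("((A,C),(B,D));"), species)
        assert res.total_cost > 0.0


class TestRooting:
    def test_congruent_topology_recovers_zero_cost_root(self, species_abcd):
        # root placed inside a subtree; event parsimony should move it back
        misrooted = parse_newick("(A,(B,(C,D)));")
        rooted = root_by_event_parsimony(misrooted, species_abcd)
        assert reconcile_dtl(rooted, species_abcd).total_cost == 0.0

    def test_best_rooting_beats_all_alternatives(self, species_abcd):
        caterpillar = parse_newick("(A,(C,(B,D)));")
        best = root_by_event_parsimony(caterpillar, species_abcd)
        best_cost = reconcile_dtl(best, species_abcd).total_cost
        # exhaustive check over every rooting of the same unrooted tree
        base = caterpillar.clone(depth=1)
        n_edges = sum(1 for _ in base.preorder_edge_iter())
        for i in range(n_edges):
            cand = base.clone(depth=1)
            edge = list(cand.preorder_edge_iter())[i]
            if edge.tail_node is None:
                continue
            cand.reroot_at_edge(edge, update_bipartitions=False)
            cand.suppress_unifurcations()
            assert reconcile_dtl(cand, species_abcd).total_cost >= best_cost

    def test_three_leaf_rooting_is_deterministic(self, species_abc):
        gene = parse_newick("((A,C),B);")
        first = canonical_newick(root_by_event_parsimony(gene, species_abc))
        second = canonical_newick(root_by_event_parsimony(gene, species_abc))
        assert first == second


class TestResolvePolytomies:
    def test_trifurcation_resolved_congruently(self, species_abc):
        out = resolve_polytomies(parse_newick("(A,B,C);"), species_abc)
        assert canonical_newick(out) == "((A,B),C);"
        assert reconcile_dtl(out, species_abc).total_cost == 0.0

    def test_binary_tree_returned_unchanged(self, species_abc):
        tree = parse_newick("((A,B),C);")
        assert resolve_polytomies(tree, species_abc) is tree

    def test_duplicate_copies_grouped_to_minimize_cost(self, species_abc):
        out = resolve_polytomies(
            parse_newick("(A_copy1,A_copy2,B);"), species_abc
        )
        assert canonical_newick(out) == "((A_copy1,A_copy2),B);"
        res = reconcile_dtl(out, species_abc)
        assert res.total_cost == pytest.approx(1.5)
        assert res.n_losses == 0

    def test_output_is_binary_even_for_large_polytomies(self):
        species = tree_from_nested(
            next(enumerate_rooted_topologies(list("ABCDEFGH")))
        )
        gene = parse_newick("(A,B,C,D,E,F,G,H);")
        out = resolve_polytomies(gene, species, exact_max_degree=4)
        assert all(
            len(n.child_nodes()) == 2
            for n in out.preorder_node_iter()
            if not n.is_leaf()
        )


class TestHgtDedup:
    def test_same_ec_same_edge_counts_once(self):
        result = dedupe_hgt_events(
            [("1.1.1.1", [("n1", "n2")]), ("1.1.1.1", [("n1", "n2")])]
        )
        assert result.n_unique == 1

    def test_different_ec_is_a_different_event(self):
        result = dedupe_hgt_events(
            [("1.1.1.1", [("n1", "n2")]), ("2.2.2.2", [("n1", "n2")])]
        )
        assert result.n_unique == 2

    def test_different_recipient_is_a_different_event(self):
        result = dedupe_hgt_events(
            [("1.1.1.1", [("n1", "n2"), ("n1", "n3")])]
        )
        assert result.n_unique == 2
        assert result.recipient_counts == {"n2": 1, "n3": 1}

    def test_key_rejects_self_transfer(self):
        with pytest.raises(ValueError):
            HGTEventKey("1.1.1.1", "n1", "n1")
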