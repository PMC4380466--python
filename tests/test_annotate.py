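"""Event placement: xy### labels, node times, clade matching, reconstruction."""

from __future__ import annotations

import copy
import logging
import random

import pytest

from cladepaint import (
    AnnotationError,
    CladeMatchError,
    EventLog,
    MergeEvent,
    MutationEvent,
    SimulationConfig,
    annotate_tree,
    compute_node_times,
    infer_mutations,
    leaf_set,
    match_clade,
    parse_newick,
    reconstruct_ancestral_sequence,
    render_mutation_label,
    simulate,
    tree_equals,
)
from cladepaint.annotate import MUTATIONS_KEY, TIME_KEY


class TestMutationLabels:
    @pytest.mark.parametrize(
        "ancestral, derived, site, expected",
        [("A", "T", 1, "AT1"), ("A", "G", 54, "AG54"), ("C", "T", 12, "CT12")],
    )
    def test_xy_site_grammar(self, ancestral, derived, site, expected):
        event = MutationEvent(None, site, ancestral, derived, frozenset({"x"}))
        assert render_mutation_label(event) == expected


class TestInferMutations:
    def test_single_substitution_at_site_one(self):
        # the worked four-site example: older ACTG vs newer TCTG
        events = infer_mutations("ACTG", "TCTG")
        assert len(events) == 1
        assert events[0].site == 1
        assert (events[0].ancestral_nt, events[0].derived_nt) == ("A", "T")
        assert render_mutation_label(events[0]) == "AT1"

    def test_identical_sequences(self):
        assert infer_mutations("ACTG", "ACTG") == []

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            infer_mutations("ACTG", "ACT")

    def test_count_equals_hamming_distance(self):
        rng = random.Random(13)
        for _ in range(100):
            n = rng.randint(1, 80)
            older = "".join(rng.choice("ACGT") for _ in range(n))
            newer = "".join(rng.choice("ACGT") for _ in range(n))
            # brute-force position-by-position oracle
            hamming = 0
            for i in range(n):
                if older[i] != newer[i]:
                    hamming += 1
            events = infer_mutations(older, newer)
            assert len(events) == hamming
            assert [e.site for e in events] == sorted(e.site for e in events)
            for e in events:
                assert older[e.site - 1] == e.ancestral_nt
                assert newer[e.site - 1] == e.derived_nt


class TestMatchClade:
    def test_cherry(self, example_tree):
        node = match_clade(example_tree, {"Eu_Am6", "Eu_Am22"})
        assert node is example_tree.root.children[0]

    def test_singleton_is_leaf(self, example_tree):
        node = match_clade(example_tree, {"Eu_Am5"})
        assert node is not None and node.is_leaf and node.label == "Eu_Am5"

    def test_non_clade_returns_none(self, example_tree):
        assert match_clade(example_tree, {"Eu_Am5", "Eu_Am6"}) is None

    def test_absent_taxon_returns_none(self, example_tree):
        assert match_clade(example_tree, {"Eu_Am5", "nobody"}) is None

    def test_exhaustive_over_all_nodes(self):
        truth = simulate(SimulationConfig(
            n_leaves=15, n_sites=10, groups=(("A", 15),), mutation_rate=0, seed=5,
        ))
        tree = parse_newick(truth.newick)
        clades = {leaf_set(node) for node in tree.nodes()}
        for clade in clades:
            assert leaf_set(match_clade(tree, clade)) == clade
        # any subset that is not a clade must not match
        rng = random.Random(0)
        labels = tree.leaf_labels()
        for _ in range(50):
            subset = frozenset(rng.sample(labels, rng.randint(1, len(labels))))
            node = match_clade(tree, subset)
            assert (node is not None) == (subset in clades)


class TestNodeTimes:
    def test_merge_sets_ancestor_time(self, example_tree, example_log):
        times = compute_node_times(example_tree, example_log)
        assert times[example_tree.root] == 2.0099
        for leaf in example_tree.root.leaves():
            assert times[leaf] == 0.0

    def test_single_leaf_tree_empty_log(self):
        tree = parse_newick("A;")
        times = compute_node_times(tree, EventLog())
        assert times == {tree.root: 0.0}

    def test_unmatched_merge_is_error(self, example_tree):
        log = EventLog(merges=[
            MergeEvent(1.0, frozenset({"Eu_Am5"}), frozenset({"Eu_Am6"}))
        ])
        with pytest.raises(CladeMatchError, match="Eu_Am5"):
            compute_node_times(example_tree, log)

    def test_untimed_internal_node_warns(self, example_tree, example_log, caplog):
        with caplog.at_level(logging.WARNING):
            times = compute_node_times(example_tree, example_log)
        cherry = example_tree.root.children[0]
        assert cherry not in times
        assert "no merge event" in caplog.text

    def test_monotonicity_violation_is_error(self):
        tree = parse_newick("((A,B),C);")
        log = EventLog(merges=[
            MergeEvent(5.0, frozenset({"A"}), frozenset({"B"})),
            MergeEvent(2.0, frozenset({"A", "B"}), frozenset({"C"})),
        ])
        log.sort()
        with pytest.raises(AnnotationError, match="monotonicity"):
            compute_node_times(tree, log)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_simulated_times_recovered_exactly(self, seed):
        truth = simulate(SimulationConfig(
            n_leaves=12, n_sites=20, groups=(("P", 12),), mutation_rate=0.5, seed=seed,
        ))
        tree = parse_newick(truth.newick)
        times = compute_node_times(tree, truth.log)
        by_clade = {leaf_set(n): t for n, t in truth.node_times.items()}
        for node, t in times.items():
            assert t == by_clade[leaf_set(node)]


class TestAnnotateTree:
    def test_worked_example(self, example_tree, example_log):
        summary = annotate_tree(example_tree, example_log)
        leaf5 = example_tree.find_leaf("Eu_Am5")
        assert leaf5.annotations[MUTATIONS_KEY] == ["AG54"]
        assert example_tree.root.annotations[TIME_KEY] == 2.0099
        for leaf in example_tree.root.leaves():
            assert leaf.annotations[TIME_KEY] == 0.0
        assert summary.n_attached == 1 and summary.n_unmatched == 0

    def test_empty_log_leaves_tree_unannotated(self, example_tree):
        before = copy.deepcopy(example_tree)
        summary = annotate_tree(example_tree, EventLog())
        assert summary.n_attached == 0 and summary.n_unmatched == 0
        assert tree_equals(before, example_tree)  # structure untouched
        assert all(MUTATIONS_KEY not in n.annotations for n in example_tree.nodes())

    def test_all_unmatched_is_error(self, example_tree):
        log = EventLog(mutations=[
            MutationEvent(1.0, 3, "A", "C", frozenset({"stranger"})),
        ])
        with pytest.raises(AnnotationError, match="pairing"):
            annotate_tree(example_tree, log)

    def test_partial_match_reported_not_fatal(self, example_tree, example_log, caplog):
        example_log.mutations.append(
            MutationEvent(1.0, 2, "C", "G", frozenset({"stranger"}))
        )
        with caplog.at_level(logging.WARNING):
            summary = annotate_tree(example_tree, example_log)
        assert summary.n_attached == 1 and summary.n_unmatched == 1
        assert "CG2" in caplog.text

    def test_topology_and_lengths_untouched(self, seed=4):
        truth = simulate(SimulationConfig(
            n_leaves=20, n_sites=30, groups=(("P", 20),), mutation_rate=1.0, seed=seed,
        ))
        tree = parse_newick(truth.newick)
        before = copy.deepcopy(tree)
        annotate_tree(tree, truth.log)
        assert tree_equals(before, tree, rel_tol=1e-12)

    def test_labels_ordered_by_descending_time_then_site(self):
        tree = parse_newick("(A:3,B:3);")
        log = EventLog(
            merges=[MergeEvent(3.0, frozenset({"A"}), frozenset({"B"}))],
            mutations=[
                MutationEvent(0.5, 9, "A", "C", frozenset({"A"})),
                MutationEvent(2.5, 4, "C", "G", frozenset({"A"})),
                MutationEvent(2.5, 1, "G", "T", frozenset({"A"})),
            ],
        )
        annotate_tree(tree, log)
        leaf = tree.find_leaf("A")
        assert leaf.annotations[MUTATIONS_KEY] == ["GT1", "CG4", "AC9"]

    def test_branch_length_time_disagreement_warns(self, caplog):
        tree = parse_newick("(A:1.0,B:3.0);")  # B's length contradicts t=3
        log = EventLog(merges=[MergeEvent(3.0, frozenset({"A"}), frozenset({"B"}))])
        with caplog.at_level(logging.WARNING):
            annotate_tree(tree, log)
        assert "disagrees" in caplog.text
        assert tree.find_leaf("A").branch_length == 1.0  # lengths never edited

    @pytest.mark.parametrize("seed", range(5))
    def test_simulated_events_recovered_per_branch(self, seed):
        truth = simulate(SimulationConfig(
            n_leaves=18, n_sites=60, groups=(("P", 18),), mutation_rate=1.0, seed=seed,
        ))
        tree = parse_newick(truth.newick)
        annotate_tree(tree, truth.log)
        expected = {
            leaf_set(node): [render_mutation_label(e) for e in events]
            for node, events in truth.branch_events.items() if events
        }
        observed = {
            leaf_set(node): node.annotations[MUTATIONS_KEY]
            for node in tree.nodes() if MUTATIONS_KEY in node.annotations
        }
        assert observed == expected


class TestAncestralReconstruction:
    def test_worked_example_site_54(self, example_tree, example_log):
        sequences = {
            "Eu_Am5": "A" * 53 + "G" + "A" * 46,
            "Eu_Am6": "A" * 100,
            "Eu_Am22": "A" * 100,
        }
        ancestral = reconstruct_ancestral_sequence(
            "Eu_Am5", 2.01, example_tree, example_log, sequences,
        )
        assert ancestral[53] == "A"  # G observed today, A in the ancestor
        assert ancestral == "A" * 100

    def test_target_time_zero_returns_leaf_sequence(self, example_tree, example_log):
        sequences = {"Eu_Am5": "GATC" * 25, "Eu_Am6": "A" * 100, "Eu_Am22": "A" * 100}
        assert reconstruct_ancestral_sequence(
            "Eu_Am5", 0.0, example_tree, example_log, sequences,
        ) == sequences["Eu_Am5"]

    def test_missing_sequence_is_error(self, example_tree, example_log):
        with pytest.raises(AnnotationError, match="Eu_Am5"):
            reconstruct_ancestral_sequence(
                "Eu_Am5", 1.0, example_tree, example_log, {"Eu_Am6": "A"},
            )

    @pytest.mark.parametrize("seed", range(4))
    def test_reconstruction_consistent_across_children(self, seed):
        """At every merge node, going up via either child gives one sequence."""
        truth = simulate(SimulationConfig(
            n_leaves=10, n_sites=40, groups=(("P", 10),), mutation_rate=1.2,
            seed=seed, allow_repeat_sites=True,
        ))
        tree = parse_newick(truth.newick)
        sequences = {r.name: r.sequence for r in truth.records}
        by_clade = {leaf_set(n): n for n in truth.tree.nodes()}
        for node in tree.nodes():
            if node.is_leaf:
                continue
            t = truth.node_times[by_clade[leaf_set(node)]]
            results = set()
            for child in node.children:
                leaf = sorted(leaf_set(child))[0]
                results.add(reconstruct_ancestral_sequence(
                    leaf, t, tree, truth.log, sequences,
                ))
            assert len(results) == 1
            # and it equals the simulator's recorded ancestral sequence
            assert results.pop() == truth.node_sequences[by_clade[leaf_set(node)]]

    @pytest.mark.parametrize("seed", range(4))
    def test_hamming_equivalence_without_repeat_sites(self, seed):
        """Per-branch label count == Hamming distance of endpoint sequences."""
        truth = simulate(SimulationConfig(
            n_leaves=12, n_sites=80, groups=(("P", 12),), mutation_rate=1.0,
            seed=seed, allow_repeat_sites=False,
        ))
        tree = parse_newick(truth.newick)
        annotate_tree(tree, truth.log)
        by_clade = {leaf_set(n): n for n in truth.tree.nodes()}
        for node in tree.nodes():
            if node is tree.root:
                continue
            truth_node = by_clade[leaf_set(node)]
            parent = next(
                n for n in truth.tree.nodes() if truth_node in n.children
            )
            hamming = sum(
                a != b
                for a, b in zip(truth.node_sequences[parent],
                                truth.node_sequences[truth_node])
            )
            labels = node.annotations.get(MUTATIONS_KEY, [])
            assert len(labels) == hamming
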