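"""Shared fixtures: the three-taxon worked example and random tree factories."""

from __future__ import annotations

import random

import pytest

from cladepaint import (
    EventLog,
    MergeEvent,
    MutationEvent,
    Tree,
    TreeNode,
    parse_newick,
)

# The three-taxon subtree used throughout: the common ancestor of Eu_Am5,
# Eu_Am6 and Eu_Am22 at t = 2.0099, where an A->G mutation at site 54 makes
# Eu_Am5 a distinct lineage; Eu_Am6 and Eu_Am22 carry identical sequences.
EXAMPLE_NEWICK = "((Eu_Am6:0.0,Eu_Am22:0.0):2.0099,Eu_Am5:2.0099);"


@pytest.fixture
def example_tree() -> Tree:
    return parse_newick(EXAMPLE_NEWICK)


@pytest.fixture
def example_log() -> EventLog:
    log = EventLog(
        mutations=[
            MutationEvent(
                time=2.0099, site=54, ancestral_nt="A", derived_nt="G",
                clade=frozenset({"Eu_Am5"}),
            )
        ],
        merges=[
            MergeEvent(
                time=2.0099,
                left_clade=frozenset({"Eu_Am5"}),
                right_clade=frozenset({"Eu_Am6", "Eu_Am22"}),
            )
        ],
    )
    log.sort()
    return log


def random_tree(rng: random.Random, n_leaves: int, *, with_lengths: bool = True,
                multifurcating: bool = False, fancy_labels: bool = False) -> Tree:
    """A random labeled tree for round-trip tests.

    Builds bottom-up by repeatedly joining 2 (or up to 4, when
    ``multifurcating``) subtrees. ``fancy_labels`` mixes in names that need
    Newick quoting (spaces, quotes, parentheses).
    """
    labels = []
    for i in range(n_leaves):
        if fancy_labels and i % 4 == 1:
            labels.append(f"sp one {i}")
        elif fancy_labels and i % 4 == 2:
            labels.append(f"o'hara({i})")
        elif i % 3 == 0:
            labels.append(f"Eu_Am{i}")
        else:
            labels.append(f"YRI_{i}")
    nodes = [TreeNode(label=lab) for lab in labels]
    while len(nodes) > 1:
        k = rng.randint(2, 4) if multifurcating else 2
        k = min(k, len(nodes))
        children = [nodes.pop(rng.randrange(len(nodes))) for _ in range(k)]
        for child in children:
            if with_lengths and rng.random() < 0.9:
                child.branch_length = round(rng.uniform(0, 10), rng.randint(0, 6))
        nodes.append(TreeNode(children=children))
    return Tree(nodes[0])
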