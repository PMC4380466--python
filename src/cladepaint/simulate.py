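"""Synthetic coalescent-style fixtures with recorded ground truth.

Generates an internally consistent bundle — tree, event log, leaf sequences,
group file — from one seed, so every other module can be tested against
known truth without any external data.

The generative model is a plain neutral coalescent: starting from ``n``
lineages at t = 0, successive pairwise merges happen after exponential
waiting gaps with the standard rate k(k-1)/2 for k active lineages, giving
strictly increasing merge times with the root oldest. Mutations fall on each
branch as a Poisson counting process at ``mutation_rate`` per unit time,
with uniform sites and a uniform choice among the three alternative
nucleotides; sequences are propagated from a uniform-random root sequence
down to the leaves. Emitted Newick branch lengths equal time differences, so
the log-derived node times and the tree agree exactly.

This emulates the *shape* of real population data (e.g. two population
groups of 34 and 18 haplotypes over 100 sites) but none of its population
genetics: no recombination, no repeat-visit site-frequency structure, and
frequencies are arbitrary positive integers. Passing tests therefore
demonstrate correct bookkeeping, not demographic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datafiles import (
    EventLog,
    GroupDefinition,
    MergeEvent,
    MutationEvent,
    SequenceRecord,
    write_group_file,
    write_log_file,
    write_sequence_file,
)
from .tree import Tree, TreeNode, format_branch_length, leaf_set, write_newick

_ALPHABET = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shape knobs for one synthetic dataset.

    ``groups`` lists (name prefix, leaf count) pairs; leaves are named
    ``<prefix><i>`` with i starting at 1, so name inference recovers the
    groups. ``mutation_rate`` is expected mutations per unit (coalescent)
    time per lineage. With ``allow_repeat_sites=False`` the sites mutated on
    any single branch are distinct, making per-branch label counts equal
    endpoint Hamming distances.
    """

    n_leaves: int = 52
    n_sites: int = 100
    groups: tuple[tuple[str, int], ...] = (("Eu_Am", 34), ("YRI", 18))
    mutation_rate: float = 0.5
    seed: int = 0
    allow_repeat_sites: bool = True

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("need at least 2 leaves")
        if self.n_sites < 1:
            raise ValueError("need at least 1 site")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        if sum(count for _, count in self.groups) != self.n_leaves:
            raise ValueError("group counts must sum to n_leaves")


@dataclass
class GroundTruth:
    """Everything the simulator knows, for exact-recovery tests."""

    config: SimulationConfig
    tree: Tree
    node_times: dict[TreeNode, float]
    branch_events: dict[TreeNode, list[MutationEvent]]  # node below the branch
    root_sequence: str
    node_sequences: dict[TreeNode, str]
    records: list[SequenceRecord]
    groups: list[GroupDefinition]
    log: EventLog = field(default_factory=EventLog)

    @property
    def newick(self) -> str:
        return write_newick(self.tree)

    def total_tree_length(self) -> float:
        return sum(
            node.branch_length
            for node in self.tree.nodes()
            if node.branch_length is not None
        )

    def n_mutations(self) -> int:
        return sum(len(events) for events in self.branch_events.values())


def simulate(config: SimulationConfig, outdir: str | Path | None = None) -> GroundTruth:
    """Run one simulation; optionally write the four input files + manifest.

    Written files (when ``outdir`` is given): ``tree.tre``, ``seqs.txt``,
    ``groups.txt``, ``events.log``, ``truth.txt``. Same seed, same config ->
    byte-identical files.
    """
    rng = np.random.default_rng(config.seed)

    names: list[str] = []
    groups: list[GroupDefinition] = []
    for prefix, count in config.groups:
        members = [f"{prefix}{i}" for i in range(1, count + 1)]
        names.extend(members)
        groups.append(GroupDefinition(group_name=prefix, members=frozenset(members)))

    # --- coalescent topology and times -----------------------------------
    active: list[TreeNode] = [TreeNode(label=name) for name in names]
    node_times: dict[TreeNode, float] = {node: 0.0 for node in active}
    merges: list[MergeEvent] = []
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        right = active.pop(int(j))
        left = active.pop(int(i))
        left.branch_length = t - node_times[left]
        right.branch_length = t - node_times[right]
        parent = TreeNode(children=[left, right])
        node_times[parent] = t
        merges.append(MergeEvent(time=t, left_clade=leaf_set(left), right_clade=leaf_set(right)))
        active.append(parent)
    tree = Tree(active[0])

    # --- sequences and mutations (root -> leaves, forward in time) --------
    root_sequence = "".join(rng.choice(_ALPHABET, size=config.n_sites))
    node_sequences: dict[TreeNode, str] = {tree.root: root_sequence}
    branch_events: dict[TreeNode, list[MutationEvent]] = {}
    mutations: list[MutationEvent] = []

    def descend(parent: TreeNode) -> None:
        for child in parent.children:
            duration = node_times[parent] - node_times[child]
            count = int(rng.poisson(config.mutation_rate * duration))
            if not config.allow_repeat_sites:
                count = min(count, config.n_sites)
            sites = rng.choice(config.n_sites, size=count, replace=config.allow_repeat_sites) + 1
            event_times = rng.uniform(node_times[child], node_times[parent], size=count)
            clade = leaf_set(child)
            seq = list(node_sequences[parent])
            events: list[MutationEvent] = []
            # forward in time = descending reverse-time order
            for site, ev_t in sorted(zip(sites.tolist(), event_times.tolist()),
                                     key=lambda pair: -pair[1]):
                ancestral = seq[site - 1]
                derived = str(rng.choice(_ALPHABET[_ALPHABET != ancestral]))
                seq[site - 1] = derived
                events.append(MutationEvent(
                    time=ev_t, site=site,
                    ancestral_nt=ancestral, derived_nt=derived, clade=clade,
                ))
            node_sequences[child] = "".join(seq)
            branch_events[child] = events
            mutations.extend(events)
            descend(child)

    descend(tree.root)

    records = [
        SequenceRecord(
            name=leaf.label,
            sequence=node_sequences[leaf],
            frequency=float(rng.integers(1, 6)),
        )
        for leaf in tree.root.leaves()
    ]
    log = EventLog(mutations=mutations, merges=merges)
    log.sort()

    truth = GroundTruth(
        config=config, tree=tree, node_times=node_times,
        branch_events=branch_events, root_sequence=root_sequence,
        node_sequences=node_sequences, records=records, groups=groups, log=log,
    )
    if outdir is not None:
        write_fixture_files(truth, outdir)
    return truth


def write_fixture_files(truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Write tree.tre, seqs.txt, groups.txt, events.log and truth.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.tre",
        "sequences": outdir / "seqs.txt",
        "groups": outdir / "groups.txt",
        "log": outdir / "events.log",
        "truth": outdir / "truth.txt",
    }
    paths["tree"].write_text(truth.newick + "\n")
    write_sequence_file(truth.records, paths["sequences"])
    write_group_file(truth.groups, paths["groups"])
    write_log_file(truth.log, paths["log"])
    paths["truth"].write_text(_manifest(truth))
    return paths


def _manifest(truth: GroundTruth) -> str:
    """Human-readable ground-truth manifest (plain text)."""
    lines = [
        "# ground truth manifest",
        f"# seed={truth.config.seed} n_leaves={truth.config.n_leaves} "
        f"n_sites={truth.config.n_sites} rate={truth.config.mutation_rate}",
        f"root_sequence {truth.root_sequence}",
    ]
    for node in truth.tree.nodes():
        clade = ",".join(sorted(leaf_set(node)))
        lines.append(f"node clade={clade} t={format_branch_length(truth.node_times[node])}")
        for event in truth.branch_events.get(node, []):
            lines.append(
                f"  event t={format_branch_length(event.time)} site={event.site} "
                f"{event.ancestral_nt}->{event.derived_nt}"
            )
    return "\n".join(lines) + "\n"
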