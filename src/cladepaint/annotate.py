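"""Placing merge times and mutation events onto tree branches.

The time model is reverse ("coalescent") time: observed sequences sit at
t = 0, ancestors at larger t, the root is the oldest node. A merge event
gives the time of the internal node whose descendant leaf set equals the
union of the two merged clades; a mutation event lives on the branch above
the node whose leaf set equals the event's clade, and is rendered in the
``xy###`` grammar — ancestral nucleotide, derived nucleotide, 1-based site,
e.g. ``AG54`` for A (older, t+eps) mutating to G (newer, t) at site 54.

Events are matched to branches by *exact* leaf-set equality. Exact matching
fails loudly rather than guessing nearest clades: silent mis-annotation is
worse than an error, and a tree that was re-rooted or ladderized after the
log was written should be rejected, not quietly mislabelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .datafiles import EventLog, MutationEvent, NUCLEOTIDES, SequenceRecord
from .errors import AnnotationError, CladeMatchError
from .tree import Tree, TreeNode, leaf_set

logger = logging.getLogger(__name__)

TIME_KEY = "time"
MUTATIONS_KEY = "mutations"

# Relative tolerance for warning when Newick branch lengths disagree with
# log-derived times; log times win for annotation, lengths stay untouched
# for display.
_LENGTH_TIME_RTOL = 1e-6


def render_mutation_label(event: MutationEvent) -> str:
    """``xy###`` text for one mutation event, e.g. ``AT1`` or ``AG54``."""
    return f"{event.ancestral_nt}{event.derived_nt}{event.site}"


def infer_mutations(older_seq: str, newer_seq: str) -> list[MutationEvent]:
    """Diff two same-length sequences into (time-less) mutation events.

    ``older_seq`` is the state at t+eps, ``newer_seq`` the state at t. One
    event per differing site, sites ascending; the event count equals the
    Hamming distance. The events carry the newer sequence itself as a
    placeholder clade (diffing alone cannot know the lineage).
    """
    if len(older_seq) != len(newer_seq):
        raise ValueError(
            f"sequence length mismatch: {len(older_seq)} vs {len(newer_seq)}"
        )
    bad = (set(older_seq) | set(newer_seq)) - NUCLEOTIDES
    if bad:
        raise ValueError(f"non-ACGT characters {sorted(bad)}")
    events: list[MutationEvent] = []
    for index, (old, new) in enumerate(zip(older_seq, newer_seq)):
        if old != new:
            events.append(MutationEvent(
                time=None,
                site=index + 1,
                ancestral_nt=old,
                derived_nt=new,
                clade=frozenset({newer_seq}),
            ))
    return events


def match_clade(tree: Tree, taxa: frozenset[str] | set[str]) -> TreeNode | None:
    """The unique node whose leaf set equals ``taxa``, else ``None``.

    Never returns a node over a proper superset or subset. Taxa absent from
    the tree entirely rule out a match (logged for diagnosis).
    """
    if not taxa:
        raise ValueError("cannot match an empty taxon set")
    taxa = frozenset(taxa)
    missing = taxa - leaf_set(tree.root)
    if missing:
        logger.debug("clade members absent from tree: %s", sorted(missing))
        return None
    for node in tree.nodes():
        if leaf_set(node) == taxa:
            return node
    return None


class NodeTimeTable(dict):
    """Mapping node -> reverse time; leaves are fixed at 0."""


def compute_node_times(tree: Tree, log: EventLog) -> NodeTimeTable:
    """Node times from merge events; leaves at 0; root-oldest monotonicity.

    Each merge event's combined clade must equal the leaf set of exactly one
    internal node (else :class:`CladeMatchError` listing the clade). Internal
    nodes with no event keep no time (warning). A parent younger than a timed
    descendant is an error naming the violating edge.
    """
    times = NodeTimeTable()
    for leaf in tree.root.leaves():
        times[leaf] = 0.0
    for merge in log.merges:
        node = match_clade(tree, merge.clade)
        if node is None or node.is_leaf:
            raise CladeMatchError(
                f"merge at t={merge.time} matches no internal node: clade "
                + ",".join(sorted(merge.clade))
            )
        times[node] = merge.time

    def check(node: TreeNode) -> float | None:
        """Max known time in the subtree; raises on monotonicity violation."""
        deepest: float | None = times.get(node)
        for child in node.children:
            child_max = check(child)
            if child_max is None:
                continue
            if node in times and times[node] < child_max - 1e-12:
                raise AnnotationError(
                    f"time monotonicity violated on edge above clade "
                    f"{{{','.join(sorted(leaf_set(child)))}}}: "
                    f"parent t={times[node]} < descendant t={child_max}"
                )
            deepest = child_max if deepest is None else max(deepest, child_max)
        return deepest

    check(tree.root)
    untimed = [n for n in tree.nodes() if not n.is_leaf and n not in times]
    if untimed:
        logger.warning("%d internal node(s) have no merge event; times left absent", len(untimed))
    return times


@dataclass
class AnnotationSummary:
    """What :func:`annotate_tree` did: counts and the leftover events."""

    n_attached: int = 0
    n_unmatched: int = 0
    unmatched: list[MutationEvent] = field(default_factory=list)
    n_timed_nodes: int = 0

    def __str__(self) -> str:
        return (
            f"events attached={self.n_attached} unmatched={self.n_unmatched} "
            f"timed nodes={self.n_timed_nodes}"
        )


def annotate_tree(tree: Tree, log: EventLog) -> AnnotationSummary:
    """Install time and mutation annotations on ``tree`` in place.

    Node times go under the ``"time"`` annotation key (leaves get 0.0);
    mutation labels under ``"mutations"`` on the node below the branch that
    carries them, ordered by descending event time then ascending site.
    Topology and branch lengths are never altered. If the log holds events
    and *none* match, the tree/log pairing is presumed wrong and an
    :class:`AnnotationError` is raised.
    """
    times = compute_node_times(tree, log)
    summary = AnnotationSummary(n_timed_nodes=len(times))
    for node, t in times.items():
        node.annotations[TIME_KEY] = t

    per_node: dict[TreeNode, list[MutationEvent]] = {}
    for event in log.mutations:
        node = match_clade(tree, event.clade)
        if node is None:
            summary.unmatched.append(event)
            continue
        per_node.setdefault(node, []).append(event)
    for node, events in per_node.items():
        events.sort(key=lambda e: (-(e.time if e.time is not None else 0.0), e.site))
        node.annotations[MUTATIONS_KEY] = [render_mutation_label(e) for e in events]
        summary.n_attached += len(events)
    summary.n_unmatched = len(summary.unmatched)

    if log.mutations and summary.n_attached == 0 and summary.n_unmatched == len(log.mutations):
        raise AnnotationError(
            f"none of {len(log.mutations)} mutation events matched any clade; "
            "wrong tree/log pairing?"
        )
    if summary.unmatched:
        logger.warning(
            "%d mutation event(s) matched no clade: %s",
            summary.n_unmatched,
            "; ".join(render_mutation_label(e) for e in summary.unmatched),
        )
    _warn_length_time_disagreements(tree, times)
    return summary


def _warn_length_time_disagreements(tree: Tree, times: NodeTimeTable) -> None:
    """Warn where branch lengths disagree with time differences.

    Log-derived times are authoritative for annotation; lengths stay as
    written because the viewer displays them.
    """

    def visit(parent: TreeNode) -> None:
        for child in parent.children:
            if parent in times and child in times and child.branch_length is not None:
                expected = times[parent] - times[child]
                scale = max(abs(child.branch_length), abs(expected), 1.0)
                if abs(expected - child.branch_length) > _LENGTH_TIME_RTOL * scale:
                    logger.warning(
                        "branch above {%s}: length %g disagrees with time difference %g; "
                        "log times used for annotation",
                        ",".join(sorted(leaf_set(child))), child.branch_length, expected,
                    )
            visit(child)

    visit(tree.root)


def reconstruct_ancestral_sequence(
    leaf: str,
    target_time: float,
    tree: Tree,
    log: EventLog,
    sequences: list[SequenceRecord] | dict[str, str],
) -> str:
    """The state of ``leaf``'s lineage at ``target_time``.

    Starts from the observed sequence at t=0 and undoes (derived -> ancestral)
    every mutation event on the leaf's root-ward path with event time <=
    ``target_time``, in ascending time order. Repeat mutations at one site
    are applied in time order.
    """
    if isinstance(sequences, dict):
        seq_by_name = dict(sequences)
    else:
        seq_by_name = {rec.name: rec.sequence for rec in sequences}
    if leaf not in seq_by_name:
        raise AnnotationError(f"no sequence for leaf {leaf!r}")
    node = tree.find_leaf(leaf)
    if node is None:
        raise AnnotationError(f"leaf {leaf!r} not in tree")

    on_path: list[MutationEvent] = []
    for event in log.mutations:
        carrier = match_clade(tree, event.clade)
        if carrier is None:
            continue
        if leaf in leaf_set(carrier) and event.time is not None and event.time <= target_time:
            on_path.append(event)
    on_path.sort(key=lambda e: (e.time, e.site))

    state = list(seq_by_name[leaf])
    for event in on_path:
        index = event.site - 1
        if index >= len(state):
            raise AnnotationError(
                f"event site {event.site} beyond sequence length {len(state)}"
            )
        if state[index] != event.derived_nt:
            logger.warning(
                "site %d: expected derived state %s before undoing event, found %s",
                event.site, event.derived_nt, state[index],
            )
        state[index] = event.ancestral_nt
    return "".join(state)
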