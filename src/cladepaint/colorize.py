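"""Taxon grouping and deterministic tree colorization.

Leaves are grouped either by an explicit group file or, failing that, by
name inference: the maximal trailing run of decimal digits is stripped, so
``Eu_Am5``/``Eu_Am22`` fall into group ``Eu_Am`` and ``YRI7`` into ``YRI``.
Each group gets a hex color, either user-overridden or drawn from a fixed
12-color palette in sorted-group-name order (cycling if exhausted) —
identical inputs always produce byte-identical colors.

Internal branches are colored by monophyletic propagation: a node takes a
group's color only when *all* its descendant leaves belong to that single
group; mixed nodes stay the default black, the ordinary color of an
unadorned tree.
"""

from __future__ import annotations

import logging
import re
from typing import Mapping, Sequence

from .datafiles import GroupDefinition
from .errors import ColorError
from .tree import Tree, TreeNode

logger = logging.getLogger(__name__)

COLOR_KEY = "!color"
DEFAULT_GROUP = "_default"
DEFAULT_COLOR = "#000000"

#: Twelve maximally-distinct colors, assigned to groups in sorted-name order.
DEFAULT_PALETTE: tuple[str, ...] = (
    "#e6194b",  # red
    "#4363d8",  # blue
    "#3cb44b",  # green
    "#f58231",  # orange
    "#911eb4",  # purple
    "#42d4f4",  # cyan
    "#f032e6",  # magenta
    "#bfef45",  # lime
    "#fabed4",  # pink
    "#469990",  # teal
    "#9a6324",  # brown
    "#808000",  # olive
)

_HEX_COLOR = re.compile(r"#[0-9a-f]{6}\Z")
_TRAILING_DIGITS = re.compile(r"[0-9]+\Z")

GroupAssignment = dict  # taxon name -> group name
ColorMap = dict  # group name -> "#rrggbb"


def infer_group_from_name(taxon: str) -> str:
    """Group name from a taxon name: strip the maximal trailing digit run.

    A name that is all digits, or has no trailing digits, is its own group.
    """
    if not taxon:
        raise ValueError("empty taxon name")
    stripped = _TRAILING_DIGITS.sub("", taxon)
    return stripped if stripped else taxon


def assign_groups(
    tree: Tree,
    groups: Sequence[GroupDefinition] | None = None,
) -> GroupAssignment:
    """Total taxon -> group mapping over the tree's leaves.

    An explicit group file wins for its members; every remaining leaf is
    grouped by name inference. Group-file taxa absent from the tree are
    warned about, not fatal.
    """
    leaves = set(tree.leaf_labels())
    assignment: GroupAssignment = {}
    if groups:
        unknown: list[str] = []
        for group in groups:
            for member in group.members:
                if member in leaves:
                    assignment[member] = group.group_name
                else:
                    unknown.append(member)
        if unknown:
            logger.warning(
                "group file names %d taxa absent from the tree: %s",
                len(unknown), ", ".join(sorted(unknown)),
            )
    for leaf in leaves:
        if leaf not in assignment:
            assignment[leaf] = infer_group_from_name(leaf)
    return assignment


def normalize_hex_color(text: str) -> str:
    """Validate and lowercase a '#rrggbb' color."""
    color = text.strip().lower()
    if not _HEX_COLOR.match(color):
        raise ColorError(f"malformed hex color {text!r} (expected '#rrggbb')")
    return color


def build_color_map(
    assignment: GroupAssignment,
    overrides: Mapping[str, str] | None = None,
) -> ColorMap:
    """Group -> color. Overrides win; the rest take palette colors in sorted
    group-name order, cycling if there are more groups than palette entries.
    The reserved ``_default`` group is always present and black."""
    overrides = {g: normalize_hex_color(c) for g, c in (overrides or {}).items()}
    color_map: ColorMap = {DEFAULT_GROUP: DEFAULT_COLOR}
    color_map.update(overrides)
    palette_index = 0
    for group in sorted(set(assignment.values())):
        if group in color_map:
            continue
        color_map[group] = DEFAULT_PALETTE[palette_index % len(DEFAULT_PALETTE)]
        palette_index += 1
    return color_map


def color_tree(tree: Tree, assignment: GroupAssignment, color_map: ColorMap) -> Tree:
    """Install ``!color`` annotations on every node, in place.

    Leaves take their group's color; an internal node takes a color only if
    all its descendant leaves share one group (monophyletic propagation),
    otherwise the default black. Topology and branch lengths are untouched.
    Idempotent. Returns the same tree for chaining.
    """

    def visit(node: TreeNode) -> set[str]:
        if node.is_leaf:
            group = assignment.get(node.label, DEFAULT_GROUP)
            node.annotations[COLOR_KEY] = color_map.get(group, DEFAULT_COLOR)
            return {group}
        groups: set[str] = set()
        for child in node.children:
            groups |= visit(child)
        if len(groups) == 1:
            node.annotations[COLOR_KEY] = color_map.get(next(iter(groups)), DEFAULT_COLOR)
        else:
            node.annotations[COLOR_KEY] = color_map.get(DEFAULT_GROUP, DEFAULT_COLOR)
        return groups

    visit(tree.root)
    return tree


def read_color_overrides(path: str) -> dict[str, str]:
    """Read a plain 'group = #rrggbb' configuration file into overrides."""
    overrides: dict[str, str] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ColorError(f"{path}:{lineno}: expected 'group = #rrggbb'")
            group, _, value = line.partition("=")
            overrides[group.strip()] = normalize_hex_color(value)
    return overrides
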