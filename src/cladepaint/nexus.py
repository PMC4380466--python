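"""FigTree-dialect Nexus serialization.

The output document uses only the ``taxa`` and ``trees`` blocks, with display
metadata embedded in FigTree-style bracketed comments: ``[&!color=#rrggbb]``
after a taxon label, and ``[&!color=...,mutations={"AG54",...},time=...]``
after a node inside the tree statement, placed before the ``:length``.

The byte layout is fixed (LF newlines, lowercase keywords, single-tab
indentation, annotation items always in the order !color, mutations, time)
so that golden-file tests can compare output bit-exactly and decimal times
survive a write/read cycle as identical text.

The reader is the exact inverse of the writer on the writer's own output and
is tolerant of keyword case and extra whitespace; it exists for round-trip
testing and for re-annotating previously written documents, not for reading
arbitrary third-party Nexus (no data/characters blocks, no translate tables).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

from .annotate import MUTATIONS_KEY, TIME_KEY
from .colorize import COLOR_KEY
from .errors import NexusFormatError
from .tree import (
    Tree,
    TreeNode,
    format_branch_length,
    format_label,
    parse_newick,
    tree_equals,
)


@dataclass
class NexusDocument:
    """A serializable annotated tree: ordered taxa + one named tree.

    ``taxa`` must equal the tree's leaf labels in traversal order; per-taxon
    colors in the taxa block mirror the leaves' ``!color`` annotations.
    """

    tree: Tree
    tree_name: str = "tree1"
    taxa: list[str] = dataclass_field(default_factory=list)

    def __post_init__(self) -> None:
        leaf_labels = self.tree.leaf_labels()
        if not self.taxa:
            self.taxa = list(leaf_labels)
        elif self.taxa != leaf_labels:
            raise NexusFormatError(
                "taxa list does not match the tree's leaves in traversal order"
            )

    @classmethod
    def from_tree(cls, tree: Tree, tree_name: str = "tree1") -> "NexusDocument":
        return cls(tree=tree, tree_name=tree_name)

    @property
    def rooted_flag(self) -> bool:
        return self.tree.rooted_flag

    def taxon_colors(self) -> dict[str, str]:
        return {
            leaf.label: leaf.annotations[COLOR_KEY]
            for leaf in self.tree.root.leaves()
            if COLOR_KEY in leaf.annotations
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NexusDocument):
            return NotImplemented
        return (
            self.tree_name == other.tree_name
            and self.taxa == other.taxa
            and self.rooted_flag == other.rooted_flag
            and tree_equals(self.tree, other.tree, compare_annotations=True)
        )


# ---------------------------------------------------------------------------
# Writing


def _format_annotations(node: TreeNode) -> str:
    """The ``[&...]`` comment for one node, or '' if it has none.

    Item order is fixed: !color, mutations, time. Only these three keys are
    serialized; anything else in the annotation map is display-irrelevant.
    """
    items: list[str] = []
    if COLOR_KEY in node.annotations:
        items.append(f"!color={node.annotations[COLOR_KEY]}")
    if MUTATIONS_KEY in node.annotations:
        labels = node.annotations[MUTATIONS_KEY]
        quoted = ",".join(f'"{label}"' for label in labels)
        items.append("mutations={" + quoted + "}")
    if TIME_KEY in node.annotations:
        items.append(f"time={format_branch_length(float(node.annotations[TIME_KEY]))}")
    return "[&" + ",".join(items) + "]" if items else ""


def write_nexus_text(doc: NexusDocument) -> str:
    """Render the document to Nexus text (LF newlines, tab indentation)."""
    colors = doc.taxon_colors()
    lines = ["#NEXUS", "begin taxa;", f"\tdimensions ntax={len(doc.taxa)};", "\ttaxlabels"]
    for taxon in doc.taxa:
        suffix = f"[&!color={colors[taxon]}]" if taxon in colors else ""
        lines.append("\t" + format_label(taxon) + suffix)
    lines.append("\t;")
    lines.append("end;")
    lines.append("begin trees;")
    rooting = "[&R]" if doc.rooted_flag else "[&U]"
    from .tree import write_newick

    newick = write_newick(doc.tree, annotation_formatter=_format_annotations)
    lines.append(f"\ttree {format_label(doc.tree_name)} = {rooting} {newick}")
    lines.append("end;")
    return "\n".join(lines) + "\n"


def write_nexus(doc: NexusDocument, path: str | Path) -> None:
    Path(path).write_text(write_nexus_text(doc))


# ---------------------------------------------------------------------------
# Reading


def _split_top_level(body: str) -> list[str]:
    """Split an annotation body on commas not inside braces or quotes."""
    parts: list[str] = []
    depth = 0
    in_quote = False
    current: list[str] = []
    for ch in body:
        if ch == '"':
            in_quote = not in_quote
        elif not in_quote:
            if ch == "{":
                depth += 1
            elif ch == "}":
                depth -= 1
            elif ch == "," and depth == 0:
                parts.append("".join(current))
                current = []
                continue
        current.append(ch)
    if current:
        parts.append("".join(current))
    return parts


def parse_annotation_comment(node: TreeNode, body: str) -> None:
    """Parse ``&key=value,...`` into ``node.annotations``.

    ``{"a","b"}`` values become string lists; ``time`` becomes a float;
    everything else stays text.
    """
    assert body.startswith("&")
    for item in _split_top_level(body[1:]):
        key, eq, value = item.partition("=")
        if not eq:
            raise NexusFormatError(f"malformed annotation item {item!r}")
        key = key.strip()
        value = value.strip()
        if value.startswith("{") and value.endswith("}"):
            inner = value[1:-1]
            labels = [tok.strip().strip('"') for tok in _split_top_level(inner) if tok.strip()]
            node.annotations[key] = labels
        elif key == TIME_KEY:
            node.annotations[key] = float(value)
        else:
            node.annotations[key] = value


_TAXA_BLOCK = re.compile(r"begin\s+taxa\s*;(.*?)end\s*;", re.IGNORECASE | re.DOTALL)
_TREES_BLOCK = re.compile(r"begin\s+trees\s*;(.*?)end\s*;", re.IGNORECASE | re.DOTALL)
_NTAX = re.compile(r"dimensions\s+ntax\s*=\s*(\d+)\s*;", re.IGNORECASE)
_TAXLABELS = re.compile(r"taxlabels(.*?);", re.IGNORECASE | re.DOTALL)
_TREE_STMT = re.compile(
    r"tree\s+(?P<name>'(?:[^']|'')*'|[^\s=]+)\s*=\s*(?P<rooting>\[&[RU]\])?\s*(?P<newick>.*?;)",
    re.IGNORECASE | re.DOTALL,
)
_TAXLABEL_TOKEN = re.compile(
    r"('(?:[^']|'')*'|[^\s\[\]]+)(\[&!color=(#[0-9a-fA-F]{6})\])?"
)


def _unquote(token: str) -> str:
    if token.startswith("'") and token.endswith("'"):
        return token[1:-1].replace("''", "'")
    return token


def read_nexus_text(text: str) -> NexusDocument:
    stripped = text.lstrip()
    if not stripped.upper().startswith("#NEXUS"):
        raise NexusFormatError("not a Nexus file (missing #NEXUS header)")

    trees_match = _TREES_BLOCK.search(text)
    if trees_match is None:
        raise NexusFormatError("missing trees block")
    tree_match = _TREE_STMT.search(trees_match.group(1))
    if tree_match is None:
        raise NexusFormatError("trees block holds no tree statement")
    tree_name = _unquote(tree_match.group("name"))
    rooting = tree_match.group("rooting")
    tree = parse_newick(tree_match.group("newick"), comment_handler=parse_annotation_comment)
    tree.rooted_flag = rooting.upper() != "[&U]" if rooting else len(tree.root.children) <= 2

    taxa_match = _TAXA_BLOCK.search(text)
    if taxa_match is not None:
        block = taxa_match.group(1)
        labels_match = _TAXLABELS.search(block)
        if labels_match is None:
            raise NexusFormatError("taxa block without taxlabels")
        taxa: list[str] = []
        colors: dict[str, str] = {}
        for token, _, color in _TAXLABEL_TOKEN.findall(labels_match.group(1)):
            name = _unquote(token)
            taxa.append(name)
            if color:
                colors[name] = color.lower()
        ntax_match = _NTAX.search(block)
        if ntax_match is not None and int(ntax_match.group(1)) != len(taxa):
            raise NexusFormatError(
                f"ntax={ntax_match.group(1)} but {len(taxa)} taxlabels"
            )
        if taxa != tree.leaf_labels():
            raise NexusFormatError("taxlabels do not match the tree's leaves")
    else:
        taxa = tree.leaf_labels()

    return NexusDocument(tree=tree, tree_name=tree_name, taxa=taxa)


def read_nexus(path: str | Path) -> NexusDocument:
    """Parse a document previously written by :func:`write_nexus`."""
    return read_nexus_text(Path(path).read_text())
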