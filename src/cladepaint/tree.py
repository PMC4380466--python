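"""Rooted phylogenies and lossless Newick round-tripping.

The in-memory model is deliberately small: a :class:`TreeNode` carries a label,
an optional branch length (the length of the edge *above* the node), an ordered
list of children, and an open annotation mapping used by the colorization and
annotation layers. A :class:`Tree` wraps the root and validates the leaf-label
invariants.

The Newick dialect follows Felsenstein's standard: parenthesized topology,
``:`` branch lengths, ``;`` terminator, single-quoted labels with ``''``
escaping. Underscores in unquoted labels are kept as-is (not turned into
spaces) — taxon names such as ``Eu_Am5`` are common in population data and
must survive untouched. Bracketed comments in plain Newick input are discarded
with a logged warning; annotation-bearing comments (``[&...]``) are only
honoured when the caller opts in (the Nexus reader does).
"""

from __future__ import annotations

import logging
import math
import re
from typing import Callable, Iterator

from .errors import NewickParseError

logger = logging.getLogger(__name__)

AnnotationValue = "str | float | list[str]"

# Characters allowed in an unquoted Newick label.
_UNQUOTED_SAFE = re.compile(r"^[^\s()\[\]{}:;,'\"=]+$")
_UNQUOTED_CHARS = frozenset(" ()[]{}:;,'\"=\t\n\r")


class TreeNode:
    """A node of a rooted tree.

    Identity (not value) equality: nodes are hashable by object identity so
    they can key dictionaries such as the node-time table.
    """

    __slots__ = ("label", "branch_length", "children", "annotations")

    def __init__(
        self,
        label: str = "",
        branch_length: float | None = None,
        children: list["TreeNode"] | None = None,
    ) -> None:
        self.label = label
        self.branch_length = branch_length
        self.children: list[TreeNode] = children if children is not None else []
        self.annotations: dict[str, object] = {}

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        """Pre-order traversal (self first, then children left to right)."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> Iterator["TreeNode"]:
        for node in self.walk():
            if node.is_leaf:
                yield node

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {kind} {self.label!r} bl={self.branch_length}>"


def leaf_set(node: TreeNode) -> frozenset[str]:
    """The set of leaf labels descending from ``node`` (itself if a leaf)."""
    return frozenset(leaf.label for leaf in node.leaves())


class Tree:
    """A rooted phylogeny with unique, non-empty leaf labels.

    ``rooted_flag`` records whether the written root was binary; trees with a
    basal multifurcation are accepted and treated as rooted at the written
    root, but the flag lets the Nexus writer declare ``[&U]`` honestly.
    """

    def __init__(self, root: TreeNode, rooted_flag: bool | None = None) -> None:
        self.root = root
        if rooted_flag is None:
            rooted_flag = len(root.children) <= 2
        self.rooted_flag = rooted_flag
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for leaf in self.root.leaves():
            if not leaf.label:
                raise NewickParseError("leaf with empty label")
            if leaf.label in seen:
                raise NewickParseError(f"duplicate leaf label {leaf.label!r}")
            seen.add(leaf.label)
        if not seen:
            raise NewickParseError("tree has no leaves")

    def leaf_labels(self) -> list[str]:
        """Leaf labels in tree (left-to-right traversal) order."""
        return [leaf.label for leaf in self.root.leaves()]

    def nodes(self) -> Iterator[TreeNode]:
        return self.root.walk()

    def find_leaf(self, label: str) -> TreeNode | None:
        for leaf in self.root.leaves():
            if leaf.label == label:
                return leaf
        return None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree leaves={len(self.leaf_labels())} rooted={self.rooted_flag}>"


# ---------------------------------------------------------------------------
# Parsing


class _Parser:
    """Recursive-descent Newick parser tracking character offsets."""

    def __init__(self, text: str, comment_handler: Callable[[TreeNode, str], None] | None):
        self.text = text
        self.pos = 0
        self.comment_handler = comment_handler
        self.leaf_offsets: dict[str, int] = {}

    def error(self, message: str) -> NewickParseError:
        return NewickParseError(message, offset=self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self, node: TreeNode | None = None) -> None:
        """Skip whitespace and bracketed comments.

        Comments are discarded with a warning unless ``node`` is given, a
        handler is installed, and the comment starts with ``&`` (the FigTree
        annotation convention).
        """
        while self.pos < len(self.text):
            ch = self.text[self.pos]
            if ch.isspace():
                self.pos += 1
            elif ch == "[":
                start = self.pos
                end = self.text.find("]", self.pos)
                if end == -1:
                    raise self.error("unterminated '[' comment")
                body = self.text[start + 1 : end]
                self.pos = end + 1
                if node is not None and self.comment_handler is not None and body.startswith("&"):
                    self.comment_handler(node, body)
                else:
                    logger.warning("discarding bracketed comment %r at offset %d", body, start)
            else:
                return

    def parse_tree(self) -> TreeNode:
        self.skip_ws()
        if self.pos >= len(self.text):
            raise self.error("empty Newick input")
        node = self.parse_subtree()
        self.skip_ws(node)
        if self.peek() != ";":
            raise self.error("expected ';' terminating the tree")
        self.pos += 1
        return node

    def parse_subtree(self) -> TreeNode:
        self.skip_ws()
        if self.peek() == "(":
            node = self.parse_internal()
        else:
            node = self.parse_leaf()
        # label (for internal nodes), annotation comment, branch length
        self.skip_ws(node)
        if self.peek() == ":":
            self.pos += 1
            node.branch_length = self.parse_number()
            self.skip_ws(node)
        return node

    def parse_internal(self) -> TreeNode:
        assert self.peek() == "("
        self.pos += 1
        children = [self.parse_subtree()]
        while self.peek() == ",":
            self.pos += 1
            children.append(self.parse_subtree())
        if self.peek() != ")":
            raise self.error("expected ')' or ',' (unbalanced parentheses?)")
        self.pos += 1
        node = TreeNode(children=children)
        self.skip_ws(node)
        if self.peek() not in ("", ":", ",", ")", ";", "["):
            node.label = self.parse_label()
        return node

    def parse_leaf(self) -> TreeNode:
        self.skip_ws()
        start = self.pos
        label = self.parse_label()
        if not label:
            raise self.error("expected a taxon label")
        if label in self.leaf_offsets:
            raise NewickParseError(f"duplicate leaf label {label!r}", offset=start)
        self.leaf_offsets[label] = start
        return TreeNode(label=label)

    def parse_label(self) -> str:
        if self.peek() == "'":
            return self.parse_quoted()
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in _UNQUOTED_CHARS:
            self.pos += 1
        return self.text[start : self.pos]

    def parse_quoted(self) -> str:
        assert self.peek() == "'"
        self.pos += 1
        out: list[str] = []
        while True:
            if self.pos >= len(self.text):
                raise self.error("unterminated quoted label")
            ch = self.text[self.pos]
            if ch == "'":
                if self.pos + 1 < len(self.text) and self.text[self.pos + 1] == "'":
                    out.append("'")
                    self.pos += 2
                else:
                    self.pos += 1
                    return "".join(out)
            else:
                out.append(ch)
                self.pos += 1

    def parse_number(self) -> float:
        self.skip_ws()
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] in "+-0123456789.eE":
            self.pos += 1
        token = self.text[start : self.pos]
        try:
            value = float(token)
        except ValueError:
            self.pos = start
            raise self.error(f"malformed branch length {token!r}")
        if math.isnan(value):
            self.pos = start
            raise self.error("branch length is NaN")
        if value < 0:
            self.pos = start
            raise self.error(f"negative branch length {token}")
        return value


def parse_newick(
    text: str,
    comment_handler: Callable[[TreeNode, str], None] | None = None,
) -> Tree:
    """Parse a single Newick tree from ``text``.

    Only the first tree of a multi-tree string is returned (a warning is
    logged for extras). Bracketed comments are discarded with a warning unless
    ``comment_handler`` is given, in which case comments of the FigTree
    ``[&...]`` form are forwarded to it with the node they follow.

    Raises :class:`NewickParseError` (carrying a character offset) on
    unbalanced parentheses, duplicate leaf labels, empty input or trailing
    garbage after the ``;``.
    """
    parser = _Parser(text, comment_handler)
    root = parser.parse_tree()
    remainder = text[parser.pos :].strip()
    if remainder:
        if ";" in remainder:
            logger.warning("input holds more than one tree; only the first is used")
        else:
            raise NewickParseError("trailing garbage after ';'", offset=parser.pos)
    return Tree(root)


# ---------------------------------------------------------------------------
# Writing


def format_branch_length(value: float) -> str:
    """Shortest decimal text that parses back to exactly ``value``."""
    text = repr(float(value))
    if text.endswith(".0"):
        text = text[:-2]
    return text


def format_label(label: str) -> str:
    """Quote a label if it contains characters unsafe for unquoted Newick."""
    if label and _UNQUOTED_SAFE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(
    tree: Tree,
    annotation_formatter: Callable[[TreeNode], str] | None = None,
) -> str:
    """Serialize ``tree`` to Newick text, terminated by ``;``.

    ``annotation_formatter``, when given, may return a bracketed-comment
    string (``"[&...]"`` or ``""``) to insert after each node's label/subtree
    and before its branch length — the hook used by the Nexus writer.
    """

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            text = format_label(node.label)
        else:
            inner = ",".join(render(child) for child in node.children)
            text = f"({inner})"
            if node.label:
                text += format_label(node.label)
        if annotation_formatter is not None:
            text += annotation_formatter(node)
        if node.branch_length is not None:
            text += ":" + format_branch_length(node.branch_length)
        return text

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# Equality


def _lengths_equal(a: float | None, b: float | None, rel_tol: float) -> bool:
    if (a is None) != (b is None):
        return False
    if a is None:
        return True
    return math.isclose(a, b, rel_tol=rel_tol, abs_tol=rel_tol)


def tree_equals(
    a: Tree | TreeNode,
    b: Tree | TreeNode,
    rel_tol: float = 1e-9,
    tolerant: bool = False,
    compare_annotations: bool = False,
) -> bool:
    """Structural tree equality.

    Child order is significant by default (parsing never reorders children);
    ``tolerant=True`` ignores child order by matching children on their leaf
    sets. Branch lengths compare within ``rel_tol``; absent and zero lengths
    are distinct states.
    """
    na = a.root if isinstance(a, Tree) else a
    nb = b.root if isinstance(b, Tree) else b

    def eq(x: TreeNode, y: TreeNode) -> bool:
        if x.label != y.label:
            return False
        if not _lengths_equal(x.branch_length, y.branch_length, rel_tol):
            return False
        if compare_annotations and x.annotations != y.annotations:
            return False
        if len(x.children) != len(y.children):
            return False
        if tolerant:
            ys = {leaf_set(c): c for c in y.children}
            for cx in x.children:
                cy = ys.get(leaf_set(cx))
                if cy is None or not eq(cx, cy):
                    return False
            return True
        return all(eq(cx, cy) for cx, cy in zip(x.children, y.children))

    return eq(na, nb)
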