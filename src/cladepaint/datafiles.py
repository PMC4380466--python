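"""Readers and writers for the three auxiliary record files.

The upstream tree-building pipeline communicates through three plain-text
files whose exact byte layout was never published; this module defines a
minimal, self-describing line dialect carrying the same semantic content and
keeps the readers and writers exactly symmetric so the fixture generator can
round-trip everything.

Dialect (version header ``# cladepaint-dialect v1``, optional on read; ``#``
lines are comments; fields are whitespace-separated; one record per line):

* sequence file  — ``<name> <ACGT-sequence> <frequency>``
* group file     — ``<group_name>: <member> <member> ...``
* event log      — ``merge t=<real> left=<csv-names> right=<csv-names>``
                   and ``mutation t=<real> site=<int> from=<nt> to=<nt>
                   clade=<csv-names>``

Sites are 1-based. Mutation direction: ``from`` is the state at time t+eps
(older), ``to`` the state at time t (newer) — reverse time, observed
sequences at t=0. The log reader is tolerant (the source format is debugging
output): unparseable lines are skipped, counted and reported, and only a log
with zero parseable events is an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FileFormatError

logger = logging.getLogger(__name__)

DIALECT_HEADER = "# cladepaint-dialect v1"
NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    """One observed haplotype: taxon name, nucleotide sequence, frequency."""

    name: str
    sequence: str
    frequency: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence record needs a non-empty name")
        if not self.sequence:
            raise ValueError(f"{self.name}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise ValueError(f"{self.name}: non-ACGT characters {sorted(bad)}")
        if self.frequency < 0:
            raise ValueError(f"{self.name}: negative frequency {self.frequency}")


@dataclass(frozen=True)
class GroupDefinition:
    """A named group of taxa (e.g. a source population)."""

    group_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.group_name!r} has no members")


@dataclass(frozen=True)
class MutationEvent:
    """A nucleotide substitution on one lineage.

    ``time`` is reverse time (0 = present). ``ancestral_nt`` is the state at
    time t+eps (immediately older), ``derived_nt`` the state at time t. The
    event is carried by the lineage whose descendant leaf set is ``clade``.
    ``time`` may be ``None`` for events inferred by sequence comparison, where
    no time is known.
    """

    time: float | None
    site: int
    ancestral_nt: str
    derived_nt: str
    clade: frozenset[str]

    def __post_init__(self) -> None:
        if self.ancestral_nt not in NUCLEOTIDES or self.derived_nt not in NUCLEOTIDES:
            raise ValueError(f"nucleotides must be in ACGT: {self.ancestral_nt}->{self.derived_nt}")
        if self.ancestral_nt == self.derived_nt:
            raise ValueError(f"site {self.site}: ancestral and derived nucleotide both {self.derived_nt}")
        if self.site < 1:
            raise ValueError(f"site must be >= 1, got {self.site}")
        if self.time is not None and self.time < 0:
            raise ValueError(f"negative event time {self.time}")
        if not self.clade:
            raise ValueError("mutation event with empty clade")


@dataclass(frozen=True)
class MergeEvent:
    """The coalescence of two lineages at a recorded (positive) time."""

    time: float
    left_clade: frozenset[str]
    right_clade: frozenset[str]

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"merge time must be positive, got {self.time}")
        if not self.left_clade or not self.right_clade:
            raise ValueError("merge event with an empty clade")
        overlap = self.left_clade & self.right_clade
        if overlap:
            raise ValueError(f"merge clades overlap: {sorted(overlap)}")

    @property
    def clade(self) -> frozenset[str]:
        return self.left_clade | self.right_clade


@dataclass
class EventLog:
    """All merge and mutation events for one tree.

    ``merges`` is kept sorted ascending by time; ``skipped`` records the
    (line number, text) pairs the tolerant reader could not parse.
    """

    mutations: list[MutationEvent] = field(default_factory=list)
    merges: list[MergeEvent] = field(default_factory=list)
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def sort(self) -> None:
        self.merges.sort(key=lambda m: m.time)

    def taxa(self) -> frozenset[str]:
        names: set[str] = set()
        for m in self.merges:
            names |= m.clade
        for mu in self.mutations:
            names |= mu.clade
        return frozenset(names)

    def validate(self) -> None:
        n = len({name for m in self.merges for name in m.clade})
        if n and len(self.merges) > n - 1:
            raise FileFormatError(
                f"{len(self.merges)} merges but only {n} taxa (at most {n - 1} merges possible)"
            )


# ---------------------------------------------------------------------------
# Line plumbing


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def _csv_names(token: str) -> frozenset[str]:
    names = frozenset(n for n in token.split(",") if n)
    if not names:
        raise ValueError(f"empty name list {token!r}")
    return names


# ---------------------------------------------------------------------------
# Sequence file


def read_sequence_file(path: str | Path) -> list[SequenceRecord]:
    """Read ``<name> <sequence> <frequency>`` records.

    Errors (with the offending line number): ragged sequence lengths,
    duplicate names, non-ACGT characters, negative frequencies. An empty file
    yields an empty list with a warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    length: int | None = None
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) != 3:
            raise FileFormatError(
                f"expected 'name sequence frequency', got {len(fields)} fields",
                line=lineno, path=str(path),
            )
        name, seq, freq_text = fields
        try:
            frequency = float(freq_text)
            record = SequenceRecord(name=name, sequence=seq.upper(), frequency=frequency)
        except ValueError as exc:
            raise FileFormatError(str(exc), line=lineno, path=str(path)) from exc
        if name in seen:
            raise FileFormatError(f"duplicate sequence name {name!r}", line=lineno, path=str(path))
        seen.add(name)
        if length is None:
            length = len(record.sequence)
        elif len(record.sequence) != length:
            raise FileFormatError(
                f"sequence length {len(record.sequence)} differs from earlier length {length}",
                line=lineno, path=str(path),
            )
        records.append(record)
    if not records:
        logger.warning("%s: no sequence records found", path)
    return records


def write_sequence_file(records: Sequence[SequenceRecord], path: str | Path) -> None:
    lines = [DIALECT_HEADER]
    for rec in records:
        freq = int(rec.frequency) if float(rec.frequency).is_integer() else rec.frequency
        lines.append(f"{rec.name} {rec.sequence} {freq}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Group file


def read_group_file(path: str | Path) -> list[GroupDefinition]:
    """Read ``group_name: member member ...`` lines, in file order.

    A taxon may belong to at most one group; empty groups are format errors.
    """
    groups: list[GroupDefinition] = []
    owner: dict[str, str] = {}
    seen_names: set[str] = set()
    for lineno, line in _data_lines(path):
        if ":" not in line:
            raise FileFormatError("expected 'group_name: member ...'", line=lineno, path=str(path))
        name, _, member_text = line.partition(":")
        name = name.strip()
        members = member_text.split()
        if not name:
            raise FileFormatError("empty group name", line=lineno, path=str(path))
        if name in seen_names:
            raise FileFormatError(f"duplicate group name {name!r}", line=lineno, path=str(path))
        if not members:
            raise FileFormatError(f"group {name!r} has no members", line=lineno, path=str(path))
        for member in members:
            if member in owner:
                raise FileFormatError(
                    f"taxon {member!r} already belongs to group {owner[member]!r}",
                    line=lineno, path=str(path),
                )
            owner[member] = name
        seen_names.add(name)
        groups.append(GroupDefinition(group_name=name, members=frozenset(members)))
    if not groups:
        raise FileFormatError("no group definitions found", path=str(path))
    return groups


def write_group_file(groups: Sequence[GroupDefinition], path: str | Path) -> None:
    lines = [DIALECT_HEADER]
    for group in groups:
        lines.append(f"{group.group_name}: " + " ".join(sorted(group.members)))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Event log


def _parse_kv(fields: list[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for token in fields:
        key, eq, value = token.partition("=")
        if not eq or not value:
            raise ValueError(f"malformed field {token!r}")
        out[key] = value
    return out


def read_log_file(path: str | Path) -> EventLog:
    """Tolerantly parse an event log.

    Every well-formed ``merge``/``mutation`` line becomes an event; anything
    else is skipped, counted and logged (the upstream source is debugging
    output). Merges come back sorted ascending by time. A log with zero
    parseable events is a format error.
    """
    log = EventLog()
    for lineno, line in _data_lines(path):
        fields = line.split()
        tag = fields[0]
        try:
            kv = _parse_kv(fields[1:])
            if tag == "merge":
                log.merges.append(MergeEvent(
                    time=float(kv["t"]),
                    left_clade=_csv_names(kv["left"]),
                    right_clade=_csv_names(kv["right"]),
                ))
            elif tag == "mutation":
                log.mutations.append(MutationEvent(
                    time=float(kv["t"]),
                    site=int(kv["site"]),
                    ancestral_nt=kv["from"].upper(),
                    derived_nt=kv["to"].upper(),
                    clade=_csv_names(kv["clade"]),
                ))
            else:
                raise ValueError(f"unknown record tag {tag!r}")
        except (ValueError, KeyError):
            log.skipped.append((lineno, line))
    if log.skipped:
        logger.warning(
            "%s: skipped %d unparseable line(s): %s",
            path, len(log.skipped), ", ".join(str(n) for n, _ in log.skipped),
        )
    if not log.merges and not log.mutations:
        raise FileFormatError("no parseable events in log", path=str(path))
    log.sort()
    log.validate()
    return log


def write_log_file(log: EventLog, path: str | Path) -> None:
    from .tree import format_branch_length as fmt  # shortest round-trip decimals

    lines = [DIALECT_HEADER]
    for merge in sorted(log.merges, key=lambda m: m.time):
        lines.append(
            f"merge t={fmt(merge.time)}"
            f" left={','.join(sorted(merge.left_clade))}"
            f" right={','.join(sorted(merge.right_clade))}"
        )
    for mut in log.mutations:
        if mut.time is None:
            raise ValueError("cannot serialize a mutation event without a time")
        lines.append(
            f"mutation t={fmt(mut.time)} site={mut.site}"
            f" from={mut.ancestral_nt} to={mut.derived_nt}"
            f" clade={','.join(sorted(mut.clade))}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
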