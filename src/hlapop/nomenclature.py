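"""HLA allele nomenclature: parsing, two-field truncation and G-group containment.

HLA alleles are named ``LOCUS*F1:F2[:F3[:F4]][suffix]`` where the colon-separated
fields carry increasing resolution (allele group, protein, synonymous coding,
non-coding) and an optional trailing expression letter (N, L, S, C, A, Q) marks
aberrant expression.  A trailing ``G`` instead designates a *G group*: the set of
alleles sharing identical DNA sequence over the exons encoding the antigen
recognition site.  G groups are defined by the IPD-IMGT/HLA ``hla_nom_g.txt``
file, whose dialect this module reads.

Analyses here operate at *two-field* (protein-level) resolution; comparison and
truncation helpers implement that convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "MISSING",
    "Allele",
    "GGroupTable",
    "parse_allele",
    "trim_to_two_fields",
    "load_g_groups",
    "g_contains",
    "is_missing",
]

#: Distinguished token for a missing / unreported allele call.  The tabular
#: dialects read by this package map "", "NA", "na", "-" and "." onto it.
MISSING = "NA"

_MISSING_TOKENS = {"", "na", "-", ".", "nan", "none"}

_EXPRESSION_SUFFIXES = "NLSCAQ"

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?"
    r"(?P<locus>[A-Z][A-Z0-9]*)\*"
    r"(?P<fields>\d+(?::\d+){0,3})"
    r"(?P<tail>[A-Za-z]?)$",
    re.IGNORECASE,
)


class AlleleParseError(ValueError):
    """Raised when an allele string does not match the HLA nomenclature grammar."""


def is_missing(token: Optional[str]) -> bool:
    """True when *token* denotes a missing allele call."""
    return token is None or str(token).strip().lower() in _MISSING_TOKENS


@dataclass(frozen=True, order=True)
class Allele:
    """A parsed HLA allele name.

    Attributes
    ----------
    locus:
        Gene label without the ``HLA-`` prefix (``A``, ``B``, ``DRB1``, ...).
    fields:
        1-4 numeric field strings with leading zeros preserved.
    suffix:
        Optional expression letter (``N``, ``L``, ``S``, ``Q``, ...), or ``""``.
    is_group:
        True when the name ends in ``G`` (a G-group name).
    """

    locus: str
    fields: tuple[str, ...]
    suffix: str = ""
    is_group: bool = False

    def __post_init__(self) -> None:
        if not self.fields:
            raise AlleleParseError("allele must have at least one field")

    def __str__(self) -> str:
        tail = "G" if self.is_group else self.suffix
        return f"{self.locus}*{':'.join(self.fields)}{tail}"

    @property
    def name(self) -> str:
        return str(self)

    def two_field(self) -> "Allele":
        return trim_to_two_fields(self)

    def two_field_key(self) -> tuple[str, str, str]:
        """Hashable identity at two-field resolution (locus, fields, suffix).

        Expression suffixes are compared literally (``01:01`` != ``01:01N``):
        expression variants are distinct gene products.  The G flag is part of
        the retained name only while the G-bearing field survives truncation.
        """
        t = trim_to_two_fields(self)
        return (t.locus, ":".join(t.fields), "G" if t.is_group else t.suffix)


def parse_allele(text: str) -> Allele:
    """Parse an HLA allele string, with or without the ``HLA-`` prefix.

    Parsing is case-insensitive; the locus is upper-cased.  A trailing ``G``
    marks a G-group name, any other trailing letter an expression suffix.

    Raises
    ------
    AlleleParseError
        If *text* does not match ``LOCUS*F1[:F2[:F3[:F4]]][letter]``.
    """
    m = _ALLELE_RE.match(str(text).strip())
    if m is None:
        raise AlleleParseError(f"not a valid HLA allele name: {text!r}")
    tail = m.group("tail").upper()
    is_group = tail == "G"
    suffix = "" if is_group else tail
    if suffix and suffix not in _EXPRESSION_SUFFIXES:
        raise AlleleParseError(
            f"unknown expression suffix {suffix!r} in allele {text!r}"
        )
    return Allele(
        locus=m.group("locus").upper(),
        fields=tuple(m.group("fields").split(":")),
        suffix=suffix,
        is_group=is_group,
    )


def trim_to_two_fields(a: Allele) -> Allele:
    """Truncate an allele to at most two fields (protein-level resolution).

    The expression suffix is retained.  The G flag is dropped when truncation
    removes the field that carried it (a G-group name has >= 3 fields, so a
    trimmed group name reverts to the plain two-field allele).
    """
    if len(a.fields) <= 2:
        return a
    return replace(a, fields=a.fields[:2], is_group=False)


@dataclass
class GGroupTable:
    """Index of G-group membership per the IPD-IMGT/HLA group file.

    ``groups`` maps ``(locus, group_name)`` -> set of member :class:`Allele`
    at the resolution given in the file; ``reverse`` maps
    ``(locus, full_member_name)`` -> group name.
    """

    groups: dict[tuple[str, str], set[Allele]] = field(default_factory=dict)
    reverse: dict[tuple[str, str], str] = field(default_factory=dict)

    def group_of(self, a: Allele) -> Optional[str]:
        return self.reverse.get((a.locus, ":".join(a.fields) + a.suffix))

    def members(self, group: Allele) -> set[Allele]:
        key = (group.locus, ":".join(group.fields) + "G")
        try:
            return self.groups[key]
        except KeyError:
            raise KeyError(f"unknown G group {group}") from None

    def two_field_members(self, group: Allele) -> set[tuple[str, str, str]]:
        return {m.two_field_key() for m in self.members(group)}

    def two_field_member_cores(self, group: Allele) -> set[tuple[str, str]]:
        """Member identities at two-field resolution ignoring expression
        suffixes (G-group coverage is about sequence identity over the
        antigen-recognition-site exons, which null/low-expression variants
        share with their expressed counterparts)."""
        return {(l, f) for l, f, _ in self.two_field_members(group)}


class GGroupFormatError(ValueError):
    """Raised on a malformed line of the group-definition file."""


def load_g_groups(stream: Iterable[str]) -> GGroupTable:
    """Parse the ``hla_nom_g.txt`` dialect into a :class:`GGroupTable`.

    Lines starting with ``#`` are comments.  Data lines have three
    semicolon-separated columns: ``LOCUS*;member1/member2/...;GROUP``.  A line
    whose third column is empty records a lone allele outside any group and
    creates no entry.
    """
    table = GGroupTable()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split(";")
        if len(parts) != 3:
            raise GGroupFormatError(
                f"line {lineno}: expected 3 ';'-separated columns, got {len(parts)}"
            )
        locus_tok, members_tok, group_tok = (p.strip() for p in parts)
        if not group_tok:
            continue
        locus = locus_tok.rstrip("*").upper()
        members = {
            parse_allele(f"{locus}*{m}") for m in members_tok.split("/") if m
        }
        key = (locus, group_tok)
        if key in table.groups:
            raise GGroupFormatError(f"line {lineno}: duplicate group {group_tok}")
        table.groups[key] = members
        for m in members:
            mkey = (locus, ":".join(m.fields) + m.suffix)
            if mkey in table.reverse:
                raise GGroupFormatError(
                    f"line {lineno}: allele {m} already assigned to "
                    f"group {table.reverse[mkey]}"
                )
            table.reverse[mkey] = group_tok
    return table


def g_contains(table: GGroupTable, group: Allele, candidate: Allele) -> bool:
    """True iff *candidate* (at two-field resolution) is covered by *group*.

    Membership is decided by trimming every member of the group to two
    fields and comparing with the trimmed candidate, ignoring expression
    suffixes on both sides (group membership reflects coding-sequence
    identity, which expression variants share).

    Raises
    ------
    KeyError
        If the group name is not in the table.
    """
    if not group.is_group:
        raise ValueError(f"{group} is not a G-group name")
    if group.locus != candidate.locus:
        return False
    locus, fields, _ = candidate.two_field_key()
    return (locus, fields) in table.two_field_member_cores(group)
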