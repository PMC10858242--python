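"""Consensus HLA genotype calling from two callers' outputs.

Two HLA callers applied to the same short-read data disagree in predictable,
locus-specific ways.  The strategy implemented here is: (1) validate each
caller per locus against a gold-standard genotype set, G-group aware;
(2) form a third "voting" call that merges the two callers' candidate alleles
using population reference allele frequencies; (3) per locus, adopt whichever
of the three has the highest validated accuracy; (4) apply that policy to the
full cohort.

Matching is at two-field resolution throughout, and a caller that reports a
G-group name matches any allele the group contains.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .nomenclature import (
    MISSING,
    Allele,
    GGroupTable,
    g_contains,
    is_missing,
    parse_allele,
    trim_to_two_fields,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceAF",
    "allele_match",
    "genotype_match_count",
    "evaluate_tool",
    "combine_by_af",
    "select_policy",
    "apply_policy",
]

VOTE = "vote"
AllelePair = tuple[Optional[Allele], Optional[Allele]]


class ReferenceAF:
    """Per-locus reference allele frequencies used by the voting strategy.

    Lookup rules: a plain allele is looked up by its two-field name and an
    absent allele has frequency 0 (rare or novel alleles must stay selectable
    but rank last).  A G-group name is looked up as the group name itself if
    the table lists it, otherwise as the maximum frequency over the group's
    two-field members (a group aggregates indistinguishable alleles).
    """

    def __init__(self, frequencies: Mapping[tuple[str, str], float]):
        self._af = dict(frequencies)
        for (locus, name), f in self._af.items():
            if f < 0:
                raise ValueError(f"negative frequency for {locus}*{name}")

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "ReferenceAF":
        """Build from a ``locus  allele  frequency`` table (allele strings
        may carry the locus prefix or not)."""
        freqs: dict[tuple[str, str], float] = {}
        for row in df.itertuples(index=False):
            name = str(row.allele)
            if "*" not in name:
                name = f"{row.locus}*{name}"
            a = parse_allele(name)
            key = (a.locus, _display(a))
            freqs[key] = freqs.get(key, 0.0) + float(row.frequency)
        return cls(freqs)

    def lookup(self, a: Allele, groups: Optional[GGroupTable] = None) -> float:
        name = _display(a)
        if not a.is_group:
            return self._af.get((a.locus, name), 0.0)
        if (a.locus, name) in self._af:
            return self._af[(a.locus, name)]
        if groups is not None:
            try:
                members = groups.two_field_members(a)
            except KeyError:
                members = set()
            if members:
                return max(
                    self._af.get((locus, fields + suffix), 0.0)
                    for locus, fields, suffix in members
                )
        # unknown group: fall back to its two-field prefix
        t = trim_to_two_fields(a)
        return self._af.get((a.locus, _display(t)), 0.0)


def _display(a: Allele) -> str:
    """Name without the locus prefix, e.g. ``02:01`` or ``01:01:01G``."""
    return ":".join(a.fields) + ("G" if a.is_group else a.suffix)


def allele_match(a: Allele, b: Allele, groups: GGroupTable) -> bool:
    """Two-field equality, or G-group containment in either direction."""
    if a.locus != b.locus:
        return False
    for g, x in ((a, b), (b, a)):
        if g.is_group:
            try:
                if g_contains(groups, g, x):
                    return True
            except KeyError:
                pass
    return a.two_field_key() == b.two_field_key()


def genotype_match_count(
    called: AllelePair, gold: AllelePair, groups: GGroupTable
) -> tuple[int, int]:
    """Matched and comparable allele counts between a call and the gold pair.

    Uses the maximum bipartite matching between the non-missing called and
    gold alleles; missing alleles on either side shrink the comparable-allele
    denominator and can never match.  A homozygous gold genotype contributes
    two comparable alleles.
    """
    c = [a for a in called if a is not None]
    d = [a for a in gold if a is not None]
    comparable = min(len(c), len(d))
    if comparable == 0:
        return 0, 0
    best = 0
    # brute force over injections from the smaller side into the larger one
    small, large = (c, d) if len(c) <= len(d) else (d, c)
    for perm in itertools.permutations(range(len(large)), len(small)):
        m = sum(
            1
            for i, j in enumerate(perm)
            if allele_match(small[i], large[j], groups)
        )
        best = max(best, m)
    return best, comparable


def _pair_from_row(row) -> AllelePair:
    out = []
    for col in ("allele1", "allele2"):
        tok = getattr(row, col)
        out.append(None if is_missing(tok) else parse_allele(f"{row.locus}*{tok}"
                                                            if "*" not in str(tok) else str(tok)))
    return tuple(out)  # type: ignore[return-value]


def _genotype_map(df: pd.DataFrame) -> dict[tuple[str, str], AllelePair]:
    out: dict[tuple[str, str], AllelePair] = {}
    for row in df.itertuples(index=False):
        out[(str(row.sample_id), str(row.locus))] = _pair_from_row(row)
    return out


def evaluate_tool(
    calls: pd.DataFrame, gold: pd.DataFrame, groups: GGroupTable
) -> pd.DataFrame:
    """Per-locus accuracy of *calls* against *gold* (matched / comparable).

    Returns a frame with columns ``locus, matched, comparable, accuracy``;
    loci whose comparable-allele denominator is zero get accuracy NaN.
    """
    cmap = _genotype_map(calls)
    gmap = _genotype_map(gold)
    shared = [k for k in cmap if k in gmap]
    if not {s for s, _ in shared}:
        raise ValueError("no samples in common between calls and gold standard")
    acc: dict[str, list[int]] = {}
    for key in shared:
        m, n = genotype_match_count(cmap[key], gmap[key], groups)
        locus = key[1]
        tot = acc.setdefault(locus, [0, 0])
        tot[0] += m
        tot[1] += n
    rows = [
        {
            "locus": locus,
            "matched": m,
            "comparable": n,
            "accuracy": (m / n) if n else float("nan"),
        }
        for locus, (m, n) in sorted(acc.items())
    ]
    return pd.DataFrame(rows)


@dataclass
class _Candidate:
    allele: Allele          # two-field representation (G groups keep the group name)
    af: float
    tool: str
    used: bool = False

    @property
    def sort_name(self) -> str:
        return str(self.allele)


def _candidates(
    pair: AllelePair, tool: str, ref: ReferenceAF, groups: GGroupTable
) -> list[_Candidate]:
    out = []
    for a in pair:
        if a is None:
            continue
        rep = a if a.is_group else trim_to_two_fields(a)
        out.append(_Candidate(rep, ref.lookup(rep, groups), tool))
    return out


def _prefer_specific(a: _Candidate, b: _Candidate) -> Allele:
    """Representative of two agreeing candidates: prefer the non-group name."""
    if a.allele.is_group and not b.allele.is_group:
        return b.allele
    return a.allele


def combine_by_af(
    pair1: AllelePair,
    pair2: AllelePair,
    ref: ReferenceAF,
    groups: GGroupTable,
    priority_tool: str = "tool_1",
) -> tuple[Allele, Allele]:
    """Merge two callers' allele pairs into one genotype by AF voting.

    Selection order over the up-to-four two-field candidates:

    1. alleles the two tools agree on (two-field equality or G-group
       containment) are selected first, the more specific name winning;
    2. a cross-tool pair sharing the first field but differing at the second
       contributes its higher-AF member;
    3. remaining output slots are filled in descending reference AF;
    4. AF ties break toward ``priority_tool``'s allele, then lexicographically.

    Exactly two alleles are returned; if the candidates are exhausted after
    one selection (both tools reported a single, concordant allele) the
    selected allele is doubled.
    """
    c1 = _candidates(pair1, "tool_1", ref, groups)
    c2 = _candidates(pair2, "tool_2", ref, groups)
    if not c1 and not c2:
        raise ValueError("both callers missing: nothing to combine")
    selected: list[Allele] = []

    # step 1: cross-tool agreement
    for a in c1:
        if len(selected) == 2:
            break
        for b in c2:
            if b.used or a.used:
                continue
            if allele_match(a.allele, b.allele, groups):
                a.used = b.used = True
                selected.append(_prefer_specific(a, b))
                break

    # step 2: cross-tool first-field concordance, higher AF wins the slot
    if len(selected) < 2:
        ff_pairs = [
            (a, b)
            for a in c1
            for b in c2
            if not a.used
            and not b.used
            and a.allele.fields[0] == b.allele.fields[0]
        ]
        ff_pairs.sort(
            key=lambda p: (-max(p[0].af, p[1].af), p[0].sort_name, p[1].sort_name)
        )
        for a, b in ff_pairs:
            if len(selected) == 2:
                break
            if a.used or b.used:
                continue
            a.used = b.used = True
            winner = _rank_pair(a, b, priority_tool)[0]
            selected.append(winner.allele)

    # step 3: descending AF among what remains
    rest = [c for c in c1 + c2 if not c.used]
    rest.sort(key=lambda c: _rank_key(c, priority_tool))
    for c in rest:
        if len(selected) == 2:
            break
        c.used = True
        selected.append(c.allele)

    if len(selected) == 1:
        selected.append(selected[0])
    return selected[0], selected[1]


def _rank_key(c: _Candidate, priority_tool: str):
    return (-c.af, 0 if c.tool == priority_tool else 1, c.sort_name)


def _rank_pair(a: _Candidate, b: _Candidate, priority_tool: str):
    return sorted((a, b), key=lambda c: _rank_key(c, priority_tool))


def select_policy(
    acc_tool1: pd.DataFrame,
    acc_tool2: pd.DataFrame,
    acc_vote: pd.DataFrame,
    tool_names: Sequence[str] = ("tool_1", "tool_2"),
) -> dict[str, str]:
    """Per-locus choice of the highest-accuracy method.

    Ties favour the vote, then tool order.  All three accuracy tables must
    cover the same loci.
    """
    tables = {
        VOTE: acc_vote.set_index("locus")["accuracy"],
        tool_names[0]: acc_tool1.set_index("locus")["accuracy"],
        tool_names[1]: acc_tool2.set_index("locus")["accuracy"],
    }
    loci = set(tables[VOTE].index)
    for name, t in tables.items():
        if set(t.index) != loci:
            raise ValueError(f"accuracy table for {name} covers different loci")
    policy = {}
    order = [VOTE, tool_names[0], tool_names[1]]
    for locus in sorted(loci):
        best = max(order, key=lambda m: (tables[m][locus], -order.index(m)))
        policy[locus] = best
    return policy


def apply_policy(
    calls_1: pd.DataFrame,
    calls_2: pd.DataFrame,
    policy: Mapping[str, str],
    ref: ReferenceAF,
    groups: GGroupTable,
    priority: Union[str, Mapping[str, str]] = "tool_1",
    tool_names: Sequence[str] = ("tool_1", "tool_2"),
) -> pd.DataFrame:
    """Emit the consensus genotype table according to a per-locus policy.

    Loci absent from one tool's output fall back to the other tool (logged);
    a sample/locus missing from both inputs is omitted with a warning.
    ``priority`` is the tie-breaking tool for the vote, either globally or
    per locus.
    """
    m1 = _genotype_map(calls_1)
    m2 = _genotype_map(calls_2)
    platforms = {}
    for df in (calls_1, calls_2):
        for row in df.itertuples(index=False):
            platforms.setdefault((str(row.sample_id), str(row.locus)),
                                 str(row.platform))
    rows = []
    for key in sorted(set(m1) | set(m2)):
        sample, locus = key
        if locus not in policy:
            continue
        choice = policy[locus]
        p1, p2 = m1.get(key), m2.get(key)
        pair: Optional[AllelePair] = None
        if choice == tool_names[0]:
            pair = p1 if p1 is not None else p2
        elif choice == tool_names[1]:
            pair = p2 if p2 is not None else p1
        else:  # vote
            if p1 is not None and p2 is not None and (
                any(a is not None for a in p1) or any(a is not None for a in p2)
            ):
                prio = priority if isinstance(priority, str) else priority.get(
                    locus, tool_names[0]
                )
                try:
                    pair = combine_by_af(p1, p2, ref, groups, prio)
                except ValueError:
                    pair = None
            elif p1 is not None:
                pair = p1
            else:
                pair = p2
        if pair is None:
            logger.warning("no call for sample %s locus %s", sample, locus)
            continue
        rows.append(
            {
                "sample_id": sample,
                "locus": locus,
                "allele1": _display(pair[0]) if pair[0] is not None else MISSING,
                "allele2": _display(pair[1]) if pair[1] is not None else MISSING,
                "tool": "consensus",
                "platform": platforms.get(key, "NA"),
            }
        )
    return pd.DataFrame(rows)
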