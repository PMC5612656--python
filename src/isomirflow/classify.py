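"""Hierarchical, mutually exclusive isomiR classification of small-RNA reads.

Each read is compared against the mature miRNA references (collapsed into
sequence-identical families) and the precursor hairpins, and assigned to
exactly one of four categories by strict precedence:

* C1 (identical): the read equals a mature sequence exactly.
* C2 (shorter): the read is an exact substring of a mature with 1-5 total
  bases trimmed off the ends (split over either or both ends).
* C3 (variant), with subtype precedence end_substitution > end_addition >
  internal_mismatch:
    - end_substitution: same length as the mature, exactly one differing
      base located at the first or last position;
    - end_addition: the mature is an exact substring of the read with 1-2
      total non-templated extra bases over the ends;
    - internal_mismatch: same length, exactly one differing base at a
      non-terminal position.
* C4 (precursor): the read is an exact substring of a precursor hairpin and
  matched no family under C1-C3.

Within the winning category the set of matching families is computed: a
unique family yields an assignment, more than one yields ``multi_mapped``
(discarded from counting), and no match at any category yields
``unassigned``.  N matches no base, including N, so the single allowed
difference in C3 must be a definite base differing from the reference.
Reads are classified on the sense strand only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import SequenceRecord

# category labels
C1_IDENTICAL = "C1_identical"
C2_SHORTER = "C2_shorter"
C3_VARIANT = "C3_variant"
C4_PRECURSOR = "C4_precursor"
MULTI_MAPPED = "multi_mapped"
UNASSIGNED = "unassigned"

# C3 subtypes, in precedence order
END_SUBSTITUTION = "end_substitution"
END_ADDITION = "end_addition"
INTERNAL_MISMATCH = "internal_mismatch"

CATEGORIES = (C1_IDENTICAL, C2_SHORTER, C3_VARIANT, C4_PRECURSOR)
BASES = "ACGT"


@dataclass(frozen=True)
class Family:
    """A set of mature miRNA ids sharing one identical sequence."""

    id: str
    sequence: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class IsomiRCall:
    read_id: str
    category: str
    subtype: str | None = None
    mirna_id: str | None = None
    edit_detail: str | None = None

    def __post_init__(self) -> None:
        assigned = self.category in CATEGORIES
        if assigned != (self.mirna_id is not None):
            raise ValueError("mirna_id must be present iff the read is assigned")
        if (self.category == C3_VARIANT) != (self.subtype is not None):
            raise ValueError("subtype present iff category is C3")


def collapse_families(mature_refs: Sequence[SequenceRecord]) -> list[Family]:
    """Collapse byte-identical mature sequences into families.

    The family id concatenates the member ids with '|' in input order;
    matching and uniqueness downstream operate on families, so two ids with
    the same sequence never spuriously void uniqueness.
    """
    if not mature_refs:
        raise ValueError("empty mature reference set")
    by_seq: dict[str, list[str]] = {}
    order: list[str] = []
    for rec in mature_refs:
        if rec.sequence not in by_seq:
            by_seq[rec.sequence] = []
            order.append(rec.sequence)
        by_seq[rec.sequence].append(rec.id)
    return [Family("|".join(by_seq[seq]), seq, tuple(by_seq[seq])) for seq in order]


def _mismatch_positions(a: str, b: str, limit: int = 2) -> list[int]:
    """Positions where equal-length strings differ, under 'N matches nothing'.

    Stops early once more than ``limit`` differences are found.
    """
    out: list[int] = []
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y or x == "N":
            out.append(i)
            if len(out) > limit:
                break
    return out


def _exact_substring_offsets(needle: str, haystack: str) -> list[int]:
    """All offsets where needle occurs in haystack; N never matches."""
    if "N" in needle:
        return []
    out = []
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


class ReferenceIndex:
    """Pre-grouped view of the families and precursors for classification."""

    def __init__(
        self,
        families: Sequence[Family],
        precursor_refs: Sequence[SequenceRecord] = (),
        max_short: int = 5,
        max_add: int = 2,
    ):
        if not families:
            raise ValueError("empty family set")
        self.families = list(families)
        self.precursors = list(precursor_refs)
        self.max_short = max_short
        self.max_add = max_add
        self.by_seq: dict[str, Family] = {f.sequence: f for f in families}
        self.by_len: dict[int, list[Family]] = {}
        for f in families:
            self.by_len.setdefault(len(f.sequence), []).append(f)
        # precursor id -> family id of the mature it hosts (id-matched member),
        # falling back to the precursor's own id
        member_to_family = {m: f.id for f in families for m in f.members}
        self.precursor_family: dict[str, str] = {
            p.id: member_to_family.get(p.id, p.id) for p in self.precursors
        }


def build_index(
    mature_refs: Sequence[SequenceRecord],
    precursor_refs: Sequence[SequenceRecord] = (),
    max_short: int = 5,
    max_add: int = 2,
) -> ReferenceIndex:
    return ReferenceIndex(collapse_families(mature_refs), precursor_refs,
                          max_short, max_add)


def _resolve(read_id: str, category: str, subtype: str | None,
             hits: Mapping[str, str]) -> IsomiRCall:
    """Apply the uniqueness rule to the matching families of the winning category."""
    if len(hits) == 1:
        (fam_id, detail), = hits.items()
        return IsomiRCall(read_id, category, subtype, fam_id, detail)
    return IsomiRCall(read_id, MULTI_MAPPED)


def classify_read(
    seq: str,
    index: ReferenceIndex,
    read_id: str = "",
) -> IsomiRCall:
    """Classify one read sequence by the category precedence described above."""
    L = len(seq)

    # C1: exact identity (hash lookup; a read with N can never be identical)
    if "N" not in seq:
        fam = index.by_seq.get(seq)
        if fam is not None:
            return IsomiRCall(read_id, C1_IDENTICAL, None, fam.id, "exact")

    # C2: exact substring of a mature, 1..max_short bases short
    hits: dict[str, str] = {}
    for fam in index.families:
        short = len(fam.sequence) - L
        if 1 <= short <= index.max_short:
            offs = _exact_substring_offsets(seq, fam.sequence)
            if offs:
                t5 = offs[0]
                t3 = len(fam.sequence) - L - t5
                hits[fam.id] = f"trim5={t5},trim3={t3}"
    if hits:
        return _resolve(read_id, C2_SHORTER, None, hits)

    # C3 end_substitution: same length, one definite-base difference at an end
    hits = {}
    for fam in index.by_len.get(L, ()):
        mm = _mismatch_positions(seq, fam.sequence, limit=1)
        if len(mm) == 1 and mm[0] in (0, L - 1) and seq[mm[0]] in BASES:
            p = mm[0]
            hits[fam.id] = f"pos={p},ref={fam.sequence[p]},alt={seq[p]}"
    if hits:
        return _resolve(read_id, C3_VARIANT, END_SUBSTITUTION, hits)

    # C3 end_addition: mature is an exact substring, 1..max_add extra bases
    hits = {}
    for fam in index.families:
        extra = L - len(fam.sequence)
        if 1 <= extra <= index.max_add and "N" not in fam.sequence:
            offs = _exact_substring_offsets(fam.sequence, seq)
            if offs:
                a5 = offs[0]
                a3 = L - len(fam.sequence) - a5
                # added bases must be definite (N matches nothing)
                added = seq[:a5] + seq[a5 + len(fam.sequence):]
                if all(b in BASES for b in added):
                    hits[fam.id] = f"add5={a5},add3={a3}"
    if hits:
        return _resolve(read_id, C3_VARIANT, END_ADDITION, hits)

    # C3 internal_mismatch: same length, one definite-base difference inside
    hits = {}
    for fam in index.by_len.get(L, ()):
        mm = _mismatch_positions(seq, fam.sequence, limit=1)
        if len(mm) == 1 and 0 < mm[0] < L - 1 and seq[mm[0]] in BASES:
            p = mm[0]
            hits[fam.id] = f"pos={p},ref={fam.sequence[p]},alt={seq[p]}"
    if hits:
        return _resolve(read_id, C3_VARIANT, INTERNAL_MISMATCH, hits)

    # C4: exact substring of a precursor, reached only if no family matched
    hits = {}
    for pre in index.precursors:
        offs = _exact_substring_offsets(seq, pre.sequence)
        if offs:
            fam_id = index.precursor_family[pre.id]
            hits.setdefault(fam_id, f"precursor={pre.id},offset={offs[0]}")
    if hits:
        return _resolve(read_id, C4_PRECURSOR, None, hits)

    return IsomiRCall(read_id, UNASSIGNED)


# ---------------------------------------------------------------------------
# brute-force oracle


class BruteForceIndex:
    """Exhaustive enumeration oracle for :func:`classify_read`.

    For every family, every legal edit under each category is enumerated
    (all trims up to ``max_short``, all single end/internal substitutions
    over A/C/G/T, all 1-2 base additions with all base combinations) and the
    resulting strings are stored in per-stage dictionaries.  Classification
    is then dictionary lookup, with the same precedence and uniqueness rules
    as the direct implementation.  Intended for miRNA-scale references only.
    """

    def __init__(self, index: ReferenceIndex):
        self.index = index
        ms, ma = index.max_short, index.max_add
        # stage -> variant string -> {family id -> edit detail}
        self.stages: list[tuple[str, str | None, dict[str, dict[str, str]]]] = [
            (C1_IDENTICAL, None, {}),
            (C2_SHORTER, None, {}),
            (C3_VARIANT, END_SUBSTITUTION, {}),
            (C3_VARIANT, END_ADDITION, {}),
            (C3_VARIANT, INTERNAL_MISMATCH, {}),
        ]
        ident, shorter, endsub, endadd, internal = (s[2] for s in self.stages)
        for fam in index.families:
            m = fam.sequence
            L = len(m)
            # variants still containing N can never equal a read: N matches
            # nothing, and reads holding N are unassigned by definition.
            if "N" not in m:
                ident.setdefault(m, {})[fam.id] = "exact"
            for total in range(1, ms + 1):
                for t5 in range(0, total + 1):
                    t3 = total - t5
                    if L - total >= 1:
                        var = m[t5:L - t3]
                        if "N" not in var:
                            shorter.setdefault(var, {}).setdefault(
                                fam.id, f"trim5={t5},trim3={t3}")
            for p in (0, L - 1):
                for b in BASES:
                    if b != m[p]:
                        var = m[:p] + b + m[p + 1:]
                        if "N" not in var:
                            endsub.setdefault(var, {}).setdefault(
                                fam.id, f"pos={p},ref={m[p]},alt={b}")
            if "N" not in m:
                for total in range(1, ma + 1):
                    for a5 in range(0, total + 1):
                        a3 = total - a5
                        for combo in _base_combos(total):
                            var = combo[:a5] + m + combo[a5:]
                            endadd.setdefault(var, {}).setdefault(
                                fam.id, f"add5={a5},add3={a3}")
            for p in range(1, L - 1):
                for b in BASES:
                    if b != m[p]:
                        var = m[:p] + b + m[p + 1:]
                        if "N" not in var:
                            internal.setdefault(var, {}).setdefault(
                                fam.id, f"pos={p},ref={m[p]},alt={b}")


def _base_combos(n: int) -> list[str]:
    combos = [""]
    for _ in range(n):
        combos = [c + b for c in combos for b in BASES]
    return combos


def classify_read_bruteforce(
    seq: str,
    oracle: BruteForceIndex,
    read_id: str = "",
) -> IsomiRCall:
    """Oracle classification by exhaustive enumeration; same contract as
    :func:`classify_read`."""
    if "N" not in seq:
        for category, subtype, table in oracle.stages:
            hits = table.get(seq)
            if hits:
                return _resolve(read_id, category, subtype, hits)
        hits = {}
        for pre in oracle.index.precursors:
            for off in range(0, len(pre.sequence) - len(seq) + 1):
                if pre.sequence[off:off + len(seq)] == seq:
                    fam_id = oracle.index.precursor_family[pre.id]
                    hits.setdefault(fam_id, f"precursor={pre.id},offset={off}")
                    break
        if hits:
            return _resolve(read_id, C4_PRECURSOR, None, hits)
    return IsomiRCall(read_id, UNASSIGNED)


# ---------------------------------------------------------------------------
# counting


@dataclass
class MiRNACountTable:
    """Per-family category counts with merged totals, plus run-level tallies."""

    table: pd.DataFrame  # index = family, per-category columns + 'merged'
    n_multi_mapped: int = 0
    n_unassigned: int = 0

    COLUMNS = (
        C1_IDENTICAL,
        C2_SHORTER,
        f"{C3_VARIANT}.{END_SUBSTITUTION}",
        f"{C3_VARIANT}.{END_ADDITION}",
        f"{C3_VARIANT}.{INTERNAL_MISMATCH}",
        C4_PRECURSOR,
    )

    @property
    def merged(self) -> pd.Series:
        return self.table["merged"]

    def total_reads(self) -> int:
        return int(self.table["merged"].sum()) + self.n_multi_mapped + self.n_unassigned


def count_mirnas(calls: Iterable[IsomiRCall]) -> MiRNACountTable:
    """Tally calls into per-family category counts and merged totals.

    Identical reads and all isomiR forms of a family are merged into one
    count; multi-mapped and unassigned reads are tallied separately and never
    attributed to any family.
    """
    rows: dict[str, dict[str, int]] = {}
    n_multi = 0
    n_unassigned = 0
    for call in calls:
        if call.category == MULTI_MAPPED:
            n_multi += 1
        elif call.category == UNASSIGNED:
            n_unassigned += 1
        else:
            col = (f"{call.category}.{call.subtype}"
                   if call.subtype else call.category)
            row = rows.setdefault(call.mirna_id,
                                  dict.fromkeys(MiRNACountTable.COLUMNS, 0))
            row[col] += 1
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=list(MiRNACountTable.COLUMNS)).fillna(0)
    df = df.astype("int64")
    df["merged"] = df.sum(axis=1)
    df.index.name = "family"
    return MiRNACountTable(df.sort_index(), n_multi, n_unassigned)


def calls_to_frame(calls: Iterable[IsomiRCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.read_id, c.category, c.subtype or "", c.mirna_id or "",
          c.edit_detail or "") for c in calls],
        columns=["read_id", "category", "subtype", "mirna_family", "edit_detail"],
    )
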