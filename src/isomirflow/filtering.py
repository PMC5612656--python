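"""Read-level QC and contaminant screening preceding miRNA classification.

Reads are first filtered on length (16-35 nt inclusive) and mean Phred
quality (>= 30, arithmetic mean of the raw integer scores), then screened
against coding-exon and other-small-RNA references by exact substring match
on either strand.  Rules are applied in a fixed order
(length -> quality -> coding exon -> other small RNA) so that every read has
exactly one removal reason and the report is additive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import SequenceRecord, SmallRead, reverse_complement

logger = logging.getLogger(__name__)

# reasons recorded for removed reads
REASON_LENGTH = "length"
REASON_QUALITY = "quality"
REASON_CODING_EXON = "coding_exon"
REASON_OTHER_SMALLRNA = "other_smallrna"


@dataclass
class FilterReport:
    """Additive tally of the QC decisions: each read is counted exactly once."""

    n_input: int = 0
    n_kept: int = 0
    n_len_fail: int = 0
    n_qual_fail: int = 0
    n_contaminant: int = 0
    n_coding_exon: int = 0

    def check(self) -> None:
        total = (self.n_kept + self.n_len_fail + self.n_qual_fail
                 + self.n_contaminant + self.n_coding_exon)
        if total != self.n_input:
            raise AssertionError("filter report does not partition the input")


def filter_reads(
    reads: Iterable[SmallRead],
    min_len: int = 16,
    max_len: int = 35,
    min_avg_phred: float = 30.0,
) -> tuple[list[SmallRead], FilterReport]:
    """Keep reads with length in [min_len, max_len] and mean Phred >= threshold.

    Bounds are inclusive on both criteria; a read failing both is counted as a
    length failure (length is checked first).
    """
    kept: list[SmallRead] = []
    report = FilterReport()
    for read in reads:
        report.n_input += 1
        if not (min_len <= len(read) <= max_len):
            report.n_len_fail += 1
        elif read.mean_phred < min_avg_phred:
            report.n_qual_fail += 1
        else:
            kept.append(read)
            report.n_kept += 1
    return kept, report


class _SubstringScreen:
    """Exact-substring membership against a set of reference sequences.

    References are concatenated with a separator that cannot occur in a read,
    so Python's C-level substring search does the scanning.  A read containing
    N can never match: N is defined to match nothing, and reference windows
    equal to the read would have to contain the same N.
    """

    def __init__(self, refs: Sequence[SequenceRecord]):
        self.blob = "#" + "#".join(r.sequence for r in refs) + "#" if refs else ""

    def contains(self, seq: str) -> bool:
        if not self.blob or "N" in seq:
            return False
        return seq in self.blob or reverse_complement(seq) in self.blob


def screen_contaminants(
    reads: Iterable[SmallRead],
    coding_exon_refs: Sequence[SequenceRecord],
    other_smallrna_refs: Sequence[SequenceRecord],
) -> tuple[list[SmallRead], list[tuple[SmallRead, str]]]:
    """Remove reads that match a screening reference on either strand.

    A read is removed iff it or its reverse complement is an exact substring
    of any reference; coding exons are checked before other small RNAs so the
    recorded reason is unambiguous.  With no references at all a warning is
    logged and every read passes.
    """
    if not coding_exon_refs and not other_smallrna_refs:
        logger.warning("no screening references supplied; all reads pass")
        return list(reads), []
    exon_screen = _SubstringScreen(coding_exon_refs)
    smallrna_screen = _SubstringScreen(other_smallrna_refs)
    passed: list[SmallRead] = []
    removed: list[tuple[SmallRead, str]] = []
    for read in reads:
        if exon_screen.contains(read.sequence):
            removed.append((read, REASON_CODING_EXON))
        elif smallrna_screen.contains(read.sequence):
            removed.append((read, REASON_OTHER_SMALLRNA))
        else:
            passed.append(read)
    return passed, removed


def run_read_qc(
    reads: Sequence[SmallRead],
    coding_exon_refs: Sequence[SequenceRecord] = (),
    other_smallrna_refs: Sequence[SequenceRecord] = (),
    min_len: int = 16,
    max_len: int = 35,
    min_avg_phred: float = 30.0,
) -> tuple[list[SmallRead], FilterReport]:
    """Length/quality filtering followed by contaminant screening."""
    kept, report = filter_reads(reads, min_len, max_len, min_avg_phred)
    passed, removed = screen_contaminants(kept, coding_exon_refs, other_smallrna_refs)
    for _, reason in removed:
        if reason == REASON_CODING_EXON:
            report.n_coding_exon += 1
        else:
            report.n_contaminant += 1
        report.n_kept -= 1
    report.check()
    return passed, report
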