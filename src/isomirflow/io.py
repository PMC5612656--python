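"""Readers and writers for the on-disk formats the pipeline touches.

All sequences are normalised to the DNA alphabet on ingest: upper-cased and
with U converted to T, so that miRBase-style RNA references and DNA
sequencing reads live in a single alphabet.  FASTQ qualities are Sanger
(Phred+33); no encoding autodetection is attempted.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence (mature miRNA, precursor hairpin, screening reference)."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SmallRead:
    """One small-RNA sequencing read with per-base Phred scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: {len(self.qualities)} quality values for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_phred(self) -> float:
        return sum(self.qualities) / len(self.qualities)


def _normalise_sequence(seq: str, record_id: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise FormatError(
            f"record {record_id}: illegal sequence characters {sorted(bad)!r}"
        )
    if not seq:
        raise FormatError(f"record {record_id}: empty sequence")
    return seq


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Multi-line sequences are concatenated, order is preserved, and the
    sequence is normalised to upper-case DNA (U becomes T).  An empty file,
    text before the first header, or characters outside {A,C,G,T,U,N} raise
    :class:`FormatError` naming the offending record.
    """
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        # SimpleFastaParser silently skips leading text; reject it instead
        pos = fh.tell()
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: sequence data before the first '>' header")
                break
        fh.seek(pos)
        try:
            for title, seq in SimpleFastaParser(fh):
                parts = title.split(None, 1)
                rec_id = parts[0] if parts else ""
                if not rec_id:
                    raise FormatError(f"{path}: FASTA header with empty id")
                desc = parts[1] if len(parts) > 1 else ""
                records.append(
                    SequenceRecord(rec_id, _normalise_sequence(seq, rec_id), desc)
                )
        except ValueError as exc:  # SimpleFastaParser: text before first '>'
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            fh.write(rec.sequence + "\n")


def read_fastq(path) -> list[SmallRead]:
    """Read a 4-line-record FASTQ file with Sanger (offset 33) qualities.

    Raises :class:`FormatError` with the read id on a sequence/quality length
    mismatch and on truncated records.  The parser is deliberately strict:
    multi-line FASTQ is not supported.
    """
    reads: list[SmallRead] = []
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FormatError(f"{path}: expected '@' header, got {header[:30]!r}")
            read_id = header[1:].split()[0] if len(header) > 1 else ""
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FormatError(f"{path}: truncated record for read {read_id}")
            if not plus.startswith("+"):
                raise FormatError(f"read {read_id}: malformed separator line {plus[:30]!r}")
            if len(seq) != len(qual):
                raise FormatError(
                    f"read {read_id}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            phred = tuple(ord(c) - 33 for c in qual)
            if any(q < 0 or q > 93 for q in phred):
                raise FormatError(f"read {read_id}: quality character out of Sanger range")
            reads.append(SmallRead(read_id, _normalise_sequence(seq, read_id), phred))
    return reads


def write_fastq(reads: Iterable[SmallRead], path) -> None:
    with open(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


@dataclass
class CountMatrix:
    """A features x samples matrix of non-negative integer counts.

    ``counts`` is a pandas DataFrame (rows = features, columns = samples);
    ``groups`` maps every sample to its group label and is index-aligned to
    the columns.
    """

    counts: pd.DataFrame
    groups: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        if self.groups is None:
            self.groups = pd.Series("all", index=self.counts.columns)
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        self.groups = self.groups.reindex(self.counts.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_features(self, keep) -> "CountMatrix":
        return CountMatrix(self.counts.loc[keep].copy(), self.groups.copy())

    def subset_samples(self, keep) -> "CountMatrix":
        return CountMatrix(self.counts[list(keep)].copy(),
                           self.groups.loc[list(keep)].copy())


def read_count_matrix(path, group_map: Mapping[str, str] | None = None) -> CountMatrix:
    """Read a TSV count matrix (first column feature id, header row of samples).

    Every cell must parse as an integer; a non-integer cell raises
    :class:`FormatError` with its (feature, sample) coordinates.  If a
    ``group_map`` is given, every sample must appear in it.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = None
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            out[col] = df[col].astype("int64")
        except (ValueError, TypeError):
            for feat, val in df[col].items():
                try:
                    int(val)
                except (ValueError, TypeError):
                    raise FormatError(
                        f"{path}: non-integer cell {val!r} at "
                        f"(feature {feat!r}, sample {col!r})"
                    ) from None
            raise
    groups = None
    if group_map is not None:
        missing = [s for s in out.columns if s not in group_map]
        if missing:
            raise FormatError(f"{path}: samples missing from group map: {missing}")
        groups = pd.Series({s: group_map[s] for s in out.columns})
    return CountMatrix(out, groups)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="feature_id")
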