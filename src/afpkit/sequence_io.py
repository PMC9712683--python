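"""Read, validate and label protein sequences for AFP/non-AFP classification.

The benchmark task is binary: antifreeze proteins (AFPs, label 1) against
non-AFPs (label 0), each side supplied as a plain multi-entry FASTA file.
This module turns those files into validated in-memory records and a labeled
dataset, and writes the tab-separated manifest used by the command line.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino-acid letters, alphabetical.
STANDARD_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_ALPHABET)

#: Ambiguity / non-standard codes that may appear in public sequence sets.
NONSTANDARD_LETTERS = frozenset("BJOUXZ")

VALIDATION_POLICIES = ("reject", "drop_nonstandard")


class SequenceValidationError(ValueError):
    """A sequence or dataset violates the module's invariants."""


@dataclass
class ProteinRecord:
    """One identified amino-acid sequence with an optional class label.

    Parameters
    ----------
    id:
        First whitespace-delimited token of the FASTA header; must be unique
        within a dataset.
    sequence:
        Residue string, uppercased. After :func:`validate_sequence` it
        contains only the 20 standard letters.
    label:
        Optional binary class: 1 = AFP, 0 = non-AFP.
    description:
        Remainder of the FASTA header, retained but unused.
    """

    id: str
    sequence: str
    label: int | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceValidationError("record id must be non-empty")
        self.sequence = self.sequence.upper()
        if self.label is not None and self.label not in (0, 1):
            raise SequenceValidationError(
                f"record {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )

    @property
    def length(self) -> int:
        """Number of residues (the n of composition encoders)."""
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """An ordered collection of labeled records with per-class counts."""

    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.label is None:
                raise SequenceValidationError(f"record {rec.id!r} has no label")
            if rec.id in seen:
                raise SequenceValidationError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    @property
    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for rec in self.records:
            counts[rec.label] = counts.get(rec.label, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def read_fasta(path: str | Path, label: int | None = None) -> list[ProteinRecord]:
    """Parse a FASTA file into records, in file order.

    Multi-line sequences are concatenated, surrounding whitespace stripped
    and residues uppercased. ``label``, when given, is applied to every
    record.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    SequenceValidationError
        On an empty sequence or a duplicate id within the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(entry.seq).split()).upper()
        if not seq:
            raise SequenceValidationError(f"record {entry.id!r}: empty sequence")
        if entry.id in seen:
            raise SequenceValidationError(f"duplicate record id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(
            ProteinRecord(id=entry.id, sequence=seq, label=label,
                          description=entry.description[len(entry.id):].strip())
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as plain multi-entry FASTA ('>'-prefixed headers)."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description=rec.description)
        for rec in records
    ]
    SeqIO.write(seq_records, str(Path(path)), "fasta")


def validate_sequence(
    record: ProteinRecord, policy: str = "drop_nonstandard"
) -> ProteinRecord:
    """Enforce the 20-letter alphabet on one record.

    Under ``reject`` any letter outside the standard alphabet raises, naming
    the offending character and its 1-based position. Under
    ``drop_nonstandard`` (the default) ambiguity codes (B/J/O/U/X/Z) are
    removed and the length recomputed; unknown non-letters still raise.
    """
    if policy not in VALIDATION_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {VALIDATION_POLICIES}")
    seq = record.sequence.upper()
    if policy == "reject":
        for pos, ch in enumerate(seq, start=1):
            if ch not in _STANDARD_SET:
                raise SequenceValidationError(
                    f"record {record.id!r}: nonstandard residue {ch!r} at position {pos}"
                )
        return replace(record, sequence=seq)
    kept = []
    for pos, ch in enumerate(seq, start=1):
        if ch in _STANDARD_SET:
            kept.append(ch)
        elif ch not in NONSTANDARD_LETTERS:
            raise SequenceValidationError(
                f"record {record.id!r}: unrecognized character {ch!r} at position {pos}"
            )
    cleaned = "".join(kept)
    if not cleaned:
        raise SequenceValidationError(
            f"record {record.id!r}: no standard residues remain after validation"
        )
    return replace(record, sequence=cleaned)


def load_dataset(
    pos_path: str | Path,
    neg_path: str | Path,
    policy: str = "drop_nonstandard",
) -> LabeledDataset:
    """Load the positive (AFP) and negative (non-AFP) FASTA files.

    Positives are labeled 1 and negatives 0; every sequence is validated
    under ``policy``. An id collision across the two files, or an empty
    file on either side, is an error.
    """
    positives = [validate_sequence(r, policy) for r in read_fasta(pos_path, label=1)]
    negatives = [validate_sequence(r, policy) for r in read_fasta(neg_path, label=0)]
    if not positives:
        raise SequenceValidationError(f"positive file {pos_path} contains no records")
    if not negatives:
        raise SequenceValidationError(f"negative file {neg_path} contains no records")
    pos_ids = {r.id for r in positives}
    collisions = pos_ids & {r.id for r in negatives}
    if collisions:
        raise SequenceValidationError(
            f"record ids present in both files: {sorted(collisions)[:5]}"
        )
    return LabeledDataset(records=positives + negatives)


def write_manifest(
    dataset: LabeledDataset,
    path: str | Path,
    sources: Mapping[int, str] | None = None,
) -> None:
    """Write a tab-separated manifest: id, label, length, source file."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "label", "length", "source"])
        for rec in dataset:
            source = sources.get(rec.label, "") if sources else ""
            writer.writerow([rec.id, rec.label, rec.length, source])


def read_manifest(path: str | Path) -> dict[str, int]:
    """Read a manifest written by :func:`write_manifest` into id → label."""
    labels: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            labels[row["id"]] = int(row["label"])
    return labels
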