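"""Protein sequence records and FASTA / metadata I/O.

A :class:`SequenceRecord` is the atom of every pipeline stage: mining,
network building, active-site extraction and featurization all consume
collections of these.  The residue alphabet is restricted to the 20
standard amino-acid one-letter codes plus ``X`` (unknown); the common
ambiguity letters (B, Z, J, U, O) are normalised to ``X`` with a warning
by default, or rejected in strict mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = STANDARD_AA + "X"
#: letters normalised to X (Asx, Glx, Xle, selenocysteine, pyrrolysine)
AMBIGUOUS = "BZJUO"


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad alphabet, duplicate ids...)."""


@dataclass
class SequenceRecord:
    """An amino-acid sequence with identifier and free-form metadata."""

    id: str
    residues: str
    description: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        self.residues = self.residues.upper()
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise SequenceError(
                f"record {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def normalise_residues(raw: str, record_id: str, strict: bool = False) -> str:
    """Uppercase *raw* and map ambiguity letters to X (or reject in strict mode)."""
    seq = raw.upper()
    ambiguous = set(seq) & set(AMBIGUOUS)
    if ambiguous:
        if strict:
            raise SequenceError(
                f"record {record_id!r}: ambiguous residues {sorted(ambiguous)} "
                "rejected in strict mode"
            )
        warnings.warn(
            f"record {record_id!r}: ambiguous residues {sorted(ambiguous)} "
            "normalised to X",
            stacklevel=2,
        )
        for letter in ambiguous:
            seq = seq.replace(letter, "X")
    return seq


def check_unique_ids(records: Iterable[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


def read_fasta(path: str | Path, strict: bool = False) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into a list of :class:`SequenceRecord`.

    Records are kept in file order; wrapped or unwrapped lines and CRLF line
    endings are handled.  Duplicate ids, empty sequences and malformed
    headers raise :class:`SequenceError` with the offending line number.
    """
    path = Path(path)
    header_lines = _header_line_numbers(path)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    with open(path) as handle:
        for i, bio in enumerate(SeqIO.parse(handle, "fasta")):
            line = header_lines[i] if i < len(header_lines) else -1
            if not bio.id:
                raise SequenceError(f"{path}:{line}: header without an id")
            if not str(bio.seq):
                raise SequenceError(
                    f"{path}:{line}: record {bio.id!r} has an empty sequence"
                )
            if bio.id in seen:
                raise SequenceError(
                    f"{path}:{line}: duplicate id {bio.id!r} "
                    f"(first seen at line {seen[bio.id]})"
                )
            seen[bio.id] = line
            residues = normalise_residues(str(bio.seq), bio.id, strict=strict)
            desc = bio.description[len(bio.id):].strip()
            records.append(SequenceRecord(id=bio.id, residues=residues, description=desc))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def _header_line_numbers(path: Path) -> list[int]:
    numbers = []
    with open(path) as handle:
        for n, line in enumerate(handle, start=1):
            if line.startswith(">"):
                numbers.append(n)
    return numbers


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (deterministic byte layout)."""
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            handle.write(header + "\n")
            for start in range(0, len(rec.residues), width):
                handle.write(rec.residues[start:start + width] + "\n")


def read_metadata(path: str | Path) -> dict[str, dict]:
    """Read a TSV keyed by sequence id into an id -> {column: value} map."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    key = table.columns[0]
    return {row[key]: row.drop(key).to_dict() for _, row in table.iterrows()}


def attach_metadata(records: list[SequenceRecord], meta: Mapping[str, dict]) -> None:
    for rec in records:
        if rec.id in meta:
            rec.metadata.update(meta[rec.id])
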