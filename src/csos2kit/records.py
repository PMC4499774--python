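"""Protein sequence records and FASTA input/output.

A :class:`ProteinRecord` is the package's single in-memory representation of
an amino-acid sequence.  Validation is strict by default: only the 20
standard one-letter codes are accepted.  ``X`` can be admitted with an
explicit permissive flag, in which case downstream mass/charge computations
skip it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside the allowed alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified protein sequence.

    Parameters
    ----------
    id:
        Record identifier (FASTA header up to first whitespace).
    sequence:
        Uppercase amino-acid sequence over the 20 standard codes.
    description:
        Free-text remainder of the FASTA header.
    allow_x:
        Permit ``X`` (unknown residue).  ``X`` positions are excluded from
        mass, charge and composition computations downstream.
    """

    id: str
    sequence: str
    description: str = ""
    allow_x: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise InvalidSequenceError(f"{self.id}: empty sequence")
        allowed = _STANDARD_SET | ({"X"} if self.allow_x else set())
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in allowed:
                raise InvalidSequenceError(
                    f"{self.id}: invalid residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def subrecord(self, start: int, end: int, *, id_suffix: str = "") -> "ProteinRecord":
        """Extract residues ``start``..``end`` (1-based inclusive) as a new record."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(
                f"range {start}-{end} outside sequence of length {len(self.sequence)}"
            )
        return ProteinRecord(
            id=self.id + id_suffix,
            sequence=self.sequence[start - 1 : end],
            description=self.description,
            allow_x=self.allow_x,
        )


def read_fasta(path, *, allow_x: bool = False) -> list[ProteinRecord]:
    """Read a (multi-record) FASTA file into :class:`ProteinRecord` objects."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=seq,
                description=rec.description[len(rec.id) :].strip(),
                allow_x=allow_x,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecords)
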