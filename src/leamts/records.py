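"""Protein records, FASTA I/O, and molecular mass.

All coordinates in this package are 1-based and ranges are inclusive on
both ends, so "residues 33 to 37" names exactly five residues.  Sequences
are restricted to the 20 standard amino-acid letters; ambiguity codes
(B, Z, X, U, O, J) and gap characters are rejected at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import molecular_weight

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    """Raised for malformed records or illegal residues."""


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence with an identifier.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header token).
    seq : str
        Amino-acid sequence over the 20 standard uppercase letters.
        Lowercase input is uppercased before validation.
    description : str
        Free-text description (may be empty).
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record has an empty identifier")
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        for i, aa in enumerate(self.seq, start=1):
            if aa not in STANDARD_AA:
                raise SequenceError(
                    f"record {self.id!r}: illegal residue {aa!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.seq):
            raise SequenceError(
                f"record {self.id!r}: position {pos} outside 1..{len(self.seq)}"
            )
        return self.seq[pos - 1]

    def segment(self, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive positions ``start..end``."""
        if start < 1 or end > len(self.seq) or start > end:
            raise SequenceError(
                f"record {self.id!r}: range {start}..{end} outside 1..{len(self.seq)}"
            )
        return self.seq[start - 1 : end]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Lowercase residues are uppercased; any character outside the 20-letter
    alphabet (including gap characters) raises :class:`SequenceError`
    naming the record and position.
    """
    records = []
    with open(path) as handle:
        parsed = list(SeqIO.parse(handle, "fasta"))
    if not parsed:
        # distinguish "empty file" from "no FASTA headers"
        text = Path(path).read_text().strip()
        if text:
            raise SequenceError(f"{path}: no FASTA records found (malformed header?)")
        return []
    for sr in parsed:
        records.append(
            ProteinRecord(id=sr.id, seq=str(sr.seq), description=sr.description)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping lines at ``width`` columns."""
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecords)


def molecular_mass(rec: ProteinRecord) -> float:
    """Average molecular mass in Da (residue masses plus one water)."""
    return float(molecular_weight(rec.seq, seq_type="protein", monoisotopic=False))
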