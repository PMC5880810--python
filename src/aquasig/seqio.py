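"""Reading and writing of protein sequences and alignments.

Sequences are plain amino-acid strings over the 20-letter alphabet plus
``X`` (unknown) and ``-`` (alignment gap), case-normalised to upper case.
FASTA and Clustal parsing is delegated to biopython; this module adds the
domain types and strict alphabet validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = AMINO_ACIDS | {"X"}
ALIGNED_ALPHABET = ALPHABET | {"-"}

_DIALECTS = {"aligned-fasta": "fasta", "clustal": "clustal"}


@dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus an amino-acid sequence (possibly gapped)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - ALIGNED_ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal residue character(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def ungapped(self) -> "ProteinRecord":
        return ProteinRecord(self.id, self.seq.replace("-", "")) if "-" in self.seq else self

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length gapped sequences."""

    records: tuple[ProteinRecord, ...]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("alignment with no rows")
        n = len(self.records[0].seq)
        for rec in self.records:
            if len(rec.seq) != n:
                raise ValidationError(
                    f"ragged alignment: row {rec.id!r} has length "
                    f"{len(rec.seq)}, expected {n}"
                )
        object.__setattr__(self, "length", n)

    def __iter__(self):
        return iter(self.records)

    def row(self, rec_id: str) -> ProteinRecord:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)


def _validate_plain(rec: ProteinRecord, path) -> ProteinRecord:
    if "-" in rec.seq:
        raise ParseError(f"{path}: record {rec.id!r} contains gap characters; "
                         "use read_alignment for aligned input")
    return rec


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    Order is preserved; sequences are upper-cased and validated against
    the amino-acid alphabet (plus ``X``).
    """
    path = Path(path)
    records = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            if not rec.id:
                raise ParseError(f"{path}: record {i + 1} has an empty header")
            try:
                records.append(_validate_plain(ProteinRecord(rec.id, str(rec.seq)), path))
            except ValidationError as exc:
                raise ParseError(f"{path}: {exc}") from exc
    except ValueError as exc:  # biopython parse failure
        raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(Path(path)), "fasta")


def read_alignment(path: str | Path, dialect: str = "aligned-fasta") -> Alignment:
    """Read an alignment in ``aligned-fasta`` or ``clustal`` dialect.

    Clustal conservation lines are ignored by the parser; gap characters
    (``.`` or ``-``) are normalised to ``-``.
    """
    if dialect not in _DIALECTS:
        raise ValidationError(f"unknown alignment dialect {dialect!r}; "
                              f"expected one of {sorted(_DIALECTS)}")
    path = Path(path)
    try:
        aln = AlignIO.read(str(path), _DIALECTS[dialect])
    except ValueError as exc:
        msg = str(exc)
        # biopython reports ragged rows as a length mismatch naming no id;
        # re-parse row lengths ourselves for a more useful message
        if "same length" in msg and dialect == "aligned-fasta":
            rows = list(SeqIO.parse(str(path), "fasta"))
            if rows:
                n = len(rows[0].seq)
                for rec in rows:
                    if len(rec.seq) != n:
                        raise ParseError(
                            f"{path}: ragged alignment at row {rec.id!r} "
                            f"(length {len(rec.seq)}, expected {n})"
                        ) from exc
        raise ParseError(f"{path}: {exc}") from exc
    try:
        records = tuple(
            ProteinRecord(rec.id, str(rec.seq).replace(".", "-")) for rec in aln
        )
        return Alignment(records)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_alignment(alignment: Alignment, path: str | Path,
                    dialect: str = "aligned-fasta") -> None:
    if dialect not in _DIALECTS:
        raise ValidationError(f"unknown alignment dialect {dialect!r}")
    from Bio.Align import MultipleSeqAlignment

    msa = MultipleSeqAlignment(
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in alignment
    )
    AlignIO.write(msa, str(Path(path)), _DIALECTS[dialect])


def alignment_from_strings(pairs: Sequence[tuple[str, str]]) -> Alignment:
    """Build an :class:`Alignment` from ``(id, gapped_seq)`` pairs."""
    return Alignment(tuple(ProteinRecord(i, s) for i, s in pairs))
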