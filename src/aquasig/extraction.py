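"""Anchoring queries to an annotated reference and extracting residues.

The query is aligned globally to the class reference (BLOSUM62,
affine gaps), each named reference coordinate is transferred through
the alignment, and the query residues at the transferred coordinates
are assembled into a :class:`ResidueExtraction` — the single input that
all downstream rule matching consumes.  Positions deleted in the query
degrade gracefully to ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AnalysisError
from .refdata import ARR_NAMES, FROGER_NAMES, ReferenceAnnotation
from .seqio import Alignment, ProteinRecord

GAP = "-"

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


def _aligner(substitution_table: str, gap_open: float, gap_extend: float
             ) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_table)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(query: ProteinRecord, reference: ProteinRecord,
                 substitution_table: str = "BLOSUM62",
                 gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND) -> Alignment:
    """Optimal global alignment of query against reference (affine gaps).

    Returns a two-row :class:`Alignment` with the reference first.  The
    first alignment of biopython's deterministic enumeration is taken,
    so repeated runs are bit-identical.
    """
    if not query.seq or not reference.seq:
        raise AnalysisError("cannot align empty sequences")
    aligner = _aligner(substitution_table, gap_open, gap_extend)
    aln = aligner.align(reference.seq.replace(GAP, ""),
                        query.seq.replace(GAP, ""))[0]
    ref_row, query_row = str(aln[0]), str(aln[1])
    return Alignment((ProteinRecord(reference.id, ref_row),
                      ProteinRecord(query.id, query_row)))


def alignment_score(a: ProteinRecord, b: ProteinRecord,
                    substitution_table: str = "BLOSUM62",
                    gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND) -> float:
    aligner = _aligner(substitution_table, gap_open, gap_extend)
    return float(aligner.score(a.seq.replace(GAP, ""), b.seq.replace(GAP, "")))


def transfer_positions(alignment: Alignment,
                       annotation: ReferenceAnnotation) -> dict[int, int | None]:
    """Map every named reference coordinate to its query coordinate.

    The alignment's first row must be the annotated reference.  A
    reference coordinate aligned against a query gap maps to ``None``.
    """
    ref_row, query_row = alignment.records[0].seq, alignment.records[1].seq
    if ref_row.replace(GAP, "") != annotation.reference.seq:
        raise AnalysisError(
            "alignment's first row does not match the annotation's reference "
            f"({alignment.records[0].id!r} vs {annotation.reference.id!r})")
    ref_pos = query_pos = 0
    full_map: dict[int, int | None] = {}
    for rc, qc in zip(ref_row, query_row):
        if rc != GAP:
            ref_pos += 1
        if qc != GAP:
            query_pos += 1
        if rc != GAP:
            full_map[ref_pos] = query_pos if qc != GAP else None
    wanted = {coord for _, coord in annotation.iter_named_positions()}
    return {c: full_map[c] for c in sorted(wanted)}


def scan_npa(record: ProteinRecord,
             variants: tuple[str, ...] = ("NPA",)) -> list[tuple[int, str]]:
    """All occurrences of the NPA motif (or relaxed variants), 1-based."""
    seq = record.seq.replace(GAP, "")
    hits = []
    for i in range(len(seq) - 2):
        tri = seq[i:i + 3]
        if tri in variants:
            hits.append((i + 1, tri))
    return hits


@dataclass(frozen=True)
class ResidueExtraction:
    """Query residues at every named signature position of the reference.

    ``positions`` maps position name -> (reference coordinate, query
    coordinate or None, residue or '-').  Grouped views expose the
    strings the rule tables are written against.
    """

    query_id: str
    class_hint: str
    positions: dict[str, tuple[int, int | None, str]]
    annotation: ReferenceAnnotation = field(repr=False)

    def residue(self, name: str) -> str:
        return self.positions[name][2]

    def _window(self, loop: str) -> str:
        n = len(self.annotation.window_coords(loop))
        return "".join(self.residue(f"loop{loop}[{i}]") for i in range(1, n + 1))

    @property
    def loopB_window(self) -> str:
        return self._window("B")

    @property
    def loopE_window(self) -> str:
        return self._window("E")

    @property
    def arr(self) -> str:
        return "".join(self.residue(f"arr.{n}") for n in ARR_NAMES)

    @property
    def froger(self) -> str:
        return "".join(self.residue(f"froger.{n}") for n in FROGER_NAMES)

    @property
    def loopD_residue(self) -> str:
        return self.residue("site.loopD_L") if "site.loopD_L" in self.positions else GAP

    @property
    def permeability_pair(self) -> tuple[str, str] | None:
        if "perm.TM2" not in self.positions:
            return None
        return self.residue("perm.TM2"), self.residue("perm.loopE")

    @property
    def gating_residues(self) -> dict[str, str]:
        return {name.removeprefix("site."): rec[2]
                for name, rec in self.positions.items()
                if name.startswith("site.")}

    def sdp_vector(self, substrate: str) -> tuple[tuple[int, str], ...]:
        coords = self.annotation.sdp.get(substrate, ())
        return tuple((c, self.residue(f"sdp.{substrate}.{c}")) for c in coords)

    def loopB_context(self, radius: int = 3) -> str:
        """Residues around the loop-B phosphosite (TIP subtype motifs)."""
        site = ("site.loopB_phospho" if "site.loopB_phospho" in self.positions
                else "site.loopB_Ser")
        if site not in self.positions:
            return ""
        coord = self.positions[site][0]
        seq = self.annotation.reference.seq
        # context is reported on the query via the coordinate map when
        # available; fall back to reference-local window
        lo, hi = max(1, coord - radius), min(len(seq), coord + radius)
        qmap = self._query_map
        out = []
        for c in range(lo, hi + 1):
            qc = qmap.get(c)
            out.append(self._query_seq[qc - 1] if qc else GAP)
        return "".join(out)

    # populated by extract_signature_residues
    _query_map: dict[int, int | None] = field(default_factory=dict, repr=False)
    _query_seq: str = field(default="", repr=False)


def extract_signature_residues(query: ProteinRecord,
                               mapping: dict[int, int | None],
                               annotation: ReferenceAnnotation,
                               full_map: dict[int, int | None] | None = None,
                               ) -> ResidueExtraction:
    """Fill every named position with the query residue (or '-' at gaps)."""
    qseq = query.seq.replace(GAP, "")
    positions: dict[str, tuple[int, int | None, str]] = {}
    for name, coord in annotation.iter_named_positions():
        qc = mapping.get(coord)
        residue = qseq[qc - 1] if qc is not None else GAP
        positions[name] = (coord, qc, residue)
    return ResidueExtraction(
        query_id=query.id, class_hint=annotation.class_label,
        positions=positions, annotation=annotation,
        _query_map=full_map if full_map is not None else dict(mapping),
        _query_seq=qseq)


def extract_for_query(query: ProteinRecord, annotation: ReferenceAnnotation
                      ) -> ResidueExtraction:
    """Convenience: align, transfer and extract in one step."""
    aln = global_align(query, annotation.reference)
    mapping = transfer_positions(aln, annotation)
    # full per-coordinate map for context windows
    ref_row, query_row = aln.records[0].seq, aln.records[1].seq
    ref_pos = query_pos = 0
    full = {}
    for rc, qc in zip(ref_row, query_row):
        if rc != GAP:
            ref_pos += 1
        if qc != GAP:
            query_pos += 1
        if rc != GAP:
            full[ref_pos] = query_pos if qc != GAP else None
    return extract_signature_residues(query, mapping, annotation, full_map=full)
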