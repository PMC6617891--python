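"""Exon/intron annotation of amplicons by projection from a reference.

The amplicon studied here spans the tail of one exon, a run of complete
exons and introns, and the head of a downstream exon.  Each query
sequence is annotated by aligning it globally to an annotated reference
copy, mapping every reference exon/intron boundary through the
alignment, and then snapping each mapped intron boundary to the nearest
position (within a small window) at which the intron starts ``GT`` and
ends ``AG`` — the canonical spliceosomal dinucleotides.  An intron whose
projected span shrinks below ``min_intron_len`` is recorded as *lost*:
its segment keeps whatever residual span the projection left (usually
zero) so that segments still tile the sequence, but it reports length 0.

Pseudogenes are diagnosed from the exonic sequence alone: a frameshift
(total exonic length differing from the reference by a non-multiple of
three) or an internal stop codon in the reference reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from Bio import Align
from Bio.Seq import Seq

from .io_core import SequenceRecord

__all__ = [
    "Segment",
    "GeneModel",
    "ReferenceModel",
    "PseudogeneReport",
    "PairwiseAlignment",
    "ProjectionError",
    "pairwise_align_global",
    "project_exon_boundaries",
    "intron_lengths",
    "detect_pseudogene",
    "exonic_sequence",
    "translate_exons",
]

DEFAULT_SNAP_WINDOW = 6
DEFAULT_MIN_INTRON_LEN = 20

# Standard DNA scoring; affine gaps.  Deterministic: the aligner's first
# reported optimum is taken, which is stable for fixed inputs and scores.
DEFAULT_MATCH = 2.0
DEFAULT_MISMATCH = -3.0
DEFAULT_GAP_OPEN = -5.0
DEFAULT_GAP_EXTEND = -2.0


class ProjectionError(ValueError):
    """Raised when a query cannot be credibly projected onto the reference."""


@dataclass(frozen=True)
class Segment:
    """One exon or intron on a sequence; 0-based half-open coordinates."""

    kind: Literal["exon", "intron"]
    index: int
    start: int
    end: int
    lost: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"segment end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Ordered exon/intron tiling of one sequence.

    ``frame_offset`` is the number of bases to skip from the start of the
    concatenated exonic sequence to reach the first complete codon (the
    codon phase anchor of the first exonic base).
    """

    seq_id: str
    segments: tuple[Segment, ...]
    frame_offset: int = 0
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0, 1 or 2")
        prev_end = None
        prev_kind = None
        for seg in self.segments:
            if prev_end is not None and seg.start != prev_end:
                raise ValueError("segments must tile with no gaps or overlaps")
            if prev_kind is not None and seg.kind == prev_kind:
                raise ValueError("exon/intron kinds must alternate")
            if seg.kind == "intron" and seg.length == 0 and not seg.lost:
                raise ValueError("zero-length intron must be flagged lost")
            prev_end = seg.end
            prev_kind = seg.kind

    @property
    def total_length(self) -> int:
        return self.segments[-1].end if self.segments else 0

    def exons(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "exon"]

    def introns(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "intron"]

    def intron(self, index: int) -> Segment:
        for s in self.segments:
            if s.kind == "intron" and s.index == index:
                return s
        raise KeyError(f"no intron {index} in model for {self.seq_id!r}")


@dataclass(frozen=True)
class ReferenceModel:
    """An annotated reference sequence trusted as the projection source."""

    record: SequenceRecord
    model: GeneModel

    def __post_init__(self) -> None:
        if self.model.total_length != len(self.record.residues):
            raise ValueError("reference model does not tile the reference sequence")
        seq = self.record.residues
        for seg in self.model.introns():
            if seg.lost or seg.length == 0:
                continue
            if seq[seg.start : seg.start + 2] != "GT" or seq[seg.end - 2 : seg.end] != "AG":
                raise ValueError(
                    f"reference intron {seg.index} is not GT..AG "
                    f"({seq[seg.start:seg.start+2]}..{seq[seg.end-2:seg.end]})"
                )


@dataclass(frozen=True)
class PseudogeneReport:
    """Frameshift / internal-stop diagnosis of one annotated sequence."""

    seq_id: str
    internal_stop: bool
    stop_positions: tuple[int, ...]
    frameshift: bool
    exonic_indels: tuple[tuple[int, int], ...]
    undetermined: bool = False

    def __post_init__(self) -> None:
        if self.internal_stop and not self.stop_positions:
            raise ValueError("internal_stop requires stop_positions")

    @property
    def is_pseudogene(self) -> bool:
        return (self.internal_stop or self.frameshift) and not self.undetermined


# ---------------------------------------------------------------------------
# pairwise global alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseAlignment:
    """Global alignment of a query against a reference.

    ``ref_to_query[p]`` is the query position aligned to reference
    position ``p``, or -1 where the reference base faces a gap.
    """

    score: float
    aligned_ref: str
    aligned_query: str
    ref_to_query: tuple[int, ...]

    @property
    def coverage(self) -> float:
        """Fraction of reference positions aligned to a query residue."""
        n = len(self.ref_to_query)
        return sum(1 for q in self.ref_to_query if q >= 0) / n if n else 0.0


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def pairwise_align_global(
    query: str,
    reference: str,
    *,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Affine-gap global alignment with a reference→query column map."""
    if not query or not reference:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    alignment = aligner.align(reference, query)[0]
    indices = alignment.indices  # shape (2, n_columns); -1 marks gaps
    ref_to_query = [-1] * len(reference)
    cols_ref: list[str] = []
    cols_query: list[str] = []
    for ref_i, query_i in zip(indices[0], indices[1]):
        cols_ref.append(reference[ref_i] if ref_i >= 0 else "-")
        cols_query.append(query[query_i] if query_i >= 0 else "-")
        if ref_i >= 0:
            ref_to_query[ref_i] = int(query_i) if query_i >= 0 else -1
    return PairwiseAlignment(
        score=float(alignment.score),
        aligned_ref="".join(cols_ref),
        aligned_query="".join(cols_query),
        ref_to_query=tuple(ref_to_query),
    )


# ---------------------------------------------------------------------------
# boundary projection
# ---------------------------------------------------------------------------

def _project_position(aln: PairwiseAlignment, ref_pos: int, query_len: int) -> int:
    """Query coordinate of the reference boundary before ``ref_pos``.

    Returns the leftmost query residue aligned at or after ``ref_pos``
    (so a reference block deleted in the query projects both of its
    flanking boundaries to the same query point).
    """
    for p in range(ref_pos, len(aln.ref_to_query)):
        q = aln.ref_to_query[p]
        if q >= 0:
            return q
    return query_len


def _snap_gt(seq: str, pos: int, lo: int, hi: int, window: int) -> tuple[int, bool]:
    """Nearest position within ±window where the intron would start 'GT'."""
    candidates = sorted(range(max(lo, pos - window), min(hi - 1, pos + window) + 1),
                        key=lambda c: (abs(c - pos), c))
    for c in candidates:
        if seq[c : c + 2] == "GT":
            return c, True
    return pos, False


def _snap_ag(seq: str, pos: int, lo: int, hi: int, window: int) -> tuple[int, bool]:
    """Nearest end position within ±window where the intron would end 'AG'."""
    candidates = sorted(range(max(lo + 2, pos - window), min(hi, pos + window) + 1),
                        key=lambda c: (abs(c - pos), c))
    for c in candidates:
        if seq[c - 2 : c] == "AG":
            return c, True
    return pos, False


def project_exon_boundaries(
    query: SequenceRecord,
    ref: ReferenceModel,
    *,
    snap_window: int = DEFAULT_SNAP_WINDOW,
    min_intron_len: int = DEFAULT_MIN_INTRON_LEN,
    min_coverage: float = 0.5,
    alignment: PairwiseAlignment | None = None,
) -> GeneModel:
    """Annotate a query by projecting the reference exon/intron boundaries.

    A pre-computed alignment of ``query.ungapped`` against the reference
    may be supplied to avoid re-aligning.
    """
    qseq = query.ungapped
    aln = alignment if alignment is not None else pairwise_align_global(
        qseq, ref.record.residues
    )
    if aln.coverage < min_coverage:
        raise ProjectionError(
            f"{query.seq_id!r}: alignment covers only "
            f"{aln.coverage:.0%} of the reference (min {min_coverage:.0%})"
        )
    qlen = len(qseq)
    warnings: list[str] = []

    # Project every intron's (start, end), snap to GT..AG, then tile.
    intron_spans: dict[int, tuple[int, int, bool]] = {}  # index -> (start, end, lost)
    prev_bound = 0
    ref_introns = ref.model.introns()
    for k, seg in enumerate(ref_introns):
        start = _project_position(aln, seg.start, qlen)
        end = _project_position(aln, seg.end, qlen)
        start = max(start, prev_bound)
        end = max(end, start)
        next_ref_start = (
            ref_introns[k + 1].start if k + 1 < len(ref_introns) else ref.model.total_length
        )
        upper = _project_position(aln, next_ref_start, qlen)
        if end - start < min_intron_len:
            # collapse to the point where the downstream exon resumes;
            # residual bases between the two projections go to the
            # upstream exon
            point = min(max(end, prev_bound), qlen)
            intron_spans[seg.index] = (point, point, True)
            prev_bound = point
            continue
        s_snap, s_ok = _snap_gt(qseq, start, prev_bound, end, snap_window)
        e_snap, e_ok = _snap_ag(qseq, end, s_snap, min(upper, qlen), snap_window)
        if not s_ok:
            warnings.append(f"intron {seg.index}: no GT within ±{snap_window} of start")
        if not e_ok:
            warnings.append(f"intron {seg.index}: no AG within ±{snap_window} of end")
        intron_spans[seg.index] = (s_snap, max(e_snap, s_snap), False)
        prev_bound = max(e_snap, s_snap)

    # tile: exon ends are the snapped starts of their following introns
    ref_segs = ref.model.segments
    tiled: list[Segment] = []
    cursor = 0
    for i, seg in enumerate(ref_segs):
        if seg.kind == "intron":
            start, end, lost = intron_spans[seg.index]
            start = max(start, cursor)
            end = max(end, start)
            tiled.append(Segment("intron", seg.index, start, end, lost=lost))
            cursor = end
        else:
            nxt = None
            for j in range(i + 1, len(ref_segs)):
                if ref_segs[j].kind == "intron":
                    nxt = intron_spans[ref_segs[j].index][0]
                    break
            end = max(nxt if nxt is not None else qlen, cursor)
            tiled.append(Segment("exon", seg.index, cursor, end))
            cursor = end
    if cursor != qlen and tiled:
        last = tiled[-1]
        tiled[-1] = Segment(last.kind, last.index, last.start, qlen, lost=last.lost)
    return GeneModel(
        seq_id=query.seq_id,
        segments=tuple(tiled),
        frame_offset=ref.model.frame_offset,
        warnings=tuple(warnings),
    )


def intron_lengths(model: GeneModel) -> dict[int, int]:
    """Intron index → length in bp; lost introns report 0."""
    return {s.index: (0 if s.lost else s.length) for s in model.introns()}


# ---------------------------------------------------------------------------
# pseudogene detection
# ---------------------------------------------------------------------------

def exonic_sequence(record: SequenceRecord, model: GeneModel) -> str:
    seq = record.ungapped
    return "".join(seq[s.start : s.end] for s in model.exons())


def translate_exons(record: SequenceRecord, model: GeneModel) -> str:
    """Translate the concatenated exons in the reference reading frame.

    IUPAC ambiguity codes translate as 'X' and never count as stops; the
    trailing partial codon is dropped.
    """
    cds = exonic_sequence(record, model)[model.frame_offset :]
    cds = cds[: len(cds) - len(cds) % 3]
    if not cds:
        return ""
    protein = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if set(codon) <= set("ACGT"):
            protein.append(str(Seq(codon).translate()))
        else:
            protein.append("X")
    return "".join(protein)


def detect_pseudogene(
    query: SequenceRecord, model: GeneModel, ref: ReferenceModel
) -> PseudogeneReport:
    """Diagnose frameshifts and internal stop codons in the exonic frame.

    The amplicon is interior to the gene, so *any* stop in the
    translation is internal.  A frameshift is declared when the total
    exonic length differs from the reference's by a non-multiple of 3.
    """
    exonic = exonic_sequence(query, model)
    ref_exonic_len = sum(s.length for s in ref.model.exons())
    deltas = tuple(
        (q.index, q.length - r.length)
        for q, r in zip(model.exons(), ref.model.exons())
        if q.length != r.length
    )
    frameshift = (len(exonic) - ref_exonic_len) % 3 != 0
    if len(exonic) < 3:
        return PseudogeneReport(
            seq_id=query.seq_id,
            internal_stop=False,
            stop_positions=(),
            frameshift=frameshift,
            exonic_indels=deltas,
            undetermined=True,
        )
    protein = translate_exons(query, model)
    stops = tuple(i for i, aa in enumerate(protein) if aa == "*")
    return PseudogeneReport(
        seq_id=query.seq_id,
        internal_stop=bool(stops),
        stop_positions=stops,
        frameshift=frameshift,
        exonic_indels=deltas,
    )
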