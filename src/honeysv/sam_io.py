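"""Alignment I/O and soft-clip tail bookkeeping.

Long reads whose best alignment truncates before the read ends leave
soft-clipped "tails" in the CIGAR.  Tails longer than a threshold are
extracted (in original read orientation), remapped independently, and
re-joined with their parent's initial alignment into a *piece-alignment*
— the evidentiary unit consumed by the tail-clustering engine.

Coordinates are 0-based half-open throughout the library; human-readable
reports convert to 1-based inclusive at the writing boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pysam

log = logging.getLogger(__name__)

CIGAR_OPS = "MIDNSHP=X"
_OP_TO_CODE = {op: i for i, op in enumerate(CIGAR_OPS)}
QUERY_CONSUMING = frozenset("MIS=X")
REF_CONSUMING = frozenset("MDN=X")

#: read names following the PacBio movie/zmw/qstart_qend convention;
#: the movie/zmw prefix identifies the sequencing well (molecule).
PACBIO_NAME_RE = re.compile(r"^(?P<mol>.+/\d+)/\d+_\d+$")

PROLOG = "prolog"
EPILOG = "epilog"
_TAIL_SUFFIXES = {"/" + PROLOG: PROLOG, "/" + EPILOG: EPILOG}

# private-namespace tags cross-referencing the other member of a piece-alignment
TAG_MEMBER_REF = "ZR"
TAG_MEMBER_POS = "ZP"  # "<0-based pos>,<strand>"
TAG_MEMBER_SIDE = "ZS"  # initial | prolog | epilog

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def molecule_id_of(read_id: str) -> str:
    """Well/molecule identifier for a read name.

    PacBio subreads are named ``movie/zmw/qstart_qend``; reads from the
    same zmw are re-reads of one molecule and must not count as
    independent SV support.  Names not matching the convention are their
    own molecule.
    """
    m = PACBIO_NAME_RE.match(read_id)
    return m.group("mol") if m else read_id


class FormatError(ValueError):
    """Malformed or inconsistent alignment input."""


class TailExtractionError(ValueError):
    """A qualifying tail exists but its sequence is unavailable."""


@dataclass
class AlignmentRecord:
    """One primary alignment line, with clip lengths in read orientation.

    ``softclip_5p``/``softclip_3p`` refer to the 5'/3' ends of the
    *original read*, i.e. they are swapped relative to CIGAR order when
    the record maps to the reverse strand.
    """

    read_id: str
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str  # '+' or '-'
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    softclip_5p: int
    softclip_3p: int
    sequence: Optional[str] = None
    molecule_id: str = ""

    def __post_init__(self) -> None:
        if not self.molecule_id:
            self.molecule_id = molecule_id_of(self.read_id)
        if self.ref_start >= self.ref_end:
            raise FormatError(
                f"{self.read_id}: ref_start {self.ref_start} >= ref_end {self.ref_end}"
            )

    @property
    def is_reverse(self) -> bool:
        return self.strand == "-"

    @property
    def has_hard_clip(self) -> bool:
        return any(op == "H" for op, _ in self.cigar)

    @property
    def aligned_read_length(self) -> int:
        """Query bases inside the alignment (excludes soft clips)."""
        return sum(n for op, n in self.cigar if op in "MI=X")

    @property
    def read_length(self) -> Optional[int]:
        if self.sequence is None:
            return None
        return len(self.sequence)

    def clip_in_cigar_order(self) -> tuple[int, int]:
        """(leading, trailing) soft-clip lengths in reference/CIGAR order."""
        if self.is_reverse:
            return self.softclip_3p, self.softclip_5p
        return self.softclip_5p, self.softclip_3p


@dataclass
class Tail:
    """A soft-clipped read end extracted for independent remapping."""

    parent_read_id: str
    side: str  # prolog | epilog
    length: int
    sequence: str
    parent_break: int  # reference position where the parent mapping stopped

    @property
    def remap_name(self) -> str:
        """Join key used when the tail is written out and remapped."""
        return f"{self.parent_read_id}/{self.side}"


@dataclass
class PieceAlignment:
    """A read's initial alignment plus at most one chosen tail alignment."""

    read_id: str
    molecule_id: str
    initial: AlignmentRecord
    tail_aln: Optional[AlignmentRecord] = None
    tail_side: Optional[str] = None

    @property
    def orientation_signature(self) -> Optional[tuple[str, str, str]]:
        if self.tail_aln is None:
            return None
        return (self.initial.strand, self.tail_aln.strand, self.tail_side)

    @property
    def component_mapqs(self) -> list[int]:
        out = [self.initial.mapq]
        if self.tail_aln is not None:
            out.append(self.tail_aln.mapq)
        return out


def _clips_from_cigar(cigar: Sequence[tuple[str, int]]) -> tuple[int, int, int, int]:
    """(lead_S, lead_H, trail_S, trail_H) in CIGAR order."""
    lead_s = lead_h = trail_s = trail_h = 0
    i = 0
    while i < len(cigar) and cigar[i][0] in "SH":
        if cigar[i][0] == "S":
            lead_s += cigar[i][1]
        else:
            lead_h += cigar[i][1]
        i += 1
    j = len(cigar) - 1
    while j >= i and cigar[j][0] in "SH":
        if cigar[j][0] == "S":
            trail_s += cigar[j][1]
        else:
            trail_h += cigar[j][1]
        j -= 1
    return lead_s, lead_h, trail_s, trail_h


def record_from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = tuple((CIGAR_OPS[op], ln) for op, ln in seg.cigartuples)
    lead_s, _, trail_s, _ = _clips_from_cigar(cigar)
    strand = "-" if seg.is_reverse else "+"
    if strand == "-":
        sc5, sc3 = trail_s, lead_s
    else:
        sc5, sc3 = lead_s, trail_s
    return AlignmentRecord(
        read_id=seg.query_name,
        ref_name=seg.reference_name,
        ref_start=seg.reference_start,
        ref_end=seg.reference_end,
        strand=strand,
        mapq=seg.mapping_quality,
        cigar=cigar,
        softclip_5p=sc5,
        softclip_3p=sc3,
        sequence=seg.query_sequence,
    )


def record_to_pysam(
    rec: AlignmentRecord, header: pysam.AlignmentHeader
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = rec.read_id
    seg.flag = 16 if rec.is_reverse else 0
    seg.reference_id = header.get_tid(rec.ref_name)
    if seg.reference_id < 0:
        raise FormatError(f"reference {rec.ref_name!r} absent from header")
    seg.reference_start = rec.ref_start
    seg.mapping_quality = min(rec.mapq, 254)
    seg.query_sequence = rec.sequence
    seg.cigartuples = [(_OP_TO_CODE[op], ln) for op, ln in rec.cigar]
    return seg


def make_header(
    ref_lengths: Mapping[str, int], sort_order: str = "unsorted"
) -> pysam.AlignmentHeader:
    from honeysv import __version__

    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": sort_order},
            "SQ": [{"SN": name, "LN": int(ln)} for name, ln in ref_lengths.items()],
            "PG": [{"ID": "honey", "PN": "honey", "VN": __version__}],
        }
    )


def read_alignments(
    path: str | Path, region: Optional[str] = None
) -> Iterator[AlignmentRecord]:
    """Yield one :class:`AlignmentRecord` per primary mapped alignment.

    Unmapped, secondary, and supplementary records are skipped.  For an
    indexed BAM, ``region`` uses the index; for a text SAM the stream is
    filtered.
    """
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    with af:
        if af.header.nreferences == 0:
            raise FormatError(f"{path}: no @SQ lines in header")
        if region is not None:
            contig = region.split(":")[0]
            if contig not in af.references:
                raise KeyError(f"region contig {contig!r} not in header of {path}")
            try:
                it: Iterable[pysam.AlignedSegment] = af.fetch(region=region)
            except ValueError:
                it = (s for s in af if s.reference_name == contig)
        else:
            it = af
        for seg in it:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            yield record_from_pysam(seg)


def extract_tails(rec: AlignmentRecord, min_tail_length: int = 200) -> list[Tail]:
    """Extract soft-clipped tails strictly longer than ``min_tail_length``.

    The tail sequence is returned in original read orientation (the
    orientation in which it would be written to FASTA for remapping).
    ``parent_break`` is the reference coordinate at which the parent's
    mapping was interrupted on that side.
    """
    lead_s, lead_h, trail_s, trail_h = _clips_from_cigar(rec.cigar)
    if rec.is_reverse:
        sides = ((PROLOG, trail_s, trail_h), (EPILOG, lead_s, lead_h))
    else:
        sides = ((PROLOG, lead_s, lead_h), (EPILOG, trail_s, trail_h))
    tails: list[Tail] = []
    for side, soft, hard in sides:
        if soft + hard <= min_tail_length:
            continue
        if hard > 0:
            raise TailExtractionError(
                f"{rec.read_id}: {side} tail bases are hard-clipped; "
                "sequence unavailable for extraction"
            )
        if rec.sequence is None:
            raise TailExtractionError(
                f"{rec.read_id}: record carries no sequence; cannot extract {side} tail"
            )
        if rec.strand == "+":
            seq = rec.sequence[:soft] if side == PROLOG else rec.sequence[-soft:]
            pbreak = rec.ref_start if side == PROLOG else rec.ref_end
        else:
            # stored SEQ is the reverse complement of the original read
            seq = (
                revcomp(rec.sequence[-soft:])
                if side == PROLOG
                else revcomp(rec.sequence[:soft])
            )
            pbreak = rec.ref_end if side == PROLOG else rec.ref_start
        tails.append(Tail(rec.read_id, side, soft, seq, pbreak))
    return tails


def split_tail_name(read_id: str) -> Optional[tuple[str, str]]:
    """(parent_read_id, side) for a remapped-tail name, else None."""
    for suffix, side in _TAIL_SUFFIXES.items():
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)], side
    return None


def assemble_piece_alignments(
    initials: Iterable[AlignmentRecord],
    tail_alns: Iterable[AlignmentRecord] = (),
) -> list[PieceAlignment]:
    """Join initial alignments with their remapped tails.

    A read producing both a mapped prolog and epilog keeps only the
    higher-mapq tail; an exact tie keeps the prolog (5' side).  Tail
    alignments whose parent is absent are dropped with a logged count.
    """
    by_parent: dict[str, dict[str, AlignmentRecord]] = {}
    orphan_names: list[str] = []
    for rec in tail_alns:
        parsed = split_tail_name(rec.read_id)
        if parsed is None:
            orphan_names.append(rec.read_id)
            continue
        parent, side = parsed
        slot = by_parent.setdefault(parent, {})
        # multiple alignments for one tail: keep the better-mapped one
        if side not in slot or rec.mapq > slot[side].mapq:
            slot[side] = rec

    pieces: list[PieceAlignment] = []
    seen = set()
    for rec in initials:
        seen.add(rec.read_id)
        slot = by_parent.get(rec.read_id, {})
        tail_rec: Optional[AlignmentRecord] = None
        tail_side: Optional[str] = None
        if PROLOG in slot and EPILOG in slot:
            if slot[EPILOG].mapq > slot[PROLOG].mapq:
                tail_rec, tail_side = slot[EPILOG], EPILOG
            else:  # tie keeps the 5' side
                tail_rec, tail_side = slot[PROLOG], PROLOG
        elif PROLOG in slot:
            tail_rec, tail_side = slot[PROLOG], PROLOG
        elif EPILOG in slot:
            tail_rec, tail_side = slot[EPILOG], EPILOG
        pieces.append(
            PieceAlignment(
                read_id=rec.read_id,
                molecule_id=rec.molecule_id,
                initial=rec,
                tail_aln=tail_rec,
                tail_side=tail_side,
            )
        )
    n_orphans = len(orphan_names) + sum(
        1 for p in by_parent if p not in seen
    )
    if n_orphans:
        log.warning("dropped %d tail alignments with no matching parent", n_orphans)
    return pieces


def write_tail_fasta(tails: Iterable[Tail], path: str | Path) -> int:
    """Write tails as FASTA for external remapping; returns count."""
    n = 0
    with open(path, "w") as fh:
        for tail in tails:
            fh.write(f">{tail.remap_name}\n{tail.sequence}\n")
            n += 1
    return n


def write_tagged_alignments(
    pieces: Iterable[PieceAlignment],
    path: str | Path,
    ref_lengths: Mapping[str, int],
) -> None:
    """Write piece-alignments as a SAM with cross-member tags.

    Each component record carries, for every other member of the same
    piece-alignment, its reference (ZR), position+strand (ZP), and side
    (ZS).  Tail records keep their ``<parent>/<side>`` names so the file
    round-trips through :func:`read_tagged_alignments`.
    """
    header = make_header(ref_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for piece in pieces:
            members: list[tuple[AlignmentRecord, str]] = [(piece.initial, "initial")]
            if piece.tail_aln is not None:
                members.append((piece.tail_aln, piece.tail_side))
            for idx, (rec, _side) in enumerate(members):
                seg = record_to_pysam(rec, header)
                for jdx, (other, other_side) in enumerate(members):
                    if jdx == idx:
                        continue
                    seg.set_tag(TAG_MEMBER_REF, other.ref_name)
                    seg.set_tag(TAG_MEMBER_POS, f"{other.ref_start},{other.strand}")
                    seg.set_tag(TAG_MEMBER_SIDE, other_side)
                out.write(seg)


def read_tagged_alignments(path: str | Path) -> list[PieceAlignment]:
    """Reassemble piece-alignments from a tagged SAM written by this module."""
    initials: list[AlignmentRecord] = []
    tails: list[AlignmentRecord] = []
    for rec in read_alignments(path):
        if split_tail_name(rec.read_id) is not None:
            tails.append(rec)
        else:
            initials.append(rec)
    return assemble_piece_alignments(initials, tails)
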