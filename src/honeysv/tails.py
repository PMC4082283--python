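"""Clustering and annotation of interrupted-mapping (tail) evidence.

Each piece-alignment with a mapped tail implies a pair of breakpoints:
``pos_a``, where the initial alignment was interrupted, and ``pos_b``,
the proximal end of the tail's alignment.  Pieces whose breakpoints lie
within a buffer of each other *and* share the same internal orientation
(initial strand, tail strand, tail side) support the same event and are
clustered; the cluster is annotated as a deletion, insertion, inversion,
or translocation from its orientation and geometry, with breakpoints
predicted as the average interrupted position over members.

Orientation/geometry table (same reference):

====================  ==========================  ============
strands               tail proximal end vs.        annotation
                      interruption, in read order
====================  ==========================  ============
equal                 beyond (gap skipped)         deletion
equal                 at or before (pushed back)   insertion
opposite              any                          inversion
(different refs)      any                          translocation
====================  ==========================  ============
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from honeysv.sam_io import EPILOG, PieceAlignment

log = logging.getLogger(__name__)

DELETION = "deletion"
INSERTION = "insertion"
INVERSION = "inversion"
TRANSLOCATION = "translocation"

#: default maximum breakpoint distance for co-clustering (bp)
DEFAULT_BUFFER = 200
DEFAULT_MIN_READS = 3
DEFAULT_MIN_AVG_MAPQ = 100.0
DEFAULT_MIN_MOLECULES = 2

REPORT_COLUMNS = (
    "ref_a",
    "bp_a",
    "ref_b",
    "bp_b",
    "sv_type",
    "n_reads",
    "n_molecules",
    "avg_mapq",
    "size_estimate",
)


def round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class BreakpointPair:
    """Breakpoints implied by one piece-alignment with a tail.

    Raw frame: ``(ref_a, pos_a)`` is always the initial alignment's
    interruption, ``(ref_b, pos_b)`` the tail's proximal endpoint.
    :meth:`normalized` gives the canonical coordinate ordering with a
    flag recording whether the ends were swapped.
    """

    ref_a: str
    pos_a: int
    strand_a: str
    ref_b: str
    pos_b: int
    strand_b: str
    tail_side: str

    @property
    def signature(self) -> tuple[str, str, str]:
        return (self.strand_a, self.strand_b, self.tail_side)

    def normalized(self) -> tuple[str, int, str, int, bool]:
        """(ref_lo, pos_lo, ref_hi, pos_hi, swapped)."""
        if (self.ref_b, self.pos_b) < (self.ref_a, self.pos_a):
            return self.ref_b, self.pos_b, self.ref_a, self.pos_a, True
        return self.ref_a, self.pos_a, self.ref_b, self.pos_b, False


@dataclass
class TailCluster:
    """Piece-alignments supporting one breakpoint pair and orientation."""

    members: list[PieceAlignment]
    pairs: list[BreakpointPair]

    @property
    def signature(self) -> tuple[str, str, str]:
        return self.pairs[0].signature

    @property
    def span_a(self) -> tuple[int, int]:
        ps = [p.pos_a for p in self.pairs]
        return min(ps), max(ps)

    @property
    def span_b(self) -> tuple[int, int]:
        ps = [p.pos_b for p in self.pairs]
        return min(ps), max(ps)


@dataclass
class TailCall:
    """An annotated cluster: one candidate structural variant."""

    sv_type: str
    ref_a: str
    bp_a: int
    ref_b: str
    bp_b: int
    n_reads: int
    n_molecules: int
    avg_mapq: float
    size_estimate: Optional[int] = None


def breakpoints_of(piece: PieceAlignment) -> BreakpointPair:
    """Breakpoint pair of a piece-alignment (requires a tail).

    ``pos_a``: reference coordinate where the initial mapping stopped on
    the tail's side.  ``pos_b``: the tail alignment's end adjacent to the
    interruption — for an epilog its 5' (read) end, for a prolog its 3'
    end, resolved through the tail's mapped strand.
    """
    if piece.tail_aln is None:
        raise ValueError(f"{piece.read_id}: piece-alignment has no tail")
    initial, tail, side = piece.initial, piece.tail_aln, piece.tail_side

    if side == EPILOG:
        pos_a = initial.ref_end if initial.strand == "+" else initial.ref_start
        # epilog's proximal end is its read-5' end
        pos_b = tail.ref_start if tail.strand == "+" else tail.ref_end
    else:
        pos_a = initial.ref_start if initial.strand == "+" else initial.ref_end
        # prolog's proximal end is its read-3' end
        pos_b = tail.ref_end if tail.strand == "+" else tail.ref_start

    return BreakpointPair(
        ref_a=initial.ref_name,
        pos_a=pos_a,
        strand_a=initial.strand,
        ref_b=tail.ref_name,
        pos_b=pos_b,
        strand_b=tail.strand,
        tail_side=side,
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_pieces(
    pieces: Sequence[PieceAlignment], buffer: int = DEFAULT_BUFFER
) -> list[TailCluster]:
    """Single-linkage clustering under the buffer + orientation predicate.

    Two pieces may share a cluster only if both breakpoint coordinates
    differ by strictly less than ``buffer`` and their orientation
    signatures are identical; clusters are the connected components of
    that pairwise relation (transitive closure), so the result is
    independent of input order.  Every piece lands in exactly one
    cluster; a single piece is a cluster.
    """
    pairs = [breakpoints_of(p) for p in pieces]
    groups: dict[tuple, list[int]] = {}
    for i, bp in enumerate(pairs):
        groups.setdefault((bp.ref_a, bp.ref_b, bp.signature), []).append(i)

    clusters: list[TailCluster] = []
    for idxs in groups.values():
        idxs.sort(key=lambda i: (pairs[i].pos_a, pairs[i].pos_b))
        uf = _UnionFind(len(idxs))
        for a in range(len(idxs)):
            pa = pairs[idxs[a]]
            for b in range(a + 1, len(idxs)):
                pb = pairs[idxs[b]]
                if pb.pos_a - pa.pos_a >= buffer:
                    break  # sorted by pos_a: no later piece can link to a
                if abs(pb.pos_b - pa.pos_b) < buffer:
                    uf.union(a, b)
        comp: dict[int, list[int]] = {}
        for a in range(len(idxs)):
            comp.setdefault(uf.find(a), []).append(idxs[a])
        for member_idxs in comp.values():
            clusters.append(
                TailCluster(
                    members=[pieces[i] for i in member_idxs],
                    pairs=[pairs[i] for i in member_idxs],
                )
            )
    clusters.sort(
        key=lambda c: (c.pairs[0].ref_a, c.span_a[0], c.pairs[0].ref_b, c.span_b[0])
    )
    return clusters


def _classify(signature: tuple[str, str, str], ref_same: bool, pos_a: float, pos_b: float) -> str:
    strand_a, strand_b, side = signature
    if not ref_same:
        return TRANSLOCATION
    if strand_a != strand_b:
        return INVERSION
    # direction the read continues past the interruption, on the reference
    direction = 1 if (side == EPILOG) == (strand_a == "+") else -1
    gap = direction * (pos_b - pos_a)
    return DELETION if gap > 0 else INSERTION


def annotate_cluster(cluster: TailCluster) -> TailCall:
    """Annotate a cluster as an SV call with averaged breakpoints.

    Breakpoints are the arithmetic means of the members' interruption
    positions (rounded half-up); the reported pair is ordered so that
    ``(ref_a, bp_a) <= (ref_b, bp_b)``.  Size is ``|bp_b - bp_a|`` for
    same-reference deletions and inversions, absent for insertions
    (tails do not measure inserted length) and translocations.
    """
    pairs = cluster.pairs
    ref_a, ref_b = pairs[0].ref_a, pairs[0].ref_b
    mean_a = sum(p.pos_a for p in pairs) / len(pairs)
    mean_b = sum(p.pos_b for p in pairs) / len(pairs)
    sv_type = _classify(cluster.signature, ref_a == ref_b, mean_a, mean_b)

    bp_a, bp_b = round_half_up(mean_a), round_half_up(mean_b)
    if (ref_b, bp_b) < (ref_a, bp_a):
        ref_a, bp_a, ref_b, bp_b = ref_b, bp_b, ref_a, bp_a

    mapqs = [q for m in cluster.members for q in m.component_mapqs]
    size: Optional[int] = None
    if sv_type in (DELETION, INVERSION) and ref_a == ref_b:
        size = abs(bp_b - bp_a)
    return TailCall(
        sv_type=sv_type,
        ref_a=ref_a,
        bp_a=bp_a,
        ref_b=ref_b,
        bp_b=bp_b,
        n_reads=len(cluster.members),
        n_molecules=len({m.molecule_id for m in cluster.members}),
        avg_mapq=sum(mapqs) / len(mapqs),
        size_estimate=size,
    )


def filter_calls(
    calls: Iterable[TailCall],
    min_reads: int = DEFAULT_MIN_READS,
    min_avg_mapq: float = DEFAULT_MIN_AVG_MAPQ,
    min_molecules: int = DEFAULT_MIN_MOLECULES,
    min_size: int = 0,
) -> list[TailCall]:
    """Support/quality filter; preserves order.

    Defaults follow the discovery setup: at least three supporting
    piece-alignments, average component mapping quality >= 100 (Phred
    scale), at least two distinct molecules (chimera guard), and no
    minimum size.  The size filter ignores calls without an estimate.
    """
    out = []
    for c in calls:
        if c.n_reads < min_reads:
            continue
        if c.avg_mapq < min_avg_mapq:
            continue
        if c.n_molecules < min_molecules:
            continue
        if c.size_estimate is not None and c.size_estimate < min_size:
            continue
        out.append(c)
    return out


def call_tails(
    pieces: Sequence[PieceAlignment],
    buffer: int = DEFAULT_BUFFER,
    min_reads: int = DEFAULT_MIN_READS,
    min_avg_mapq: float = DEFAULT_MIN_AVG_MAPQ,
    min_molecules: int = DEFAULT_MIN_MOLECULES,
    min_size: int = 0,
) -> list[TailCall]:
    """Cluster -> annotate -> filter, for pieces that carry tails."""
    tailed = [p for p in pieces if p.tail_aln is not None]
    clusters = cluster_pieces(tailed, buffer=buffer)
    calls = [annotate_cluster(c) for c in clusters]
    kept = filter_calls(
        calls,
        min_reads=min_reads,
        min_avg_mapq=min_avg_mapq,
        min_molecules=min_molecules,
        min_size=min_size,
    )
    log.info(
        "tails: %d tailed pieces -> %d clusters -> %d calls after filtering",
        len(tailed),
        len(clusters),
        len(kept),
    )
    return kept


def write_tails_report(calls: Iterable[TailCall], path: str | Path) -> None:
    """Tab-separated call report (positions 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(REPORT_COLUMNS) + "\n")
        for c in calls:
            size = "." if c.size_estimate is None else str(c.size_estimate)
            fh.write(
                f"{c.ref_a}\t{c.bp_a + 1}\t{c.ref_b}\t{c.bp_b + 1}\t{c.sv_type}\t"
                f"{c.n_reads}\t{c.n_molecules}\t{c.avg_mapq:.2f}\t{size}\n"
            )


def write_tails_bed(calls: Iterable[TailCall], path: str | Path) -> None:
    """BED (0-based half-open) of same-reference calls."""
    with open(path, "w") as fh:
        for c in calls:
            if c.ref_a != c.ref_b:
                continue
            start, end = sorted((c.bp_a, c.bp_b))
            if end == start:
                end = start + 1
            fh.write(f"{c.ref_a}\t{start}\t{end}\t{c.sv_type}\t{c.n_reads}\n")
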