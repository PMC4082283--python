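"""Synthetic long-read datasets with known structural variants.

The simulator builds a random reference, implants ground-truth SVs into
a sample haplotype, draws noisy multi-kilobase reads from the sample,
and emits each read's alignment *analytically* from the known
sample-to-reference map — no external aligner is involved, so breakpoint
geometry in the output is exact up to the injected errors.

Two regimes fall out of the sample->reference map, controlled by
``span_clip_threshold``:

* an SV small enough to be absorbed is written into the read's CIGAR
  (e.g. a mid-read ``327D``) — the "hidden variant" regime detected by
  the discordance (spots) engine;
* a larger SV interrupts the mapping at the breakpoint, producing an
  initial alignment with a soft-clipped tail plus the tail's own
  alignment across the event — the interrupted-mapping (tails) regime.

Defaults emulate a PacBio-style run: ~6.1 kb mean read length, 15%
total per-base error (2% mismatch / 10% insertion / 3% deletion),
40x coverage.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pysam

from honeysv.sam_io import (
    AlignmentRecord,
    EPILOG,
    PROLOG,
    make_header,
    record_to_pysam,
    revcomp,
)

DELETION = "deletion"
INSERTION = "insertion"
INVERSION = "inversion"
TRANSLOCATION = "translocation"
SV_TYPES = (DELETION, INSERTION, INVERSION, TRANSLOCATION)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i

#: margin required between SVs and from contig edges (bp)
EDGE_MARGIN = 1000

TRUTH_COLUMNS = ("sv_type", "ref_name", "start", "end", "size", "allele_fraction")


class SimulationError(ValueError):
    """Invalid simulator configuration or SV layout."""


@dataclass(frozen=True)
class SVTruthRecord:
    """Ground-truth SV in reference coordinates (0-based half-open)."""

    sv_type: str
    ref_name: str
    start: int
    end: int
    size: int
    allele_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise SimulationError(f"unknown sv_type {self.sv_type!r}")
        if self.size <= 0:
            raise SimulationError(f"{self.sv_type} size must be > 0")
        if self.sv_type != INSERTION and self.start >= self.end:
            raise SimulationError(f"{self.sv_type} requires start < end")
        if self.sv_type != INSERTION and self.end - self.start != self.size:
            raise SimulationError(f"{self.sv_type} size != end - start")
        if not 0.0 < self.allele_fraction <= 1.0:
            raise SimulationError("allele_fraction must be in (0, 1]")


@dataclass
class SimConfig:
    ref_length: int = 100_000
    gc: float = 0.5
    read_length_mean: float = 6100.0
    read_length_sigma: float = 0.55  # lognormal shape parameter
    read_length_n50_target: float = 8700.0  # informational only
    coverage: float = 40.0
    error_rates: tuple[float, float, float] = (0.02, 0.10, 0.03)  # mis, ins, del
    span_clip_threshold: int = 1000
    tail_min_length: int = 200
    min_read_length: int = 100
    n_contigs: int = 1
    seed: int = 42

    def __post_init__(self) -> None:
        if any(not 0.0 <= r < 1.0 for r in self.error_rates):
            raise SimulationError("error rates must each lie in [0, 1)")
        if sum(self.error_rates) >= 1.0:
            raise SimulationError("total error rate must be < 1")
        if not 0.0 < self.gc < 1.0:
            raise SimulationError("gc must lie in (0, 1)")


@dataclass
class Segment:
    """One piece of a sample contig, mapped or novel.

    ``strand`` +1 maps sample offset k to ``ref_start + k``; -1 maps it
    to ``ref_start + length - 1 - k`` (reverse complement).
    """

    length: int
    ref_name: Optional[str]  # None: novel (inserted) sequence
    ref_start: int = 0
    strand: int = 1
    novel_seq: Optional[str] = None


@dataclass
class SampleContig:
    name: str
    segments: list[Segment]
    seq: str
    seg_offsets: list[int]  # sample start of each segment

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class Haplotype:
    contigs: dict[str, SampleContig]
    weight: float


@dataclass
class Sample:
    reference: dict[str, str]
    haplotypes: list[Haplotype]
    truth: list[SVTruthRecord]


@dataclass
class SimulatedDataset:
    config: SimConfig
    reference: dict[str, str]
    sample: Sample
    reads: list[tuple[str, str]]  # (name, as-sequenced sequence)
    initial_records: list[AlignmentRecord]
    tail_records: list[AlignmentRecord]
    truth: list[SVTruthRecord]


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=n, p=p)
    return _BASES[codes].tobytes().decode("ascii")


def make_reference(config: SimConfig) -> dict[str, str]:
    """Random reference contig(s); deterministic for a fixed seed."""
    if config.ref_length < 10_000:
        raise SimulationError(
            f"ref_length must be >= 10000, got {config.ref_length}"
        )
    rng = np.random.default_rng([config.seed, 0])
    return {
        f"ref{i + 1}": _random_seq(rng, config.ref_length, config.gc)
        for i in range(config.n_contigs)
    }


def _validate_svs(
    reference: Mapping[str, str], svs: Sequence[SVTruthRecord]
) -> None:
    names = sorted(reference)
    for sv in svs:
        if sv.ref_name not in reference:
            raise SimulationError(f"SV on unknown contig {sv.ref_name!r}")
        clen = len(reference[sv.ref_name])
        hi = max(sv.end, sv.start + 1)
        if sv.start < EDGE_MARGIN or hi > clen - EDGE_MARGIN:
            raise SimulationError(
                f"{sv.sv_type} at {sv.ref_name}:{sv.start} within "
                f"{EDGE_MARGIN} bp of a contig edge"
            )
        if sv.sv_type == TRANSLOCATION:
            if len(reference) < 2:
                raise SimulationError(
                    "translocation requires at least two reference contigs"
                )
            donor = names[(names.index(sv.ref_name) + 1) % len(names)]
            if sv.end > len(reference[donor]) - EDGE_MARGIN:
                raise SimulationError(
                    f"translocation donor window exceeds contig {donor!r}"
                )
    by_contig: dict[str, list[SVTruthRecord]] = {}
    for sv in svs:
        by_contig.setdefault(sv.ref_name, []).append(sv)
    for recs in by_contig.values():
        recs.sort(key=lambda r: r.start)
        for prev, cur in zip(recs, recs[1:]):
            if cur.start < max(prev.end, prev.start + 1) + EDGE_MARGIN:
                raise SimulationError(
                    f"SVs at {prev.ref_name}:{prev.start} and {cur.start} overlap "
                    f"or sit closer than {EDGE_MARGIN} bp"
                )
    fracs = {sv.allele_fraction for sv in svs}
    if len(fracs) > 1:
        raise SimulationError(
            "all SVs must share one allele_fraction (one variant haplotype)"
        )


def _identity_contig(name: str, seq: str) -> SampleContig:
    seg = Segment(length=len(seq), ref_name=name, ref_start=0, strand=1)
    return SampleContig(name=name, segments=[seg], seq=seq, seg_offsets=[0])


def _build_contig(
    name: str,
    ref: Mapping[str, str],
    svs: Sequence[SVTruthRecord],
    rng: np.random.Generator,
    gc: float,
) -> SampleContig:
    names = sorted(ref)
    seq = ref[name]
    segments: list[Segment] = []
    chunks: list[str] = []
    cursor = 0

    def emit_ref(a: int, b: int) -> None:
        if b > a:
            segments.append(Segment(length=b - a, ref_name=name, ref_start=a))
            chunks.append(seq[a:b])

    for sv in sorted(svs, key=lambda r: r.start):
        emit_ref(cursor, sv.start)
        if sv.sv_type == DELETION:
            cursor = sv.end
        elif sv.sv_type == INSERTION:
            novel = _random_seq(rng, sv.size, gc)
            segments.append(Segment(length=sv.size, ref_name=None, novel_seq=novel))
            chunks.append(novel)
            cursor = sv.start
        elif sv.sv_type == INVERSION:
            segments.append(
                Segment(length=sv.size, ref_name=name, ref_start=sv.start, strand=-1)
            )
            chunks.append(revcomp(seq[sv.start : sv.end]))
            cursor = sv.end
        else:  # translocation: replace window with the next contig's window
            donor = names[(names.index(name) + 1) % len(names)]
            segments.append(
                Segment(length=sv.size, ref_name=donor, ref_start=sv.start)
            )
            chunks.append(ref[donor][sv.start : sv.end])
            cursor = sv.end
    emit_ref(cursor, len(seq))

    offsets = [0]
    for seg in segments[:-1]:
        offsets.append(offsets[-1] + seg.length)
    return SampleContig(
        name=name, segments=segments, seq="".join(chunks), seg_offsets=offsets
    )


def implant_svs(
    reference: Mapping[str, str],
    svs: Sequence[SVTruthRecord],
    seed: int = 0,
    gc: float = 0.5,
) -> Sample:
    """Build the sample haplotype(s) carrying the SVs.

    SVs must be pairwise non-overlapping and at least 1 kb from contig
    edges and from each other.  If the shared allele fraction is below
    1, a second SV-free haplotype is emitted and reads are drawn from
    the two in proportion.
    """
    svs = list(svs)
    _validate_svs(reference, svs)
    rng = np.random.default_rng([seed, 1])
    by_contig: dict[str, list[SVTruthRecord]] = {}
    for sv in svs:
        by_contig.setdefault(sv.ref_name, []).append(sv)
    var_contigs = {
        name: _build_contig(name, reference, by_contig.get(name, []), rng, 0.5)
        for name in sorted(reference)
    }
    frac = svs[0].allele_fraction if svs else 1.0
    haplotypes = [Haplotype(contigs=var_contigs, weight=frac)]
    if frac < 1.0:
        ref_contigs = {
            name: _identity_contig(name, reference[name])
            for name in sorted(reference)
        }
        haplotypes.append(Haplotype(contigs=ref_contigs, weight=1.0 - frac))
    return Sample(reference=dict(reference), haplotypes=haplotypes, truth=svs)


# ---------------------------------------------------------------------------
# read drawing and analytic alignment

_OP_EQ, _OP_X, _OP_D, _OP_I = 0, 1, 2, 3
_OP_CHARS = "=XDI"


def _mutate_run(
    rng: np.random.Generator,
    codes: np.ndarray,
    rates: tuple[float, float, float],
) -> tuple[list[tuple[str, int]], str]:
    """Inject per-base errors into one mapped run.

    Returns CIGAR ops (sample order) and the emitted read bases.
    Substitution/deletion are exclusive per position; single-base
    insertions occur after a position independently.
    """
    pm, pi, pd = rates
    L = codes.shape[0]
    if pm == 0.0 and pi == 0.0 and pd == 0.0:
        return [("=", L)], _BASES[codes].tobytes().decode("ascii")
    u = rng.random(L)
    mis = u < pm
    dele = (u >= pm) & (u < pm + pd)
    ins = rng.random(L) < pi

    pos_ops = np.zeros(L, dtype=np.uint8)
    pos_ops[mis] = _OP_X
    pos_ops[dele] = _OP_D
    bases = codes.copy()
    n_mis = int(mis.sum())
    if n_mis:
        bases[mis] = (codes[mis] + rng.integers(1, 4, n_mis)) % 4
    ins_idx = np.flatnonzero(ins)
    if ins_idx.size:
        ops_full = np.insert(pos_ops, ins_idx + 1, _OP_I)
        base_full = np.insert(bases, ins_idx + 1, rng.integers(0, 4, ins_idx.size))
    else:
        ops_full, base_full = pos_ops, bases
    read = _BASES[base_full[ops_full != _OP_D]].tobytes().decode("ascii")

    bounds = np.flatnonzero(np.diff(ops_full.astype(np.int8))) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [ops_full.shape[0]]))
    ops = [
        (_OP_CHARS[ops_full[s]], int(e - s)) for s, e in zip(starts, ends)
    ]
    return ops, read


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, ln in ops:
        if ln == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


@dataclass
class _Block:
    """One contiguous alignment piece of a read, sample-order frame."""

    ops: list[tuple[str, int]] = field(default_factory=list)
    q_start: int = 0  # emitted-read offset, sample order
    q_len: int = 0
    strand: int = 1
    ref_name: str = ""
    ref_start: int = 0
    ref_end: int = 0

    def trim(self) -> bool:
        """Drop boundary D/I ops (aligners never start or end on them).

        Boundary D shrinks the reference span; boundary I moves its
        bases into the soft clip.  Returns False if nothing alignable
        remains.
        """
        ops = _merge_ops(self.ops)
        lead_ref = lead_q = 0
        while ops and ops[0][0] in "DI":
            op, ln = ops.pop(0)
            if op == "D":
                lead_ref += ln
            else:
                lead_q += ln
        trail_ref = trail_q = 0
        while ops and ops[-1][0] in "DI":
            op, ln = ops.pop()
            if op == "D":
                trail_ref += ln
            else:
                trail_q += ln
        if not ops:
            return False
        self.ops = ops
        self.q_start += lead_q
        self.q_len -= lead_q + trail_q
        if self.strand == 1:
            self.ref_start += lead_ref
            self.ref_end -= trail_ref
        else:
            self.ref_end -= lead_ref
            self.ref_start += trail_ref
        ref_len = sum(ln for op, ln in ops if op in "=XD")
        if self.strand == 1:
            self.ref_end = self.ref_start + ref_len
        else:
            self.ref_start = self.ref_end - ref_len
        return True


def _record_for_block(
    block: _Block,
    name: str,
    stored_pool: str,
    pool_len: int,
    pool_offset: int,
    read_strand: int,
) -> AlignmentRecord:
    """AlignmentRecord for a block within a query 'pool' (read or tail).

    ``stored_pool`` is the pool's sample-order sequence; ``pool_offset``
    is the pool's sample-order start within the read.
    """
    q0 = block.q_start - pool_offset
    q1 = q0 + block.q_len
    if block.strand == 1:
        cig_ops = list(block.ops)
        lead, trail = q0, pool_len - q1
        stored = stored_pool
    else:
        cig_ops = list(reversed(block.ops))
        lead, trail = pool_len - q1, q0
        stored = revcomp(stored_pool)
    cigar: list[tuple[str, int]] = []
    if lead:
        cigar.append(("S", lead))
    cigar.extend(cig_ops)
    if trail:
        cigar.append(("S", trail))
    strand = "+" if block.strand * read_strand == 1 else "-"
    sc5, sc3 = (lead, trail) if strand == "+" else (trail, lead)
    return AlignmentRecord(
        read_id=name,
        ref_name=block.ref_name,
        ref_start=block.ref_start,
        ref_end=block.ref_end,
        strand=strand,
        mapq=min(254, block.q_len // 10),
        cigar=tuple(cigar),
        softclip_5p=sc5,
        softclip_3p=sc3,
        sequence=stored,
    )


def _simulate_read(
    rng: np.random.Generator,
    contig: SampleContig,
    codes: np.ndarray,
    s: int,
    e: int,
    read_strand: int,
    name: str,
    config: SimConfig,
) -> tuple[str, list[AlignmentRecord], list[AlignmentRecord]]:
    """Emit one read's sequence plus initial and tail alignment records."""
    thr = config.span_clip_threshold
    # overlapped (segment index, offset-in-segment, part-length) triples
    parts: list[tuple[int, int, int]] = []
    i = bisect_right(contig.seg_offsets, s) - 1
    pos = s
    while pos < e:
        seg = contig.segments[i]
        off = pos - contig.seg_offsets[i]
        take = min(e - pos, seg.length - off)
        parts.append((i, off, take))
        pos += take
        i += 1

    blocks: list[_Block] = []
    chunks: list[str] = []
    qcursor = 0
    block: Optional[_Block] = None
    last_mapped: Optional[tuple[Segment, int, int]] = None  # (seg, off, length)

    def close() -> None:
        nonlocal block, last_mapped
        if block is not None and block.trim():
            blocks.append(block)
        block = None
        last_mapped = None

    def continuity(seg: Segment, off: int) -> Optional[int]:
        """Reference gap to ``last_mapped`` if absorbable, else None."""
        if last_mapped is None:
            return None
        pseg, poff, plen = last_mapped
        if seg.strand != 1 or pseg.strand != 1 or seg.ref_name != pseg.ref_name:
            return None
        gap = (seg.ref_start + off) - (pseg.ref_start + poff + plen)
        if 0 <= gap <= thr:
            return gap
        return None

    for idx, (seg_idx, off, length) in enumerate(parts):
        seg = contig.segments[seg_idx]
        if seg.ref_name is None:
            # novel sequence: absorbable only if fully covered, small, and
            # flanked by continuable mapped parts on both sides
            nxt_seg = (
                contig.segments[parts[idx + 1][0]] if idx + 1 < len(parts) else None
            )
            nxt_off = parts[idx + 1][1] if idx + 1 < len(parts) else 0
            absorbable = (
                block is not None
                and off == 0
                and length == seg.length
                and seg.length <= thr
                and nxt_seg is not None
                and nxt_seg.ref_name is not None
                and last_mapped is not None
                and nxt_seg.strand == 1
                and last_mapped[0].strand == 1
                and nxt_seg.ref_name == last_mapped[0].ref_name
                and 0
                <= (nxt_seg.ref_start + nxt_off)
                - (
                    last_mapped[0].ref_start
                    + last_mapped[1]
                    + last_mapped[2]
                )
                <= thr
            )
            bases = seg.novel_seq[off : off + length]
            if absorbable:
                block.ops.append(("I", length))
                block.q_len += length
            else:
                close()
            chunks.append(bases)
            qcursor += length
            continue

        gap = continuity(seg, off) if block is not None else None
        if block is None or gap is None:
            close()
            if seg.strand == 1:
                rs = seg.ref_start + off
                re_ = rs + length
            else:
                re_ = seg.ref_start + seg.length - off
                rs = re_ - length
            block = _Block(
                q_start=qcursor,
                strand=seg.strand,
                ref_name=seg.ref_name,
                ref_start=rs,
                ref_end=re_,
            )
        else:
            if gap > 0:
                block.ops.append(("D", gap))
            block.ref_end += gap + length

        sub_start = contig.seg_offsets[seg_idx]
        sub = codes[sub_start + off : sub_start + off + length]
        ops, bases = _mutate_run(rng, sub, config.error_rates)
        block.ops.extend(ops)
        block.q_len += len(bases)
        chunks.append(bases)
        qcursor += len(bases)
        last_mapped = (seg, off, length)
    close()

    sample_order_seq = "".join(chunks)
    Lr = len(sample_order_seq)
    read_seq = sample_order_seq if read_strand == 1 else revcomp(sample_order_seq)
    if not blocks or Lr < config.min_read_length:
        return read_seq, [], []

    def as_seq_interval(b: _Block) -> tuple[int, int]:
        if read_strand == 1:
            return b.q_start, b.q_start + b.q_len
        return Lr - (b.q_start + b.q_len), Lr - b.q_start

    initial = max(blocks, key=lambda b: (b.q_len, -as_seq_interval(b)[0]))
    init_lo, init_hi = as_seq_interval(initial)
    initial_rec = _record_for_block(
        initial, name, sample_order_seq, Lr, 0, read_strand
    )

    tail_recs: list[AlignmentRecord] = []
    for side in (PROLOG, EPILOG):
        clip = init_lo if side == PROLOG else Lr - init_hi
        if clip <= config.tail_min_length:
            continue
        if side == PROLOG:
            cands = [b for b in blocks if as_seq_interval(b)[1] <= init_lo]
            if not cands:
                continue
            adj = max(cands, key=lambda b: as_seq_interval(b)[1])
            t_lo, t_hi = 0, init_lo
        else:
            cands = [b for b in blocks if as_seq_interval(b)[0] >= init_hi]
            if not cands:
                continue
            adj = min(cands, key=lambda b: as_seq_interval(b)[0])
            t_lo, t_hi = init_hi, Lr
        if adj.q_len < 100:
            continue  # too short for the stand-in remapper
        # tail pool in sample-order coordinates
        if read_strand == 1:
            p_lo, p_hi = t_lo, t_hi
        else:
            p_lo, p_hi = Lr - t_hi, Lr - t_lo
        tail_recs.append(
            _record_for_block(
                adj,
                f"{name}/{side}",
                sample_order_seq[p_lo:p_hi],
                p_hi - p_lo,
                p_lo,
                read_strand,
            )
        )
    return read_seq, [initial_rec], tail_recs


def sequence_and_align(
    sample: Sample, config: SimConfig
) -> tuple[list[tuple[str, str]], list[AlignmentRecord], list[AlignmentRecord]]:
    """Draw reads from the sample and emit their analytic alignments.

    Read starts are uniform over each sample contig (lengths truncated
    at the end); lengths are log-normal with the configured mean.
    Returns (reads, initial alignments, tail alignments).
    """
    rng = np.random.default_rng([config.seed, 2])
    mu = np.log(config.read_length_mean) - config.read_length_sigma**2 / 2
    weights = np.array([h.weight for h in sample.haplotypes])
    weights = weights / weights.sum()

    reads: list[tuple[str, str]] = []
    initials: list[AlignmentRecord] = []
    tails: list[AlignmentRecord] = []
    zmw = 0
    for ci, ref_name in enumerate(sorted(sample.reference)):
        ref_len = len(sample.reference[ref_name])
        n_reads = int(round(config.coverage * ref_len / config.read_length_mean))
        code_cache: dict[int, np.ndarray] = {}
        for _ in range(n_reads):
            hap_idx = int(rng.choice(len(sample.haplotypes), p=weights))
            contig = sample.haplotypes[hap_idx].contigs[ref_name]
            if hap_idx not in code_cache:
                code_cache[hap_idx] = _CODE_LUT[
                    np.frombuffer(contig.seq.encode("ascii"), dtype=np.uint8)
                ]
            start = int(rng.integers(0, contig.length))
            length = int(rng.lognormal(mu, config.read_length_sigma))
            end = min(start + length, contig.length)
            strand = 1 if rng.random() < 0.5 else -1
            if end - start < config.min_read_length:
                continue
            zmw += 1
            name = f"movie{ci + 1}/{zmw}/0_{end - start}"
            seq, init, tl = _simulate_read(
                rng, contig, code_cache[hap_idx], start, end, strand, name, config
            )
            reads.append((name, seq))
            initials.extend(init)
            tails.extend(tl)
    return reads, initials, tails


def simulate_dataset(
    config: SimConfig, svs: Sequence[SVTruthRecord] = ()
) -> SimulatedDataset:
    """Reference -> implant -> sequence, end to end."""
    reference = make_reference(config)
    sample = implant_svs(reference, svs, seed=config.seed, gc=config.gc)
    reads, initials, tails = sequence_and_align(sample, config)
    return SimulatedDataset(
        config=config,
        reference=reference,
        sample=sample,
        reads=reads,
        initial_records=initials,
        tail_records=tails,
        truth=list(svs),
    )


# ---------------------------------------------------------------------------
# file emission

def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Placeholder uniform qualities (long-read callers ignore them here)."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_sam(
    records: Sequence[AlignmentRecord],
    ref_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    header = make_header(ref_lengths, sort_order="coordinate")
    ordered = sorted(records, key=lambda r: (r.ref_name, r.ref_start, r.read_id))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in ordered:
            out.write(record_to_pysam(rec, header))


def write_truth(svs: Sequence[SVTruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(TRUTH_COLUMNS) + "\n")
        for sv in sorted(svs, key=lambda r: (r.ref_name, r.start)):
            fh.write(
                f"{sv.sv_type}\t{sv.ref_name}\t{sv.start}\t{sv.end}\t{sv.size}\t"
                f"{sv.allele_fraction}\n"
            )


def read_truth(path: str | Path) -> list[SVTruthRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            t, ref, start, end, size, frac = line.rstrip("\n").split("\t")
            out.append(
                SVTruthRecord(t, ref, int(start), int(end), int(size), float(frac))
            )
    return out


def write_dataset(ds: SimulatedDataset, outdir: str | Path, force: bool = False) -> None:
    """Emit reference/sample/reads/alignments/truth plus a manifest."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    ref_lengths = {n: len(s) for n, s in ds.reference.items()}
    write_fasta(ds.reference, outdir / "reference.fasta")
    write_fasta(
        {
            f"{h.contigs[n].name}_hap{i}": h.contigs[n].seq
            for i, h in enumerate(ds.sample.haplotypes)
            for n in sorted(h.contigs)
        },
        outdir / "sample.fasta",
    )
    write_fastq(ds.reads, outdir / "reads.fastq")
    write_sam(ds.initial_records, ref_lengths, outdir / "alignments.sam")
    write_sam(ds.tail_records, ref_lengths, outdir / "tails.sam")
    write_truth(ds.truth, outdir / "truth.tsv")
    manifest = {
        "config": asdict(ds.config),
        "n_reads": len(ds.reads),
        "n_initial_alignments": len(ds.initial_records),
        "n_tail_alignments": len(ds.tail_records),
        "truth": [asdict(sv) for sv in ds.truth],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
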