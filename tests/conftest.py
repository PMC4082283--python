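"""Shared fixtures: hand-built alignment records and simulated datasets."""

from __future__ import annotations

import pytest

from honeysv import sam_io, simulate
from honeysv.sam_io import AlignmentRecord, PieceAlignment


def make_record(
    read_id: str = "movie1/1/0_5000",
    ref_name: str = "ref1",
    ref_start: int = 1000,
    cigar: tuple = (("S", 300), ("=", 4500), ("S", 200)),
    strand: str = "+",
    mapq: int = 200,
    sequence: str | None = "auto",
) -> AlignmentRecord:
    """Record with clip fields derived from the CIGAR, like the reader does."""
    lead_s = trail_s = 0
    i = 0
    while i < len(cigar) and cigar[i][0] in "SH":
        if cigar[i][0] == "S":
            lead_s += cigar[i][1]
        i += 1
    j = len(cigar) - 1
    while j >= i and cigar[j][0] in "SH":
        if cigar[j][0] == "S":
            trail_s += cigar[j][1]
        j -= 1
    ref_len = sum(n for op, n in cigar if op in "MDN=X")
    qlen = sum(n for op, n in cigar if op in "MIS=X")
    if sequence == "auto":
        sequence = ("ACGT" * (qlen // 4 + 1))[:qlen]
    sc5, sc3 = (trail_s, lead_s) if strand == "-" else (lead_s, trail_s)
    return AlignmentRecord(
        read_id=read_id,
        ref_name=ref_name,
        ref_start=ref_start,
        ref_end=ref_start + ref_len,
        strand=strand,
        mapq=mapq,
        cigar=tuple(cigar),
        softclip_5p=sc5,
        softclip_3p=sc3,
        sequence=sequence,
    )


def make_piece(
    signature: tuple[str, str, str],
    pos_a: int,
    pos_b: int,
    read_id: str = "movie1/1/0_6000",
    ref_a: str = "ref1",
    ref_b: str = "ref1",
    mapq_initial: int = 200,
    mapq_tail: int = 200,
    span: int = 1000,
) -> PieceAlignment:
    """Piece-alignment whose breakpoint pair is exactly (pos_a, pos_b).

    The initial/tail records are laid out so that the interruption side
    and the tail's proximal end land on the requested coordinates.
    """
    strand_i, strand_t, side = signature
    if side == sam_io.EPILOG:
        # interruption at initial 3' mapping end
        if strand_i == "+":
            init_start, init_end = pos_a - span, pos_a
        else:
            init_start, init_end = pos_a, pos_a + span
        # epilog proximal end is its read-5' end
        if strand_t == "+":
            tail_start, tail_end = pos_b, pos_b + span
        else:
            tail_start, tail_end = pos_b - span, pos_b
    else:
        if strand_i == "+":
            init_start, init_end = pos_a, pos_a + span
        else:
            init_start, init_end = pos_a - span, pos_a
        # prolog proximal end is its read-3' end
        if strand_t == "+":
            tail_start, tail_end = pos_b - span, pos_b
        else:
            tail_start, tail_end = pos_b, pos_b + span

    def rec(name, ref, start, end, strand, mapq, clip5, clip3):
        lead, trail = (clip5, clip3) if strand == "+" else (clip3, clip5)
        cigar = []
        if lead:
            cigar.append(("S", lead))
        cigar.append(("=", end - start))
        if trail:
            cigar.append(("S", trail))
        return make_record(
            read_id=name, ref_name=ref, ref_start=start, cigar=tuple(cigar),
            strand=strand, mapq=mapq, sequence=None,
        )

    initial = rec(read_id, ref_a, init_start, init_end, strand_i, mapq_initial,
                  span if side == sam_io.PROLOG else 0,
                  span if side == sam_io.EPILOG else 0)
    tail = rec(f"{read_id}/{side}", ref_b, tail_start, tail_end, strand_t,
               mapq_tail, 0, 0)
    return PieceAlignment(
        read_id=read_id,
        molecule_id=sam_io.molecule_id_of(read_id),
        initial=initial,
        tail_aln=tail,
        tail_side=side,
    )


@pytest.fixture(scope="session")
def sv_dataset() -> simulate.SimulatedDataset:
    """30x dataset with a 5 kb deletion and a 2 kb inversion (tails regime)."""
    config = simulate.SimConfig(ref_length=80_000, coverage=30.0, seed=3)
    svs = [
        simulate.SVTruthRecord("deletion", "ref1", 20_000, 25_000, 5_000),
        simulate.SVTruthRecord("inversion", "ref1", 50_000, 52_000, 2_000),
    ]
    return simulate.simulate_dataset(config, svs)


@pytest.fixture(scope="session")
def hidden_deletion_dataset() -> simulate.SimulatedDataset:
    """40x dataset with a 327 bp deletion absorbed into CIGARs (spots regime)."""
    config = simulate.SimConfig(ref_length=60_000, coverage=40.0, seed=11)
    svs = [simulate.SVTruthRecord("deletion", "ref1", 30_000, 30_327, 327)]
    return simulate.simulate_dataset(config, svs)


@pytest.fixture(scope="session")
def clean_dataset() -> simulate.SimulatedDataset:
    """Zero-error, zero-SV negative control."""
    config = simulate.SimConfig(
        ref_length=40_000, coverage=15.0, error_rates=(0.0, 0.0, 0.0), seed=7
    )
    return simulate.simulate_dataset(config, [])
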