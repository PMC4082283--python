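"""Intra-read discordance: error channels, kernels, and spot calling.

Noisy long reads can absorb a structural variant into an otherwise
contiguous alignment ("hidden" variants).  Because sequencing errors are
stochastic, the per-position rates of mismatches, insertions and
deletions are locally elevated wherever many reads disagree with the
reference in the same way.  This module counts the three error channels
plus coverage into a 4xG integer array, normalizes them to rates
(E = A / C), smooths with a centered mean window of length 2B+1,

    M[j, i] = mean(E[j, i-B .. i+B]),

and applies a slope kernel contrasting the window before each position
with the window after,

    S[j, i] = (1/B) * (sum(M[j, i-B .. i-1]) - sum(M[j, i+1 .. i+B])),

so that a step *increase* in discordance yields a negative S excursion
and a step decrease a positive one.  Per channel, excursions beyond
N * sigma (sigma: standard deviation of M over the whole reference;
default N = 5) are extracted as peaks; a negative peak paired with the
nearest following positive peak yields a candidate variant with inner /
outer boundary triplets (start_out, start, start_in) and
(end_in, end, end_out), the exact breakpoints being the apexes of
maximum |S|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import h5py
import numpy as np

from honeysv.sam_io import AlignmentRecord

log = logging.getLogger(__name__)

#: channel order in the 3xG array
CHANNELS = ("mismatch", "insertion", "deletion")
MISMATCH, INSERTION_CH, DELETION_CH = 0, 1, 2

DEFAULT_B = 400
DEFAULT_N = 5.0
DEFAULT_MAX_PAIR_DISTANCE = 100_000
DEFAULT_MIN_COVERAGE = 5
DEFAULT_MIN_SIZE = 50

STATE_FORMAT_VERSION = "honeysv-state-1"

REPORT_COLUMNS = (
    "ref",
    "start_out",
    "start",
    "start_in",
    "end_in",
    "end",
    "end_out",
    "type",
    "size",
    "support",
)


class StateError(RuntimeError):
    """Unreadable or incompatible persisted channel state."""


class ConsistencyError(ValueError):
    """Alignment refers to positions beyond the reference length."""


@dataclass
class ErrorChannelArray:
    """Per-position error counts (3xG) and coverage (G) for one reference."""

    ref_name: str
    A: np.ndarray  # (3, G) int64: mismatch, insertion, deletion
    C: np.ndarray  # (G,) int64 coverage

    @property
    def length(self) -> int:
        return int(self.C.shape[0])


@dataclass
class SignalTrack:
    """Derived rate/smoothed/slope tracks and whole-reference statistics."""

    E: np.ndarray
    M: np.ndarray
    S: np.ndarray
    B: int
    mu: np.ndarray  # (3,) per-channel mean of M
    sigma: np.ndarray  # (3,) per-channel population std of M


@dataclass(frozen=True)
class DiscordancePeak:
    """A contiguous run of |S| beyond threshold on one channel."""

    channel: int
    sign: int  # -1 or +1
    start: int  # first position of the run
    end: int  # last position of the run (inclusive)
    apex: int  # leftmost position of extreme |S| within the run


@dataclass
class SpotCall:
    """A paired-excursion candidate variant."""

    sv_type: str  # channel name
    ref_name: str
    start_out: int
    start: int
    start_in: int
    end_in: int
    end: int
    end_out: int
    size_estimate: int = 0
    support: float = 0.0

    def __post_init__(self) -> None:
        self.size_estimate = self.end - self.start


def _expand_runs(starts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Concatenate [s, s+1, .., s+l-1] for each run; vectorized."""
    total = int(lengths.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    offsets = np.repeat(np.cumsum(lengths) - lengths, lengths)
    return np.repeat(starts, lengths) + (np.arange(total) - offsets)


_SEQ_OPS = "MIDNSHP=X"
_OPS_IDX = {op: i for i, op in enumerate(_SEQ_OPS)}
_CONSUMES_REF = np.array([1, 0, 1, 1, 0, 0, 0, 1, 1], dtype=np.int64)
_CONSUMES_QUERY = np.array([1, 1, 0, 0, 1, 0, 0, 1, 1], dtype=np.int64)


def count_channels(
    alignments: Iterable[AlignmentRecord],
    ref_length: int,
    ref_name: str = "ref",
    ref_seq: Optional[str] = None,
) -> ErrorChannelArray:
    """Count coverage and per-position errors from aligned reads.

    Conventions: deleted reference positions count as covered (the read
    spans them); an insertion of length L between reference positions
    i and i+1 credits L to the insertion channel at position i (its
    5'-flanking base); soft clips contribute to nothing.  Mismatches
    come from X CIGAR ops, or from comparing the read sequence against
    ``ref_seq`` for records using plain M ops (an error if M ops are
    present and no reference sequence was supplied).
    """
    A = np.zeros((3, ref_length), dtype=np.int64)
    C = np.zeros(ref_length, dtype=np.int64)
    ref_arr = (
        np.frombuffer(ref_seq.upper().encode("ascii"), dtype=np.uint8)
        if ref_seq is not None
        else None
    )
    if ref_arr is not None and ref_arr.shape[0] != ref_length:
        raise ConsistencyError(
            f"reference sequence length {ref_arr.shape[0]} != declared {ref_length}"
        )
    for rec in alignments:
        if rec.ref_name != ref_name:
            raise ConsistencyError(
                f"{rec.read_id}: aligned to {rec.ref_name!r}, expected {ref_name!r}"
            )
        if rec.ref_end > ref_length:
            raise ConsistencyError(
                f"{rec.read_id}: alignment end {rec.ref_end} beyond reference "
                f"length {ref_length}"
            )
        ops = np.fromiter((_OPS_IDX[o] for o, _ in rec.cigar), dtype=np.int64)
        lens = np.fromiter((l for _, l in rec.cigar), dtype=np.int64)
        ref_adv = lens * _CONSUMES_REF[ops]
        ref_starts = rec.ref_start + np.cumsum(ref_adv) - ref_adv

        C[rec.ref_start : rec.ref_end] += 1

        x_mask = ops == _OPS_IDX["X"]
        if x_mask.any():
            np.add.at(A[MISMATCH], _expand_runs(ref_starts[x_mask], lens[x_mask]), 1)
        d_mask = ops == _OPS_IDX["D"]
        if d_mask.any():
            np.add.at(A[DELETION_CH], _expand_runs(ref_starts[d_mask], lens[d_mask]), 1)
        i_mask = ops == _OPS_IDX["I"]
        if i_mask.any():
            anchors = np.maximum(ref_starts[i_mask] - 1, 0)
            np.add.at(A[INSERTION_CH], anchors, lens[i_mask])
        m_mask = ops == _OPS_IDX["M"]
        if m_mask.any():
            if ref_arr is None:
                raise ConsistencyError(
                    f"{rec.read_id}: CIGAR uses M ops; a reference sequence is "
                    "required to resolve mismatches"
                )
            if rec.sequence is None:
                raise ConsistencyError(
                    f"{rec.read_id}: CIGAR uses M ops but record has no sequence"
                )
            q_adv = lens * _CONSUMES_QUERY[ops]
            q_starts = np.cumsum(q_adv) - q_adv
            ridx = _expand_runs(ref_starts[m_mask], lens[m_mask])
            qidx = _expand_runs(q_starts[m_mask], lens[m_mask])
            q_arr = np.frombuffer(rec.sequence.upper().encode("ascii"), dtype=np.uint8)
            mism = ridx[ref_arr[ridx] != q_arr[qidx]]
            if mism.size:
                np.add.at(A[MISMATCH], mism, 1)
    return ErrorChannelArray(ref_name=ref_name, A=A, C=C)


def count_channels_multi(
    alignments: Iterable[AlignmentRecord],
    ref_lengths: Mapping[str, int],
    ref_seqs: Optional[Mapping[str, str]] = None,
) -> dict[str, ErrorChannelArray]:
    """Partition a mixed-reference stream and count each reference."""
    by_ref: dict[str, list[AlignmentRecord]] = {name: [] for name in ref_lengths}
    for rec in alignments:
        if rec.ref_name not in by_ref:
            raise ConsistencyError(f"{rec.read_id}: unknown reference {rec.ref_name!r}")
        by_ref[rec.ref_name].append(rec)
    return {
        name: count_channels(
            recs,
            ref_lengths[name],
            ref_name=name,
            ref_seq=ref_seqs.get(name) if ref_seqs else None,
        )
        for name, recs in by_ref.items()
    }


def normalize(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Per-position error rates E = A / C, with E = 0 where coverage is 0."""
    E = np.zeros_like(A, dtype=np.float64)
    np.divide(A, C, out=E, where=C > 0)
    return E


def smooth(E: np.ndarray, B: int = DEFAULT_B) -> np.ndarray:
    """Centered mean over a window of length 2B+1, truncated at edges."""
    if B < 1:
        raise ValueError(f"window half-width B must be >= 1, got {B}")
    G = E.shape[-1]
    if G <= 2 * B:
        raise ValueError(f"reference length {G} too short for window 2*{B}+1")
    idx = np.arange(G)
    hi = np.minimum(idx + B, G - 1)
    lo = np.maximum(idx - B, 0)
    cs = np.cumsum(E, axis=-1)
    upper = cs[..., hi]
    lower = np.where(lo > 0, cs[..., np.maximum(lo - 1, 0)], 0.0)
    counts = hi - lo + 1
    return (upper - lower) / counts


def channel_stats(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Population mean and standard deviation per channel over all positions."""
    return M.mean(axis=-1), M.std(axis=-1)


def slope(M: np.ndarray, B: int = DEFAULT_B) -> np.ndarray:
    """Before-minus-after slope kernel, zero where a full window is missing.

    ``S[j,i] = (1/B) * (sum M[j, i-B..i-1] - sum M[j, i+1..i+B])``; an
    increase in the smoothed rate gives negative S, a decrease positive S.
    """
    if B < 1:
        raise ValueError(f"window half-width B must be >= 1, got {B}")
    G = M.shape[-1]
    if G <= 2 * B:
        raise ValueError(f"reference length {G} too short for window 2*{B}+1")
    S = np.zeros_like(M, dtype=np.float64)
    cs = np.cumsum(M, axis=-1)
    idx = np.arange(B, G - B)
    left = cs[..., idx - 1] - np.where(idx - B - 1 >= 0, cs[..., idx - B - 1], 0.0)
    right = cs[..., idx + B] - cs[..., idx]
    S[..., idx] = (left - right) / B
    return S


def compute_tracks(channels: ErrorChannelArray, B: int = DEFAULT_B) -> SignalTrack:
    """Full kernel chain: normalize -> smooth -> stats -> slope."""
    E = normalize(channels.A, channels.C)
    M = smooth(E, B)
    mu, sigma = channel_stats(M)
    S = slope(M, B)
    return SignalTrack(E=E, M=M, S=S, B=B, mu=mu, sigma=sigma)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = [int(i) + 1 for i in np.flatnonzero(d == 1)]
    ends = [int(i) for i in np.flatnonzero(d == -1)]
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(int(mask.shape[0]) - 1)
    return list(zip(starts, ends))


def find_peaks(S_row: np.ndarray, tau: float, channel: int) -> list[DiscordancePeak]:
    """Threshold excursions of one channel's slope signal."""
    peaks: list[DiscordancePeak] = []
    for sign in (-1, 1):
        mask = S_row < -tau if sign < 0 else S_row > tau
        for start, end in _runs(mask):
            seg = S_row[start : end + 1]
            apex = start + int(np.argmin(seg) if sign < 0 else np.argmax(seg))
            peaks.append(DiscordancePeak(channel, sign, start, end, apex))
    peaks.sort(key=lambda p: (p.start, p.sign))
    return peaks


def call_spots(
    S: np.ndarray,
    sigma: np.ndarray,
    C: np.ndarray,
    N: float = DEFAULT_N,
    max_pair_distance: int = DEFAULT_MAX_PAIR_DISTANCE,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_size: int = DEFAULT_MIN_SIZE,
    ref_name: str = "ref",
) -> list[SpotCall]:
    """Pair threshold excursions into candidate variants.

    Per channel, runs of ``S < -N*sigma`` (discordance increases) are
    negative peaks and runs of ``S > +N*sigma`` positive peaks.  Each
    negative peak is paired with the nearest following positive peak
    whose run starts after the negative run ends and whose apex lies
    within ``max_pair_distance``; unpaired peaks are dropped with a
    logged count.  Calls below ``min_coverage`` (mean coverage over
    [start, end]) are dropped, as are mismatch/deletion calls shorter
    than ``min_size``.
    """
    calls: list[SpotCall] = []
    n_unpaired = 0
    cum_cov = np.concatenate(([0], np.cumsum(C)))
    for j, name in enumerate(CHANNELS):
        tau = N * float(sigma[j])
        peaks = find_peaks(S[j], tau, j)
        negs = [p for p in peaks if p.sign < 0]
        poss = [p for p in peaks if p.sign > 0]
        used = 0
        for neg in negs:
            while used < len(poss) and poss[used].start <= neg.end:
                used += 1
            if used >= len(poss) or poss[used].apex - neg.apex > max_pair_distance:
                n_unpaired += 1
                continue
            pos = poss[used]
            used += 1
            start, end = neg.apex, pos.apex
            support = float(cum_cov[end + 1] - cum_cov[start]) / (end - start + 1)
            call = SpotCall(
                sv_type=name,
                ref_name=ref_name,
                start_out=neg.start,
                start=start,
                start_in=neg.end,
                end_in=pos.start,
                end=end,
                end_out=pos.end,
                support=support,
            )
            if support < min_coverage:
                continue
            if name in ("mismatch", "deletion") and call.size_estimate < min_size:
                continue
            calls.append(call)
        n_unpaired += len(poss) - used
    if n_unpaired:
        log.info("spots: %d unpaired peaks discarded", n_unpaired)
    calls.sort(key=lambda c: (c.start, c.sv_type))
    return calls


def spots_pipeline(
    channels: ErrorChannelArray,
    B: int = DEFAULT_B,
    N: float = DEFAULT_N,
    max_pair_distance: int = DEFAULT_MAX_PAIR_DISTANCE,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_size: int = DEFAULT_MIN_SIZE,
) -> tuple[SignalTrack, list[SpotCall]]:
    """Kernels plus calling for one reference's channel array."""
    track = compute_tracks(channels, B=B)
    calls = call_spots(
        track.S,
        track.sigma,
        channels.C,
        N=N,
        max_pair_distance=max_pair_distance,
        min_coverage=min_coverage,
        min_size=min_size,
        ref_name=channels.ref_name,
    )
    return track, calls


def save_state(
    arrays: Sequence[ErrorChannelArray],
    params: Mapping[str, float],
    path: str | Path,
) -> None:
    """Persist channel arrays to HDF5 for later reprocessing.

    Counting the channels dominates runtime on real data; the saved
    state lets calling be rerun with different B / N without recounting.
    """
    from honeysv import __version__

    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = STATE_FORMAT_VERSION
        fh.attrs["tool_version"] = __version__
        for key, val in params.items():
            fh.attrs[key] = val
        for arr in arrays:
            grp = fh.create_group(arr.ref_name)
            grp.create_dataset("channels", data=arr.A, compression="gzip")
            grp.create_dataset("coverage", data=arr.C, compression="gzip")


def load_state(path: str | Path) -> tuple[list[ErrorChannelArray], dict]:
    """Restore channel arrays; raises :class:`StateError` on mismatch."""
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise StateError(f"{path}: cannot open state file ({exc})") from exc
    with fh:
        version = fh.attrs.get("format_version")
        if version != STATE_FORMAT_VERSION:
            raise StateError(
                f"{path}: state format {version!r} incompatible with "
                f"{STATE_FORMAT_VERSION!r}"
            )
        params = {
            k: fh.attrs[k]
            for k in fh.attrs
            if k not in ("format_version", "tool_version")
        }
        arrays = []
        for name in fh:
            grp = fh[name]
            if "channels" not in grp or "coverage" not in grp:
                raise StateError(f"{path}: group {name!r} is missing datasets")
            A = np.asarray(grp["channels"], dtype=np.int64)
            C = np.asarray(grp["coverage"], dtype=np.int64)
            if A.ndim != 2 or A.shape[0] != 3 or A.shape[1] != C.shape[0]:
                raise StateError(f"{path}: group {name!r} has inconsistent shapes")
            arrays.append(ErrorChannelArray(ref_name=name, A=A, C=C))
    return arrays, params


def write_spots_report(calls: Iterable[SpotCall], path: str | Path) -> None:
    """Tab-separated spot report (positions 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(REPORT_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.ref_name}\t{c.start_out + 1}\t{c.start + 1}\t{c.start_in + 1}\t"
                f"{c.end_in + 1}\t{c.end + 1}\t{c.end_out + 1}\t{c.sv_type}\t"
                f"{c.size_estimate}\t{c.support:.2f}\n"
            )


def write_spots_bed(calls: Iterable[SpotCall], path: str | Path) -> None:
    """BED (0-based half-open) over [start, end)."""
    with open(path, "w") as fh:
        for c in calls:
            end = max(c.end, c.start + 1)
            fh.write(f"{c.ref_name}\t{c.start}\t{end}\t{c.sv_type}\t{c.support:.1f}\n")
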