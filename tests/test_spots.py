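"""Error-channel counting, kernels, peak pairing, and state persistence."""

from __future__ import annotations

import h5py
import numpy as np
import pytest

from honeysv import spots
from honeysv.spots import (
    DELETION_CH,
    INSERTION_CH,
    MISMATCH,
    ConsistencyError,
    ErrorChannelArray,
    StateError,
    call_spots,
    channel_stats,
    count_channels,
    load_state,
    normalize,
    save_state,
    slope,
    smooth,
    spots_pipeline,
)

from conftest import make_record


def naive_pileup(records, ref_length, ref_seq=None):
    """Independent oracle: per-base walk of each CIGAR."""
    A = np.zeros((3, ref_length), dtype=int)
    C = np.zeros(ref_length, dtype=int)
    for rec in records:
        C[rec.ref_start : rec.ref_end] += 1
        pos, qpos = rec.ref_start, 0
        for op, ln in rec.cigar:
            if op in "SH":
                qpos += ln if op == "S" else 0
            elif op == "=":
                pos += ln
                qpos += ln
            elif op == "X":
                for k in range(ln):
                    A[MISMATCH, pos + k] += 1
                pos += ln
                qpos += ln
            elif op == "M":
                for k in range(ln):
                    if ref_seq[pos + k] != rec.sequence[qpos + k]:
                        A[MISMATCH, pos + k] += 1
                pos += ln
                qpos += ln
            elif op == "I":
                A[INSERTION_CH, max(pos - 1, 0)] += ln
                qpos += ln
            elif op == "D":
                for k in range(ln):
                    A[DELETION_CH, pos + k] += 1
                pos += ln
    return A, C


class TestCountChannels:
    def test_perfect_read(self):
        rec = make_record(ref_start=0, cigar=(("=", 100),))
        arr = count_channels([rec], 200, ref_name="ref1")
        assert arr.C[:100].tolist() == [1] * 100 and arr.C[100:].sum() == 0
        assert arr.A.sum() == 0

    def test_deletion_positions_counted_and_covered(self):
        rec = make_record(ref_start=0, cigar=(("=", 50), ("D", 10), ("=", 50)))
        arr = count_channels([rec], 200, ref_name="ref1")
        assert arr.A[DELETION_CH, 50:60].tolist() == [1] * 10
        assert arr.A[DELETION_CH].sum() == 10
        # deleted reference positions are still spanned by the read
        assert arr.C[:110].tolist() == [1] * 110

    def test_insertion_credited_to_flanking_base(self):
        rec = make_record(ref_start=0, cigar=(("=", 50), ("I", 5), ("=", 50)))
        arr = count_channels([rec], 200, ref_name="ref1")
        assert arr.A[INSERTION_CH, 49] == 5
        assert arr.A[INSERTION_CH].sum() == 5
        assert arr.C[:100].tolist() == [1] * 100

    def test_mismatch_via_m_ops_needs_reference(self):
        rec = make_record(ref_start=0, cigar=(("M", 8),), sequence="ACGTACGT")
        with pytest.raises(ConsistencyError, match="reference"):
            count_channels([rec], 100, ref_name="ref1")
        arr = count_channels([rec], 8, ref_name="ref1", ref_seq="ACGAACGA")
        assert arr.A[MISMATCH].tolist() == [0, 0, 0, 1, 0, 0, 0, 1]

    def test_out_of_range_alignment_rejected(self):
        rec = make_record(ref_start=150, cigar=(("=", 100),))
        with pytest.raises(ConsistencyError, match="beyond"):
            count_channels([rec], 200, ref_name="ref1")

    def test_matches_naive_pileup_on_simulated_reads(self, hidden_deletion_dataset):
        ds = hidden_deletion_dataset
        recs = ds.initial_records[:40]
        arr = count_channels(recs, ds.config.ref_length, ref_name="ref1")
        A, C = naive_pileup(recs, ds.config.ref_length)
        np.testing.assert_array_equal(arr.A, A)
        np.testing.assert_array_equal(arr.C, C)


class TestKernels:
    def test_normalize_rates_and_zero_coverage(self):
        A = np.array([[2, 0, 4]], dtype=np.int64)
        C = np.array([10, 0, 4], dtype=np.int64)
        np.testing.assert_allclose(normalize(A, C), [[0.2, 0.0, 1.0]])

    def test_smooth_window_mean_and_truncated_edges(self):
        E = np.array([[0.0, 3.0, 0.0]])
        M = smooth(E, B=1)
        np.testing.assert_allclose(M, [[1.5, 1.0, 1.5]])

    def test_smooth_constant_is_identity(self):
        E = np.full((3, 50), 0.25)
        np.testing.assert_allclose(smooth(E, B=5), E)

    def test_smooth_rejects_degenerate_length(self):
        with pytest.raises(ValueError, match="too short"):
            smooth(np.zeros((3, 10)), B=5)

    def test_smooth_matches_direct_mean(self):
        rng = np.random.default_rng(0)
        E = rng.random((3, 300))
        M = smooth(E, B=2)
        for i in range(2, 298):
            np.testing.assert_allclose(M[:, i], E[:, i - 2 : i + 3].mean(axis=1),
                                       rtol=1e-12)

    def test_channel_stats_closed_forms(self):
        mu, sigma = channel_stats(np.array([[0.0, 0.0, 1.0, 1.0]]))
        assert mu[0] == pytest.approx(0.5) and sigma[0] == pytest.approx(0.5)
        mu, sigma = channel_stats(np.full((3, 7), 0.3))
        np.testing.assert_allclose(mu, 0.3)
        np.testing.assert_allclose(sigma, 0.0)

    def test_slope_step_example(self):
        M = np.array([[0.0, 0.0, 1.0, 1.0]])
        S = slope(M, B=1)
        assert S[0, 2] == pytest.approx(-1.0)  # (M_1 - M_3) / 1
        assert S[0, 0] == 0.0 and S[0, 3] == 0.0  # no full window at edges

    def test_slope_constant_is_zero(self):
        np.testing.assert_allclose(slope(np.full((3, 40), 0.7), B=4), 0.0,
                                   atol=1e-12)

    def test_slope_matches_direct_sums(self):
        rng = np.random.default_rng(1)
        M = rng.random((3, 200))
        S = slope(M, B=3)
        for i in range(3, 197):
            expected = (M[:, i - 3 : i].sum(axis=1) - M[:, i + 1 : i + 4].sum(axis=1)) / 3
            np.testing.assert_allclose(S[:, i], expected, rtol=1e-9, atol=1e-12)

    def test_slope_antisymmetric_under_axis_reversal(self):
        rng = np.random.default_rng(2)
        M = rng.random((3, 500))
        S_fwd = slope(M, B=7)
        S_rev = slope(M[:, ::-1], B=7)
        np.testing.assert_allclose(S_rev[:, ::-1], -S_fwd, atol=1e-12)

    def test_sign_convention_increase_negative(self):
        """A step increase in discordance gives negative S at the step,
        the later decrease gives positive S."""
        E = np.zeros((3, 400))
        E[DELETION_CH, 150:250] = 0.9
        M = smooth(E, B=10)
        S = slope(M, B=10)
        assert S[DELETION_CH, 150] < 0
        assert S[DELETION_CH, 250] > 0
        assert S[DELETION_CH].argmin() == pytest.approx(150, abs=1)
        assert S[DELETION_CH].argmax() == pytest.approx(250, abs=1)


def synthetic_signal(G=1000):
    """Slope track with one paired -/+ excursion on the deletion channel."""
    S = np.zeros((3, G))
    S[DELETION_CH, 300:341] = -np.hanning(41)  # apex at 320
    S[DELETION_CH, 640:701] = np.hanning(61)  # apex at 670
    sigma = np.full(3, 0.1)
    C = np.full(G, 20)
    return S, sigma, C


class TestCallSpots:
    def test_constructed_excursion_pair(self):
        S, sigma, C = synthetic_signal()
        calls = call_spots(S, sigma, C, N=5, max_pair_distance=10_000,
                           min_coverage=5, min_size=50)
        assert len(calls) == 1
        c = calls[0]
        assert c.sv_type == "deletion"
        assert (c.start, c.end) == (320, 670)
        assert c.start_out <= c.start <= c.start_in <= c.end_in <= c.end <= c.end_out
        assert c.start_out >= 300 and c.end_out <= 700
        assert c.size_estimate == 350
        assert c.support == pytest.approx(20.0)

    def test_zero_signal_no_calls(self):
        S = np.zeros((3, 500))
        assert call_spots(S, np.full(3, 0.1), np.full(500, 20)) == []

    def test_unpaired_negative_peak_dropped(self):
        S, sigma, C = synthetic_signal()
        S[DELETION_CH, 640:701] = 0.0  # remove the positive partner
        assert call_spots(S, sigma, C, N=5) == []

    def test_pairing_respects_max_distance(self):
        S, sigma, C = synthetic_signal()
        assert call_spots(S, sigma, C, N=5, max_pair_distance=100) == []

    def test_min_coverage_filter(self):
        S, sigma, C = synthetic_signal()
        assert call_spots(S, sigma, C, N=5, min_coverage=25) == []

    def test_min_size_applies_to_deletion_channel(self):
        S, sigma, C = synthetic_signal()
        assert call_spots(S, sigma, C, N=5, min_size=400) == []
        # insertion-channel calls are not size-filtered
        S2 = np.zeros_like(S)
        S2[INSERTION_CH] = S[DELETION_CH]
        calls = call_spots(S2, sigma, C, N=5, min_size=400)
        assert [c.sv_type for c in calls] == ["insertion"]

    def test_raising_threshold_never_adds_calls(self, hidden_deletion_dataset):
        ds = hidden_deletion_dataset
        arr = count_channels(ds.initial_records, ds.config.ref_length, ref_name="ref1")
        for B in (150, 400):
            keys_prev = None
            for N in (3, 5, 7, 9):
                _, calls = spots_pipeline(arr, B=B, N=N)
                keys = {(c.sv_type, c.start, c.end) for c in calls}
                if keys_prev is not None:
                    assert keys <= keys_prev
                keys_prev = keys

    def test_translation_equivariance(self):
        """Shifting the discordant region shifts every reported
        coordinate by exactly the same amount."""
        G, cov = 60_000, 30

        def calls_at(a):
            A = np.zeros((3, G), dtype=np.int64)
            C = np.full(G, cov, dtype=np.int64)
            A[DELETION_CH, a : a + 400] = cov - 2
            arr = ErrorChannelArray("ref1", A, C)
            _, calls = spots_pipeline(arr, B=100, N=5)
            return calls

        base, shifted = calls_at(20_000), calls_at(20_531)
        assert len(base) == len(shifted) == 1
        b, s = base[0], shifted[0]
        for fld in ("start_out", "start", "start_in", "end_in", "end", "end_out"):
            assert getattr(s, fld) - getattr(b, fld) == 531


class TestStatePersistence:
    def arrays(self):
        rng = np.random.default_rng(3)
        return [
            ErrorChannelArray(
                "ref1",
                rng.integers(0, 5, (3, 500)).astype(np.int64),
                rng.integers(1, 40, 500).astype(np.int64),
            ),
            ErrorChannelArray(
                "ref2",
                rng.integers(0, 5, (3, 300)).astype(np.int64),
                rng.integers(1, 40, 300).astype(np.int64),
            ),
        ]

    def test_round_trip_bit_identical(self, tmp_path):
        path = tmp_path / "state.h5"
        arrays = self.arrays()
        save_state(arrays, {"B": 100, "N": 5.0}, path)
        back, params = load_state(path)
        assert params["B"] == 100 and params["N"] == 5.0
        for a, b in zip(arrays, sorted(back, key=lambda x: x.ref_name)):
            assert a.ref_name == b.ref_name
            np.testing.assert_array_equal(a.A, b.A)
            np.testing.assert_array_equal(a.C, b.C)

    def test_reprocessing_reproduces_calls(self, tmp_path, hidden_deletion_dataset):
        ds = hidden_deletion_dataset
        arr = count_channels(ds.initial_records, ds.config.ref_length, ref_name="ref1")
        path = tmp_path / "state.h5"
        save_state([arr], {"B": 150, "N": 5.0}, path)
        (loaded,), _ = load_state(path)
        _, fresh = spots_pipeline(arr, B=150, N=5.0)
        _, replay = spots_pipeline(loaded, B=150, N=5.0)
        assert fresh == replay

    def test_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "state.h5"
        save_state(self.arrays(), {}, path)
        with h5py.File(path, "a") as fh:
            fh.attrs["format_version"] = "someone-elses-format"
        with pytest.raises(StateError, match="incompatible"):
            load_state(path)

    def test_corrupted_group_rejected(self, tmp_path):
        path = tmp_path / "state.h5"
        save_state(self.arrays(), {}, path)
        with h5py.File(path, "a") as fh:
            del fh["ref1"]["coverage"]
        with pytest.raises(StateError, match="missing"):
            load_state(path)
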