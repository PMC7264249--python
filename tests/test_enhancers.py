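"""Enhancer stitching, quantification and the slope-1 tangency cutoff."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sekit.core import Gene, GenomicInterval, Peak, PipelineParams, SignalTrack, ValidationError
from sekit.enhancers import (
    call_enhancers,
    filter_distal,
    find_se_cutoff,
    profile_matrix,
    quantify,
    stitch,
)


def gene(gene_id, tss, strand="+", chrom="chr1"):
    return Gene(gene_id, GenomicInterval(chrom, tss, tss + 1, gene_id), strand)


def peak(start, end, chrom="chr1", **kw):
    return Peak.from_coords(chrom, start, end, **kw)


# ---------------------------------------------------------------- distal filter

class TestFilterDistal:
    def test_two_clause_rule(self):
        genes = [gene("g", 5000)]
        # far peak: kept via boundary clause
        assert filter_distal([peak(0, 1000)], genes)
        # peak containing the TSS: both distances 0 -> removed
        assert not filter_distal([peak(4000, 6000)], genes)
        # boundary 1200 < 1500 and center 1300 < 3000 -> removed
        assert not filter_distal([peak(3600, 3800)], genes)
        # same peak, TSS at 6900: center distance 3200 >= 3000 -> kept
        assert filter_distal([peak(3600, 3800)], [gene("g", 6900)])

    def test_conjunction_switch(self):
        genes = [gene("g", 6900)]
        params = PipelineParams(distal_conjunction=True)
        # boundary 3100 >= 1500 AND center 3200 >= 3000 -> kept either way
        assert filter_distal([peak(3600, 3800)], genes, params)
        # boundary 2000 >= 1500 but center 2100 < 3000 -> dropped under AND
        p = peak(4600, 4900)
        assert filter_distal([p], genes)
        assert not filter_distal([p], genes, params)

    def test_empty_annotation_errors(self):
        with pytest.raises(ValidationError):
            filter_distal([peak(0, 100)], [])

    def test_order_preserved(self):
        genes = [gene("g", 100_000)]
        peaks = [peak(5000, 6000), peak(1000, 2000), peak(9000, 9500)]
        assert filter_distal(peaks, genes) == peaks


# ------------------------------------------------------------------- stitching

class TestStitch:
    def test_gap_boundary_is_strict(self):
        merged = stitch([peak(0, 100), peak(12_599, 12_700)], 12_500)
        assert len(merged) == 1
        assert (merged[0].region.start, merged[0].region.end) == (0, 12_700)
        split = stitch([peak(0, 100), peak(12_600, 12_700)], 12_500)
        assert len(split) == 2

    def test_single_peak_identity(self):
        (enh,) = stitch([peak(10, 50)], 12_500)
        assert (enh.region.start, enh.region.end) == (10, 50)
        assert enh.constituent_peaks == (peak(10, 50),)

    @given(
        st.lists(
            st.tuples(st.integers(0, 200_000), st.integers(1, 3_000)),
            min_size=1,
            max_size=40,
        ),
        st.integers(100, 20_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_exhaustive(self, coords, gap):
        peaks = [peak(s, s + w) for s, w in coords]
        first = stitch(peaks, gap)
        # every input peak lands in exactly one enhancer
        assert sum(len(e.constituent_peaks) for e in first) == len(peaks)
        # output regions are pairwise separated by at least the gap
        regions = sorted((e.region.start, e.region.end) for e in first)
        for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
            assert s2 - e1 >= gap
        # restitching the regions changes nothing
        again = stitch(
            [peak(s, e) for s, e in regions], gap
        )
        assert sorted((e.region.start, e.region.end) for e in again) == regions


# -------------------------------------------------------------- quantification

class TestQuantify:
    def test_area_examples(self):
        track = SignalTrack.from_records([("chr1", 0, 100, 1.0), ("chr1", 100, 200, 3.0)])
        enh = stitch([peak(50, 150)], 1)
        (q,) = quantify(enh, track)
        assert q.total_signal == pytest.approx(50 * 1.0 + 50 * 3.0)
        uniform = SignalTrack.from_records([("chr1", 0, 1000, 2.0)])
        (q2,) = quantify(stitch([peak(0, 100)], 1), uniform)
        assert q2.total_signal == pytest.approx(200.0)

    def test_zero_coverage_gets_rank_one(self):
        track = SignalTrack.from_records([("chr1", 0, 100, 5.0)])
        enhs = quantify(stitch([peak(0, 50), peak(200_000, 200_100)], 1), track)
        empty = next(e for e in enhs if e.region.start == 200_000)
        assert empty.total_signal == 0.0
        assert empty.rank == 1

    def test_matches_per_base_oracle(self, rng):
        """Interval-arithmetic area equals brute-force per-base summation."""
        for _ in range(20):
            edges = np.sort(rng.choice(np.arange(1, 500), size=8, replace=False))
            records, dense = [], np.zeros(600)
            for s, e in zip(edges[::2], edges[1::2]):
                v = float(rng.uniform(0, 5))
                records.append(("chr1", int(s), int(e), v))
                dense[s:e] = v
            track = SignalTrack.from_records(records)
            lo, hi = sorted(rng.choice(600, size=2, replace=False).tolist())
            if lo == hi:
                continue
            assert track.area("chr1", lo, hi) == pytest.approx(
                dense[lo:hi].sum(), rel=1e-6
            )


# ------------------------------------------------------------- tangency cutoff

def oracle_tangency_index(signals):
    """Brute force: the (highest) index whose slope-1 line through the scaled
    point lies at or below the entire curve."""
    s = np.sort(np.asarray(signals, float))
    n = s.size
    x = np.arange(n) / (n - 1)
    y = s / s[-1]
    best = None
    for i in range(n):
        if np.all(y - (x + (y[i] - x[i])) >= -1e-12):
            best = i
    return best


class TestSeCutoff:
    def test_parabola_tangency_at_half(self):
        n = 1001
        signals = (np.arange(n) / (n - 1)) ** 2
        cut = find_se_cutoff(signals)
        assert abs(cut.tangency_rank - 501) <= 1
        assert abs(cut.n_super - 500) <= 1
        assert cut.tangency_rank - 1 == oracle_tangency_index(signals)

    def test_single_outlier_is_super(self):
        signals = [1.0] * 999 + [1000.0]
        cut = find_se_cutoff(signals)
        assert cut.n_super == 1

    def test_flat_curve_has_no_supers(self):
        cut = find_se_cutoff([5.0] * 100)
        assert cut.n_super == 0

    def test_scale_invariance(self, rng):
        signals = np.sort(rng.exponential(10.0, size=200))
        a, b = find_se_cutoff(signals), find_se_cutoff(signals * 10.0)
        assert (a.tangency_rank, a.n_super) == (b.tangency_rank, b.n_super)

    def test_agrees_with_support_line_oracle(self, rng):
        """100 random monotone curves: implementation == brute-force oracle."""
        for _ in range(100):
            n = int(rng.integers(10, 300))
            s = np.cumsum(rng.exponential(rng.uniform(0.5, 5.0), size=n))
            cut = find_se_cutoff(s)
            assert cut.tangency_rank - 1 == oracle_tangency_index(s)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValidationError):
            find_se_cutoff([1.0, 2.0])
        with pytest.raises(ValidationError):
            find_se_cutoff([0.0, 0.0, 0.0])


# ------------------------------------------------------------------ end-to-end

class TestCallEnhancers:
    def test_super_set_is_top_k_and_contiguous(self, rng):
        genes = [gene("g", 1000)]
        peaks, records = [], []
        for i in range(50):
            s = 100_000 + i * 30_000
            v = float(rng.exponential(2.0)) + 0.1
            peaks.append(peak(s, s + 1000))
            records.append(("chr1", s, s + 1000, v))
        track = SignalTrack.from_records(records)
        enhancers, cutoff = call_enhancers(peaks, genes, track)
        supers = {e.total_signal for e in enhancers if e.is_super}
        typicals = {e.total_signal for e in enhancers if not e.is_super}
        assert cutoff.n_super == len(supers)
        if supers and typicals:
            assert min(supers) > max(typicals)

    def test_empty_distal_set(self):
        genes = [gene("g", 500)]
        track = SignalTrack.from_records([("chr1", 0, 1000, 1.0)])
        enhancers, cutoff = call_enhancers([peak(400, 600)], genes, track)
        assert enhancers == [] and cutoff is None

    def test_label_scale_invariance(self, rng):
        genes = [gene("g", 1000)]
        peaks, rec1, rec10 = [], [], []
        for i in range(30):
            s = 100_000 + i * 30_000
            v = float(rng.exponential(3.0)) + 0.1
            peaks.append(peak(s, s + 500))
            rec1.append(("chr1", s, s + 500, v))
            rec10.append(("chr1", s, s + 500, v * 10))
        e1, _ = call_enhancers(peaks, genes, SignalTrack.from_records(rec1))
        e10, _ = call_enhancers(peaks, genes, SignalTrack.from_records(rec10))
        assert [e.is_super for e in e1] == [e.is_super for e in e10]


# --------------------------------------------------------------------- profile

class TestProfileMatrix:
    def test_uniform_track_fills_every_cell(self):
        track = SignalTrack.from_records([("chr1", 0, 100_000, 1.5)])
        anchors = [peak(5_000, 6_000), peak(40_000, 41_000)]
        mat, means = profile_matrix(anchors, track, flank=1_000, nbins=10)
        assert np.allclose(mat, 1.5)
        assert np.allclose(means, 1.5)

    def test_locality_of_a_narrow_spike(self):
        anchor = peak(9_000, 11_000)  # summit at 10_000
        track = SignalTrack.from_records([("chr1", 9_990, 10_010, 4.0)])
        mat, _ = profile_matrix([anchor], track, flank=1_000, nbins=100)
        nonzero = np.nonzero(mat[0])[0]
        assert set(nonzero) == {49, 50}

    def test_column_means_match_hand_arithmetic(self):
        track = SignalTrack.from_records(
            [("chr1", 0, 1_000, 2.0), ("chr1", 1_000, 2_000, 4.0)]
        )
        # two anchors with summits 1000 and 1500; flank 500, 2 bins of 500 bp
        anchors = [peak(500, 1_501, summit=1_000), peak(1_000, 2_001, summit=1_500)]
        mat, means = profile_matrix(anchors, track, flank=500, nbins=2)
        assert np.allclose(mat, [[2.0, 4.0], [4.0, 4.0]])
        assert np.allclose(means, [3.0, 4.0])

    def test_window_clipped_at_chromosome_start(self):
        track = SignalTrack.from_records([("chr1", 0, 10_000, 1.0)])
        anchor = peak(0, 200, summit=100)
        mat, _ = profile_matrix([anchor], track, flank=1_000, nbins=10)
        # first bins lie entirely before base 0 -> zero; later bins partial/full
        assert mat[0, 0] == 0.0
        assert mat[0, -1] == 1.0
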