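"""Super-enhancer caller: stitching, ranking and the tangent-line cutoff."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aposenet.intervals import GenomicInterval, SignalTrack
from aposenet.se_caller import (
    SECallParameters,
    StitchedRegion,
    call_cutoff,
    call_super_enhancers,
    rank_regions,
    stitch_peaks,
)
from aposenet.simulate import SimulationConfig, generate_bundle
from _oracles import brute_cutoff, brute_stitch


def _iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestStitchPeaks:
    def test_gap_rule(self):
        peaks = [_iv("chr1", 0, 100), _iv("chr1", 5000, 5100), _iv("chr1", 20000, 20100)]
        regions = stitch_peaks(peaks, SECallParameters(stitch_distance=12_500))
        assert [(r.interval.start, r.interval.end) for r in regions] == [
            (0, 5100),
            (20000, 20100),
        ]
        assert len(regions[0].constituent_peaks) == 2  # gap 4900 <= 12500
        assert len(regions[1].constituent_peaks) == 1  # gap 14900 > 12500

    def test_single_peak_identity(self):
        (r,) = stitch_peaks([_iv("chr1", 10, 20)])
        assert r.interval == _iv("chr1", 10, 20)
        assert r.constituent_peaks == [_iv("chr1", 10, 20)]

    def test_duplicate_peaks_merge(self):
        (r,) = stitch_peaks([_iv("chr1", 10, 20), _iv("chr1", 10, 20)])
        assert r.interval == _iv("chr1", 10, 20)
        assert len(r.constituent_peaks) == 2

    def test_empty_input(self):
        assert stitch_peaks([]) == []

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(0, 2000),
                st.integers(1, 300),
            ),
            max_size=15,
        ),
        st.integers(0, 500),
    )
    def test_matches_union_find_oracle(self, raw, gap):
        peaks = [(c, s, s + w) for c, s, w in raw]
        expected = [
            (c, s, e) for c, s, e, _ in brute_stitch(peaks, gap)
        ]
        got = stitch_peaks(
            [_iv(*p) for p in peaks], SECallParameters(stitch_distance=gap)
        )
        assert [(r.interval.chrom, r.interval.start, r.interval.end) for r in got] == expected

    @settings(derandomize=True, max_examples=30)
    @given(st.randoms(use_true_random=False))
    def test_idempotent_and_order_invariant(self, rnd):
        peaks = [
            _iv("chr1", s, s + rnd.randint(1, 400))
            for s in (rnd.randint(0, 5000) for _ in range(12))
        ]
        params = SECallParameters(stitch_distance=300)
        once = stitch_peaks(peaks, params)
        shuffled = list(peaks)
        rnd.shuffle(shuffled)
        assert [r.interval for r in stitch_peaks(shuffled, params)] == [
            r.interval for r in once
        ]
        # restitching the stitched spans changes nothing
        again = stitch_peaks([r.interval for r in once], params)
        assert [r.interval for r in again] == [r.interval for r in once]


class TestRankRegions:
    def _region(self, start, end):
        return StitchedRegion(_iv("chr1", start, end), [_iv("chr1", start, end)])

    def test_net_signal_zero_when_chip_equals_input(self):
        track = SignalTrack.from_records([("chr1", 0, 1000, 2.0)])
        (r,) = rank_regions([self._region(0, 500)], track, track)
        assert r.net_signal == 0.0

    def test_net_signal_clamped_at_zero(self):
        chip = SignalTrack.from_records([("chr1", 0, 1000, 1.0)])
        inp = SignalTrack.from_records([("chr1", 0, 1000, 5.0)])
        (r,) = rank_regions([self._region(0, 500)], chip, inp)
        assert r.net_signal == 0.0

    def test_rank_order(self):
        # net signals 10, 30, 20 -> ranks 3, 1, 2
        chip = SignalTrack.from_records(
            [("chr1", 0, 10, 1.0), ("chr1", 100, 110, 3.0), ("chr1", 200, 210, 2.0)]
        )
        inp = SignalTrack()
        regions = [self._region(0, 10), self._region(100, 110), self._region(200, 210)]
        ranked = rank_regions(regions, chip, inp)
        by_start = {r.interval.start: r.rank for r in ranked}
        assert by_start == {100: 1, 200: 2, 0: 3}

    def test_ties_broken_by_position(self):
        chip = SignalTrack.from_records(
            [("chr1", 0, 10, 1.0), ("chr1", 100, 110, 1.0)]
        )
        ranked = rank_regions(
            [self._region(100, 110), self._region(0, 10)], chip, SignalTrack()
        )
        assert [(r.interval.start, r.rank) for r in ranked] == [(0, 1), (100, 2)]


class TestCallCutoff:
    def test_linear_curve_has_no_elbow(self):
        s = [2.0 * i for i in range(1, 11)]
        # every slope-m line passes through all points; tie-break -> top value
        assert call_cutoff(s) == s[-1]

    def test_flat_curve(self):
        assert call_cutoff([5.0] * 8) == 5.0

    def test_single_outlier_matches_oracle(self):
        s = [1.0, 1.0, 1.0, 1.0, 10.0]
        threshold, i_star, _ = brute_cutoff(s)
        assert (threshold, i_star) == (1.0, 3)  # frozen from the oracle
        assert call_cutoff(s) == threshold
        assert [x for x in s if x > threshold] == [10.0]

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="insufficient regions"):
            call_cutoff([1.0])

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            call_cutoff([3.0, 1.0, 2.0])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            n = int(rng.integers(2, 200))
            s = np.sort(rng.gamma(1.0, 10.0, size=n))
            assert call_cutoff(s) == brute_cutoff(list(s))[0]

    @pytest.mark.parametrize("scale", [0.5, 3.0, 1e6])
    def test_membership_scale_invariant(self, scale):
        rng = np.random.default_rng(42)
        s = np.sort(rng.gamma(1.0, 10.0, size=60))
        base = s > call_cutoff(s)
        scaled = (s * scale) > call_cutoff(s * scale)
        assert np.array_equal(base, scaled)

    @pytest.mark.parametrize("seed", range(5))
    def test_never_calls_all_regions_super(self, seed):
        rng = np.random.default_rng(seed)
        s = np.sort(rng.uniform(0, 100, size=int(rng.integers(2, 150))))
        threshold = call_cutoff(s)
        assert int((s > threshold).sum()) <= len(s) - 1


class TestCallSuperEnhancers:
    def test_planted_cluster_recovered(self, bundle):
        regions = call_super_enhancers(bundle.peaks, bundle.chip, bundle.input_track)
        called = {
            (r.interval.chrom, r.interval.start, r.interval.end)
            for r in regions
            if r.is_super
        }
        planted = {
            (p.interval.chrom, p.interval.start, p.interval.end)
            for p in bundle.truth.planted
        }
        assert called == planted

    def test_no_peaks_gives_no_ses(self):
        assert call_super_enhancers([], SignalTrack(), SignalTrack()) == []

    def test_equal_isolated_peaks_give_zero_ses(self):
        chip = SignalTrack.from_records(
            [("chr1", i * 100_000, i * 100_000 + 500, 4.0) for i in range(10)]
        )
        regions = call_super_enhancers(
            [_iv("chr1", i * 100_000, i * 100_000 + 500) for i in range(10)],
            chip,
            SignalTrack(),
        )
        assert sum(r.is_super for r in regions) == 0

    def test_single_isolated_equal_peaks_are_indistinguishable(self):
        """Negative control: single-peak 'clusters' at ratio 1 cannot be called."""
        cfg = SimulationConfig(seed=3, peaks_per_se=1, se_signal_ratio=1.0,
                               n_genes=50, n_background_peaks=30)
        b = generate_bundle(cfg)
        regions = call_super_enhancers(b.peaks, b.chip, b.input_track)
        assert sum(r.is_super for r in regions) == 0

    def test_output_sorted_by_rank_with_centers(self, bundle):
        regions = call_super_enhancers(bundle.peaks, bundle.chip, bundle.input_track)
        assert [r.rank for r in regions] == list(range(1, len(regions) + 1))
        for r in regions:
            assert r.center == (r.interval.start + r.interval.end) // 2
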