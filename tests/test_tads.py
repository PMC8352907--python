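"""Insulation scores, TAD boundary calling, differential insulation, overlap."""

import numpy as np
import pytest

from hicks import contact, core, synth, tads

from conftest import symmetric_matrix


def brute_force_insulation(values, s):
    """Windowed square means and log2 ratio, written independently."""
    n = values.shape[0]
    raw = np.full(n, np.nan)
    for i in range(s, n - s):
        raw[i] = values[i - s : i, i + 1 : i + 1 + s].mean()
    mean = np.nanmean(raw)
    return np.log2(raw / mean)


@pytest.fixture
def bins50():
    return core.make_bins(core.ChromSizes([("chr1", 50)]), 1)


class TestInsulationTrack:
    def test_uniform_matrix_scores_zero(self, bins50):
        m = symmetric_matrix(bins50, np.full((50, 50), 4.0))
        track = tads.insulation_track(m, square_size=5)
        assert np.allclose(track.values[track.mask], 0.0)
        assert not track.mask[:5].any() and not track.mask[-5:].any()

    def test_two_block_junction_is_global_minimum(self, bins50):
        v = np.zeros((50, 50))
        v[:25, :25] = 1.0
        v[25:, 25:] = 1.0
        m = contact.ContactMatrix(bins50, v)
        track = tads.insulation_track(m, square_size=5)
        expected = brute_force_insulation(v, 5)
        finite = np.isfinite(expected)
        # zero-window bins are masked by the implementation (log2 0 = -inf)
        zero_window = finite & np.isclose(2.0 ** expected[finite].min(), 0)
        assert np.allclose(track.values[track.mask], expected[track.mask])
        # the junction region carries the lowest windowed means
        valid_min = np.nanargmin(np.where(track.mask, track.values, np.nan))
        assert 20 <= valid_min <= 30

    def test_matches_brute_force_on_random_matrix(self, bins50):
        rng = np.random.default_rng(1)
        m = symmetric_matrix(bins50, rng.random((50, 50)) + 0.5)
        track = tads.insulation_track(m, square_size=5)
        expected = brute_force_insulation(m.values, 5)
        assert np.allclose(track.values[track.mask], expected[track.mask])

    def test_global_rescaling_leaves_track_unchanged(self, bins50):
        rng = np.random.default_rng(2)
        m = symmetric_matrix(bins50, rng.random((50, 50)) + 0.5)
        t1 = tads.insulation_track(m, square_size=5)
        m2 = contact.ContactMatrix(bins50, m.values * 11.0)
        t2 = tads.insulation_track(m2, square_size=5)
        assert np.allclose(t1.values[t1.mask], t2.values[t2.mask])

    def test_short_chromosome_fully_masked_with_warning(self):
        bins = core.make_bins(core.ChromSizes([("chr1", 8)]), 1)
        m = contact.ContactMatrix(bins, np.ones((8, 8)))
        with pytest.warns(UserWarning):
            track = tads.insulation_track(m, square_size=5)
        assert not track.mask.any()


class TestCallBoundaries:
    def test_flat_track_gives_one_whole_domain(self, bins50):
        m = symmetric_matrix(bins50, np.full((50, 50), 2.0))
        track = tads.insulation_track(m, square_size=5)
        tadset = tads.call_boundaries(track)
        assert tadset.boundaries == []
        assert len(tadset.domains) == 1
        a, b = tadset.domains[0]
        assert b - a == int(track.mask.sum())

    def test_infinite_threshold_suppresses_all_boundaries(self, bins50):
        rng = np.random.default_rng(3)
        m = symmetric_matrix(bins50, rng.random((50, 50)) + 0.2)
        track = tads.insulation_track(m, square_size=5)
        tadset = tads.call_boundaries(track, min_strength=np.inf)
        assert tadset.boundaries == []

    def test_fully_masked_track_gives_empty_tadset(self, bins50):
        track = tads.InsulationTrack(bins50, np.full(50, np.nan), np.zeros(50, bool), 5)
        tadset = tads.call_boundaries(track)
        assert tadset.boundaries == [] and tadset.domains == []

    def test_domains_partition_between_boundaries(self):
        cs = core.ChromSizes([("chr1", 8_000_000)])
        spec = synth.SyntheticSpec(cs, 40_000, tad_boundaries=[30, 80, 140], tad_tau=2.0,
                                   cis_depth=300_000, seed=11)
        recs, _ = synth.simulate_hic(spec)
        m = contact.bin_pairs(recs, spec.bins())
        bal = contact.ice_balance(contact.mask_low_coverage(m), max_iter=1000, tol=1e-10)
        tadset = tads.call_boundaries(tads.insulation_track(bal, 10))
        for (a1, b1), (a2, b2) in zip(tadset.domains[:-1], tadset.domains[1:]):
            assert b1 <= a2
        bset = tadset.boundary_bins()
        assert bset == sorted(bset)

    def test_planted_boundaries_recovered_within_one_bin(self):
        planted = [30, 80, 140]
        hits, n_called = 0, 0
        for seed in range(3):
            cs = core.ChromSizes([("chr1", 8_000_000)])
            spec = synth.SyntheticSpec(cs, 40_000, tad_boundaries=planted, tad_tau=2.0,
                                       cis_depth=300_000, seed=11 + seed)
            recs, _ = synth.simulate_hic(spec)
            m = contact.bin_pairs(recs, spec.bins())
            bal = contact.ice_balance(contact.mask_low_coverage(m), max_iter=1000, tol=1e-10)
            tadset = tads.call_boundaries(tads.insulation_track(bal, 10))
            called = tadset.boundary_bins()
            n_called += len(called)
            hits += sum(1 for p in planted if any(abs(c - p) <= 1 for c in called))
        recall = hits / (3 * len(planted))
        precision = hits / max(n_called, 1)
        assert recall >= 0.8 and precision >= 0.8


class TestDifferentialInsulation:
    def _track(self, bins, values):
        return tads.InsulationTrack(bins, values, np.isfinite(values), 5)

    def test_identical_tracks_yield_nothing(self, bins50):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(50)
        t = self._track(bins50, v)
        assert tads.differential_insulation(t, t) == []

    def test_negated_track_flags_everything(self, bins50):
        rng = np.random.default_rng(5)
        v = rng.standard_normal(50)
        t1 = self._track(bins50, v)
        t2 = self._track(bins50, -v)
        regions = tads.differential_insulation(t1, t2)
        assert len(regions) == 1
        assert (regions[0].start_bin, regions[0].end_bin) == (0, 50)

    def test_constant_windows_count_as_not_different(self, bins50):
        t1 = self._track(bins50, np.zeros(50))
        t2 = self._track(bins50, np.ones(50))
        assert tads.differential_insulation(t1, t2) == []

    def test_planted_reorganised_segment_found(self):
        # boundary reorganisation: inside bins 20-50 the periodic insulation
        # profile of condition 2 is phase-inverted (old minima become maxima),
        # the realistic signature of gained/lost boundaries
        bins = core.make_bins(core.ChromSizes([("chr1", 70)]), 1)
        overlaps = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            i = np.arange(70)
            base = 0.3 * np.sin(2 * np.pi * i / 14) + 0.05 * rng.standard_normal(70)
            v2 = base.copy()
            seg = np.arange(20, 50)
            v2[20:50] = 0.3 * np.sin(2 * np.pi * seg / 14 + np.pi) + 0.05 * rng.standard_normal(30)
            t1 = tads.InsulationTrack(bins, base, np.isfinite(base), 5)
            t2 = tads.InsulationTrack(bins, v2, np.isfinite(v2), 5)
            regions = tads.differential_insulation(t1, t2)
            assert len(regions) == 1
            covered = set(range(regions[0].start_bin, regions[0].end_bin))
            overlaps.append(len(covered & set(range(20, 50))) / 30)
            assert not covered - set(range(10, 60))  # nothing far from the segment
        assert np.mean(overlaps) >= 0.8

    def test_symmetric_in_inputs(self, bins50):
        rng = np.random.default_rng(7)
        v1 = np.cumsum(rng.standard_normal(50))
        v2 = v1.copy()
        v2[10:30] = np.cumsum(rng.standard_normal(20))
        t1, t2 = self._track(bins50, v1), self._track(bins50, v2)
        r12 = tads.differential_insulation(t1, t2)
        r21 = tads.differential_insulation(t2, t1)
        assert [(r.start_bin, r.end_bin) for r in r12] == [(r.start_bin, r.end_bin) for r in r21]

    def test_grid_mismatch_rejected(self, bins50):
        other = core.make_bins(core.ChromSizes([("chr1", 60)]), 1)
        t1 = self._track(bins50, np.zeros(50))
        t2 = tads.InsulationTrack(other, np.zeros(60), np.ones(60, bool), 5)
        with pytest.raises(core.AlignmentError):
            tads.differential_insulation(t1, t2)


class TestBoundaryOverlap:
    def _tadset(self, bins, bounds):
        return tads.TadSet(bins, [(b, 1.0) for b in bounds], [])

    def test_identical_sets_all_shared(self, bins50):
        t = self._tadset(bins50, [10, 25, 40])
        res = tads.boundary_overlap(t, t)
        assert res["shared"] == [10, 25, 40] and res["gained"] == [] and res["lost"] == []

    def test_one_extra_boundary_is_gained(self, bins50):
        t1 = self._tadset(bins50, [10, 25])
        t2 = self._tadset(bins50, [10, 25, 40])
        res = tads.boundary_overlap(t1, t2)
        assert res["gained"] == [40] and res["lost"] == []

    def test_jitter_within_slack_still_shared(self, bins50):
        rng = np.random.default_rng(3)
        bounds = [10, 20, 30, 40]
        jittered = [b + int(rng.integers(-1, 2)) for b in bounds]
        res = tads.boundary_overlap(self._tadset(bins50, bounds), self._tadset(bins50, jittered), slack=1)
        assert res["gained"] == [] and res["lost"] == []

    def test_translation_equivariance_of_insulation_minima(self):
        # shifting the block structure shifts the insulation minimum identically
        bins = core.make_bins(core.ChromSizes([("chr1", 60)]), 1)
        for cut in (25, 31):
            v = np.zeros((60, 60))
            v[:cut, :cut] = 1.0
            v[cut:, cut:] = 1.0
            v += 0.01  # keep windows nonzero
            m = contact.ContactMatrix(bins, v)
            track = tads.insulation_track(m, square_size=5)
            arg = np.nanargmin(np.where(track.mask, track.values, np.nan))
            assert abs(arg - cut) <= 1
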