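"""EAT extraction: border binning, window accounting, parameter recovery."""

import numpy as np
import pytest

from eatmap import (EATWindows, GroundTruth, eat_profile, extract_eat,
                    simulate_recording, time_to_nearest_border)
from eatmap.detection import RBCTransit, detect_transits, estimate_baseline
from eatmap.exceptions import (EatmapError, InvariantError,
                               WindowUnsatisfiedError)


def brute_force_distance(times_ms, transits):
    """O(N*M) oracle: distance to every border of every transit, signed by
    interval membership."""
    borders = []
    for tr in transits:
        borders += [tr.entry_ms, tr.exit_ms]
    dist = np.empty(len(times_ms))
    inside = np.zeros(len(times_ms), dtype=bool)
    for i, t in enumerate(times_ms):
        dist[i] = min(abs(t - b) for b in borders)
        inside[i] = any(tr.entry_ms < t < tr.exit_ms for tr in transits)
        if inside[i]:
            dist[i] = -dist[i]
    return dist, inside


def analyze(rec, **window_kw):
    transits = detect_transits(rec.fluorescence,
                               estimate_baseline(rec.fluorescence))
    return extract_eat(rec, transits, EATWindows(**window_kw))


class TestTimeToNearestBorder:
    def test_hand_cases(self):
        transits = [RBCTransit(10.0, 20.0, 1.0)]
        dist, inside = time_to_nearest_border(np.array([25.0, 12.0]), transits)
        assert dist[0] == pytest.approx(5.0) and not inside[0]
        assert dist[1] == pytest.approx(-2.0) and inside[1]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        entries = np.sort(rng.uniform(0, 10_000, 100))
        transits = []
        prev_end = -1.0
        for e in entries:
            start = max(e, prev_end + 0.5)
            end = start + rng.uniform(1.0, 20.0)
            transits.append(RBCTransit(start, end, 1.0))
            prev_end = end
        times = rng.uniform(0, transits[-1].exit_ms + 50, 10_000)
        dist, inside = time_to_nearest_border(times, transits)
        dist_bf, inside_bf = brute_force_distance(times, transits)
        assert np.array_equal(inside, inside_bf)
        assert np.max(np.abs(dist - dist_bf)) == 0.0

    def test_no_transits_flagged_undefined(self):
        dist, inside = time_to_nearest_border(np.array([1.0, 2.0]), [])
        assert np.all(np.isnan(dist))
        assert not inside.any()

    def test_overlapping_transits_rejected(self):
        with pytest.raises(InvariantError):
            time_to_nearest_border(np.array([0.0]),
                                   [RBCTransit(0, 10, 1), RBCTransit(5, 15, 1)])


class TestExtractEAT:
    def test_recovery_within_in_vivo_sd_scale(self, acq, calib):
        """Po2InterRBC within 3 and Po2RBC within 6 mm Hg in >= 90% of
        seeds (tolerances on the scale of within-capillary scatter)."""
        hits_inter = hits_rbc = 0
        n_seeds = 10
        for seed in range(n_seeds):
            truth = GroundTruth(po2_rbc_true=60.0, po2_inter_true=23.0,
                                rbc_flow_true=30.0, hematocrit_true=35.0,
                                seed=seed)
            rec, _ = simulate_recording(truth, acq, 20_000, calib)
            res = analyze(rec)
            hits_inter += abs(res.po2_inter_rbc - 23.0) <= 3.0
            hits_rbc += abs(res.po2_rbc - 60.0) <= 6.0
        assert hits_inter >= 0.9 * n_seeds
        assert hits_rbc >= 0.9 * n_seeds

    def test_flat_profile_degenerate_eat(self, acq, calib):
        """No EAT: all three Po2 read-outs agree within joint fit error."""
        truth = GroundTruth(po2_rbc_true=40.0, po2_inter_true=40.0, seed=21)
        rec, _ = simulate_recording(truth, acq, 20_000, calib)
        res = analyze(rec)
        se = 3 * max(res.diagnostics["rbc"]["po2_se"],
                     res.diagnostics["inter_rbc"]["po2_se"], 0.3)
        assert abs(res.po2_rbc - res.po2_inter_rbc) < 2 * se
        assert abs(res.po2_mean - 40.0) < 2 * se

    def test_po2_ordering_with_positive_eat(self, acq, calib):
        """Po2RBC > Po2Mean > Po2InterRBC whenever the EAT amplitude is
        positive."""
        for seed in range(6):
            truth = GroundTruth(po2_rbc_true=55.0 + 2 * seed,
                                po2_inter_true=20.0 + seed, seed=seed)
            rec, _ = simulate_recording(truth, acq, 12_000, calib)
            res = analyze(rec)
            assert res.po2_rbc > res.po2_mean > res.po2_inter_rbc

    def test_window_partition_audit(self, small_recording):
        """Border and mid-distance pools are disjoint; every decay is in
        the Po2Mean pool."""
        rec, _ = small_recording
        res = analyze(rec)
        d = res.diagnostics
        assert d["mean"]["n_decays"] == rec.n_cycles
        assert d["rbc"]["n_decays"] + d["inter_rbc"]["n_decays"] <= rec.n_cycles
        assert d["rbc"]["n_decays"] > 0 and d["inter_rbc"]["n_decays"] > 0

    def test_window_dilution_monotonicity(self, acq, calib):
        """Symmetric-window convention: shrinking the border half-width
        sheds relaxing-plasma decays, so Po2RBC must not decrease."""
        truth = GroundTruth(po2_rbc_true=70.0, po2_inter_true=15.0,
                            decay_amplitude=6.0, seed=31)
        rec, _ = simulate_recording(truth, acq, 30_000, calib)
        estimates = [analyze(rec, rbc_half_width_ms=w,
                             border_mode="symmetric").po2_rbc
                     for w in (2.0, 1.25, 0.5)]
        assert estimates[1] >= estimates[0] - 0.5
        assert estimates[2] >= estimates[1] - 0.5

    def test_inside_window_undiluted_vs_symmetric(self, acq, calib):
        """The symmetric window mixes in relaxing plasma and reads lower
        than the inside-anchored default."""
        truth = GroundTruth(po2_rbc_true=70.0, po2_inter_true=15.0, seed=32)
        rec, _ = simulate_recording(truth, acq, 20_000, calib)
        inside = analyze(rec, border_mode="inside").po2_rbc
        symmetric = analyze(rec, border_mode="symmetric").po2_rbc
        assert symmetric < inside

    def test_fast_flow_window_unsatisfied(self, acq, calib):
        """Gaps shorter than twice the guard leave no mid-distance pool."""
        truth = GroundTruth(rbc_flow_true=80.0, hematocrit_true=60.0, seed=33)
        rec, transits = simulate_recording(truth, acq, 4000, calib)
        with pytest.raises(WindowUnsatisfiedError, match="fast flow"):
            extract_eat(rec, transits, EATWindows(inter_guard_ms=6.0))

    def test_no_complete_transit_rejected(self, acq):
        from eatmap import Recording
        rec = Recording(acq, np.full(100, 50, dtype=np.int64),
                        np.zeros((100, acq.n_bins), dtype=np.uint16))
        with pytest.raises(EatmapError, match="no complete"):
            extract_eat(rec, [])


@pytest.fixture(scope="module")
def profiled(acq, calib):
    truth = GroundTruth(seed=55)
    rec, transits = simulate_recording(truth, acq, 40_000, calib)
    prof = eat_profile(rec, transits, bin_width_ms=0.5, calib=calib,
                       span_ms=(-4.0, 8.0))
    return truth, prof


class TestEATProfile:

    def test_profile_tracks_generating_curve(self, profiled):
        from eatmap import po2_at
        truth, prof = profiled
        ok = np.isfinite(prof.po2_mmhg)
        assert ok.sum() >= 10
        expected = po2_at(prof.bin_centers_ms[ok], truth)
        assert np.max(np.abs(prof.po2_mmhg[ok] - expected)) < 5.0
        # plateau inside, relaxation outside
        inside = prof.bin_centers_ms < 0
        assert np.nanstd(prof.po2_mmhg[ok & inside]) < 2.5

    def test_flat_profile_is_flat(self, acq, calib):
        truth = GroundTruth(po2_rbc_true=40.0, po2_inter_true=40.0, seed=56)
        rec, transits = simulate_recording(truth, acq, 30_000, calib)
        prof = eat_profile(rec, transits, calib=calib, span_ms=(-4.0, 8.0))
        ok = np.isfinite(prof.po2_mmhg)
        assert np.nanmax(np.abs(prof.po2_mmhg[ok] - 40.0)) < 4.0

    def test_sparse_bins_masked(self, profiled):
        _, prof = profiled
        sparse = prof.n_decays < 500
        assert np.all(np.isnan(prof.po2_mmhg[sparse]))


class TestEATWindowsValidation:
    def test_guard_must_cover_half_width(self):
        with pytest.raises(InvariantError):
            EATWindows(rbc_half_width_ms=2.0, inter_guard_ms=1.0)

    def test_bad_mode_rejected(self):
        with pytest.raises(InvariantError):
            EATWindows(border_mode="sideways")
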