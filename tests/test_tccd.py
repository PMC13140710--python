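"""Noise modeling, peak finding and coincidence detection."""

import numpy as np
import pytest

from _oracles import best_matching_brute_force
from phasekin import synth, tccd
from phasekin.io import PhotonTrace


def _spike_trace(spike_bins, n_bins=1000, base=10, spike=60, bin_width_ms=1.0):
    counts = np.full(n_bins, base, dtype=float)
    for b, h in spike_bins:
        counts[b] = h if h is not None else spike
    return PhotonTrace(bin_width_ms=bin_width_ms, counts=counts, channel="x")


def test_fwhm_and_threshold_identities():
    nm = tccd.NoiseModel(p_center=10.0, sigma=1.0)
    assert nm.fwhm == pytest.approx(2.3548200450309493, abs=1e-9)
    assert nm.threshold == pytest.approx(10.0 + 4.709640090061899, abs=1e-9)
    assert nm.threshold - nm.p_center == pytest.approx(2 * nm.fwhm, abs=1e-12)
    assert tccd.FWHM_PER_SIGMA == pytest.approx(2.354820045, abs=1e-9)


def test_noise_fit_on_pure_gaussian_background(rng):
    counts = np.maximum(rng.normal(10.0, 2.0, 100_000), 0)
    nm = tccd.fit_noise(PhotonTrace(bin_width_ms=1.0, counts=np.rint(counts)))
    assert nm.p_center == pytest.approx(10.0, rel=0.02)
    assert nm.fwhm == pytest.approx(2.0 * tccd.FWHM_PER_SIGMA, rel=0.02)
    assert nm.threshold == pytest.approx(10.0 + 4.0 * tccd.FWHM_PER_SIGMA, rel=0.02)


def test_noise_fit_robust_to_burst_contamination(rng):
    base = np.rint(np.maximum(rng.normal(10.0, 2.0, 50_000), 0))
    clean = tccd.fit_noise(PhotonTrace(bin_width_ms=1.0, counts=base))
    dirty_counts = base.copy()
    idx = rng.choice(len(base), size=len(base) // 100, replace=False)
    dirty_counts[idx] += 40.0  # 1% of bins carry 20-sigma bursts
    dirty = tccd.fit_noise(PhotonTrace(bin_width_ms=1.0, counts=dirty_counts))
    assert abs(dirty.threshold / clean.threshold - 1) < 0.05


def test_zero_variance_trace_is_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        tccd.fit_noise(PhotonTrace(bin_width_ms=1.0, counts=np.full(200, 7)))


def test_minimum_separation_rule():
    nm = tccd.NoiseModel(p_center=10.0, sigma=2.0)
    close = _spike_trace([(100, 50), (120, 60)])  # 20 ms apart
    peaks = tccd.find_peaks(close, nm, min_separation_ms=40.0)
    assert len(peaks) == 1
    assert peaks.heights[0] == 60  # the taller survives
    assert peaks.times_ms[0] == pytest.approx(120.5)

    far = _spike_trace([(100, 50), (160, 60)])  # 60 ms apart
    assert len(tccd.find_peaks(far, nm, min_separation_ms=40.0)) == 2


def test_subthreshold_peaks_ignored():
    nm = tccd.NoiseModel(p_center=10.0, sigma=2.0)  # threshold ~19.4
    tr = _spike_trace([(100, 15), (300, 19), (500, 25)])
    peaks = tccd.find_peaks(tr, nm)
    assert list(peaks.heights) == [25]
    assert (peaks.heights > nm.threshold).all()


def test_burst_detection_rate_against_truth():
    """500 spaced bursts of ~10 sigma: >= 99% found, few false positives."""
    truth = synth.TccdTruth(n_bursts_per_channel=500, coincident_fraction=0.0,
                            burst_amplitude=20.0, burst_width_ms=15.0,
                            bg_mean=10.0, bg_sd=2.0, duration_s=150.0)
    tr, _, info = synth.gen_photon_pair(truth, seed=12)
    nm, peaks = tccd.detect(tr)
    matched = tccd.match_pairs(peaks.times_ms, info["a_times_ms"], window_ms=20.0)
    assert len(matched) >= 0.99 * 500
    assert len(peaks) - len(matched) <= 5  # false positives bounded by the tail


def test_coincidence_trivial_cases():
    a = tccd.PeakSet(times_ms=np.array([10.0, 50.0, 90.0]),
                     heights=np.array([30.0, 40.0, 50.0]), channel="a",
                     duration_ms=1000.0)
    same = tccd.PeakSet(times_ms=a.times_ms.copy(), heights=a.heights.copy(),
                        channel="b", duration_ms=1000.0)
    res = tccd.coincidence(a, same, window_ms=10.0, reference="a")
    assert res.percent_coincident_ref == pytest.approx(100.0)

    offset = tccd.PeakSet(times_ms=a.times_ms + 15.0, heights=a.heights,
                          channel="b", duration_ms=1000.0)
    res = tccd.coincidence(a, offset, window_ms=10.0, reference="a")
    assert res.n_coincident == 0
    assert res.percent_coincident_ref == 0.0


def test_empty_reference_channel_is_undefined_not_zero():
    empty = tccd.PeakSet(times_ms=np.array([]), heights=np.array([]),
                         channel="a", duration_ms=1000.0)
    other = tccd.PeakSet(times_ms=np.array([10.0]), heights=np.array([30.0]),
                         channel="b", duration_ms=1000.0)
    res = tccd.coincidence(empty, other, reference="a")
    assert res.undefined
    assert np.isnan(res.percent_coincident_ref)


def test_matching_is_symmetric_and_one_to_one(rng):
    ta = np.sort(rng.uniform(0, 1000, 40))
    tb = np.sort(rng.uniform(0, 1000, 35))
    ab = tccd.match_pairs(ta, tb, window_ms=10.0)
    ba = tccd.match_pairs(tb, ta, window_ms=10.0)
    assert {(x, y) for x, y in ab} == {(y, x) for x, y in ba}
    assert len({p[0] for p in ab}) == len(ab)  # no peak used twice
    assert len({p[1] for p in ab}) == len(ab)
    assert all(abs(x - y) <= 10.0 for x, y in ab)


def test_matching_is_optimal_on_small_instances(rng):
    """Greedy nearest-dt matching attains the exhaustive maximum pairing
    when candidate pairs do not overlap (peaks spaced beyond twice the
    window, so each peak has at most one possible partner); on arbitrary
    instances it never exceeds the maximum or reuses a peak."""
    window = 12.0
    for _ in range(30):
        na, nb = rng.integers(1, 6), rng.integers(1, 6)
        ta = np.cumsum(rng.uniform(4 * window, 6 * window, na))
        tb = np.sort(ta[rng.permutation(na)[:min(na, nb)]] + rng.uniform(
            -1.5 * window, 1.5 * window, min(na, nb)))
        got = len(tccd.match_pairs(ta, tb, window_ms=window))
        best = best_matching_brute_force(list(ta), list(tb), window)
        assert got == best
    for _ in range(30):
        na, nb = rng.integers(1, 6), rng.integers(1, 6)
        ta = np.sort(rng.uniform(0, 100, na))
        tb = np.sort(rng.uniform(0, 100, nb))
        pairs = tccd.match_pairs(ta, tb, window_ms=window)
        best = best_matching_brute_force(list(ta), list(tb), window)
        assert len(pairs) <= best
        assert len({p[0] for p in pairs}) == len(pairs)
        assert len({p[1] for p in pairs}) == len(pairs)


def test_estimated_coincidence_tracks_truth_at_half():
    truth = synth.TccdTruth(n_bursts_per_channel=1000, coincident_fraction=0.5,
                            burst_amplitude=40.0, burst_width_ms=15.0,
                            duration_s=240.0)
    a, b, info = synth.gen_photon_pair(truth, seed=2025)
    _, pa = tccd.detect(a)
    _, pb = tccd.detect(b)
    res = tccd.coincidence(pa, pb, window_ms=10.0, reference="a")
    se = 100 * np.sqrt(0.5 * 0.5 / 1000)
    assert abs(res.percent_coincident_ref - 50.0) <= 3 * se


def test_coincidence_estimator_error_shrinks_with_n():
    """Consistency: mean |error| over seeds decreases from 100 to 1600 bursts."""
    errs = {}
    # dilute acquisitions (1.2 s per burst) keep chance coincidences <1%
    for n, dur in ((100, 120.0), (400, 480.0), (1600, 1920.0)):
        truth = synth.TccdTruth(n_bursts_per_channel=n, coincident_fraction=0.5,
                                burst_amplitude=40.0, burst_width_ms=15.0,
                                duration_s=dur)
        e = []
        for seed in range(3):
            a, b, _ = synth.gen_photon_pair(truth, seed=seed)
            _, pa = tccd.detect(a)
            _, pb = tccd.detect(b)
            res = tccd.coincidence(pa, pb)
            e.append(abs(res.percent_coincident_ref - 50.0))
        errs[n] = np.mean(e)
    assert errs[1600] < errs[100]
    assert errs[1600] < 2.0  # within ~2 binomial SE at n=1600


def test_chance_coincidence_diagnostic_scales_with_density():
    rng = np.random.default_rng(5)
    sparse = tccd.PeakSet(times_ms=np.sort(rng.uniform(0, 10_000, 10)),
                          heights=np.ones(10), duration_ms=10_000.0)
    dense = tccd.PeakSet(times_ms=np.sort(rng.uniform(0, 10_000, 200)),
                         heights=np.ones(200), duration_ms=10_000.0)
    few = tccd.chance_coincidence(sparse, sparse, n_iter=50, seed=1)
    many = tccd.chance_coincidence(dense, dense, n_iter=50, seed=1)
    assert many > few
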