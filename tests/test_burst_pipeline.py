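import math

import numpy as np
import pytest

from nickfret.burst_pipeline import (Burst, CorrectionFactors, FretHistogram,
                                     alex_2cde, burst_anisotropy,
                                     burst_lifetime_mle, burst_rate_filter,
                                     burst_search, bva, correct_burst,
                                     correct_counts, fit_gaussians,
                                     propagate_fret_error, select_fret_events,
                                     static_fret_line,
                                     time_window_histograms)
from nickfret.photon_sim import (CH_AA_P, CH_DA_P, CH_DD_P, FretState,
                                 PhotonStream, StreamConfig, simulate_stream)


def make_stream(times_s, channels, microtimes_s=None):
    times_s = np.asarray(times_s, dtype=float)
    order = np.argsort(times_s)
    macro = (times_s[order] / 12.5e-9).astype(np.int64)
    ch = np.asarray(channels, dtype=np.int8)[order]
    micro = (np.zeros(len(times_s)) if microtimes_s is None
             else np.asarray(microtimes_s)[order])
    return PhotonStream(macrotime=macro, channel=ch,
                        microtime=(micro / 16e-12).astype(np.int32),
                        macrotime_tick=12.5e-9, microtime_unit=16e-12,
                        duration=float(times_s.max() + 1.0), period=50e-9,
                        pulse_shift=20e-9)


def brute_force_burst_search(times, window, min_in_window, min_total):
    """O(N^2) oracle for the centered all-photon sliding-window search."""
    n = len(times)
    eligible = np.zeros(n, dtype=bool)
    for i in range(n):
        count = np.sum((times >= times[i] - window / 2)
                       & (times <= times[i] + window / 2))
        eligible[i] = count >= min_in_window
    runs = []
    i = 0
    while i < n:
        if eligible[i]:
            j = i
            while j + 1 < n and eligible[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    bursts = []
    for i0, i1 in runs:
        start = i0
        for k in range(i0, i1):
            if times[k + 1] - times[k] > window:  # unbridgeable gap
                bursts.append((start, k))
                start = k + 1
        bursts.append((start, i1))
    return [(a, b) for a, b in bursts if b - a + 1 > min_total]


class TestBurstSearch:
    def test_empty_stream(self):
        stream = make_stream([0.0], [CH_DD_P])
        assert burst_search(stream, min_total=50) == []

    def test_single_dense_burst_captured_whole(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0.5000, 0.5010, 200))  # 200 ph in 1 ms
        stream = make_stream(times, [CH_DD_P] * 200)
        bursts = burst_search(stream)
        assert len(bursts) == 1
        assert bursts[0].n_photons == 200

    def test_small_cluster_fails_min_total(self):
        rng = np.random.default_rng(1)
        times = np.sort(rng.uniform(0.1, 0.1001, 40))
        stream = make_stream(times, [CH_DD_P] * 40)
        assert burst_search(stream) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        # sparse background plus several dense clusters
        bg = rng.uniform(0, 2.0, 800)
        clusters = [rng.normal(c, 4e-4, rng.integers(30, 120))
                    for c in (0.3, 0.7, 1.1, 1.5)]
        times = np.sort(np.concatenate([bg] + clusters))
        stream = make_stream(times, [CH_DD_P] * len(times))
        got = [(b.first, b.last) for b in burst_search(stream)]
        t = stream.times  # oracle runs on the quantized times
        expected = brute_force_burst_search(t, 500e-6, 10, 50)
        assert got == expected


class TestBurstRateFilter:
    @pytest.mark.parametrize("n_bursts,passed", [(10, True), (13, True),
                                                 (14, False)])
    def test_strictly_more_than_cut(self, n_bursts, passed):
        bursts = [Burst(first=i, last=i, start=i / n_bursts * 0.99,
                        stop=i / n_bursts * 0.99 + 1e-3,
                        counts=np.zeros(6, dtype=np.int64))
                  for i in range(n_bursts)]
        table = burst_rate_filter(bursts, duration=1.0)
        assert bool(table["passed"].iloc[0]) is passed


class TestCorrections:
    def test_proximity_ratio_without_corrections(self):
        e, s, ok = correct_counts(50, 50, 100, 1e-3, CorrectionFactors())
        assert ok and e == pytest.approx(0.5) and s == pytest.approx(0.5)

    def test_zero_acceptor_signal(self):
        e, s, ok = correct_counts(80, 0, 80, 1e-3, CorrectionFactors())
        assert ok and e == pytest.approx(0.0)

    def test_hand_evaluated_factors(self):
        # F_DA' = 50 - 0.05*60 - 0.05*80 = 43; den = 1.2*60 + 43 = 115
        cf = CorrectionFactors(alpha=0.05, delta=0.05, gamma=1.2, beta=1.0)
        e, s, ok = correct_counts(60, 50, 80, 1e-3, cf)
        assert e == pytest.approx(43.0 / 115.0)
        assert s == pytest.approx(115.0 / (115.0 + 80.0))

    def test_invalid_burst_flagged(self):
        cf = CorrectionFactors(b_dd=100.0, b_da=100.0, b_aa=100.0)
        e, s, ok = correct_counts(5, 5, 5, 1e-3, cf)
        assert not ok

    def test_round_trip_recovers_ground_truth(self, static_stream,
                                              static_bursts):
        """Generator oracle: corrected E of >= 200-photon bursts is an
        unbiased estimate of the configured efficiency."""
        e = np.array([b.e_corr for b in static_bursts
                      if b.valid and b.n_photons >= 200])
        assert len(e) > 100
        assert abs(e.mean() - 0.5) < 0.01


class TestAlex2cde:
    def test_uniform_burst_passes(self):
        times = np.arange(300) * 10e-6
        ch = np.where(np.arange(300) % 3 == 0, CH_AA_P, CH_DD_P)
        stream = make_stream(times, ch)
        b = burst_search(stream)[0]
        assert alex_2cde(b, stream) < 10.0

    def test_acceptor_bleach_rejected(self):
        times = np.arange(300) * 10e-6
        ch = np.where(np.arange(300) < 100, CH_AA_P, CH_DD_P)
        stream = make_stream(times, ch)
        b = burst_search(stream)[0]
        assert alex_2cde(b, stream) > 10.0

    def test_no_red_photons_is_maximal(self):
        times = np.arange(100) * 10e-6
        stream = make_stream(times, [CH_DD_P] * 100)
        b = burst_search(stream)[0]
        assert alex_2cde(b, stream) == math.inf

    def test_matches_direct_formula_on_toy_burst(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, 2e-3, 60))
        ch = rng.choice([CH_DD_P, CH_AA_P], size=60, p=[0.7, 0.3])
        stream = make_stream(times, ch)
        bursts = burst_search(stream, min_in_window=5, min_total=20)
        b = bursts[0]
        t = stream.times[b.first:b.last + 1]
        c = stream.channel[b.first:b.last + 1]
        td, ta = t[c == CH_DD_P], t[c == CH_AA_P]
        tau = 100e-6
        kde = lambda x, src: np.exp(-np.abs(x[:, None] - src[None, :])
                                    / tau).sum(axis=1)
        br_da = np.sum(kde(td, ta) / (kde(td, td) - 1)) / len(ta)
        br_ad = np.sum(kde(ta, td) / (kde(ta, ta) - 1)) / len(td)
        expected = 100 - 50 * (br_da + br_ad)
        assert alex_2cde(b, stream) == pytest.approx(expected, abs=1e-9)


class TestEventFilters:
    def _burst(self, **kw):
        base = dict(first=0, last=149, start=0.0, stop=5e-3,
                    counts=np.array([40, 30, 40, 30, 5, 5]),
                    e_corr=0.5, s_corr=0.5, valid=True, alex_2cde=1.0)
        base.update(kw)
        return Burst(**base)

    def test_stoichiometry_window(self):
        kept, log = select_fret_events([self._burst(s_corr=0.8)])
        assert kept == [] and log["stoichiometry"] == 0

    def test_min_photon_edge(self):
        b = self._burst(counts=np.array([33, 33, 33, 0, 0, 0]))  # 99 total
        kept, _ = select_fret_events([b])
        assert kept == []

    def test_tightening_never_increases_survivors(self, static_bursts):
        loose, _ = select_fret_events(static_bursts, min_photons=50,
                                      alex_2cde_max=np.inf)
        tight, _ = select_fret_events(static_bursts, min_photons=100,
                                      alex_2cde_max=np.inf)
        tighter, _ = select_fret_events(static_bursts, min_photons=100,
                                        s_window=(0.4, 0.6),
                                        alex_2cde_max=np.inf)
        assert len(loose) >= len(tight) >= len(tighter)

    def test_species_mixture_resolved_by_stoichiometry(self):
        from nickfret.photon_sim import merge_streams
        # donor-only (S ~ 1) + acceptor-only (S ~ 0) + FRET species
        donor_only = StreamConfig(duration=20.0, seed=1, burst_rate=3,
                                  brightness=150, stoichiometry=0.98,
                                  states=(FretState(0.0),),
                                  background=(0.0,) * 6)
        acceptor_only = StreamConfig(duration=20.0, seed=2, burst_rate=3,
                                     brightness=150, stoichiometry=0.05,
                                     states=(FretState(1.0),),
                                     background=(0.0,) * 6)
        fret = StreamConfig(duration=20.0, seed=3, burst_rate=3,
                            brightness=150, states=(FretState(0.6),),
                            background=(0.0,) * 6)
        stream = merge_streams([simulate_stream(c)[0]
                                for c in (donor_only, acceptor_only, fret)])
        bursts = burst_search(stream)
        cf = CorrectionFactors()
        for b in bursts:
            correct_burst(b, cf)
        kept, _ = select_fret_events(bursts, alex_2cde_max=np.inf)
        e = np.array([b.e_corr for b in kept])
        frac_fret = np.mean(np.abs(e - 0.6) < 0.2)
        assert frac_fret > 0.9


class TestErrorPropagation:
    def test_only_background_term_survives_at_unit_efficiency(self):
        total, terms = propagate_fret_error(1.0, CorrectionFactors())
        assert total == pytest.approx(1.0 / 75.0)
        assert terms["gamma"] == 0.0 and terms["delta"] == 0.0

    def test_hand_evaluated_mid_efficiency(self):
        cf = CorrectionFactors(alpha=0.05, delta=0.05)
        total, terms = propagate_fret_error(0.5, cf)
        # term-by-term quadrature evaluated by hand
        assert terms["gamma"] == pytest.approx(0.025)
        assert terms["b_dd"] == pytest.approx(0.525 / 75.0)
        assert total == pytest.approx(0.027, abs=5e-4)

    def test_stays_within_stated_range(self):
        cf = CorrectionFactors(alpha=0.05, delta=0.05)
        for e in np.linspace(0.2, 0.95, 16):
            total, terms = propagate_fret_error(float(e), cf)
            assert 0.01 <= total <= 0.03
            assert all(v >= 0 for v in terms.values())

    def test_zero_uncertainty_gives_zero(self):
        cf = CorrectionFactors(alpha=0.05, delta=0.05, rel_alpha=0.0,
                               rel_beta=0.0, rel_gamma=0.0,
                               delta_delta=0.0, delta_b=0.0)
        total, _ = propagate_fret_error(0.5, cf)
        assert total == 0.0


class TestGaussianFits:
    def test_single_state_peak_recovered(self, static_bursts):
        kept, _ = select_fret_events(static_bursts, alex_2cde_max=np.inf)
        hist = FretHistogram.from_bursts(kept, bins=100)
        fit = fit_gaussians(hist, n_components=1)
        mu, sd, amp = fit.components[0]
        assert mu == pytest.approx(0.50, abs=0.01)

    def test_delta_histogram_mean_at_bin_center(self):
        counts = np.zeros(50)
        counts[24] = 500
        counts[[10, 12, 14, 16, 18, 20, 30, 32, 34]] = 1  # sparse shoulders
        hist = FretHistogram(edges=np.linspace(0, 1, 51), counts=counts)
        fit = fit_gaussians(hist, n_components=1)
        assert fit.components[0][0] == pytest.approx(hist.centers[24],
                                                     abs=0.01)

    def test_three_state_mixture(self):
        """Three static species at E = 0.51 / 0.70 / 0.85 resolved to
        within 0.02 (generator ground truth)."""
        cfg = StreamConfig(duration=120.0, seed=17, burst_rate=8,
                           brightness=400,
                           states=(FretState(0.51), FretState(0.70),
                                   FretState(0.85)),
                           background=(0.1,) * 6)
        stream, _ = simulate_stream(cfg)
        bursts = burst_search(stream)
        cf = CorrectionFactors(b_dd=0.2, b_da=0.2, b_aa=0.2)
        for b in bursts:
            correct_burst(b, cf)
        kept, _ = select_fret_events(bursts, min_photons=250,
                                     alex_2cde_max=np.inf)
        hist = FretHistogram.from_bursts(kept, bins=60)
        fit = fit_gaussians(hist, n_components=3)
        means = sorted(c[0] for c in fit.components)
        for got, want in zip(means, (0.51, 0.70, 0.85)):
            assert got == pytest.approx(want, abs=0.02)


class TestLifetimeAndAnisotropy:
    def test_mle_consistency(self):
        # estimator consistency: per-draw scatter is ~tau/sqrt(n), the
        # mean over draws converges on the truth
        rng = np.random.default_rng(0)
        estimates = [burst_lifetime_mle(rng.exponential(2.0, 200) % 20.0,
                                        20.0) for _ in range(20)]
        assert np.std(estimates, ddof=1) < 0.3
        assert np.mean(estimates) == pytest.approx(2.0, abs=0.15)

    def test_mle_with_uniform_background(self):
        rng = np.random.default_rng(1)
        t = np.concatenate([rng.exponential(2.0, 800) % 20.0,
                            rng.uniform(0, 20.0, 200)])
        est = burst_lifetime_mle(t, 20.0, background_fraction=0.2)
        assert est == pytest.approx(2.0, abs=0.25)

    def test_identical_microtimes_rejected(self):
        with pytest.raises(ValueError):
            burst_lifetime_mle(np.full(30, 1.0), 20.0)

    def test_isotropic_case(self):
        assert burst_anisotropy(100.0, 95.0, l1=0, l2=0, g_factor=0.95) == \
            pytest.approx(0.0)

    def test_hand_evaluated_values(self):
        assert burst_anisotropy(2.0, 1.0, l1=0, l2=0, g_factor=1.0) == \
            pytest.approx(0.25)
        assert burst_anisotropy(2.0, 1.0) == pytest.approx(0.273, abs=1e-3)


@pytest.fixture(scope="module")
def dynamic_bursts():
    cfg = StreamConfig(duration=60.0, seed=31, burst_rate=5,
                       brightness=250,
                       states=(FretState(0.15), FretState(0.85)),
                       transition_rates=((0.0, 2000.0), (2000.0, 0.0)),
                       background=(0.0,) * 6)
    stream, _ = simulate_stream(cfg)
    bursts = burst_search(stream)
    cf = CorrectionFactors()
    for b in bursts:
        correct_burst(b, cf)
    return stream, bursts


class TestDynamicsDiagnostics:

    def _attach_lifetimes(self, stream, bursts, tau_d_ns):
        from nickfret.photon_sim import DD_CHANNELS
        for b in bursts:
            sl = slice(b.first, b.last + 1)
            ch = stream.channel[sl]
            micro = stream.microtimes_s[sl] * 1e9
            dd = micro[np.isin(ch, DD_CHANNELS)]
            if len(dd) >= 20 and np.ptp(dd) > 0:
                b.lifetime_ns = burst_lifetime_mle(dd, 20.0)

    def test_static_species_on_static_line(self, static_stream,
                                           static_bursts):
        stream, _ = static_stream
        self._attach_lifetimes(stream, static_bursts, 3.5)
        out = static_fret_line(static_bursts, donor_only_lifetime_ns=3.5)
        assert out["n"] > 50
        assert abs(out["mean_deviation"]) < max(4 * out["se_deviation"],
                                                0.03)

    def test_dynamic_species_above_static_line(self, dynamic_bursts):
        stream, bursts = dynamic_bursts
        self._attach_lifetimes(stream, bursts, 3.5)
        out = static_fret_line(bursts, donor_only_lifetime_ns=3.5)
        assert out["mean_deviation"] > 3 * out["se_deviation"]
        assert out["mean_deviation"] > 0.03

    def test_bva_static_follows_shot_noise(self, static_stream,
                                           static_bursts):
        stream, _ = static_stream
        table = bva(static_bursts, stream, n_sub=5)
        excess = table["sd_sub"] - table["expected_sd"]
        assert abs(excess.mean()) < 0.02

    def test_bva_dynamic_shows_excess_variance(self, dynamic_bursts):
        stream, bursts = dynamic_bursts
        table = bva(bursts, stream, n_sub=5)
        excess = table["sd_sub"] - table["expected_sd"]
        assert excess.mean() > 0.05

    def test_time_windows_static_mean_invariant(self, static_stream,
                                                static_bursts,
                                                static_correction_factors):
        stream, _ = static_stream
        hists = time_window_histograms(
            static_bursts, stream, static_correction_factors,
            bin_sizes=(0.5e-3, 2e-3, 5e-3))
        means = []
        for w, h in hists.items():
            total = h.counts.sum()
            assert total > 50
            means.append(np.sum(h.centers * h.counts) / total)
        assert np.ptp(means) < 0.03

    def test_time_windows_dynamic_broadening(self, dynamic_bursts):
        stream, bursts = dynamic_bursts
        cf = CorrectionFactors()
        hists = time_window_histograms(bursts, stream, cf,
                                       bin_sizes=(0.2e-3, 5e-3))

        def sd(h):
            total = h.counts.sum()
            m = np.sum(h.centers * h.counts) / total
            return np.sqrt(np.sum(h.counts * (h.centers - m) ** 2) / total)

        assert sd(hists[0.2e-3]) > sd(hists[5e-3]) + 0.03
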