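"""Simulator: event-schedule statistics, rendering arithmetic, Bessel filter."""

import numpy as np
import pytest

from nanopept import (
    SimConfig,
    Trace,
    TruthEvent,
    apply_filter,
    render_trace,
    sample_truth_events,
    simulate,
)
from conftest import make_config, make_species


class TestTruthSampling:
    def test_zero_capture_rate_gives_no_events(self):
        cfg = make_config([make_species(capture_rate=0.0)], duration=5.0)
        assert sample_truth_events(cfg, seed=1) == []

    def test_poisson_event_count(self):
        # rate 10/s over 100 s -> ~1000 events, within 3 sqrt(1000)
        cfg = make_config(
            [make_species(capture_rate=10.0, dwell_mean=1.0)],
            duration=100.0,
        )
        n = len(sample_truth_events(cfg, seed=3))
        assert abs(n - 1000) < 3 * np.sqrt(1000)

    def test_species_fractions_follow_rates(self):
        # Poisson thinning: rates 10 and 30/s -> labels in ~1:3 proportion
        cfg = make_config(
            [
                make_species("a", capture_rate=10.0, dwell_mean=1.0),
                make_species("b", capture_rate=30.0, dwell_mean=1.0),
            ],
            duration=100.0,
        )
        truth = sample_truth_events(cfg, seed=4)
        n = len(truth)
        frac_a = sum(ev.species == "a" for ev in truth) / n
        # 4 sigma binomial envelope around 0.25
        assert abs(frac_a - 0.25) < 4 * np.sqrt(0.25 * 0.75 / n)

    def test_events_sorted_and_disjoint(self):
        cfg = make_config(
            [make_species(capture_rate=20.0, dwell_mean=5.0)], duration=20.0
        )
        truth = sample_truth_events(cfg, seed=5)
        assert len(truth) > 100
        for prev, nxt in zip(truth, truth[1:]):
            assert prev.end <= nxt.start

    def test_excessive_occupancy_rejected(self):
        cfg_kw = dict(duration=10.0)
        sp = make_species(capture_rate=50.0, dwell_mean=20.0)  # occupancy 1.0
        with pytest.raises(ValueError, match="occupancy"):
            sample_truth_events(make_config([sp], **cfg_kw), seed=1)

    def test_determinism(self):
        cfg = make_config(
            [make_species(capture_rate=10.0)], duration=5.0, seed=9
        )
        t1, tr1 = sample_truth_events(cfg), render_trace(cfg, sample_truth_events(cfg))
        t2, tr2 = sample_truth_events(cfg), render_trace(cfg, sample_truth_events(cfg))
        assert t1 == t2
        np.testing.assert_array_equal(tr1.samples, tr2.samples)


class TestRendering:
    def test_eventless_quiet_trace_is_flat(self):
        cfg = make_config([], open_noise_sd=1e-12, filter_cutoff=0.0, duration=0.1)
        trace = render_trace(cfg, [], seed=1)
        np.testing.assert_allclose(trace.samples, 100.0, atol=1e-9)

    def test_event_level_from_iex_definition(self):
        # I_ex 70% of a 100 pA pore -> 30 pA inside the event
        cfg = make_config(
            [make_species(sigma_b=0.0)],
            open_noise_sd=1e-12,
            filter_cutoff=0.0,
            duration=0.1,
        )
        ev = TruthEvent("pep", 1000, 1500, true_iex=70.0, true_dwell=10.0)
        trace = render_trace(cfg, [ev], seed=1)
        np.testing.assert_allclose(trace.samples[1000:1500], 30.0, atol=1e-9)
        np.testing.assert_allclose(trace.samples[:1000], 100.0, atol=1e-9)

    def test_level_conservation_noise_free(self):
        # recomputing (I0 - level)/I0*100 from samples returns true_iex exactly
        cfg = make_config(
            [make_species(sigma_b=0.0, capture_rate=10.0)],
            open_noise_sd=1e-12,
            filter_cutoff=0.0,
            duration=5.0,
        )
        truth = sample_truth_events(cfg, seed=7)
        trace = render_trace(cfg, truth, seed=8)
        for ev in truth:
            level = trace.samples[ev.start : ev.end]
            iex = (100.0 - level) / 100.0 * 100.0
            np.testing.assert_allclose(iex, ev.true_iex, atol=1e-9)

    def test_filtered_long_event_keeps_mid_level(self):
        # 10 ms square event: a 10 kHz low-pass only touches the edges
        cfg = make_config(
            [make_species(sigma_b=0.0)], open_noise_sd=1e-12, duration=0.1
        )
        ev = TruthEvent("pep", 2000, 2500, true_iex=70.0, true_dwell=10.0)
        trace = render_trace(cfg, [ev], seed=1)
        mid = trace.samples[2200:2300]
        assert abs(mid.mean() - 30.0) / 30.0 < 0.005

    def test_two_level_mode_fluctuates_more(self):
        kw = dict(sigma_b=0.5, capture_rate=1.0)
        quiet = make_species(**kw)
        noisy = make_species(
            fluctuation_mode="two_level",
            two_level_split=10.0,
            two_level_rate=1.0,
            **kw,
        )
        ev = TruthEvent("pep", 1000, 6000, true_iex=70.0, true_dwell=100.0)
        sds = {}
        for sp in (quiet, noisy):
            cfg = make_config([sp], open_noise_sd=1e-6, filter_cutoff=0.0, duration=0.2)
            trace = render_trace(cfg, [ev], seed=11)
            sds[sp.fluctuation_mode] = trace.samples[1000:6000].std()
        assert sds["two_level"] > 3 * sds["white"]
        assert sds["two_level"] > 2.0  # split of 10% of 100 pA dominates

    def test_unknown_species_rejected(self):
        cfg = make_config([], duration=0.1)
        ev = TruthEvent("ghost", 10, 20, 50.0, 0.2)
        with pytest.raises(ValueError, match="unknown species"):
            render_trace(cfg, [ev], seed=1)

    def test_occupancy_matches_rate_dwell_product(self):
        cfg = make_config(
            [make_species(capture_rate=10.0, dwell_mean=10.0)], duration=60.0
        )
        truth = sample_truth_events(cfg, seed=13)
        frac = sum(ev.end - ev.start for ev in truth) / cfg.n_samples
        assert abs(frac - 0.10) < 0.02


class TestBesselFilter:
    fs = 50_000.0

    def test_dc_gain_unity(self):
        trace = Trace(np.full(5000, 42.0), self.fs)
        out = apply_filter(trace, 10_000.0)
        np.testing.assert_allclose(out.samples, 42.0, atol=1e-6 * 42.0)

    def test_impulse_response_integrates_to_one(self):
        x = np.zeros(5000)
        x[2000] = 1.0
        out = apply_filter(Trace(x, self.fs), 10_000.0)
        assert abs(out.samples.sum() - 1.0) < 1e-6

    def test_minus_3db_at_cutoff(self):
        # amplitude ratio at the cutoff ~ 1/sqrt(2); measured by projection
        f = 10_000.0
        t = np.arange(50_000) / self.fs
        x = np.sin(2 * np.pi * f * t)
        y = apply_filter(Trace(x, self.fs), f).samples
        # skip the startup, project on the quadrature pair at f
        sl = slice(5000, None)
        c = np.cos(2 * np.pi * f * t[sl])
        s = np.sin(2 * np.pi * f * t[sl])
        amp = 2 * np.hypot((y[sl] * c).mean(), (y[sl] * s).mean())
        assert abs(amp - 2 ** -0.5) / 2 ** -0.5 < 0.05

    def test_cutoff_at_or_above_nyquist_rejected(self):
        trace = Trace(np.zeros(100) + 1.0, self.fs)
        with pytest.raises(ValueError, match="Nyquist"):
            apply_filter(trace, 25_000.0)


def test_simulate_wrapper_reproducible():
    cfg = make_config([make_species(capture_rate=5.0)], duration=2.0, seed=21)
    tr1, th1 = simulate(cfg)
    tr2, th2 = simulate(cfg)
    assert th1 == th2
    np.testing.assert_array_equal(tr1.samples, tr2.samples)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(open_current=-1.0, open_noise_sd=1.0, duration=1.0, species=())
    with pytest.raises(ValueError):
        make_config([], sample_rate=15_000.0, filter_cutoff=10_000.0)
    with pytest.raises(ValueError):
        make_species(iex_mean=101.0)
    with pytest.raises(ValueError):
        make_species(dwell_mean=0.0)
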