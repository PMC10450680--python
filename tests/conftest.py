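import numpy as np
import pytest

from nanopept import EventRecord, SimConfig, SpeciesParams


def make_species(
    name="pep",
    iex_mean=70.0,
    iex_sd=1.5,
    dwell_mean=5.0,
    sigma_b=1.0,
    capture_rate=5.0,
    **kw,
):
    return SpeciesParams(
        name=name,
        iex_mean=iex_mean,
        iex_sd=iex_sd,
        dwell_mean=dwell_mean,
        sigma_b=sigma_b,
        capture_rate=capture_rate,
        **kw,
    )


def make_config(species=(), filter_cutoff=10_000.0, **kw):
    defaults = dict(
        open_current=100.0,
        open_noise_sd=2.0,
        duration=10.0,
        sample_rate=50_000.0,
        seed=0,
    )
    defaults.update(kw)
    return SimConfig(species=tuple(species), filter_cutoff=filter_cutoff, **defaults)


def make_event(iex_pct=70.0, dwell_ms=1.0, sigma_b=1.0, start=0, sample_rate=50_000.0):
    end = start + max(1, int(round(dwell_ms / 1000.0 * sample_rate)))
    i0 = 100.0
    mean_ib = i0 * (1 - iex_pct / 100.0)
    return EventRecord(
        start=start,
        end=end,
        dwell_ms=dwell_ms,
        mean_ib=mean_ib,
        delta_ib=i0 - mean_ib,
        iex_pct=iex_pct,
        sigma_b=sigma_b,
    )


def make_event_population(rng, n, iex_mu, iex_sd, log_dwell_mu=0.0, log_dwell_sd=0.4,
                          sigma_b_mu=1.5, sigma_b_sd=0.3):
    """Synthetic EventRecord population with Gaussian iex, log-normal dwell,
    Gaussian sigma_b (clipped positive)."""
    iex = rng.normal(iex_mu, iex_sd, n)
    dwell = 10.0 ** rng.normal(log_dwell_mu, log_dwell_sd, n)
    sb = np.clip(rng.normal(sigma_b_mu, sigma_b_sd, n), 0.05, None)
    return [make_event(i, d, s) for i, d, s in zip(iex, dwell, sb)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
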