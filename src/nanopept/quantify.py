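"""Capture-bias-corrected quantification of lanthipeptide cyclization.

Cyclized and linear forms of a lanthipeptide have identical mass but distinct
excluded-current clusters, so their ratio can be counted from nanopore events
— provided the differential capture of the two forms is corrected.  Events
are counted inside each cluster's mu +/- sigma window (strict); from an
equimolar control mixture the relative detection factor

    F = E(mix) / (100 - E(mix))

measures how much more often the cyclized form is captured than the linear
form at equal concentration.  The extent of modification (conversion) in a
sample with cyclized-event percentage E is then

    conversion = 100 * E / (E + F * (100 - E)),

the odds-ratio correction that inverts the forward observation model
E = 100 * c * F / (c * F + (100 - c)) exactly.  Percentages on the 0-100
scale are the public unit throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectrum import ClusterFit

__all__ = [
    "QuantResult",
    "count_in_window",
    "event_fraction",
    "detection_factor",
    "conversion",
    "observed_fraction",
    "quantify",
]


def _iex_array(events) -> np.ndarray:
    return np.asarray(
        [e.iex_pct if hasattr(e, "iex_pct") else e for e in events], dtype=float
    )


def count_in_window(events, cluster: ClusterFit) -> int:
    """Events with mu - sigma < I_ex% < mu + sigma (strict inequalities)."""
    v = _iex_array(events)
    return int(np.sum((v > cluster.mu - cluster.sigma) & (v < cluster.mu + cluster.sigma)))


def event_fraction(count_a: int, count_b: int) -> float:
    """Percentage of species-A events: 100 * a / (a + b)."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    total = count_a + count_b
    if total == 0:
        raise ValueError("no events in either window")
    return 100.0 * count_a / total


def detection_factor(e_mix: float) -> float:
    """Relative detection factor F from the equimolar mixture.

    F = e_mix / (100 - e_mix); F = 1 iff the two species are captured equally
    often (e_mix = 50).
    """
    if not 0.0 < e_mix < 100.0:
        raise ValueError(
            f"e_mix must be strictly inside (0, 100), got {e_mix} (unbounded bias)"
        )
    return e_mix / (100.0 - e_mix)


def conversion(e_sample: float, f: float) -> float:
    """Extent of modification from the sample event fraction and F.

    conversion = 100 * e / (e + F * (100 - e)); equals e_sample when F = 1.
    """
    if f <= 0:
        raise ValueError("detection factor must be > 0")
    if not 0.0 <= e_sample <= 100.0:
        raise ValueError("e_sample must be in [0, 100]")
    denom = e_sample + f * (100.0 - e_sample)
    return 100.0 * e_sample / denom


def observed_fraction(conversion_pct: float, f: float) -> float:
    """Forward observation model: event percentage produced by a sample of
    true conversion c under capture bias F.  Inverse of :func:`conversion`."""
    if f <= 0:
        raise ValueError("detection factor must be > 0")
    c = conversion_pct
    return 100.0 * c * f / (c * f + (100.0 - c))


@dataclass(frozen=True)
class QuantResult:
    """Event fractions, detection factor and conversion estimate."""

    e_sample: float
    e_mix: float
    detection_factor: float
    conversion: float
    counts: dict
    ci: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None


def quantify(
    sample_events,
    mixture_events,
    cluster_a: ClusterFit,
    cluster_b: ClusterFit,
    n_boot: int = 0,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> QuantResult:
    """Full quantification: count, correct for capture bias, estimate conversion.

    ``cluster_a`` is the modified (e.g. cyclized) species, ``cluster_b`` the
    unmodified one; the mixture must be equimolar.  With ``n_boot > 0`` a
    percentile bootstrap over events gives a confidence interval for the
    conversion.
    """
    s_iex = _iex_array(sample_events)
    m_iex = _iex_array(mixture_events)

    def _estimate(s: np.ndarray, m: np.ndarray) -> tuple[float, float, float, float, dict]:
        counts = {
            "sample_a": count_in_window(s, cluster_a),
            "sample_b": count_in_window(s, cluster_b),
            "mix_a": count_in_window(m, cluster_a),
            "mix_b": count_in_window(m, cluster_b),
        }
        e_s = event_fraction(counts["sample_a"], counts["sample_b"])
        e_m = event_fraction(counts["mix_a"], counts["mix_b"])
        f = detection_factor(e_m)
        return e_s, e_m, f, conversion(e_s, f), counts

    e_s, e_m, f, conv, counts = _estimate(s_iex, m_iex)

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            sb = rng.choice(s_iex, size=s_iex.size, replace=True)
            mb = rng.choice(m_iex, size=m_iex.size, replace=True)
            try:
                reps.append(_estimate(sb, mb)[3])
            except ValueError:  # a resample emptied a window
                continue
        if reps:
            alpha = (1.0 - ci_level) / 2.0
            lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
            ci = (float(lo), float(hi))
    return QuantResult(
        e_sample=e_s, e_mix=e_m, detection_factor=f, conversion=conv,
        counts=counts, ci=ci, n_boot=n_boot, seed=seed,
    )
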