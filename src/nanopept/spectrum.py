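"""Excluded-current spectra and the cluster-resolution statistic.

Each peptide species forms an approximately Gaussian cluster in the I_ex%
histogram ("nanopore spectrum").  Discrimination between two species is
summarised by the chromatography-style resolution

    R_s = 2 |mu_1 - mu_2| / (sigma_1 + sigma_2),

where mu_i, sigma_i are the Gaussian centers and spreads of the two clusters.
For equal-spread clusters the fraction of events correctly assigned by the
midpoint threshold is Phi(R_s / 2) (standard normal CDF), which this module
reports as ``separation_pct``; ``overlap_pct`` is its complement.  R_s >= 2
therefore corresponds to more than 84% separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "ClusterFit",
    "ResolutionResult",
    "fit_cluster",
    "compute_resolution",
    "build_spectrum",
]

DEFAULT_BIN_WIDTH = 0.5  # percent I_ex; resolves the narrowest clusters (~0.9%)
MIN_CLUSTER_EVENTS = 30


@dataclass(frozen=True)
class ClusterFit:
    """Gaussian parameters of one peptide population in the I_ex% spectrum."""

    mu: float
    sigma: float
    amplitude: float = float("nan")
    n_events: int = 0
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 < self.mu < 100.0:
            raise ValueError("mu must be in (0, 100)")


@dataclass(frozen=True)
class ResolutionResult:
    """R_s with its separation/overlap interpretation (percent)."""

    rs: float
    separation_pct: float
    overlap_pct: float


def _gauss(x: np.ndarray, a: float, mu: float, sig: float) -> np.ndarray:
    return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)


def fit_cluster(
    iex_values,
    window: tuple[float, float],
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> ClusterFit:
    """Least-squares Gaussian fit to the I_ex% histogram inside a window.

    The window isolates one cluster (clusters are identified by sequential
    addition of peptides, so windows are user knowledge, not fitted).
    Requires at least 30 events in the window.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lo, hi = window
    if lo >= hi:
        raise ValueError("window low must be below window high")
    vals = np.asarray(
        [v.iex_pct if hasattr(v, "iex_pct") else v for v in iex_values], dtype=float
    )
    sel = vals[(vals >= lo) & (vals < hi)]
    if sel.size < MIN_CLUSTER_EVENTS:
        raise ValueError(
            f"only {sel.size} events in window {window}; "
            f"need at least {MIN_CLUSTER_EVENTS}"
        )
    if np.ptp(sel) == 0:
        raise ValueError("degenerate cluster: all values identical")
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(sel, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), float(sel.mean()), max(float(sel.std()), bin_width / 4))
    try:
        popt, _ = optimize.curve_fit(
            _gauss, centers, counts, p0=p0,
            bounds=([0.0, lo, 1e-9], [np.inf, hi, hi - lo]),
            maxfev=10_000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"cluster Gaussian fit did not converge: {err}") from err
    a, mu, sigma = popt
    return ClusterFit(mu=float(mu), sigma=float(sigma), amplitude=float(a),
                      n_events=int(sel.size), window=(float(lo), float(hi)))


def compute_resolution(c1: ClusterFit, c2: ClusterFit) -> ResolutionResult:
    """Cluster resolution R_s = 2|mu1 - mu2| / (sigma1 + sigma2).

    ``separation_pct`` = 100 * Phi(R_s / 2) is the fraction of events a
    midpoint threshold assigns correctly for equal-spread clusters;
    ``overlap_pct`` is the complement.  Symmetric in its arguments.
    """
    rs = 2.0 * abs(c1.mu - c2.mu) / (c1.sigma + c2.sigma)
    separation = 100.0 * norm.cdf(rs / 2.0)
    return ResolutionResult(
        rs=float(rs),
        separation_pct=float(separation),
        overlap_pct=float(100.0 - separation),
    )


def build_spectrum(events, bin_width: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of I_ex% over [0, 100]; returns (counts, bin_edges).

    The total count equals the number of events: out-of-range values (the
    detector keeps them, flagged) are clipped into [0, 100] for binning.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    vals = np.asarray(
        [v.iex_pct if hasattr(v, "iex_pct") else v for v in events], dtype=float
    )
    if vals.size < 1:
        raise ValueError("need at least one event")
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    clipped = np.clip(vals, 0.0, np.nextafter(edges[-1], 0.0))
    counts, edges = np.histogram(clipped, bins=edges)
    return counts, edges
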