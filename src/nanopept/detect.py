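"""Blockade-event detection from ionic-current traces.

The open-pore level I_O and its noise sigma_I0 are estimated from a Gaussian
fit to the current histogram; events are then found by a threshold search at
I_O - k*sigma_I0 (k = 5 by default) with a minimum duration of 50 microseconds,
and summarised by mean blockade current I_B, blockade magnitude
dI_B = I_O - I_B, excluded current I_ex% = dI_B / I_O * 100, intra-event
fluctuation sigma_b and dwell time.

All analysis operates on current magnitudes; polarity is handled at I/O time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .simulate import Trace

__all__ = [
    "OpenPoreFit",
    "EventRecord",
    "estimate_open_pore",
    "detect_events",
    "extract_features",
    "analyze_trace",
]

DEFAULT_THRESHOLD_K = 5.0
DEFAULT_MIN_DURATION_US = 50.0


class FitError(RuntimeError):
    """Raised when a histogram Gaussian fit cannot be performed."""


@dataclass(frozen=True)
class OpenPoreFit:
    """Open-pore current estimate: center i0, width sigma0 (both pA)."""

    i0: float
    sigma0: float
    fit_window: tuple[float, float]
    n_samples_used: int

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        lo, hi = self.fit_window
        if not lo <= self.i0 <= hi:
            raise ValueError("i0 must lie inside fit_window")


@dataclass(frozen=True)
class EventRecord:
    """One detected blockade, half-open sample bounds [start, end).

    ``iex_pct`` is not clamped: values outside [0, 100] (possible for noisy
    shallow events or overshoot) are retained and flagged via
    :attr:`iex_in_range`.
    """

    start: int
    end: int
    dwell_ms: float
    mean_ib: float
    delta_ib: float
    iex_pct: float
    sigma_b: float

    @property
    def iex_in_range(self) -> bool:
        return 0.0 <= self.iex_pct <= 100.0


def _gauss(x: np.ndarray, a: float, mu: float, sig: float) -> np.ndarray:
    return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)


def estimate_open_pore(trace: Trace) -> OpenPoreFit:
    """Estimate I_O and sigma_I0 from the current-magnitude histogram.

    Blockades only reduce the current, so among candidate histogram peaks the
    one at the highest current is the open pore.  A Gaussian is least-squares
    fitted over mode +/- 4 robust scales.  Bin width is a fifth of the robust
    scale (1.4826 * MAD) of the upper half of the distribution, which keeps
    at least ~10 bins across the open-pore peak.
    """
    x = np.abs(trace.samples)
    if x.size < 1000:
        raise ValueError("need at least 1000 samples to fit the open-pore peak")
    med = np.median(x)
    upper = x[x >= med]
    scale = 1.4826 * np.median(np.abs(upper - np.median(upper)))
    if scale <= 0:
        raise FitError("degenerate current histogram (no spread above the median)")
    bw = scale / 5.0
    edges = np.arange(x.min(), x.max() + bw, bw)
    if edges.size < 3:
        raise FitError("degenerate current histogram (all samples in one bin)")
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    peaks, _ = signal.find_peaks(counts, prominence=0.05 * counts.max())
    candidates = set(peaks.tolist()) | {int(np.argmax(counts))}
    candidates = [i for i in candidates if counts[i] >= 0.1 * counts.max()]
    mode_idx = max(candidates, key=lambda i: centers[i])
    mode = centers[mode_idx]

    lo, hi = mode - 4.0 * scale, mode + 4.0 * scale
    sel = (centers >= lo) & (centers <= hi)
    if sel.sum() < 4:
        raise FitError("too few histogram bins around the open-pore peak")
    try:
        popt, _ = optimize.curve_fit(
            _gauss,
            centers[sel],
            counts[sel],
            p0=(counts[mode_idx], mode, scale),
            bounds=([0.0, lo, 1e-12], [np.inf, hi, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise FitError(f"open-pore Gaussian fit did not converge: {err}") from err
    _, i0, sigma0 = popt
    n_used = int(x[(x >= lo) & (x <= hi)].size)
    return OpenPoreFit(i0=float(i0), sigma0=float(sigma0),
                       fit_window=(float(lo), float(hi)), n_samples_used=n_used)


def detect_events(
    trace: Trace,
    fit: OpenPoreFit,
    threshold_k: float = DEFAULT_THRESHOLD_K,
    min_duration_us: float = DEFAULT_MIN_DURATION_US,
) -> list[tuple[int, int]]:
    """Threshold search for blockades.

    An event opens at the first sample whose magnitude drops below
    ``i0 - threshold_k * sigma0`` and closes at the first subsequent sample
    back above that threshold; events shorter than
    ``ceil(min_duration * sample_rate)`` samples (3 samples for 50 us at
    50 kHz) are discarded.  An excursion still below threshold at the end of
    the trace has no observed return and is dropped.
    """
    thr = fit.i0 - threshold_k * fit.sigma0
    if thr <= 0:
        raise ValueError(
            f"threshold {thr:.3g} pA is not a positive current "
            f"(i0={fit.i0:.3g}, k={threshold_k}, sigma0={fit.sigma0:.3g})"
        )
    below = np.abs(trace.samples) < thr
    padded = np.concatenate(([0], below.astype(np.int8), [0]))
    idx = np.flatnonzero(np.diff(padded))
    starts, ends = idx[::2], idx[1::2]
    if below[-1]:  # unterminated final excursion
        starts, ends = starts[:-1], ends[:-1]
    min_samples = math.ceil(min_duration_us * 1e-6 * trace.sample_rate)
    keep = (ends - starts) >= min_samples
    return list(zip(starts[keep].tolist(), ends[keep].tolist()))


def extract_features(
    trace: Trace, bounds: tuple[int, int], fit: OpenPoreFit
) -> EventRecord:
    """Summarise one event: I_B, dI_B, I_ex%, sigma_b, dwell.

    All samples between the threshold crossings contribute (no edge
    trimming); sigma_b is the population SD of the in-event samples.
    """
    start, end = bounds
    if not (0 <= start < end <= trace.samples.size):
        raise ValueError(f"bounds {bounds} outside trace of {trace.samples.size} samples")
    seg = np.abs(trace.samples[start:end])
    mean_ib = float(seg.mean())
    delta_ib = fit.i0 - mean_ib
    iex_pct = delta_ib / fit.i0 * 100.0
    return EventRecord(
        start=int(start),
        end=int(end),
        dwell_ms=(end - start) / trace.sample_rate * 1000.0,
        mean_ib=mean_ib,
        delta_ib=float(delta_ib),
        iex_pct=float(iex_pct),
        sigma_b=float(seg.std(ddof=0)),
    )


def analyze_trace(
    trace: Trace,
    fit: OpenPoreFit | None = None,
    threshold_k: float = DEFAULT_THRESHOLD_K,
    min_duration_us: float = DEFAULT_MIN_DURATION_US,
) -> tuple[OpenPoreFit, list[EventRecord]]:
    """Open-pore fit + detection + feature extraction in one call."""
    if fit is None:
        fit = estimate_open_pore(trace)
    bounds = detect_events(trace, fit, threshold_k, min_duration_us)
    return fit, [extract_features(trace, b, fit) for b in bounds]
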