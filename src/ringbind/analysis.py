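"""Spike-train and field-signal analyses.

Spike counting in bump windows, lagged and sliding Pearson correlations,
correlogram spectra, alpha-kernel LFP synthesis, Welch power peaks, Morlet
wavelet phase, the phase-preservation index, and bump strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "BinnedCounts",
    "BumpWindow",
    "CorrelationFunction",
    "LfpTrace",
    "PhaseSeries",
    "PpiCurve",
    "SpectrumResult",
    "bump_spike_counts",
    "cross_correlogram",
    "sliding_count_correlation",
    "correlation_spectrum",
    "lfp_from_spikes",
    "power_peak",
    "load_frequency_ratio",
    "wavelet_phase",
    "phase_preservation_index",
    "bump_strength",
]

DEFAULT_BIN_MS = 5.0
DEFAULT_BUMP_HALFWIDTH = 340  # neurons, on the 2048-neuron reference grid
DEFAULT_PEAK_BAND = (10.0, 100.0)


@dataclass
class BinnedCounts:
    """Spike counts in fixed-width time bins, aggregated over a bump."""

    bin_width: float  # ms
    start: float  # ms
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return self.start + (np.arange(self.counts.size) + 0.5) * self.bin_width


@dataclass(frozen=True)
class BumpWindow:
    """Set of E neurons within circular index distance of a center."""

    center: int
    halfwidth: int = DEFAULT_BUMP_HALFWIDTH

    def member_mask(self, n_exc: int) -> np.ndarray:
        if not 0 < self.halfwidth < n_exc / 2:
            raise ValueError("halfwidth must be in (0, n_exc/2)")
        idx = np.arange(n_exc)
        d = np.abs(idx - self.center % n_exc)
        d = np.minimum(d, n_exc - d)
        return d <= self.halfwidth

    @staticmethod
    def scaled(center: int, n_exc: int, reference_n: int = 2048,
               reference_halfwidth: int = DEFAULT_BUMP_HALFWIDTH) -> "BumpWindow":
        """±340-neuron window re-expressed on a ring of ``n_exc`` neurons."""
        hw = max(1, int(round(reference_halfwidth * n_exc / reference_n)))
        return BumpWindow(center=center % n_exc, halfwidth=hw)


@dataclass
class CorrelationFunction:
    lags: np.ndarray  # ms
    values: np.ndarray  # Pearson correlation per lag; NaN where undefined
    normalization: str = "pearson_per_lag"


@dataclass
class LfpTrace:
    samples: np.ndarray
    dt: float  # ms
    kernel_tau: float = 5.0
    start: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(self.samples.size) * self.dt


@dataclass
class PhaseSeries:
    """Instantaneous phase at a fixed frequency, per trial."""

    phases: np.ndarray  # (n_trials, n_times), radians in (-pi, pi]
    times: np.ndarray  # ms
    f0: float  # Hz
    trial_ids: np.ndarray | None = None


@dataclass
class PpiCurve:
    values: np.ndarray  # in [0, 1]
    times: np.ndarray  # ms
    t_ref: float
    n_trials: int


@dataclass
class SpectrumResult:
    frequencies: np.ndarray  # Hz
    power: np.ndarray
    peak_frequency: float | None  # None when no band peak exists


def bump_spike_counts(record, window: BumpWindow, bin_width: float = DEFAULT_BIN_MS,
                      t_start: float = 0.0, t_end: float | None = None) -> BinnedCounts:
    """5-ms (default) spike counts of the E neurons inside a bump window."""
    t_end = record.duration if t_end is None else t_end
    times, ids = record.select("E")
    mask = window.member_mask(record.n_exc)[ids]
    times = times[(mask) & (times >= t_start) & (times < t_end)]
    n_bins = int(np.ceil((t_end - t_start) / bin_width))
    edges = t_start + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(times, bins=edges)
    return BinnedCounts(bin_width=bin_width, start=t_start, counts=counts)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def cross_correlogram(a: BinnedCounts, b: BinnedCounts, max_lag: float) -> CorrelationFunction:
    """Pearson correlation of two count series at every integer-bin lag.

    Overlapping-segment normalization: at lag L the correlation is computed
    on the overlapping parts of the two series only, so
    ``C_ab(L) == C_ba(-L)`` exactly.
    """
    if a.bin_width != b.bin_width or a.counts.size != b.counts.size:
        raise ValueError("series must share bin width and span")
    w = a.bin_width
    max_bins = int(round(max_lag / w))
    lags = np.arange(-max_bins, max_bins + 1)
    x = a.counts.astype(float)
    y = b.counts.astype(float)
    values = np.empty(lags.size)
    for k, lag in enumerate(lags):
        if lag >= 0:
            xs, ys = x[: x.size - lag] if lag else x, y[lag:]
        else:
            xs, ys = x[-lag:], y[: y.size + lag]
        values[k] = _pearson(xs, ys)
    return CorrelationFunction(lags=lags * w, values=values)


def sliding_count_correlation(a: BinnedCounts, b: BinnedCounts,
                              window: float = 100.0) -> tuple:
    """Pearson correlation inside consecutive windows; NaN where undefined.

    Returns ``(window_centers_ms, correlations)``.
    """
    if a.bin_width != b.bin_width or a.counts.size != b.counts.size:
        raise ValueError("series must share bin width and span")
    bins_per_win = int(round(window / a.bin_width))
    if abs(bins_per_win * a.bin_width - window) > 1e-9:
        raise ValueError("window must be a multiple of the bin width")
    n_win = a.counts.size // bins_per_win
    centers = np.empty(n_win)
    values = np.empty(n_win)
    for k in range(n_win):
        sl = slice(k * bins_per_win, (k + 1) * bins_per_win)
        values[k] = _pearson(a.counts[sl].astype(float), b.counts[sl].astype(float))
        centers[k] = a.start + (k + 0.5) * window
    return centers, values


def correlation_spectrum(corr: CorrelationFunction,
                         band: tuple = DEFAULT_PEAK_BAND,
                         nfft: int = 4096) -> SpectrumResult:
    """Power spectrum of a correlation function; peak within a band.

    Missing lags are dropped by mean-imputation; an all-missing correlation
    is an error. Zero-padding refines the frequency grid beyond the raw
    lag resolution.
    """
    values = corr.values.copy()
    if np.all(np.isnan(values)):
        raise ValueError("correlation function is entirely undefined")
    values[np.isnan(values)] = np.nanmean(values)
    values = values - values.mean()
    d_lag = float(corr.lags[1] - corr.lags[0])  # ms
    taper = np.hanning(values.size)
    spec = np.abs(np.fft.rfft(values * taper, n=max(nfft, values.size))) ** 2
    freqs = np.fft.rfftfreq(max(nfft, values.size), d=d_lag / 1000.0)
    return _with_band_peak(freqs, spec, band)


def _with_band_peak(freqs, power, band) -> SpectrumResult:
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    peak = None
    if np.any(in_band) and np.any(power[in_band] > 0):
        band_power = np.where(in_band, power, -np.inf)
        idx = int(np.argmax(band_power))
        # flag a flat spectrum (no stable peak): peak must exceed the
        # in-band median appreciably
        med = np.median(power[in_band])
        if power[idx] > 2.0 * med and power[idx] > 0:
            peak = float(freqs[idx])
    return SpectrumResult(frequencies=freqs, power=power, peak_frequency=peak)


def lfp_from_spikes(spike_times, duration: float, dt: float = 1.0,
                    tau: float = 5.0) -> LfpTrace:
    """Alpha-kernel synthetic LFP from aggregated spike times.

    ``LFP(t) = sum_s H(t - t_s) * ((t - t_s)/tau) * exp(-(t - t_s)/tau)``
    sampled on the ``dt`` grid.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    n = int(np.ceil(duration / dt)) + 1
    spike_times = np.asarray(spike_times, dtype=float)
    impulses = np.zeros(n)
    if spike_times.size:
        idx = np.round(spike_times / dt).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        np.add.at(impulses, idx, 1.0)
    # kernel support: ~12 tau covers >99.99% of the mass
    kt = np.arange(0, 12.0 * tau + dt, dt)
    kernel = (kt / tau) * np.exp(-kt / tau)
    samples = signal.fftconvolve(impulses, kernel)[:n]
    return LfpTrace(samples=samples, dt=dt, kernel_tau=tau)


def power_peak(lfp: LfpTrace, window: tuple | None = None,
               band: tuple = DEFAULT_PEAK_BAND,
               nperseg: int = 512) -> SpectrumResult:
    """Hann-tapered Welch power spectrum of an LFP window; peak in band.

    The window must span at least two cycles of the band's lower edge.
    """
    x = lfp.samples
    t = lfp.times
    if window is not None:
        mask = (t >= window[0]) & (t < window[1])
        x = x[mask]
        span_ms = window[1] - window[0]
    else:
        span_ms = lfp.samples.size * lfp.dt
    if span_ms < 2 * 1000.0 / band[0]:
        raise ValueError(
            f"window of {span_ms} ms is shorter than two cycles at {band[0]} Hz"
        )
    fs = 1000.0 / lfp.dt  # Hz
    x = signal.detrend(x)
    scale = np.max(np.abs(lfp.samples)) if lfp.samples.size else 0.0
    if np.std(x) <= 1e-12 * max(scale, 1.0):
        freqs = np.fft.rfftfreq(max(8192, x.size), d=1.0 / fs)
        return SpectrumResult(frequencies=freqs, power=np.zeros(freqs.size),
                              peak_frequency=None)
    nper = min(nperseg, x.size)
    freqs, power = signal.welch(x, fs=fs, window="hann", nperseg=nper,
                                noverlap=nper // 2, nfft=max(8192, nper))
    return _with_band_peak(freqs, power, band)


def load_frequency_ratio(peaks: dict) -> dict:
    """Normalize peak frequencies to load 1 and emit reference scenarios.

    Returns ``{"ratios": {load: f_k/f_1}, "scenario1": {load: load},
    "scenario2": {load: 1/load}}``.
    """
    if 1 not in peaks:
        raise ValueError("load 1 peak frequency required")
    f1 = peaks[1]
    if not f1:
        raise ValueError("load-1 frequency is zero")
    loads = sorted(peaks)
    return {
        "ratios": {k: peaks[k] / f1 for k in loads},
        "scenario1": {k: float(k) for k in loads},
        "scenario2": {k: 1.0 / k for k in loads},
    }


def morlet_kernel(f0: float, dt: float, n_cycles: float = 6.0) -> np.ndarray:
    """Complex Morlet kernel at f0 Hz sampled at dt ms."""
    sigma_t = n_cycles / (2.0 * np.pi * f0)  # s
    half = int(np.ceil(4.0 * sigma_t * 1000.0 / dt))
    t = np.arange(-half, half + 1) * dt / 1000.0  # s
    kern = np.exp(2j * np.pi * f0 * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return kern / np.abs(kern).sum()


def wavelet_phase(lfp: LfpTrace, f0: float = 30.0, n_cycles: float = 6.0) -> PhaseSeries:
    """Instantaneous phase at ``f0`` from a complex Morlet transform."""
    nyquist = 1000.0 / (2.0 * lfp.dt)
    if not 0 < f0 < nyquist:
        raise ValueError(f"f0={f0} Hz not resolvable at dt={lfp.dt} ms")
    kern = morlet_kernel(f0, lfp.dt, n_cycles)
    if kern.size > lfp.samples.size:
        raise ValueError("trace shorter than the wavelet support")
    x = lfp.samples - lfp.samples.mean()
    analytic = signal.fftconvolve(x, kern, mode="same")
    phases = np.angle(analytic)
    return PhaseSeries(phases=phases[None, :], times=lfp.times, f0=f0)


def stack_phase_series(series_list) -> PhaseSeries:
    """Stack single-trial phase series into one ensemble."""
    f0 = series_list[0].f0
    times = series_list[0].times
    for s in series_list[1:]:
        if s.f0 != f0 or s.times.size != times.size:
            raise ValueError("phase series must share f0 and time grid")
    phases = np.vstack([s.phases for s in series_list])
    return PhaseSeries(phases=phases, times=times, f0=f0,
                       trial_ids=np.arange(phases.shape[0]))


def phase_preservation_index(phases: PhaseSeries, t_ref: float) -> PpiCurve:
    """Trial-averaged consistency of phase differences vs. a reference time.

    ``PPI(t) = (1/N) |sum_k exp(i phi_k(t_ref) - i phi_k(t))|``; equals 1 at
    ``t_ref`` exactly and lives in [0, 1].
    """
    n_trials = phases.phases.shape[0]
    if n_trials < 2:
        raise ValueError("PPI requires at least 2 trials")
    times = phases.times
    if not (times[0] - 1e-9 <= t_ref <= times[-1] + 1e-9):
        raise ValueError("t_ref outside the phase series time range")
    ref_idx = int(np.argmin(np.abs(times - t_ref)))
    ref = phases.phases[:, ref_idx][:, None]
    phasors = np.exp(1j * (ref - phases.phases))
    values = np.abs(phasors.mean(axis=0))
    values = np.clip(values, 0.0, 1.0)
    return PpiCurve(values=values, times=times, t_ref=float(times[ref_idx]),
                    n_trials=n_trials)


def bump_strength(record, window: tuple, population: str = "E") -> float:
    """Standard deviation of per-neuron spike counts in a time window."""
    times, ids = record.select(population)
    n = record.n_exc if population == "E" else record.n_inh
    mask = (times >= window[0]) & (times < window[1])
    counts = np.bincount(ids[mask], minlength=n).astype(float)
    return float(counts.std())
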