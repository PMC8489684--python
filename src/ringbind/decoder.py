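"""Rate-based behavioral readout and swap-error taxonomy.

A two-component Gaussian mixture is fit (weighted EM on the neuron-index
axis) to the color network's mean rates during the probe window; the
stronger component's center is the reported color. Swap trials are
classified as memory / attentional / decoding swaps from the sliding
cross-network spike-count correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .analysis import (
    BumpWindow,
    bump_spike_counts,
    sliding_count_correlation,
)

__all__ = [
    "RateProfile",
    "MixtureFit",
    "DecodeResult",
    "SwapDiagnosis",
    "delay_rate_profile",
    "fit_two_gaussians",
    "readout_color",
    "classify_response",
    "diagnose_swap",
    "pair_correlation_contrast",
]

EM_TOL = 1e-6
EM_MAX_ITER = 500
MIN_SIGMA = 1.0  # neurons; floors the component width

SWAP_WINDOW_MS = 250.0  # early/late contrast windows
PERSISTENCE_WINDOWS = 3  # consecutive windows for a reversal to count


@dataclass
class RateProfile:
    """Per-E-neuron mean firing rate (spikes/s) over a decode window."""

    rates: np.ndarray
    window: tuple  # (start, end) ms

    def __post_init__(self) -> None:
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class MixtureFit:
    centers: np.ndarray  # (2,), neuron-index scale
    widths: np.ndarray  # (2,), neurons
    weights: np.ndarray  # (2,), sum to 1
    converged: bool
    n_iter: int
    log_likelihood: float


@dataclass
class DecodeResult:
    readout_position: float  # neuron index
    chosen_component: int  # 1 | 2
    label: str  # "on_target" | "swap"
    tie_broken: bool = False


@dataclass
class SwapDiagnosis:
    category: str  # "memory" | "attentional" | "decoding"
    early_corr: float
    late_corr: float
    reversal_time: float | None


def delay_rate_profile(record, window: tuple) -> RateProfile:
    """Mean firing rate of every E neuron over a time window."""
    start, end = window
    if end <= start:
        raise ValueError("zero- or negative-length decode window")
    times, ids = record.select("E")
    mask = (times >= start) & (times < end)
    counts = np.bincount(ids[mask], minlength=record.n_exc).astype(float)
    rates = counts / ((end - start) / 1000.0)
    return RateProfile(rates=rates, window=(start, end))


def _gauss_pdf(x, mu, sigma):
    return np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) / (sigma * math.sqrt(2.0 * math.pi))


def fit_two_gaussians(profile: RateProfile, init_centers: tuple) -> MixtureFit:
    """Weighted EM for a two-Gaussian mixture on the neuron-index axis.

    The rate profile acts as sample weights at integer positions;
    deterministic given ``init_centers``.
    """
    rates = profile.rates.astype(float)
    total = rates.sum()
    if total <= 0:
        raise ValueError("cannot fit a mixture to an identically-zero profile")
    x = np.arange(rates.size, dtype=float)
    w = rates / total
    mu = np.array(init_centers, dtype=float)
    sigma = np.array([20.0, 20.0]) * max(1.0, rates.size / 2048.0)
    pi = np.array([0.5, 0.5])
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, EM_MAX_ITER + 1):
        dens = np.stack([pi[k] * _gauss_pdf(x, mu[k], sigma[k]) for k in range(2)])
        norm = dens.sum(axis=0)
        norm = np.where(norm <= 0, np.finfo(float).tiny, norm)
        resp = dens / norm
        ll = float(np.sum(w * np.log(norm)))
        # M-step with the rate profile as sample weights
        for k in range(2):
            rk = resp[k] * w
            mass = rk.sum()
            if mass <= 0:
                continue
            pi[k] = mass
            mu[k] = float((rk * x).sum() / mass)
            var = float((rk * (x - mu[k]) ** 2).sum() / mass)
            sigma[k] = max(math.sqrt(max(var, 0.0)), MIN_SIGMA)
        pi = pi / pi.sum()
        if abs(ll - prev_ll) < EM_TOL:
            converged = True
            break
        prev_ll = ll
    return MixtureFit(
        centers=mu, widths=sigma, weights=pi, converged=converged,
        n_iter=n_iter, log_likelihood=ll,
    )


def readout_color(fit: MixtureFit, target: float | None = None) -> tuple:
    """Center of the stronger mixture component.

    Returns ``(position, chosen_component, tie_broken)``. Exact weight ties
    break toward the component nearer ``target`` (component 1 when no
    target is given).
    """
    w1, w2 = fit.weights
    tie = bool(abs(w1 - w2) < 1e-12)
    if tie:
        if target is not None:
            d = np.abs(fit.centers - target)
            k = int(np.argmin(d))
        else:
            k = 0
    else:
        k = 0 if w1 > w2 else 1
    return float(fit.centers[k]), k + 1, tie


def classify_response(readout: float, target: int, nontarget: int, n_exc: int) -> str:
    """Label by smaller circular index distance; equidistant -> on_target."""
    if target == nontarget:
        raise ValueError("target and nontarget must differ")

    def circ(a, b):
        d = abs(a - b) % n_exc
        return min(d, n_exc - d)

    d_t = circ(readout, target)
    d_nt = circ(readout, nontarget)
    return "on_target" if d_t <= d_nt else "swap"


def decode_trial(record, protocol, init_centers=None) -> DecodeResult:
    """Full decode of one trial's color record: rates -> mixture -> label."""
    window = protocol.decode_window
    if window is None:
        raise ValueError("protocol has no decode window")
    target, nontarget = protocol.item_centers["color"]
    if init_centers is None:
        init_centers = (target, nontarget)
    profile = delay_rate_profile(record, window)
    fit = fit_two_gaussians(profile, init_centers)
    pos, comp, tie = readout_color(fit, target=target)
    label = classify_response(pos, target, nontarget, record.n_exc)
    return DecodeResult(readout_position=pos, chosen_component=comp, label=label,
                        tie_broken=tie)


def pair_correlation_contrast(sim, protocol, bin_width: float = 5.0,
                              corr_window: float = 100.0,
                              halfwidth: int | None = None) -> tuple:
    """Sliding bound-pair minus opposite-pair cross-network correlation.

    Computes sliding spike-count correlations for both cross-network
    pairings of the two bumps and returns ``(window_centers, contrast)``
    where positive contrast means the initially bound association dominates.
    """
    color_rec = sim.records["color"]
    loc_rec = sim.records["location"]
    n_exc = color_rec.n_exc
    c_t, c_nt = protocol.item_centers["color"]
    l_t, l_nt = protocol.item_centers["location"]
    if halfwidth is None:
        win = BumpWindow.scaled(0, n_exc).halfwidth
    else:
        win = halfwidth

    def counts(rec, center):
        return bump_spike_counts(rec, BumpWindow(center, win), bin_width)

    col_t = counts(color_rec, c_t)
    col_nt = counts(color_rec, c_nt)
    loc_t = counts(loc_rec, l_t)
    loc_nt = counts(loc_rec, l_nt)
    centers, bound = sliding_count_correlation(col_t, loc_t, corr_window)
    _, cross = sliding_count_correlation(col_nt, loc_t, corr_window)
    # average both pairings for robustness: bound = (cT,lT)+(cNT,lNT);
    # opposite = (cNT,lT)+(cT,lNT)
    _, bound2 = sliding_count_correlation(col_nt, loc_nt, corr_window)
    _, cross2 = sliding_count_correlation(col_t, loc_nt, corr_window)
    bound_avg = np.nanmean(np.vstack([bound, bound2]), axis=0)
    cross_avg = np.nanmean(np.vstack([cross, cross2]), axis=0)
    return centers, bound_avg - cross_avg


def diagnose_swap(sim, protocol, decode: DecodeResult,
                  contrast: tuple | None = None,
                  window_ms: float = SWAP_WINDOW_MS,
                  persistence: int = PERSISTENCE_WINDOWS) -> SwapDiagnosis:
    """Classify a swap trial as memory, attentional, or decoding.

    Rule: attentional if the bound-minus-opposite correlation contrast is
    negative over the first ``window_ms`` of the delay; else memory if it is
    negative over the last ``window_ms``; else decoding. ``reversal_time``
    is the first window where the contrast flips sign for at least
    ``persistence`` consecutive windows.
    """
    if decode.label != "swap":
        raise ValueError("diagnose_swap applies to swap trials only")
    if contrast is None:
        centers, values = pair_correlation_contrast(sim, protocol)
    else:
        centers, values = contrast
    delay_start, delay_end = protocol.delay_window
    in_delay = (centers >= delay_start) & (centers < delay_end)
    c = centers[in_delay]
    v = values[in_delay]
    early = v[c < delay_start + window_ms]
    late = v[c >= delay_end - window_ms]
    early_corr = float(np.nanmean(early)) if early.size else np.nan
    late_corr = float(np.nanmean(late)) if late.size else np.nan

    reversal_time = _first_persistent_flip(c, v, persistence)

    if np.isnan(early_corr) or early_corr < 0:
        category = "attentional"
    elif np.isnan(late_corr) or late_corr < 0:
        category = "memory"
    else:
        category = "decoding"
    return SwapDiagnosis(category=category, early_corr=early_corr,
                         late_corr=late_corr, reversal_time=reversal_time)


def _first_persistent_flip(centers, values, persistence: int):
    """First window where the contrast sign flips for >= persistence windows."""
    signs = np.sign(values)
    valid = ~np.isnan(values)
    start_sign = 0.0
    for s, ok in zip(signs, valid):
        if ok and s != 0:
            start_sign = s
            break
    if start_sign == 0:
        return None
    run = 0
    for k in range(centers.size):
        if valid[k] and signs[k] == -start_sign:
            run += 1
            if run >= persistence:
                return float(centers[k - persistence + 1])
        else:
            run = 0
    return None
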