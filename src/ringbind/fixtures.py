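"""Parametric synthetic spike/phase data with known ground truth.

Oscillatory bump ensembles are inhomogeneous Poisson processes (thinning
algorithm) with sinusoidal rate modulation at controllable frequency,
pairwise phase offsets, and programmed phase-reversal events, so every
analysis and decoding operation is testable without the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import SpikeRecord, SimResult
from .protocol import TrialProtocol, make_binding_trial, rescale_protocol

__all__ = [
    "OscillationSpec",
    "oscillatory_bump_spikes",
    "correlated_pair_fixture",
    "phase_trial_ensemble",
    "swap_scenario_fixture",
]


@dataclass(frozen=True)
class OscillationSpec:
    """Ensemble of units firing as sinusoidally modulated Poisson processes."""

    n_units: int = 50
    base_rate: float = 20.0  # spikes/s per unit
    mod_depth: float = 1.0  # 0..1
    frequency: float = 30.0  # Hz
    phase: float = 0.0  # radians
    duration: float = 2000.0  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mod_depth <= 1.0:
            raise ValueError("mod_depth must be in [0, 1]")
        if self.base_rate < 0:
            raise ValueError("base_rate must be non-negative")


def _thinned_times(rng, rate_fn, rate_max, duration_ms):
    """Inhomogeneous Poisson times on [0, duration) by thinning."""
    if rate_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(rate_max * duration_ms / 1000.0)
    cand = np.sort(rng.uniform(0.0, duration_ms, size=n_cand))
    keep = rng.uniform(0.0, rate_max, size=n_cand) < rate_fn(cand)
    return cand[keep]


def oscillatory_bump_spikes(
    spec: OscillationSpec,
    center: int = 0,
    n_exc: int | None = None,
    network: str = "color",
    phase_fn=None,
) -> SpikeRecord:
    """Spike record of one oscillatory bump.

    Each unit is an independent inhomogeneous Poisson process with rate
    ``base_rate * (1 + mod_depth * cos(2 pi f t + phase))``. Units occupy
    consecutive E indices centered on ``center`` (wrapping around the ring).
    ``phase_fn(t_ms)`` overrides the constant phase for programmed
    reversals.
    """
    rng = np.random.default_rng(spec.seed)
    n_exc = n_exc or spec.n_units
    f_ms = spec.frequency / 1000.0  # cycles per ms

    if phase_fn is None:
        def phase_fn(t):  # noqa: shadows on purpose
            return spec.phase

    def rate_fn(t):
        return spec.base_rate * (
            1.0 + spec.mod_depth * np.cos(2.0 * np.pi * f_ms * t + phase_fn(t))
        )

    rate_max = spec.base_rate * (1.0 + spec.mod_depth)
    offsets = np.arange(spec.n_units) - spec.n_units // 2
    all_t, all_i = [], []
    for off in offsets:
        times = _thinned_times(rng, rate_fn, rate_max, spec.duration)
        all_t.append(times)
        all_i.append(np.full(times.size, (center + off) % n_exc, dtype=np.int64))
    times = np.concatenate(all_t) if all_t else np.empty(0)
    ids = np.concatenate(all_i) if all_i else np.empty(0, dtype=np.int64)
    order = np.argsort(times, kind="stable")
    times, ids = times[order], ids[order]
    return SpikeRecord(
        times=times,
        neurons=ids,
        populations=np.full(times.size, "E", dtype="U1"),
        network=network,
        duration=spec.duration,
        dt=0.0,
        seed=spec.seed,
        n_exc=n_exc,
        n_inh=0,
    )


def merge_records(records, network: str) -> SpikeRecord:
    """Merge spike records sharing a grid into one, re-sorted by time."""
    times = np.concatenate([r.times for r in records])
    ids = np.concatenate([r.neurons for r in records])
    pops = np.concatenate([r.populations for r in records])
    order = np.argsort(times, kind="stable")
    first = records[0]
    return SpikeRecord(
        times=times[order], neurons=ids[order], populations=pops[order],
        network=network, duration=max(r.duration for r in records),
        dt=first.dt, seed=first.seed, n_exc=first.n_exc, n_inh=first.n_inh,
    )


def correlated_pair_fixture(
    f: float = 30.0,
    relative_phase: float = 0.0,
    reversal_time: float | None = None,
    seed: int = 0,
    duration: float = 2000.0,
    n_units: int = 50,
    base_rate: float = 40.0,
    mod_depth: float = 1.0,
) -> tuple:
    """Two oscillatory ensembles with a programmed phase relationship.

    The second ensemble runs at ``relative_phase`` offset; if
    ``reversal_time`` is given its offset jumps by pi from then on.
    """
    spec_a = OscillationSpec(n_units, base_rate, mod_depth, f, 0.0, duration, seed)
    spec_b = OscillationSpec(n_units, base_rate, mod_depth, f, relative_phase,
                             duration, seed + 1)
    rec_a = oscillatory_bump_spikes(spec_a, network="color")

    if reversal_time is None:
        rec_b = oscillatory_bump_spikes(spec_b, network="location")
    else:
        def phase_fn(t):
            t = np.asarray(t)
            return relative_phase + np.pi * (t >= reversal_time)

        rec_b = oscillatory_bump_spikes(spec_b, network="location", phase_fn=phase_fn)
    return rec_a, rec_b


def phase_trial_ensemble(
    n_trials: int,
    concentration: float = 10.0,
    drift_model: str = "locked",
    seed: int = 0,
    f0: float = 30.0,
    duration: float = 3000.0,
    dt: float = 5.0,
    reversal_time: float | None = None,
):
    """Ensemble of per-trial phase trajectories for PPI testing.

    ``locked``: all trials advance identically (PPI = 1 everywhere).
    ``random_walk``: per-trial Brownian phase jitter with diffusion
    ``1/concentration`` rad^2 per ms (PPI decays with time).
    ``reversal``: locked until ``reversal_time`` (default mid-trace), then
    each trial jumps by an independent random offset (PPI drops).
    """
    from .analysis import PhaseSeries

    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + dt / 2, dt)
    omega = 2.0 * np.pi * f0 / 1000.0  # rad per ms
    base = omega * times[None, :]
    theta0 = rng.uniform(-np.pi, np.pi, size=(n_trials, 1))
    phases = base + theta0
    if drift_model == "locked":
        pass
    elif drift_model == "random_walk":
        step_var = dt / max(concentration, 1e-12)
        steps = rng.normal(0.0, np.sqrt(step_var), size=(n_trials, times.size))
        steps[:, 0] = 0.0
        phases = phases + np.cumsum(steps, axis=1)
    elif drift_model == "reversal":
        t_rev = duration / 2 if reversal_time is None else reversal_time
        jumps = rng.uniform(-np.pi, np.pi, size=(n_trials, 1))
        phases = phases + jumps * (times[None, :] >= t_rev)
    else:
        raise ValueError(f"unknown drift_model {drift_model!r}")
    wrapped = np.angle(np.exp(1j * phases))
    return PhaseSeries(phases=wrapped, times=times, f0=f0,
                       trial_ids=np.arange(n_trials))


def swap_scenario_fixture(
    category: str,
    seed: int = 0,
    n_exc: int = 256,
    delay_ms: float = 2000.0,
    f: float = 30.0,
    base_rate: float = 40.0,
    n_units: int | None = None,
) -> tuple:
    """Programmed trial realizing exactly one swap category.

    Returns ``(SimResult, TrialProtocol, category)``. Bumps oscillate at
    ``f`` Hz; the within-network pair is anti-phase. The cross-network
    phase relationship encodes the category: ``attentional`` pairs the
    wrong bumps from the start, ``memory`` reverses the correct pairing
    mid-delay, ``decoding`` keeps the correct pairing throughout.
    """
    if category not in ("memory", "attentional", "decoding"):
        raise ValueError(f"unknown swap category {category!r}")
    protocol = rescale_protocol(make_binding_trial(delay_ms=delay_ms), n_exc)
    duration = protocol.duration
    c_t, c_nt = protocol.item_centers["color"]
    l_t, l_nt = protocol.item_centers["location"]
    if n_units is None:
        n_units = max(8, n_exc // 8)
    t_rev = protocol.delay_window[0] + delay_ms / 2.0

    # phase offsets for the color-target bump relative to location-target
    if category == "attentional":
        color_t_phase = lambda t: np.pi * np.ones_like(np.asarray(t, dtype=float))
    elif category == "memory":
        color_t_phase = lambda t: np.pi * (np.asarray(t, dtype=float) >= t_rev)
    else:  # decoding: correct in-phase association throughout
        color_t_phase = lambda t: np.zeros_like(np.asarray(t, dtype=float))

    def anti(fn):
        return lambda t: fn(t) + np.pi

    def bump(center, network, phase_fn, s):
        spec = OscillationSpec(n_units, base_rate, 1.0, f, 0.0, duration, seed=s)
        return oscillatory_bump_spikes(spec, center=center, n_exc=n_exc,
                                       network=network, phase_fn=phase_fn)

    loc_t_phase = lambda t: np.zeros_like(np.asarray(t, dtype=float))
    color_rec = merge_records(
        [bump(c_t, "color", color_t_phase, seed * 10 + 1),
         bump(c_nt, "color", anti(color_t_phase), seed * 10 + 2)],
        "color",
    )
    loc_rec = merge_records(
        [bump(l_t, "location", loc_t_phase, seed * 10 + 3),
         bump(l_nt, "location", anti(loc_t_phase), seed * 10 + 4)],
        "location",
    )
    sim = SimResult(records={"color": color_rec, "location": loc_rec},
                    protocol=protocol, spec=None, seed=seed, dt=0.0)
    return sim, protocol, category
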