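"""CLI-driven reproductions of the main dynamical regimes at configurable scale.

Conductance sweeps, load-frequency curves, swap-rate experiments, readout
histograms, and the phase-preservation contrast between on-target and swap
trials. Every experiment is a pure function of (config, seeds); summaries
are written as TSV tables with a JSON provenance sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import netmodel as nm
from . import protocol as pr
from . import analysis as an
from . import decoder as dc
from .engine import integrate_trial

__all__ = [
    "SweepGrid",
    "ExperimentResult",
    "run_binding_trial",
    "run_grid_sweep",
    "swap_rate_experiments",
    "decode_histogram_experiment",
    "ppi_experiment",
    "load_frequency_experiment",
    "write_results",
]

DEFAULT_SCALE = 8
DEFAULT_DT = 0.05


@dataclass(frozen=True)
class SweepGrid:
    """Cartesian sweep over conductance axes."""

    axes: dict  # axis name -> sequence of values (absolute, unscaled nS)
    trials_per_cell: int = 3
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not self.axes or any(len(v) == 0 for v in self.axes.values()):
            raise ValueError("sweep axes must be non-empty")
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")

    def cells(self):
        names = list(self.axes)
        grids = np.meshgrid(*[np.asarray(self.axes[n]) for n in names], indexing="ij")
        flat = [g.ravel() for g in grids]
        for k in range(flat[0].size):
            yield {n: float(flat[i][k]) for i, n in enumerate(names)}


@dataclass
class ExperimentResult:
    name: str
    table: pd.DataFrame
    provenance: dict
    extras: dict = field(default_factory=dict)


def _scaled_spec(spec: nm.NetworkSpec, scale: float) -> nm.NetworkSpec:
    return nm.scale_network(spec, scale) if scale != 1 else spec


def _bump_counts(rec, center, window, bin_width=5.0):
    bw = an.BumpWindow.scaled(center, rec.n_exc)
    return an.bump_spike_counts(rec, bw, bin_width, window[0], window[1])


def _zero_lag(corr: an.CorrelationFunction) -> float:
    return float(corr.values[np.argmin(np.abs(corr.lags))])


def trial_summaries(sim, protocol) -> dict:
    """Within-network anti-phase, dominant frequency, bump strength, binding."""
    rec = sim.records["color"]
    dw = protocol.delay_window
    centers = protocol.item_centers["color"]
    out = {}
    if len(centers) >= 2:
        bcs = [_bump_counts(rec, c, dw) for c in centers[:2]]
        cc = an.cross_correlogram(bcs[0], bcs[1], 100.0)
        out["zero_lag_within"] = _zero_lag(cc)
        spec_res = an.correlation_spectrum(cc)
        out["dominant_freq"] = spec_res.peak_frequency
    else:
        bc = _bump_counts(rec, centers[0], dw)
        ac = an.cross_correlogram(bc, bc, 200.0)
        out["dominant_freq"] = an.correlation_spectrum(ac).peak_frequency
        out["zero_lag_within"] = np.nan
    out["bump_strength"] = an.bump_strength(rec, (dw[1] - 500.0, dw[1]))
    if protocol.bound_pair is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            centers_t, contrast = dc.pair_correlation_contrast(sim, protocol)
        mask = (centers_t >= dw[0]) & (centers_t < dw[1])
        out["binding_stability"] = float(np.nanmean(contrast[mask]))
    return out


def run_binding_trial(spec, protocol, seed, dt=DEFAULT_DT):
    """One binding trial: simulate, decode, and diagnose (if swap)."""
    sim = integrate_trial(spec, protocol, seed=seed, dt=dt)
    proto = sim.protocol
    decode = dc.decode_trial(sim.records["color"], proto)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        contrast = dc.pair_correlation_contrast(sim, proto)
    diagnosis = None
    if decode.label == "swap":
        diagnosis = dc.diagnose_swap(sim, proto, decode, contrast=contrast)
    return sim, decode, diagnosis, contrast


def run_grid_sweep(
    grid: SweepGrid,
    spec: nm.NetworkSpec | None = None,
    protocol: pr.TrialProtocol | None = None,
    scale: float = DEFAULT_SCALE,
    dt: float = DEFAULT_DT,
) -> ExperimentResult:
    """Per-cell summaries over a conductance grid.

    Each cell replaces the named conductances (printed, unscaled values),
    scales the network, and averages trial summaries over seeds. Failed
    simulations are recorded per cell, not fatal.
    """
    if spec is None:
        spec = nm.capacity2_spec()
    if protocol is None:
        protocol = pr.make_load_trial(2, delay_ms=1500.0)
    rows = []
    seeds_used = []
    for cell_idx, cell in enumerate(grid.cells()):
        cell_spec = replace(spec, conductances=replace(spec.conductances, **cell))
        scaled = _scaled_spec(cell_spec, scale)
        summaries = []
        failures = 0
        for k in range(grid.trials_per_cell):
            seed = grid.base_seed + cell_idx * 1000 + k
            seeds_used.append(seed)
            try:
                sim = integrate_trial(scaled, protocol, seed=seed, dt=dt)
                summaries.append(trial_summaries(sim, sim.protocol))
            except FloatingPointError:
                failures += 1
        row = dict(cell)
        row["n_ok"] = len(summaries)
        row["n_failed"] = failures
        for key in ("zero_lag_within", "dominant_freq", "bump_strength", "binding_stability"):
            vals = [s[key] for s in summaries if key in s and s[key] is not None]
            row[key] = float(np.nanmean(vals)) if vals else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    prov = _provenance("grid_sweep", spec, scale, dt, seeds_used,
                       axes={k: list(map(float, v)) for k, v in grid.axes.items()})
    return ExperimentResult("grid_sweep", table, prov)


def swap_rate_experiments(
    delays=(1000.0, 2000.0, 3000.0),
    distances_deg=(),
    n_trials: int = 10,
    scale: float = DEFAULT_SCALE,
    base_seed: int = 0,
    spec: nm.NetworkSpec | None = None,
    dt: float = DEFAULT_DT,
) -> ExperimentResult:
    """Swap fraction (± binomial SE) vs. delay duration and item distance."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if spec is None:
        spec = nm.capacity2_spec()
    scaled = _scaled_spec(spec, scale)
    rows = []
    seeds_used = []
    conditions = [("delay", d, pr.make_binding_trial(delay_ms=d)) for d in delays]
    for dist in distances_deg:
        proto = pr.make_distance_protocols([dist], delay_ms=3000.0)[0]
        conditions.append(("distance", dist, proto))
    trial_rows = []
    for ci, (kind, value, proto) in enumerate(conditions):
        n_swap = 0
        cats = {"memory": 0, "attentional": 0, "decoding": 0}
        for k in range(n_trials):
            seed = base_seed + ci * 10000 + k
            seeds_used.append(seed)
            sim, decode, diagnosis, _ = run_binding_trial(scaled, proto, seed, dt)
            if decode.label == "swap":
                n_swap += 1
                cats[diagnosis.category] += 1
            trial_rows.append(dict(kind=kind, value=value, seed=seed,
                                   readout=decode.readout_position,
                                   label=decode.label,
                                   category=None if diagnosis is None else diagnosis.category))
        frac = n_swap / n_trials
        se = float(np.sqrt(frac * (1 - frac) / n_trials))
        rows.append(dict(kind=kind, value=value, n_trials=n_trials,
                         swap_fraction=frac, swap_se=se, **cats))
    table = pd.DataFrame(rows)
    prov = _provenance("swap_rates", spec, scale, dt, seeds_used,
                       delays=list(delays), distances_deg=list(distances_deg))
    extras = {"trials": pd.DataFrame(trial_rows)}
    # monotonicity statistic across delays
    drows = table[table["kind"] == "delay"].sort_values("value")
    if len(drows) >= 2:
        from scipy.stats import spearmanr

        rho = spearmanr(drows["value"], drows["swap_fraction"]).statistic
        prov["delay_rank_correlation"] = None if np.isnan(rho) else float(rho)
    return ExperimentResult("swap_rates", table, prov, extras)


def decode_histogram_experiment(
    n_trials: int = 100,
    scale: float = DEFAULT_SCALE,
    base_seed: int = 0,
    delay_ms: float = 3000.0,
    spec: nm.NetworkSpec | None = None,
    dt: float = DEFAULT_DT,
    classify_swaps: bool = True,
) -> ExperimentResult:
    """Readout histogram over binding trials plus swap fraction and taxonomy."""
    if spec is None:
        spec = nm.capacity2_spec()
    scaled = _scaled_spec(spec, scale)
    proto = pr.make_binding_trial(delay_ms=delay_ms)
    rows = []
    for k in range(n_trials):
        seed = base_seed + k
        sim, decode, diagnosis, _ = run_binding_trial(scaled, proto, seed, dt)
        rows.append(dict(
            trial=k, seed=seed,
            readout=decode.readout_position,
            readout_ref=decode.readout_position * 2048.0 / scaled.topology.n_exc,
            label=decode.label,
            category=None if diagnosis is None else diagnosis.category,
        ))
    table = pd.DataFrame(rows)
    n_swap = int((table["label"] == "swap").sum())
    prov = _provenance("decode_histogram", spec, scale, dt,
                       list(range(base_seed, base_seed + n_trials)),
                       delay_ms=delay_ms)
    prov["swap_fraction"] = n_swap / n_trials
    if n_swap:
        cats = table.loc[table["label"] == "swap", "category"].value_counts()
        prov["taxonomy_pct"] = {
            c: 100.0 * int(cats.get(c, 0)) / n_swap
            for c in ("memory", "attentional", "decoding")
        }
    return ExperimentResult("decode_histogram", table, prov)


def _trial_delay_phase(sim, protocol, f0=30.0, lfp_dt=1.0):
    """Wavelet phase of the color-target bump LFP through the delay."""
    rec = sim.records["color"]
    dw = protocol.delay_window
    c_t = protocol.item_centers["color"][0]
    bw = an.BumpWindow.scaled(c_t, rec.n_exc)
    times, ids = rec.select("E")
    mask = bw.member_mask(rec.n_exc)[ids] & (times >= dw[0]) & (times < dw[1])
    lfp = an.lfp_from_spikes(times[mask] - dw[0], dw[1] - dw[0], dt=lfp_dt)
    ph = an.wavelet_phase(lfp, f0=f0)
    return an.PhaseSeries(phases=ph.phases, times=ph.times + dw[0], f0=f0)


def ppi_experiment(
    n_on_target: int = 10,
    n_swap: int = 10,
    scale: float = DEFAULT_SCALE,
    base_seed: int = 0,
    delay_ms: float = 2000.0,
    f0: float = 30.0,
    n_bootstrap: int = 500,
    spec: nm.NetworkSpec | None = None,
    dt: float = DEFAULT_DT,
    fixture_groups: tuple | None = None,
    max_sims: int | None = None,
) -> ExperimentResult:
    """PPI curves for on-target vs. swap groups with bootstrap SEs.

    Runs binding trials until each behavioral group has its quota (or
    ``max_sims`` is exhausted), takes the early delay as reference, and
    contrasts late-delay PPI. ``fixture_groups=(on_series, swap_series)``
    bypasses simulation (analysis-only path for tests).
    """
    if n_on_target < 1 or n_swap < 1:
        raise ValueError("both groups must be non-empty")
    rng_info = {}
    if fixture_groups is not None:
        groups = {"on_target": fixture_groups[0], "swap": fixture_groups[1]}
        t_ref = float(groups["on_target"].times[0])
    else:
        if spec is None:
            spec = nm.capacity2_spec()
        scaled = _scaled_spec(spec, scale)
        proto = pr.make_binding_trial(delay_ms=delay_ms)
        series = {"on_target": [], "swap": []}
        quota = {"on_target": n_on_target, "swap": n_swap}
        seed = base_seed
        n_run = 0
        cap = max_sims if max_sims is not None else 5 * (n_on_target + n_swap)
        while (len(series["on_target"]) < quota["on_target"]
               or len(series["swap"]) < quota["swap"]) and n_run < cap:
            sim, decode, _, _ = run_binding_trial(scaled, proto, seed, dt)
            if len(series[decode.label]) < quota[decode.label]:
                series[decode.label].append(_trial_delay_phase(sim, sim.protocol, f0))
            seed += 1
            n_run += 1
        rng_info["n_sims_run"] = n_run
        groups = {k: an.stack_phase_series(v) for k, v in series.items() if len(v) >= 2}
        if "on_target" not in groups or "swap" not in groups:
            raise RuntimeError("could not populate both behavioral groups")
        t_ref = float(groups["on_target"].times[0])
    rng = np.random.default_rng(base_seed + 991)
    rows = []
    curves = {}
    for label, ph in groups.items():
        n = ph.phases.shape[0]
        if n < 10:
            warnings.warn(f"group {label!r} has only {n} trials; bootstrap SEs unstable")
        curve = an.phase_preservation_index(ph, t_ref)
        boot = np.empty((n_bootstrap, curve.values.size))
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            resampled = an.PhaseSeries(phases=ph.phases[idx], times=ph.times, f0=ph.f0)
            boot[b] = an.phase_preservation_index(resampled, t_ref).values
        se = boot.std(axis=0)
        curves[label] = (curve, se)
        late = slice(-max(1, curve.values.size // 5), None)
        rows.append(dict(group=label, n_trials=n,
                         late_ppi=float(np.mean(curve.values[late])),
                         late_ppi_se=float(np.mean(se[late]))))
    table = pd.DataFrame(rows)
    prov = _provenance("ppi", spec, scale, dt, [base_seed], f0=f0,
                       n_bootstrap=n_bootstrap, **rng_info)
    on = table.set_index("group")
    prov["late_contrast"] = float(
        on.loc["on_target", "late_ppi"] - on.loc["swap", "late_ppi"]
    )
    return ExperimentResult("ppi", table, prov, extras={"curves": curves})


def load_frequency_experiment(
    loads=(1, 2, 3),
    n_seeds: int = 4,
    scale: float = DEFAULT_SCALE,
    base_seed: int = 0,
    delay_ms: float = 2000.0,
    spec: nm.NetworkSpec | None = None,
    dt: float = DEFAULT_DT,
) -> ExperimentResult:
    """Peak LFP frequency vs. memory load, for network and bump aggregates."""
    if spec is None:
        spec = nm.capacity3_spec()
    scaled = _scaled_spec(spec, scale)
    net_peaks, bump_peaks = {}, {}
    rows = []
    for load in loads:
        proto = pr.make_load_trial(load, delay_ms=delay_ms)
        net_power = None
        bump_power = None
        freqs = None
        for k in range(n_seeds):
            sim = integrate_trial(scaled, proto, seed=base_seed + 100 * load + k, dt=dt)
            rec = sim.records["color"]
            dw = sim.protocol.delay_window
            times, ids = rec.select("E")
            dmask = (times >= dw[0]) & (times < dw[1])
            lfp = an.lfp_from_spikes(times[dmask] - dw[0], dw[1] - dw[0], dt=1.0)
            sp = an.power_peak(lfp)
            freqs = sp.frequencies
            net_power = sp.power if net_power is None else net_power + sp.power
            for c in sim.protocol.item_centers["color"]:
                bw = an.BumpWindow.scaled(c, rec.n_exc)
                bmask = dmask & bw.member_mask(rec.n_exc)[ids]
                blfp = an.lfp_from_spikes(times[bmask] - dw[0], dw[1] - dw[0], dt=1.0)
                bsp = an.power_peak(blfp)
                bump_power = bsp.power if bump_power is None else bump_power + bsp.power
        band = (freqs >= 10.0) & (freqs <= 100.0)
        net_peaks[load] = float(freqs[band][np.argmax(net_power[band])])
        bump_peaks[load] = float(freqs[band][np.argmax(bump_power[band])])
        rows.append(dict(load=load, network_peak_hz=net_peaks[load],
                         bump_peak_hz=bump_peaks[load]))
    table = pd.DataFrame(rows)
    prov = _provenance("load_frequency", spec, scale, dt,
                       [base_seed + 100 * l + k for l in loads for k in range(n_seeds)])
    prov["network_ratios"] = an.load_frequency_ratio(net_peaks)
    prov["bump_ratios"] = an.load_frequency_ratio(bump_peaks)
    return ExperimentResult("load_frequency", table, prov)


def _provenance(name, spec, scale, dt, seeds, **extra) -> dict:
    prov = {
        "experiment": name,
        "scale": scale,
        "dt": dt,
        "seeds": sorted(set(int(s) for s in seeds)),
        "spec": None if spec is None else nm.spec_to_dict(spec),
    }
    prov.update(extra)
    return prov


def write_results(result: ExperimentResult, out_dir) -> list:
    """Write TSV table(s) + JSON summary; deterministic for fixed seeds."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    table_path = out / f"{result.name}.tsv"
    result.table.to_csv(table_path, sep="\t", index=False)
    written.append(table_path)
    for key, value in result.extras.items():
        if isinstance(value, pd.DataFrame):
            p = out / f"{result.name}_{key}.tsv"
            value.to_csv(p, sep="\t", index=False)
            written.append(p)
    summary_path = out / f"{result.name}_summary.json"
    summary_path.write_text(json.dumps(result.provenance, indent=2, default=_json_default))
    written.append(summary_path)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
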