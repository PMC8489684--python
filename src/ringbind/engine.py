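"""Forward-Euler integration of the two coupled spiking ring networks.

Conductance-based leaky integrate-and-fire dynamics with AMPA/GABA_A
instantaneous-jump exponential synapses, two-variable saturating NMDA
gating with voltage-dependent magnesium block, and independent Poisson
background drive onto every neuron.

The inner loop advances both networks in fixed-size blocks; external
Poisson arrivals are pregenerated per block with named numpy generator
streams, so the dynamics are deterministic per (spec, protocol, seed, dt)
and the hot kernel is free of RNG calls (and JIT-compiled when numba is
available).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .netmodel import NetworkSpec, build_network
from .protocol import TrialProtocol, rescale_protocol, stimulus_profile

__all__ = [
    "SpikeRecord",
    "SimResult",
    "background_drive",
    "integrate_trial",
    "validate_record",
    "write_spikes_tsv",
    "read_spikes_tsv",
]

MAX_DT_MS = 0.1
DEFAULT_DT_MS = 0.02
DEFAULT_BACKGROUND_RATE_HZ = 1800.0
BLOCK_STEPS = 2000


@dataclass
class SpikeRecord:
    """Timestamped spikes of one network (both populations)."""

    times: np.ndarray  # ms
    neurons: np.ndarray  # index within population
    populations: np.ndarray  # "E" / "I"
    network: str  # "color" | "location"
    duration: float  # ms
    dt: float  # ms
    seed: int
    n_exc: int = 0
    n_inh: int = 0

    def __len__(self) -> int:
        return self.times.size

    def select(self, population: str = "E") -> tuple:
        """(times, neuron indices) of one population."""
        mask = self.populations == population
        return self.times[mask], self.neurons[mask]


@dataclass
class SimResult:
    """Outcome of one trial: one spike record per network plus provenance."""

    records: dict  # network name -> SpikeRecord
    protocol: TrialProtocol
    spec: NetworkSpec | None
    seed: int
    dt: float


def background_drive(
    rate_per_neuron: float,
    duration: float,
    n_neurons: int,
    seed: int,
) -> list:
    """Homogeneous Poisson external event streams, one array of times per neuron.

    ``rate_per_neuron`` is in events/s, ``duration`` in ms. Streams are
    independent across neurons and deterministic per seed.
    """
    if rate_per_neuron < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    rate_ms = rate_per_neuron / 1000.0
    streams = []
    for _ in range(n_neurons):
        n = rng.poisson(rate_ms * duration)
        streams.append(np.sort(rng.uniform(0.0, duration, size=n)))
    return streams


def _step_block(
    # state, stacked over the two networks: shape (2, n)
    v_e, v_i, ref_e, ref_i,
    s_ampa, x_nmda, s_nmda, s_gaba, s_ext_e, s_ext_i,
    spk_e, spk_i,
    # pregenerated external arrival counts: (nsteps, 2, n)
    ext_e, ext_i,
    # connectivity (dense) and conductances
    w_ee, w_ei, w_ie,
    g_ee_ampa, g_ei_ampa, g_ee_nmda, g_ei_nmda, g_ii_gaba, g_ie_gaba,
    g_ext_e, g_ext_i, g_ee_across, g_ei_across, g_ee_nmda_across, g_ei_nmda_across,
    # stimulus: profiles (n_ev, ne), net id, [on, off) step indices
    stim_prof, stim_net, stim_on, stim_off,
    # kinetics / intrinsic
    dec_ampa, dec_gaba, dec_x, dt, tau_nmda, alpha, mg,
    c_e, gl_e, el_e, th_e, re_e, tref_e,
    c_i, gl_i, el_i, th_i, re_i, tref_i,
    e_exc, e_inh,
    step_offset, out_e, out_i,
):
    nsteps = ext_e.shape[0]
    ne = v_e.shape[1]
    ni = v_i.shape[1]
    for s in range(nsteps):
        gstep = step_offset + s
        t = gstep * dt
        # 1) gates <- spikes from previous step, decay, external arrivals
        for net in range(2):
            for j in range(ne):
                if spk_e[net, j]:
                    s_ampa[net, j] += 1.0
                    x_nmda[net, j] += 1.0
            for j in range(ni):
                if spk_i[net, j]:
                    s_gaba[net, j] += 1.0
            for j in range(ne):
                s_ampa[net, j] *= dec_ampa
                x_nmda[net, j] *= dec_x
                sn = s_nmda[net, j] + dt * (
                    -s_nmda[net, j] / tau_nmda
                    + alpha * x_nmda[net, j] * (1.0 - s_nmda[net, j])
                )
                if sn < 0.0:
                    sn = 0.0
                elif sn > 1.0:
                    sn = 1.0
                s_nmda[net, j] = sn
                s_ext_e[net, j] = s_ext_e[net, j] * dec_ampa + ext_e[s, net, j]
            for j in range(ni):
                s_gaba[net, j] *= dec_gaba
                s_ext_i[net, j] = s_ext_i[net, j] * dec_ampa + ext_i[s, net, j]

        # 2) currents and voltage update
        sum_ampa = np.empty(2)
        sum_nmda = np.empty(2)
        sum_gaba = np.empty(2)
        for net in range(2):
            sum_ampa[net] = s_ampa[net].sum()
            sum_nmda[net] = s_nmda[net].sum()
            sum_gaba[net] = s_gaba[net].sum()
        # batched products: columns = (ampa net0, nmda net0, ampa net1, nmda net1)
        gates_e = np.empty((ne, 4))
        for j in range(ne):
            gates_e[j, 0] = s_ampa[0, j]
            gates_e[j, 1] = s_nmda[0, j]
            gates_e[j, 2] = s_ampa[1, j]
            gates_e[j, 3] = s_nmda[1, j]
        gates_i = np.empty((ni, 2))
        for j in range(ni):
            gates_i[j, 0] = s_gaba[0, j]
            gates_i[j, 1] = s_gaba[1, j]
        conv_ee = np.dot(w_ee, gates_e)  # (ne, 4)
        conv_ei = np.dot(w_ei, gates_e)  # (ni, 4)
        conv_ie = np.dot(w_ie, gates_i)  # (ne, 2)
        for net in range(2):
            other = 1 - net
            conv_ampa = conv_ee[:, 2 * net]
            conv_nmda = conv_ee[:, 2 * net + 1]
            ei_ampa = conv_ei[:, 2 * net]
            ei_nmda = conv_ei[:, 2 * net + 1]
            ie_gaba = conv_ie[:, net]

            # stimulus current (pA) onto E
            i_stim = np.zeros(ne)
            for ev in range(stim_prof.shape[0]):
                if stim_net[ev] == net and stim_on[ev] <= gstep and gstep < stim_off[ev]:
                    for j in range(ne):
                        i_stim[j] += stim_prof[ev, j]

            for j in range(ne):
                v = v_e[net, j]
                block = 1.0 / (1.0 + mg * np.exp(-0.062 * v) / 3.57)
                g_fast = (
                    g_ee_ampa * conv_ampa[j]
                    + g_ee_across * sum_ampa[other]
                    + g_ext_e * s_ext_e[net, j]
                )
                g_nm = g_ee_nmda * conv_nmda[j] + g_ee_nmda_across * sum_nmda[other]
                g_gb = g_ie_gaba * ie_gaba[j]
                i_syn = (
                    g_fast * (v - e_exc)
                    + g_nm * block * (v - e_exc)
                    + g_gb * (v - e_inh)
                )
                i_leak = gl_e * (v - el_e)
                v_new = v + dt * (-(i_leak + i_syn) + i_stim[j]) / (c_e * 1000.0)
                if t < ref_e[net, j]:
                    v_new = re_e
                    spk_e[net, j] = False
                elif v_new >= th_e:
                    v_new = re_e
                    ref_e[net, j] = t + tref_e
                    spk_e[net, j] = True
                else:
                    spk_e[net, j] = False
                v_e[net, j] = v_new
                out_e[s, net, j] = spk_e[net, j]

            for j in range(ni):
                v = v_i[net, j]
                block = 1.0 / (1.0 + mg * np.exp(-0.062 * v) / 3.57)
                g_fast = (
                    g_ei_ampa * ei_ampa[j]
                    + g_ei_across * sum_ampa[other]
                    + g_ext_i * s_ext_i[net, j]
                )
                g_nm = g_ei_nmda * ei_nmda[j] + g_ei_nmda_across * sum_nmda[other]
                g_gb = g_ii_gaba * sum_gaba[net]
                i_syn = (
                    g_fast * (v - e_exc)
                    + g_nm * block * (v - e_exc)
                    + g_gb * (v - e_inh)
                )
                i_leak = gl_i * (v - el_i)
                v_new = v + dt * (-(i_leak + i_syn)) / (c_i * 1000.0)
                if t < ref_i[net, j]:
                    v_new = re_i
                    spk_i[net, j] = False
                elif v_new >= th_i:
                    v_new = re_i
                    ref_i[net, j] = t + tref_i
                    spk_i[net, j] = True
                else:
                    spk_i[net, j] = False
                v_i[net, j] = v_new
                out_i[s, net, j] = spk_i[net, j]
    return 0


try:  # JIT-compile the hot kernel when numba is available
    from numba import njit

    _step_block_jit = njit(cache=False, fastmath=True)(_step_block)
except Exception:  # pragma: no cover - exercised only without numba
    _step_block_jit = _step_block


def _rng_streams(seed: int, networks) -> dict:
    """One independent generator per (network, purpose)."""
    root = np.random.SeedSequence(seed)
    purposes = ("ext_e", "ext_i")
    keys = [(net, p) for net in networks for p in purposes]
    children = root.spawn(len(keys))
    return {k: np.random.default_rng(c) for k, c in zip(keys, children)}


def integrate_trial(
    spec: NetworkSpec,
    protocol: TrialProtocol,
    seed: int = 0,
    dt: float = DEFAULT_DT_MS,
    background_rate: float = DEFAULT_BACKGROUND_RATE_HZ,
    record_from: float = 0.0,
) -> SimResult:
    """Integrate both networks through one trial and record all spikes.

    Deterministic given ``(spec, protocol, seed, dt)``. Raises on ``dt``
    above 0.1 ms; aborts with a diagnostic on numerical blow-up.
    """
    if dt > MAX_DT_MS:
        raise ValueError(f"dt={dt} ms exceeds maximum {MAX_DT_MS} ms")
    protocol = rescale_protocol(protocol, spec.topology.n_exc)
    built = build_network(spec)
    duration = protocol.duration
    n_steps = int(round(duration / dt))
    networks = list(spec.networks)
    kin = spec.synapses
    g = spec.conductances
    ne, ni = spec.topology.n_exc, spec.topology.n_inh
    rngs = _rng_streams(seed, networks)

    # stacked state over the two networks
    v_e = np.full((2, ne), spec.exc.leak_reversal)
    v_i = np.full((2, ni), spec.inh.leak_reversal)
    ref_e = np.full((2, ne), -1.0)
    ref_i = np.full((2, ni), -1.0)
    s_ampa = np.zeros((2, ne))
    x_nmda = np.zeros((2, ne))
    s_nmda = np.zeros((2, ne))
    s_gaba = np.zeros((2, ni))
    s_ext_e = np.zeros((2, ne))
    s_ext_i = np.zeros((2, ni))
    spk_e = np.zeros((2, ne), dtype=np.bool_)
    spk_i = np.zeros((2, ni), dtype=np.bool_)

    w_ee = built.w_ee.dense()
    w_ei = built.w_ei
    w_ie = built.w_ie

    events = list(protocol.events)
    if events:
        stim_prof = np.stack(
            [stimulus_profile(ev, ne) * protocol.i_stim * 1000.0 for ev in events]
        )
        stim_net = np.array([networks.index(ev.network) for ev in events], dtype=np.int64)
        stim_on = np.array([int(round(ev.onset / dt)) for ev in events], dtype=np.int64)
        stim_off = np.array([int(round(ev.offset / dt)) for ev in events], dtype=np.int64)
    else:
        stim_prof = np.zeros((0, ne))
        stim_net = np.zeros(0, dtype=np.int64)
        stim_on = np.zeros(0, dtype=np.int64)
        stim_off = np.zeros(0, dtype=np.int64)

    dec_ampa = np.exp(-dt / kin.tau_ampa)
    dec_gaba = np.exp(-dt / kin.tau_gaba)
    dec_x = np.exp(-dt / kin.tau_nmda_rise)
    lam = background_rate / 1000.0 * dt

    times = {net: [] for net in networks}
    ids = {net: [] for net in networks}
    pops = {net: [] for net in networks}

    step0 = 0
    while step0 < n_steps:
        nb = min(BLOCK_STEPS, n_steps - step0)
        ext_e = np.empty((nb, 2, ne))
        ext_i = np.empty((nb, 2, ni))
        for k, net in enumerate(networks):
            ext_e[:, k, :] = rngs[(net, "ext_e")].poisson(lam, (nb, ne))
            ext_i[:, k, :] = rngs[(net, "ext_i")].poisson(lam, (nb, ni))
        out_e = np.zeros((nb, 2, ne), dtype=np.bool_)
        out_i = np.zeros((nb, 2, ni), dtype=np.bool_)
        _step_block_jit(
            v_e, v_i, ref_e, ref_i,
            s_ampa, x_nmda, s_nmda, s_gaba, s_ext_e, s_ext_i,
            spk_e, spk_i,
            ext_e, ext_i,
            w_ee, w_ei, w_ie,
            g.g_ee_ampa, g.g_ei_ampa, g.g_ee_nmda, g.g_ei_nmda,
            g.g_ii_gaba, g.g_ie_gaba, g.g_ext_e, g.g_ext_i,
            g.g_ee_ampa_across, g.g_ei_ampa_across,
            g.g_ee_nmda_across, g.g_ei_nmda_across,
            stim_prof, stim_net, stim_on, stim_off,
            dec_ampa, dec_gaba, dec_x, dt,
            kin.tau_nmda_decay, kin.nmda_saturation_rate, kin.mg_concentration,
            spec.exc.membrane_capacitance, spec.exc.leak_conductance,
            spec.exc.leak_reversal, spec.exc.spike_threshold,
            spec.exc.reset_potential, spec.exc.refractory_period,
            spec.inh.membrane_capacitance, spec.inh.leak_conductance,
            spec.inh.leak_reversal, spec.inh.spike_threshold,
            spec.inh.reset_potential, spec.inh.refractory_period,
            kin.exc_reversal, kin.inh_reversal,
            step0, out_e, out_i,
        )
        if not (np.all(np.isfinite(v_e)) and np.all(np.isfinite(v_i))):
            raise FloatingPointError(
                f"numerical blow-up near t={step0 * dt:.2f} ms"
            )
        for k, net in enumerate(networks):
            for out, label in ((out_e[:, k, :], "E"), (out_i[:, k, :], "I")):
                step_idx, nrn = np.nonzero(out)
                t_arr = (step0 + step_idx) * dt
                keep = t_arr >= record_from
                times[net].append(t_arr[keep])
                ids[net].append(nrn[keep])
                pops[net].append(np.full(keep.sum(), label, dtype="U1"))
        step0 += nb

    records = {}
    for net in networks:
        t_all = np.concatenate(times[net]) if times[net] else np.empty(0)
        i_all = np.concatenate(ids[net]) if ids[net] else np.empty(0, dtype=np.int64)
        p_all = np.concatenate(pops[net]) if pops[net] else np.empty(0, dtype="U1")
        order = np.argsort(t_all, kind="stable")
        records[net] = SpikeRecord(
            times=t_all[order],
            neurons=i_all[order].astype(np.int64),
            populations=p_all[order],
            network=net,
            duration=duration,
            dt=dt,
            seed=seed,
            n_exc=ne,
            n_inh=ni,
        )
    return SimResult(records=records, protocol=protocol, spec=spec, seed=seed, dt=dt)


def validate_record(record: SpikeRecord, spec: NetworkSpec) -> list:
    """Check bounds, time-ordering, and refractoriness; return violations."""
    violations = []
    t = record.times
    if t.size and (t.min() < 0 or t.max() > record.duration):
        violations.append("spike time outside [0, duration]")
    if np.any(np.diff(t) < 0):
        violations.append("events not time-sorted")
    for pop, params, n in (("E", spec.exc, record.n_exc), ("I", spec.inh, record.n_inh)):
        ptimes, pids = record.select(pop)
        if pids.size and (pids.min() < 0 or pids.max() >= n):
            violations.append(f"{pop} neuron index out of range")
        for neuron in np.unique(pids):
            st = np.sort(ptimes[pids == neuron])
            bad = int(np.sum(np.diff(st) < params.refractory_period - 1e-9))
            if bad:
                violations.append(
                    f"{pop} neuron {neuron}: {bad} inter-spike interval(s) "
                    f"below refractory period {params.refractory_period} ms"
                )
    return violations


# ---------------------------------------------------------------------------
# Spike I/O: TSV + JSON sidecar (optionally HDF5)


def write_spikes_tsv(result: SimResult, path) -> None:
    """Write all spikes as TSV (time_ms, neuron, pop, net) + JSON sidecar."""
    path = Path(path)
    rows = []
    for net, rec in result.records.items():
        for t, i, p in zip(rec.times, rec.neurons, rec.populations):
            rows.append((t, int(i), p, net))
    rows.sort(key=lambda r: (r[0], r[3], r[2], r[1]))
    with path.open("w") as fh:
        fh.write("time_ms\tneuron\tpop\tnet\n")
        for t, i, p, net in rows:
            fh.write(f"{t:.5f}\t{i}\t{p}\t{net}\n")

    from dataclasses import asdict as dc_asdict
    from .netmodel import spec_to_dict

    proto = dc_asdict(result.protocol)
    proto["events"] = [dc_asdict(ev) for ev in result.protocol.events]
    sidecar = {
        "spec": None if result.spec is None else spec_to_dict(result.spec),
        "protocol": proto,
        "seed": result.seed,
        "dt": result.dt,
        "duration": next(iter(result.records.values())).duration,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_spikes_tsv(path) -> dict:
    """Read spikes back into one SpikeRecord per network."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    raw = np.genfromtxt(
        path, delimiter="\t", skip_header=1,
        dtype=[("t", float), ("i", np.int64), ("p", "U1"), ("n", "U16")],
    )
    raw = np.atleast_1d(raw)
    topo = meta.get("spec", {}).get("topology", {}) if meta.get("spec") else {}
    records = {}
    for net in np.unique(raw["n"]):
        mask = raw["n"] == net
        records[str(net)] = SpikeRecord(
            times=raw["t"][mask],
            neurons=raw["i"][mask],
            populations=raw["p"][mask],
            network=str(net),
            duration=float(meta.get("duration", raw["t"].max() if raw.size else 0.0)),
            dt=float(meta.get("dt", DEFAULT_DT_MS)),
            seed=int(meta.get("seed", -1)),
            n_exc=int(topo.get("n_exc", 0)),
            n_inh=int(topo.get("n_inh", 0)),
        )
    return records


def write_spikes_hdf5(result: SimResult, path) -> None:
    """Optional HDF5 container mirroring the TSV schema."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["seed"] = result.seed
        fh.attrs["dt"] = result.dt
        for net, rec in result.records.items():
            grp = fh.create_group(net)
            grp.create_dataset("time_ms", data=rec.times)
            grp.create_dataset("neuron", data=rec.neurons)
            grp.create_dataset("pop", data=rec.populations.astype("S1"))
            grp.attrs["n_exc"] = rec.n_exc
            grp.attrs["n_inh"] = rec.n_inh
            grp.attrs["duration"] = rec.duration
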