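"""Network description: populations, ring connectivity, conductance sets.

Two one-dimensional ring networks ("color" and "location"), each with
excitatory and inhibitory leaky integrate-and-fire populations, all-to-all
connected with distance-tuned weights within a ring and untuned weak
AMPA-mediated excitation across rings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

__all__ = [
    "PopulationParams",
    "SynapseKinetics",
    "ConductanceSet",
    "RingTopology",
    "NetworkSpec",
    "ring_profile",
    "projection_matrix",
    "build_network",
    "mg_block",
    "scale_network",
    "capacity2_spec",
    "capacity3_spec",
    "load_network_config",
    "save_network_config",
]

NETWORK_NAMES = ("color", "location")


@dataclass(frozen=True)
class PopulationParams:
    """Intrinsic leaky integrate-and-fire parameters for one population."""

    membrane_capacitance: float  # nF
    leak_conductance: float  # nS
    leak_reversal: float  # mV
    spike_threshold: float  # mV
    reset_potential: float  # mV
    refractory_period: float  # ms

    def __post_init__(self) -> None:
        if not self.reset_potential < self.spike_threshold:
            raise ValueError("reset_potential must be below spike_threshold")
        if self.refractory_period <= 0:
            raise ValueError("refractory_period must be positive")
        if self.membrane_capacitance <= 0 or self.leak_conductance <= 0:
            raise ValueError("capacitance and leak conductance must be positive")


@dataclass(frozen=True)
class SynapseKinetics:
    """Kinetic constants for AMPA, GABA_A and two-variable NMDA gating."""

    tau_ampa: float = 2.0  # ms
    tau_gaba: float = 10.0  # ms
    tau_nmda_decay: float = 100.0  # ms
    tau_nmda_rise: float = 2.0  # ms
    nmda_saturation_rate: float = 0.5  # 1/ms
    mg_concentration: float = 1.0  # mM
    exc_reversal: float = 0.0  # mV
    inh_reversal: float = -70.0  # mV

    def __post_init__(self) -> None:
        for name in ("tau_ampa", "tau_gaba", "tau_nmda_decay", "tau_nmda_rise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.tau_nmda_decay > self.tau_ampa:
            raise ValueError("NMDA decay must be slower than AMPA decay")


@dataclass(frozen=True)
class ConductanceSet:
    """Unitary synaptic conductances (nS) for every projection class.

    ``*_across`` entries govern the inter-ring projections; setting all of
    them to zero recovers two fully independent networks.
    """

    g_ee_ampa: float
    g_ei_ampa: float
    g_ee_nmda: float
    g_ei_nmda: float
    g_ii_gaba: float
    g_ie_gaba: float
    g_ext_e: float
    g_ext_i: float
    g_ee_ampa_across: float = 0.0
    g_ei_ampa_across: float = 0.0
    g_ee_nmda_across: float = 0.0
    g_ei_nmda_across: float = 0.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")

    def decoupled(self) -> "ConductanceSet":
        """Copy with all across-network conductances set to zero."""
        return replace(
            self,
            g_ee_ampa_across=0.0,
            g_ei_ampa_across=0.0,
            g_ee_nmda_across=0.0,
            g_ei_nmda_across=0.0,
        )


@dataclass(frozen=True)
class RingTopology:
    """Ring sizes and tuning of the distance-dependent weight profiles.

    Neuron ``i`` of a population of size ``N`` sits at angle ``360*i/N``
    (0-based). EE, EI and IE projections are tuned; II and across-network
    projections are flat.
    """

    n_exc: int = 2048
    n_inh: int = 512
    j_plus_ee: float = 10.0
    sigma_ee: float = 9.0
    j_plus_ei: float = 2.4
    j_plus_ie: float = 2.4
    sigma_ei: float = 18.0
    sigma_ie: float = 18.0

    def __post_init__(self) -> None:
        if self.n_exc < 4 or self.n_inh < 4:
            raise ValueError("populations need at least 4 neurons")
        for name in ("sigma_ee", "sigma_ei", "sigma_ie"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def angles_exc(self) -> np.ndarray:
        return 360.0 * np.arange(self.n_exc) / self.n_exc

    def angles_inh(self) -> np.ndarray:
        return 360.0 * np.arange(self.n_inh) / self.n_inh


@dataclass(frozen=True)
class NetworkSpec:
    """Complete description of the two coupled rings.

    Both rings share identical parameters by default; ``scale_factor``
    records how far the description has been shrunk from the printed sizes.
    """

    exc: PopulationParams
    inh: PopulationParams
    synapses: SynapseKinetics
    topology: RingTopology
    conductances: ConductanceSet
    scale_factor: float = 1.0
    capacity_profile: str = "capacity2"
    networks: tuple = NETWORK_NAMES

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.capacity_profile not in ("capacity2", "capacity3", "custom"):
            raise ValueError(f"unknown capacity_profile {self.capacity_profile!r}")


def ring_profile(j_plus: float, sigma_deg: float, n: int) -> np.ndarray:
    """Distance-tuned weight profile on a ring of ``n`` neurons.

    ``W(theta) = J_minus + (j_plus - J_minus) * exp(-theta**2 / (2 sigma**2))``
    on circular distance ``theta`` in degrees, with ``J_minus`` chosen so the
    discrete circular mean of the profile equals 1 exactly. Entry ``k`` is
    the weight at index offset ``k`` (so entry 0 is the peak ``j_plus``).
    """
    if j_plus < 1:
        raise ValueError("j_plus must be >= 1")
    if sigma_deg <= 0:
        raise ValueError("sigma_deg must be positive")
    if n < 4:
        raise ValueError("need n >= 4")
    theta = circular_distance_deg(360.0 * np.arange(n) / n, 0.0)
    gauss = np.exp(-(theta**2) / (2.0 * sigma_deg**2))
    m = gauss.mean()
    if math.isclose(m, 1.0):
        return np.ones(n)
    j_minus = (1.0 - j_plus * m) / (1.0 - m)
    if j_minus < 0:
        raise ValueError(
            f"infeasible normalization: j_plus={j_plus} with sigma={sigma_deg} "
            f"requires negative baseline weight ({j_minus:.4g})"
        )
    return j_minus + (j_plus - j_minus) * gauss


def circular_distance_deg(a, b):
    """Shortest angular distance in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def projection_matrix(
    j_plus: float,
    sigma_deg: float,
    n_pre: int,
    n_post: int,
    tuned: bool = True,
) -> np.ndarray:
    """Dense (n_post, n_pre) weight matrix for one projection class.

    Tuned projections use :func:`ring_profile` evaluated at the angular
    distance between post and pre neurons, normalized so every row has mean
    1 over presynaptic neurons. Untuned projections are all-ones.
    """
    if not tuned:
        return np.ones((n_post, n_pre))
    ang_pre = 360.0 * np.arange(n_pre) / n_pre
    ang_post = 360.0 * np.arange(n_post) / n_post
    theta = circular_distance_deg(ang_post[:, None], ang_pre[None, :])
    gauss = np.exp(-(theta**2) / (2.0 * sigma_deg**2))
    m = gauss.mean(axis=1, keepdims=True)
    j_minus = (1.0 - j_plus * m) / (1.0 - m)
    if np.any(j_minus < 0):
        raise ValueError("infeasible normalization for tuned projection")
    return j_minus + (j_plus - j_minus) * gauss


class CirculantOperator:
    """Rotation-invariant weight operator applied by FFT convolution.

    Stores only the first row; ``apply`` matches the dense matrix-vector
    product with the full circulant matrix to floating-point accuracy.
    """

    def __init__(self, first_row: np.ndarray):
        self.first_row = np.asarray(first_row, dtype=float)
        self._fft = np.conj(np.fft.rfft(self.first_row))

    @property
    def n(self) -> int:
        return self.first_row.size

    def apply(self, x: np.ndarray) -> np.ndarray:
        # row i of the dense operator is first_row[(j - i) mod n]
        return np.fft.irfft(np.fft.rfft(x) * self._fft, n=self.n)

    def dense(self) -> np.ndarray:
        n = self.n
        idx = (np.arange(n)[None, :] - np.arange(n)[:, None]) % n
        return self.first_row[idx]


@dataclass
class BuiltNetwork:
    """Materialized connectivity operators for one ring (and across-links).

    Within-ring tuned operators are circulant on their own grids; untuned
    operators (II, across-network) are represented by constant matrices.
    """

    w_ee: CirculantOperator
    w_ei: np.ndarray  # (n_inh, n_exc)
    w_ie: np.ndarray  # (n_exc, n_inh)
    w_ii: np.ndarray  # (n_inh, n_inh), constant
    w_ee_across: np.ndarray  # (n_exc, n_exc), constant (possibly zero)
    w_ei_across: np.ndarray  # (n_inh, n_exc), constant (possibly zero)


def build_network(spec: NetworkSpec) -> BuiltNetwork:
    """Build connectivity operators for every projection class of one ring.

    Both rings are identical, so a single :class:`BuiltNetwork` serves both.
    """
    top = spec.topology
    g = spec.conductances
    w_ee = CirculantOperator(ring_profile(top.j_plus_ee, top.sigma_ee, top.n_exc))
    w_ei = projection_matrix(top.j_plus_ei, top.sigma_ei, top.n_exc, top.n_inh)
    w_ie = projection_matrix(top.j_plus_ie, top.sigma_ie, top.n_inh, top.n_exc)
    w_ii = projection_matrix(1.0, 1.0, top.n_inh, top.n_inh, tuned=False)
    any_across_ee = g.g_ee_ampa_across > 0 or g.g_ee_nmda_across > 0
    any_across_ei = g.g_ei_ampa_across > 0 or g.g_ei_nmda_across > 0
    w_ee_across = (
        np.ones((top.n_exc, top.n_exc)) if any_across_ee else np.zeros((top.n_exc, top.n_exc))
    )
    w_ei_across = (
        np.ones((top.n_inh, top.n_exc)) if any_across_ei else np.zeros((top.n_inh, top.n_exc))
    )
    return BuiltNetwork(w_ee, w_ei, w_ie, w_ii, w_ee_across, w_ei_across)


def mg_block(v, mg_mm: float = 1.0):
    """Voltage-dependent magnesium unblock factor of the NMDA conductance.

    ``1 / (1 + [Mg] * exp(-0.062 V) / 3.57)``: strictly increasing in ``v``,
    tending to 0 at very hyperpolarized and 1 at very depolarized voltages.
    """
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + mg_mm * np.exp(-0.062 * v) / 3.57)


def scale_network(spec: NetworkSpec, factor: float) -> NetworkSpec:
    """Shrink population sizes by ``factor``, preserving total synaptic drive.

    Recurrent and across-network unitary conductances are multiplied by
    ``factor``; external drive and tuning widths (degrees) are unchanged.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return spec
    top = spec.topology
    n_exc = top.n_exc / factor
    n_inh = top.n_inh / factor
    if n_exc != int(n_exc) or n_inh != int(n_inh):
        raise ValueError(
            f"factor {factor} does not divide populations ({top.n_exc}, {top.n_inh})"
        )
    g = spec.conductances
    scaled_g = replace(
        g,
        g_ee_ampa=g.g_ee_ampa * factor,
        g_ei_ampa=g.g_ei_ampa * factor,
        g_ee_nmda=g.g_ee_nmda * factor,
        g_ei_nmda=g.g_ei_nmda * factor,
        g_ii_gaba=g.g_ii_gaba * factor,
        g_ie_gaba=g.g_ie_gaba * factor,
        g_ee_ampa_across=g.g_ee_ampa_across * factor,
        g_ei_ampa_across=g.g_ei_ampa_across * factor,
        g_ee_nmda_across=g.g_ee_nmda_across * factor,
        g_ei_nmda_across=g.g_ei_nmda_across * factor,
    )
    scaled_top = replace(top, n_exc=int(n_exc), n_inh=int(n_inh))
    return replace(
        spec,
        topology=scaled_top,
        conductances=scaled_g,
        scale_factor=spec.scale_factor * factor,
    )


# ---------------------------------------------------------------------------
# Printed parameter sets

_EXC_DEFAULT = dict(
    membrane_capacitance=0.5,
    leak_conductance=25.0,
    leak_reversal=-70.0,
    spike_threshold=-50.0,
    reset_potential=-60.0,
    refractory_period=2.0,
)
_INH_DEFAULT = dict(
    membrane_capacitance=0.2,
    leak_conductance=20.0,
    leak_reversal=-70.0,
    spike_threshold=-50.0,
    reset_potential=-60.0,
    refractory_period=1.0,
)

_ACROSS = dict(
    g_ee_ampa_across=0.45,
    g_ei_ampa_across=0.18,
    g_ee_nmda_across=0.0,
    g_ei_nmda_across=0.0,
)

CAPACITY2 = dict(
    conductances=dict(
        g_ee_ampa=0.09,
        g_ei_ampa=0.256,
        g_ee_nmda=0.24,
        g_ei_nmda=0.11,
        g_ii_gaba=2.0,
        g_ie_gaba=3.0,
        g_ext_e=3.5,
        g_ext_i=2.74,
        **_ACROSS,
    ),
    topology=dict(
        n_exc=2048,
        n_inh=512,
        j_plus_ee=10.0,
        sigma_ee=9.0,
        j_plus_ei=2.4,
        j_plus_ie=2.4,
        sigma_ei=18.0,
        sigma_ie=18.0,
    ),
)

CAPACITY3 = dict(
    conductances=dict(
        g_ee_ampa=0.126,
        g_ei_ampa=0.256,
        g_ee_nmda=0.2,
        g_ei_nmda=0.11,
        g_ii_gaba=2.0,
        g_ie_gaba=3.0,
        g_ext_e=3.58,
        g_ext_i=2.8,
        **_ACROSS,
    ),
    topology=dict(
        n_exc=2048,
        n_inh=512,
        j_plus_ee=11.0,
        sigma_ee=9.0,
        j_plus_ei=2.6,
        j_plus_ie=2.6,
        sigma_ei=30.0,
        sigma_ie=30.0,
    ),
)


def _spec_from_block(block: dict, name: str, coupled: bool) -> NetworkSpec:
    cond = dict(block["conductances"])
    if not coupled:
        for key in list(cond):
            if key.endswith("_across"):
                cond[key] = 0.0
    return NetworkSpec(
        exc=PopulationParams(**block.get("exc", _EXC_DEFAULT)),
        inh=PopulationParams(**block.get("inh", _INH_DEFAULT)),
        synapses=SynapseKinetics(**block.get("synapses", {})),
        topology=RingTopology(**block["topology"]),
        conductances=ConductanceSet(**cond),
        capacity_profile=name,
    )


def capacity2_spec(coupled: bool = True) -> NetworkSpec:
    """Parameter set for rings holding up to two simultaneous bumps."""
    return _spec_from_block(CAPACITY2, "capacity2", coupled)


def capacity3_spec(coupled: bool = True) -> NetworkSpec:
    """Parameter set for rings holding up to three simultaneous bumps."""
    return _spec_from_block(CAPACITY3, "capacity3", coupled)


def spec_to_dict(spec: NetworkSpec) -> dict:
    d = asdict(spec)
    d["networks"] = list(spec.networks)
    return d


def spec_from_dict(d: dict) -> NetworkSpec:
    return NetworkSpec(
        exc=PopulationParams(**d["exc"]),
        inh=PopulationParams(**d["inh"]),
        synapses=SynapseKinetics(**d["synapses"]),
        topology=RingTopology(**d["topology"]),
        conductances=ConductanceSet(**d["conductances"]),
        scale_factor=d.get("scale_factor", 1.0),
        capacity_profile=d.get("capacity_profile", "custom"),
        networks=tuple(d.get("networks", NETWORK_NAMES)),
    )


def save_network_config(path, specs: dict | None = None) -> None:
    """Write named parameter blocks (JSON) to ``path``.

    Defaults to the two printed parameter sets under keys ``capacity2`` and
    ``capacity3``.
    """
    if specs is None:
        specs = {"capacity2": capacity2_spec(), "capacity3": capacity3_spec()}
    payload = {name: spec_to_dict(s) for name, s in specs.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_network_config(path, block: str = "capacity2") -> NetworkSpec:
    """Load one named parameter block from a JSON network configuration."""
    payload = json.loads(Path(path).read_text())
    if block not in payload:
        raise KeyError(f"block {block!r} not in {sorted(payload)}")
    return spec_from_dict(payload[block])
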