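"""Timed stimulation schedules: cues, binding pulse, delay, probe."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "StimulusEvent",
    "TrialProtocol",
    "make_load_trial",
    "make_binding_trial",
    "make_distance_protocols",
    "stimulus_drive",
    "save_protocol",
    "load_protocol",
]

# Base cue intensity (nA) and geometry. The cue drives a Gaussian current
# profile wide enough to seed a bump; calibrated once against the capacity-2
# set so a lone 250 ms cue reliably instantiates a persistent bump.
I_STIM_NA = 0.35
CUE_DURATION_MS = 250.0
CUE_WIDTH_DEG = 9.0  # = sigma_ee of both printed parameter sets
BINDING_AMPLITUDE = 7.5
BINDING_DURATION_MS = 50.0
PROBE_AMPLITUDE = 0.25  # read as 1/4 of cue intensity
PROBE_DURATION_MS = 500.0
DEFAULT_TARGET = 520  # of 2048
DEFAULT_NONTARGET = 1480


@dataclass(frozen=True)
class StimulusEvent:
    """One rectangular-in-time, Gaussian-in-space current injection."""

    network: str  # "color" | "location"
    center: int  # neuron index (on the reference n_exc grid)
    width_deg: float
    amplitude: float  # multiples of the base cue intensity
    onset: float  # ms
    offset: float  # ms
    kind: str = "cue"  # "cue" | "binding" | "probe"

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class TrialProtocol:
    """Full schedule of one trial on the two coupled rings.

    ``item_centers`` maps network name to the cue positions (neuron indices
    on a ring of ``n_exc`` neurons). ``bound_pair`` names the (color,
    location) centers tied together by the binding pulse, if any.
    """

    n_exc: int
    load: int
    item_centers: dict
    events: tuple  # of StimulusEvent
    cue_onset: float
    cue_offset: float
    delay_duration: float
    probe_window: tuple | None = None  # (start, end) ms
    decode_window: tuple | None = None
    bound_pair: tuple | None = None  # (color center, location center)
    i_stim: float = I_STIM_NA

    def __post_init__(self) -> None:
        if not 1 <= self.load <= 3:
            raise ValueError("load must be 1..3")
        if self.decode_window is not None and self.probe_window is not None:
            a, b = self.decode_window
            pa, pb = self.probe_window
            if a < pa - 1e-9 or b > pb + 1e-9:
                raise ValueError("decode window must lie within the probe window")

    @property
    def duration(self) -> float:
        end = self.cue_offset + self.delay_duration
        if self.probe_window is not None:
            end = max(end, self.probe_window[1])
        for ev in self.events:
            end = max(end, ev.offset)
        return end

    @property
    def delay_window(self) -> tuple:
        start = max([self.cue_offset] + [ev.offset for ev in self.events if ev.kind == "binding"])
        return (start, start + self.delay_duration)

    def events_for(self, network: str):
        return [ev for ev in self.events if ev.network == network]


def _spaced_centers(load: int, n_exc: int) -> list:
    """Equally spaced item centers; load-1 sits at n_exc//2 by convention."""
    base = n_exc // 2
    return [int((base + round(k * n_exc / load)) % n_exc) for k in range(load)]


def make_load_trial(
    load: int,
    n_exc: int = 2048,
    delay_ms: float = 1000.0,
    cue_onset: float = 250.0,
    network: str = "color",
) -> TrialProtocol:
    """Cue-only protocol presenting 1-3 equally spaced bumps on one ring."""
    if not 1 <= load <= 3:
        raise ValueError("load must be between 1 and 3")
    centers = _spaced_centers(load, n_exc)
    cue_offset = cue_onset + CUE_DURATION_MS
    events = tuple(
        StimulusEvent(network, c, CUE_WIDTH_DEG, 1.0, cue_onset, cue_offset, "cue")
        for c in centers
    )
    return TrialProtocol(
        n_exc=n_exc,
        load=load,
        item_centers={network: centers},
        events=events,
        cue_onset=cue_onset,
        cue_offset=cue_offset,
        delay_duration=delay_ms,
    )


def make_binding_trial(
    delay_ms: float = 3000.0,
    target: int = DEFAULT_TARGET,
    nontarget: int = DEFAULT_NONTARGET,
    n_exc: int = 2048,
    cue_onset: float = 250.0,
    pulse_during_cue: bool = False,
) -> TrialProtocol:
    """Load-2 binding protocol: cues, 7.5x/50 ms pulse, delay, weak probe.

    Two items per ring; the binding pulse hits the (color target, location
    target) pair. The probe stimulates the cued location at 0.25x cue
    intensity for 500 ms, which is also the decode window.
    """
    if target == nontarget:
        raise ValueError("target and nontarget must differ")
    for idx in (target, nontarget):
        if not 0 <= idx < n_exc:
            raise ValueError(f"index {idx} out of range for n_exc={n_exc}")
    cue_offset = cue_onset + CUE_DURATION_MS
    if pulse_during_cue:
        pulse_on = cue_offset - BINDING_DURATION_MS
    else:
        pulse_on = cue_offset
    pulse_off = pulse_on + BINDING_DURATION_MS
    delay_start = pulse_off
    probe_on = delay_start + delay_ms
    probe_off = probe_on + PROBE_DURATION_MS
    events = []
    for net in ("color", "location"):
        for c in (target, nontarget):
            events.append(
                StimulusEvent(net, c, CUE_WIDTH_DEG, 1.0, cue_onset, cue_offset, "cue")
            )
    for net in ("color", "location"):
        events.append(
            StimulusEvent(
                net, target, CUE_WIDTH_DEG, BINDING_AMPLITUDE, pulse_on, pulse_off, "binding"
            )
        )
    events.append(
        StimulusEvent(
            "location", target, CUE_WIDTH_DEG, PROBE_AMPLITUDE, probe_on, probe_off, "probe"
        )
    )
    return TrialProtocol(
        n_exc=n_exc,
        load=2,
        item_centers={"color": [target, nontarget], "location": [target, nontarget]},
        events=tuple(events),
        cue_onset=cue_onset,
        cue_offset=cue_offset,
        delay_duration=delay_ms,
        probe_window=(probe_on, probe_off),
        decode_window=(probe_on, probe_off),
        bound_pair=(target, target),
    )


def make_distance_protocols(
    distances_deg, delay_ms: float = 3000.0, n_exc: int = 2048, target: int = DEFAULT_TARGET
):
    """Binding protocols with the non-target at each circular distance."""
    protocols = []
    for d in distances_deg:
        if not 0 < d <= 180:
            raise ValueError(f"distance must be in (0, 180], got {d}")
        offset = int(round(d / 360.0 * n_exc))
        nontarget = int((target + offset) % n_exc)
        protocols.append(
            make_binding_trial(delay_ms, target=target, nontarget=nontarget, n_exc=n_exc)
        )
    return protocols


def stimulus_drive(
    event: StimulusEvent, t: float, n_exc: int, i_stim: float = I_STIM_NA
) -> np.ndarray:
    """Injected current vector (nA) for one event at time ``t`` (ms).

    Gaussian spatial profile over circular distance from the event center;
    amplitude ``event.amplitude * i_stim`` at the center inside
    ``[onset, offset)``; zero outside.
    """
    if not (event.onset <= t < event.offset):
        return np.zeros(n_exc)
    return stimulus_profile(event, n_exc) * i_stim


def stimulus_profile(event: StimulusEvent, n_exc: int) -> np.ndarray:
    """Unit-peak spatial profile scaled by the event amplitude."""
    from .netmodel import circular_distance_deg

    ang = 360.0 * np.arange(n_exc) / n_exc
    center_ang = 360.0 * event.center / n_exc
    theta = circular_distance_deg(ang, center_ang)
    return event.amplitude * np.exp(-(theta**2) / (2.0 * event.width_deg**2))


def scale_center(center: int, n_from: int, n_to: int) -> int:
    """Map a neuron index between grids of different sizes (same angle)."""
    return int(round(center * n_to / n_from)) % n_to


def rescale_protocol(protocol: TrialProtocol, n_exc: int) -> TrialProtocol:
    """Re-express a protocol on a ring of a different size."""
    if n_exc == protocol.n_exc:
        return protocol

    def sc(c):
        return scale_center(c, protocol.n_exc, n_exc)

    events = tuple(
        StimulusEvent(
            ev.network, sc(ev.center), ev.width_deg, ev.amplitude, ev.onset, ev.offset, ev.kind
        )
        for ev in protocol.events
    )
    return TrialProtocol(
        n_exc=n_exc,
        load=protocol.load,
        item_centers={k: [sc(c) for c in v] for k, v in protocol.item_centers.items()},
        events=events,
        cue_onset=protocol.cue_onset,
        cue_offset=protocol.cue_offset,
        delay_duration=protocol.delay_duration,
        probe_window=protocol.probe_window,
        decode_window=protocol.decode_window,
        bound_pair=None
        if protocol.bound_pair is None
        else tuple(sc(c) for c in protocol.bound_pair),
        i_stim=protocol.i_stim,
    )


def save_protocol(protocol: TrialProtocol, path) -> None:
    d = asdict(protocol)
    d["events"] = [asdict(ev) for ev in protocol.events]
    Path(path).write_text(json.dumps(d, indent=2))


def load_protocol(path) -> TrialProtocol:
    d = json.loads(Path(path).read_text())
    events = tuple(StimulusEvent(**ev) for ev in d.pop("events"))
    d["item_centers"] = {k: list(v) for k, v in d["item_centers"].items()}
    for key in ("probe_window", "decode_window", "bound_pair"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return TrialProtocol(events=events, **d)
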