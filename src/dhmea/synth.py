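"""Synthetic dorsal-horn MEA recordings with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised without animal data:

* homogeneous Poisson background firing per channel (2 Hz default);
* electrically evoked spikes per afferent class, drawn Poisson with mean
  ``mean_evoked x recruitment x depth_weight x windup_gain x drug_factor``
  and placed inside the class latency window (Abeta 3-11 ms, Adelta
  11-90 ms, C 90-300 ms);
* a post-discharge process (300-800 ms) coupled to Adelta and C
  recruitment, deep-biased;
* strength-duration recruitment following the Weiss law
  ``I_th(d) = rheobase x (1 + chronaxie / d)`` passed through a logistic,
  with thresholds ordered Abeta < Adelta < C;
* wind-up gain growing with position in >= 0.5 Hz trains (C, PD and
  ongoing background), flat at 0.1 Hz and below;
* first-order morphine suppression kinetics per fibre class and region;
* region-level response envelopes for von Frey, thermal and capsaicin
  stimulation.

Per-channel mean evoked counts at full recruitment (Abeta 1.7, Adelta 2.4,
C 5.0, PD 1.5) are calibrated so the array-summed responses at the
standard test amplitudes land in the few-tens-of-spikes range typical of
in-vivo recordings of this kind.  All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    ArrayGeometry,
    SpikeTable,
    StimulusEvent,
    ValidationError,
    write_events,
    write_spikes,
)

__all__ = [
    "FibreClassParams",
    "DrugSensitivity",
    "PostDischargeParams",
    "BackgroundParams",
    "CohortSpec",
    "Recording",
    "default_fibres",
    "default_postdischarge",
    "default_background",
    "recruitment_fraction",
    "windup_gain",
    "drug_factor",
    "simulate_train",
    "simulate_natural",
    "simulate_cohort",
    "amplitude_series_events",
    "duration_series_events",
    "frequency_train_events",
    "morphine_schedule",
    "natural_events",
    "expected_evoked_sum",
    "inject_pulses",
]


@dataclass(frozen=True)
class DrugSensitivity:
    """First-order suppression: ``1 - A_region (1 - exp(-(t - delay)/tau))``."""

    amplitude_by_region: dict = field(default_factory=dict)
    delay_min: float = 0.0
    tau_min: float = 10.0


@dataclass(frozen=True)
class FibreClassParams:
    """Ground-truth parameters for one afferent class."""

    name: str
    rheobase_mA: float
    chronaxie_ms: float
    recruitment_slope_mA: float
    latency_window_ms: tuple[float, float]
    mean_evoked: float  # spikes/channel/stimulus at full recruitment
    depth_weights: np.ndarray  # [channel], sums to n_channels
    latency_shape: str = "uniform"
    windup_beta: float = 0.0
    windup_cap: int = 10
    drug: DrugSensitivity = field(default_factory=DrugSensitivity)

    def __post_init__(self) -> None:
        w = np.asarray(self.depth_weights, dtype=float)
        if (w < 0).any():
            raise ValidationError("depth_weights must be >= 0")
        if abs(w.sum() - w.size) > 1e-9:
            raise ValidationError("depth_weights must sum to n_channels")
        object.__setattr__(self, "depth_weights", w)
        if self.windup_beta < 0:
            raise ValidationError("windup_beta must be >= 0")
        if self.latency_shape not in ("uniform", "shifted-gamma"):
            raise ValidationError(f"unknown latency_shape {self.latency_shape!r}")


@dataclass(frozen=True)
class PostDischargeParams:
    """Post-discharge process: gain coupled to Adelta and C recruitment."""

    window_ms: tuple[float, float] = (300.0, 800.0)
    mean_evoked: float = 1.5
    depth_weights: np.ndarray = field(
        default_factory=lambda: _region_weights(0.8, 0.6, 10.0 / 7.0)
    )
    windup_beta: float = 0.2
    windup_cap: int = 10

    def __post_init__(self) -> None:
        w = np.asarray(self.depth_weights, dtype=float)
        if (w < 0).any():
            raise ValidationError("depth_weights must be >= 0")
        object.__setattr__(self, "depth_weights", w)


@dataclass(frozen=True)
class BackgroundParams:
    """Ongoing (stimulus-independent) firing."""

    baseline_rate_hz: float = 2.0  # per channel
    windup_background_beta: float = 0.03  # ongoing growth within 0.5 Hz trains
    windup_cap: int = 10

    def __post_init__(self) -> None:
        if self.baseline_rate_hz < 0 or self.windup_background_beta < 0:
            raise ValidationError("background rates must be >= 0")


def _region_weights(sup: float, inter: float, deep: float, n: int = 16) -> np.ndarray:
    w = np.empty(n)
    w[0:3] = sup
    w[3:9] = inter
    w[9:16] = deep
    return w


def default_fibres(n_channels: int = 16) -> dict[str, FibreClassParams]:
    """Default afferent classes; rheobases sit strictly between the tested
    amplitudes (0.1/0.5/1/5/10 mA) so the discrete series shows thresholds
    at 0.5 (Abeta), 1 (Adelta) and 5 mA (C) without tuning."""
    uniform = np.ones(n_channels)
    return {
        "Abeta": FibreClassParams(
            name="Abeta",
            rheobase_mA=0.3,
            chronaxie_ms=0.15,
            recruitment_slope_mA=0.04,
            latency_window_ms=(3.0, 11.0),
            mean_evoked=1.7,
            depth_weights=uniform,
            windup_beta=0.0,
            drug=DrugSensitivity({"deep": 0.15}, delay_min=60.0, tau_min=20.0),
        ),
        "Adelta": FibreClassParams(
            name="Adelta",
            rheobase_mA=0.8,
            chronaxie_ms=0.4,
            recruitment_slope_mA=0.1,
            latency_window_ms=(11.0, 90.0),
            mean_evoked=2.4,
            depth_weights=uniform,
            windup_beta=0.0,
            drug=DrugSensitivity(
                {"superficial": 0.5, "deep": 0.5}, delay_min=10.0, tau_min=20.0
            ),
        ),
        "C": FibreClassParams(
            name="C",
            rheobase_mA=3.0,
            chronaxie_ms=1.5,
            recruitment_slope_mA=0.5,
            latency_window_ms=(90.0, 300.0),
            mean_evoked=5.0,
            depth_weights=_region_weights(2.2, 1.0 / 6.0, 1.2, n_channels),
            windup_beta=0.15,
            drug=DrugSensitivity(
                {"superficial": 0.8, "intermediate": 0.8, "deep": 0.8},
                delay_min=5.0,
                tau_min=10.0,
            ),
        ),
    }


def default_postdischarge() -> PostDischargeParams:
    return PostDischargeParams()


def default_background() -> BackgroundParams:
    return BackgroundParams()


# ---------------------------------------------------------------------------
# deterministic building blocks


def recruitment_fraction(
    fibre: FibreClassParams, amplitude_mA: float, duration_ms: float
) -> float:
    """Fraction of the class recruited by a square pulse.

    Weiss strength-duration law gives the threshold
    ``I_th(d) = rheobase (1 + chronaxie/d)`` (so ``I_th(chronaxie) = 2 x
    rheobase``); recruitment is a logistic in amplitude around that
    threshold, clamped to 0 below 1 % and to 1 above 99 %.
    """
    if duration_ms <= 0:
        raise ValidationError("duration_ms must be > 0")
    if amplitude_mA < 0:
        raise ValidationError("amplitude_mA must be >= 0")
    if amplitude_mA == 0:
        return 0.0
    i_th = fibre.rheobase_mA * (1.0 + fibre.chronaxie_ms / duration_ms)
    with np.errstate(over="ignore"):
        f = 1.0 / (1.0 + np.exp(-(amplitude_mA - i_th) / fibre.recruitment_slope_mA))
    if f < 0.01:
        return 0.0
    if f > 0.99:
        return 1.0
    return float(f)


def windup_gain(beta: float, cap: int, index_in_train: int, train_frequency_hz: float) -> float:
    """``1 + beta * min(i, cap)`` for trains at >= 0.5 Hz, else exactly 1."""
    if train_frequency_hz >= 0.5:
        return 1.0 + beta * min(index_in_train, cap)
    return 1.0


def drug_factor(fibre: FibreClassParams, region: str, t_min: float) -> float:
    """Multiplicative suppression at ``t_min`` minutes after application.

    ``1 - A (1 - exp(-(t - delay)/tau))``; 1 before application and in
    regions the class is insensitive in.
    """
    amp = fibre.drug.amplitude_by_region.get(region, 0.0)
    if amp == 0.0 or t_min <= 0:
        return 1.0
    t_eff = max(0.0, t_min - fibre.drug.delay_min)
    return 1.0 - amp * (1.0 - np.exp(-t_eff / fibre.drug.tau_min))


def _draw_latencies(rng, n: int, window_ms: tuple[float, float], shape: str) -> np.ndarray:
    lo, hi = window_ms
    if shape == "uniform":
        return rng.uniform(lo, hi, n)
    # shifted gamma rising from the window floor, clipped inside the window
    t = lo + rng.gamma(2.0, (hi - lo) / 4.0, n)
    return np.clip(t, lo, np.nextafter(hi, lo))


# ---------------------------------------------------------------------------
# stimulus protocols


def _pulse_train(
    start_s: float,
    n: int,
    freq: float,
    amplitude: float,
    duration_ms: float,
    train_id: str,
    label: str,
) -> list[StimulusEvent]:
    gap = 1.0 / freq
    return [
        StimulusEvent(start_s + i * gap, "electrical", amplitude, duration_ms, train_id, i, freq, label)
        for i in range(n)
    ]


def amplitude_series_events(
    amplitudes=(0.1, 0.5, 1.0, 5.0, 10.0),
    n_per_train: int = 20,
    frequency_hz: float = 0.015,
    duration_ms: float = 2.0,
    rest_s: float = 300.0,
    start_s: float = 60.0,
) -> list[StimulusEvent]:
    """Ascending amplitude series: trains of 2 ms pulses at 0.015 Hz."""
    events, t = [], start_s
    for amp in amplitudes:
        events += _pulse_train(t, n_per_train, frequency_hz, amp, duration_ms, f"amp_{amp:g}", f"{amp:g}mA")
        t = events[-1].time_s + rest_s
    return events


def duration_series_events(
    durations_ms=(0.2, 1.0, 2.0, 10.0, 20.0),
    amplitude_mA: float = 5.0,
    n_per_train: int = 20,
    frequency_hz: float = 0.015,
    rest_s: float = 300.0,
    start_s: float = 60.0,
) -> list[StimulusEvent]:
    """Fixed 5 mA trains of increasing pulse duration."""
    events, t = [], start_s
    for dur in durations_ms:
        events += _pulse_train(t, n_per_train, frequency_hz, amplitude_mA, dur, f"dur_{dur:g}", f"{dur:g}ms")
        t = events[-1].time_s + rest_s
    return events


def frequency_train_events(
    frequencies_hz=(0.1, 0.5),
    n_per_train: int = 20,
    amplitude_mA: float = 5.0,
    duration_ms: float = 2.0,
    rest_s: float = 900.0,
    start_s: float = 60.0,
) -> list[StimulusEvent]:
    """Control (0.1 Hz) and wind-up (0.5 Hz) trains of 5 mA, 2 ms pulses."""
    events, t = [], start_s
    for freq in frequencies_hz:
        events += _pulse_train(t, n_per_train, freq, amplitude_mA, duration_ms, f"freq_{freq:g}", f"{freq:g}Hz")
        t = events[-1].time_s + rest_s
    return events


def morphine_schedule(
    saline_min: float = 30.0,
    drug_min: float = 90.0,
    frequency_hz: float = 0.015,
    amplitude_mA: float = 5.0,
    duration_ms: float = 2.0,
    start_s: float = 60.0,
) -> tuple[list[StimulusEvent], float]:
    """Fixed-stimulus pharmacology schedule.

    Returns ``(events, application_time_s)``: a saline block then continued
    stimulation after drug application, all at 0.015 Hz.
    """
    gap = 1.0 / frequency_hz
    n_sal = int(round(saline_min * 60.0 * frequency_hz))
    n_drug = int(round(drug_min * 60.0 * frequency_hz))
    events = _pulse_train(start_s, n_sal, frequency_hz, amplitude_mA, duration_ms, "saline", "saline")
    t_app = events[-1].time_s + gap / 2.0
    drug_start = events[-1].time_s + gap
    events += _pulse_train(drug_start, n_drug, frequency_hz, amplitude_mA, duration_ms, "morphine", "morphine")
    return events, t_app


def natural_events(
    modality: str, amplitudes, duration_s: float = 5.0, gap_s: float = 60.0, start_s: float = 30.0
) -> list[StimulusEvent]:
    """One application per amplitude (grams, deg C, or unitless for chemical)."""
    events, t = [], start_s
    for i, amp in enumerate(amplitudes):
        events.append(
            StimulusEvent(t, modality, float(amp), duration_s * 1000.0, f"{modality}_{amp:g}", 0, 0.0, f"{modality}_{amp:g}")
        )
        t += duration_s + gap_s
    return events


# ---------------------------------------------------------------------------
# spike generation


def _background_spikes(
    rng, n_channels: int, t0: float, t1: float, rate_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    span = max(0.0, t1 - t0)
    times, chans = [], []
    for c in range(n_channels):
        k = rng.poisson(rate_hz * span)
        times.append(t0 + rng.uniform(0.0, span, k))
        chans.append(np.full(k, c + 1, dtype=np.int64))
    return np.concatenate(times), np.concatenate(chans)


def simulate_train(
    events: list[StimulusEvent],
    geometry: ArrayGeometry = ArrayGeometry(),
    fibres: dict[str, FibreClassParams] | None = None,
    pd_params: PostDischargeParams | None = None,
    bg: BackgroundParams | None = None,
    seed=0,
    drug_application_s: float | None = None,
    tail_s: float = 1.5,
) -> SpikeTable:
    """Simulate one animal's recording for an electrical-stimulation protocol.

    Background firing is homogeneous Poisson per channel over the whole
    recording (with ongoing-activity growth inside >= 0.5 Hz trains);
    evoked spikes are Poisson per stimulus, afferent class and channel
    with rate ``mean_evoked x recruitment x depth_weight x windup_gain x
    drug_factor``, placed inside the class latency window.  Bit-identical
    output for identical seed.
    """
    if not events:
        raise ValidationError("events must be non-empty")
    fibres = fibres or default_fibres(geometry.n_channels)
    pd_params = pd_params or default_postdischarge()
    bg = bg or default_background()
    rng = np.random.default_rng(seed)
    events = sorted(events, key=lambda e: e.time_s)
    t_end = events[-1].time_s + tail_s

    times, chans = _background_spikes(rng, geometry.n_channels, 0.0, t_end, bg.baseline_rate_hz)
    all_t, all_c = [times], [chans]

    region_of = np.array([geometry.region_map[c] for c in range(1, geometry.n_channels + 1)])

    for ev in events:
        if ev.modality != "electrical":
            continue
        t_min = (
            (ev.time_s - drug_application_s) / 60.0 if drug_application_s is not None else -1.0
        )
        fracs = {}
        for name, fibre in fibres.items():
            frac = recruitment_fraction(fibre, ev.amplitude, ev.duration_ms)
            fracs[name] = frac
            if frac == 0.0:
                continue
            gain = windup_gain(fibre.windup_beta, fibre.windup_cap, ev.index_in_train, ev.train_frequency_hz)
            dfac = np.array([drug_factor(fibre, r, t_min) for r in region_of])
            lam = fibre.mean_evoked * frac * fibre.depth_weights * gain * dfac
            counts = rng.poisson(lam)
            total = int(counts.sum())
            if total:
                lat = _draw_latencies(rng, total, fibre.latency_window_ms, fibre.latency_shape)
                all_t.append(ev.time_s + lat / 1000.0)
                all_c.append(np.repeat(np.arange(1, geometry.n_channels + 1), counts))
        # post-discharge coupled to Adelta and C recruitment; inherits the
        # C-fibre drug sensitivity (it is driven by nociceptive input)
        pd_frac = 0.5 * (fracs.get("Adelta", 0.0) + fracs.get("C", 0.0))
        if pd_frac > 0.0:
            gain = windup_gain(pd_params.windup_beta, pd_params.windup_cap, ev.index_in_train, ev.train_frequency_hz)
            dfac = np.array([drug_factor(fibres["C"], r, t_min) for r in region_of])
            lam = pd_params.mean_evoked * pd_frac * pd_params.depth_weights * gain * dfac
            counts = rng.poisson(lam)
            total = int(counts.sum())
            if total:
                lat = _draw_latencies(rng, total, pd_params.window_ms, "uniform")
                all_t.append(ev.time_s + lat / 1000.0)
                all_c.append(np.repeat(np.arange(1, geometry.n_channels + 1), counts))
        # ongoing-activity growth between 0.5 Hz train stimuli
        if ev.train_frequency_hz >= 0.5 and bg.windup_background_beta > 0:
            extra = bg.baseline_rate_hz * bg.windup_background_beta * min(ev.index_in_train, bg.windup_cap)
            if extra > 0:
                t1 = ev.time_s + 1.0 / ev.train_frequency_hz
                et, ec = _background_spikes(rng, geometry.n_channels, ev.time_s, t1, extra)
                all_t.append(et)
                all_c.append(ec)

    return SpikeTable(np.concatenate(all_t), np.concatenate(all_c), geometry.n_channels)


# --- natural stimuli -------------------------------------------------------

# sustained-drive weight thresholds (g) per region: intermediate recruits
# at the lightest hairs, deep at moderate ones, superficial only at the
# noxious 26 g hair
_VFH_THRESHOLD_G = {"superficial": 26.0, "intermediate": 2.0, "deep": 6.0}
_NOXIOUS_HEAT_C = 50.0


def _mech_envelope(t: np.ndarray, grams: float, duration_s: float, region: str) -> np.ndarray:
    """Region firing-rate envelope (Hz/channel above background) for a vFH."""
    rate = np.zeros_like(t)
    on = (t >= 0) & (t < 0.3)
    off = (t >= duration_s) & (t < duration_s + 0.3)
    transient = 6.0 * np.log1p(grams)
    rate[on | off] += transient
    thr = _VFH_THRESHOLD_G[region]
    if grams >= thr:
        sus = 4.0 * np.log1p(grams - thr + 1.0)
        rate[(t >= 0) & (t < duration_s)] += sus
        # after-discharge lengthens with hair weight
        ad_dur = 0.05 * grams
        ad = (t >= duration_s) & (t < duration_s + ad_dur)
        rate[ad] += sus * np.exp(-(t[ad] - duration_s) / max(ad_dur, 1e-9))
    return rate


def _thermal_envelope(t: np.ndarray, temp_c: float, duration_s: float, region: str) -> np.ndarray:
    """Contact transients (temperature-independent) plus, for noxious heat,
    a late ramp in superficial and deep regions as the skin heats."""
    rate = np.zeros_like(t)
    on = (t >= 0) & (t < 0.3)
    off = (t >= duration_s) & (t < duration_s + 0.3)
    rate[on | off] += 12.0
    if temp_c >= _NOXIOUS_HEAT_C and region in ("superficial", "deep"):
        ramp = (t >= 0.7 * duration_s) & (t < duration_s + 0.5)
        x = (t[ramp] - 0.7 * duration_s) / (0.3 * duration_s)
        rate[ramp] += 10.0 * np.minimum(x, 1.0)
    return rate


def _chemical_envelope(t: np.ndarray, region: str) -> np.ndarray:
    """Capsaicin: ~30 s broad activation, then a delayed deep component."""
    rate = np.zeros_like(t)
    burst = (t >= 0) & (t < 30.0)
    rate[burst] += 8.0 * np.exp(-t[burst] / 15.0)
    if region == "deep":
        late = (t >= 110.0) & (t < 130.0)
        rate[late] += 3.0
    return rate


def simulate_natural(
    events: list[StimulusEvent],
    geometry: ArrayGeometry = ArrayGeometry(),
    bg: BackgroundParams | None = None,
    seed=0,
    tail_s: float = 30.0,
) -> SpikeTable:
    """Simulate a natural-stimulation recording (vFH / thermal / capsaicin).

    Spikes are an inhomogeneous Poisson process whose rate is the region
    envelope for the stimulus plus the homogeneous background; envelopes
    are evaluated on a 10 ms grid.  Applications may not overlap.
    """
    if not events:
        raise ValidationError("events must be non-empty")
    bg = bg or default_background()
    rng = np.random.default_rng(seed)
    events = sorted(events, key=lambda e: e.time_s)
    horizon = {"mechanical": 10.0, "thermal": 10.0, "chemical": 180.0}
    for a, b in zip(events, events[1:]):
        if a.time_s + horizon.get(a.modality, 10.0) > b.time_s:
            raise ValidationError("natural-stimulus applications overlap")
    last = events[-1]
    t_end = last.time_s + horizon.get(last.modality, 10.0) + tail_s
    times, chans = _background_spikes(rng, geometry.n_channels, 0.0, t_end, bg.baseline_rate_hz)
    all_t, all_c = [times], [chans]
    dt = 0.01
    for ev in events:
        grid = np.arange(0.0, horizon.get(ev.modality, 10.0), dt)
        dur = ev.duration_ms / 1000.0
        for c in range(geometry.n_channels):
            region = geometry.region_map[c + 1]
            if ev.modality == "mechanical":
                rate = _mech_envelope(grid, ev.amplitude, dur, region)
            elif ev.modality == "thermal":
                rate = _thermal_envelope(grid, ev.amplitude, dur, region)
            elif ev.modality == "chemical":
                rate = _chemical_envelope(grid, region)
            else:
                raise ValidationError(f"simulate_natural cannot handle {ev.modality!r}")
            counts = rng.poisson(rate * dt)
            total = int(counts.sum())
            if total:
                offs = np.repeat(grid, counts) + rng.uniform(0.0, dt, total)
                all_t.append(ev.time_s + offs)
                all_c.append(np.full(total, c + 1, dtype=np.int64))
    return SpikeTable(np.concatenate(all_t), np.concatenate(all_c), geometry.n_channels)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Recording:
    """One simulated animal: spikes + events (+ drug application time)."""

    spikes: SpikeTable
    events: list[StimulusEvent]
    drug_application_s: float | None = None


PROTOCOLS = ("amplitude_series", "duration_series", "frequency_trains", "morphine", "vfh", "thermal", "capsaicin")


@dataclass(frozen=True)
class CohortSpec:
    """A cohort to simulate: protocol, size and the master seed."""

    protocol: str = "amplitude_series"
    n_animals: int = 4
    seed: int = 0
    protocol_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")
        if self.protocol not in PROTOCOLS:
            raise ValidationError(f"unknown protocol {self.protocol!r}")


def _build_protocol(spec: CohortSpec) -> tuple[list[StimulusEvent], float | None]:
    kw = spec.protocol_kwargs
    if spec.protocol == "amplitude_series":
        return amplitude_series_events(**kw), None
    if spec.protocol == "duration_series":
        return duration_series_events(**kw), None
    if spec.protocol == "frequency_trains":
        return frequency_train_events(**kw), None
    if spec.protocol == "morphine":
        return morphine_schedule(**kw)
    if spec.protocol == "vfh":
        amps = kw.get("amplitudes", (1.4, 2.0, 6.0, 8.0, 10.0, 26.0))
        return natural_events("mechanical", amps), None
    if spec.protocol == "thermal":
        amps = kw.get("amplitudes", (30.0, 55.0))
        return natural_events("thermal", amps), None
    if spec.protocol == "capsaicin":
        return natural_events("chemical", (1.0,), gap_s=300.0), None
    raise ValidationError(f"unknown protocol {spec.protocol!r}")


def simulate_cohort(
    spec: CohortSpec,
    geometry: ArrayGeometry = ArrayGeometry(),
    fibres: dict[str, FibreClassParams] | None = None,
    pd_params: PostDischargeParams | None = None,
    bg: BackgroundParams | None = None,
    out_dir=None,
) -> list[Recording]:
    """Simulate ``n_animals`` independent recordings of one protocol.

    Animal sub-seeds derive deterministically from the master seed; with
    ``out_dir`` each animal's spikes/events are written as CSV (refusing
    to overwrite existing files).
    """
    events, t_app = _build_protocol(spec)
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_animals)
    cohort = []
    for a, child in enumerate(children):
        if spec.protocol in ("vfh", "thermal", "capsaicin"):
            spikes = simulate_natural(events, geometry, bg, seed=child)
        else:
            spikes = simulate_train(
                events, geometry, fibres, pd_params, bg, seed=child, drug_application_s=t_app
            )
        cohort.append(Recording(spikes, list(events), t_app))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for a, rec in enumerate(cohort):
            sp = out / f"animal_{a:02d}_spikes.csv"
            evp = out / f"animal_{a:02d}_events.csv"
            for p in (sp, evp):
                if p.exists():
                    raise FileExistsError(f"refusing to overwrite {p}")
            write_spikes(sp, rec.spikes)
            write_events(evp, rec.events)
    return cohort


# ---------------------------------------------------------------------------
# oracles and trace synthesis helpers


def expected_evoked_sum(
    band: str,
    amplitude_mA: float,
    duration_ms: float,
    fibres: dict[str, FibreClassParams] | None = None,
    pd_params: PostDischargeParams | None = None,
    index_in_train: int = 0,
    train_frequency_hz: float = 0.015,
    channels: np.ndarray | None = None,
) -> float:
    """Expected evoked count for one stimulus, summed over ``channels``.

    Closed-form Poisson mean for the named band (``Abeta``/``Adelta``/
    ``C``/``PD``/``CPD``) — the oracle against which simulated counts are
    checked.
    """
    fibres = fibres or default_fibres()
    pd_params = pd_params or default_postdischarge()
    if channels is None:
        channels = np.arange(1, 17)
    idx = np.asarray(channels) - 1

    def fibre_mean(name: str) -> float:
        f = fibres[name]
        frac = recruitment_fraction(f, amplitude_mA, duration_ms)
        gain = windup_gain(f.windup_beta, f.windup_cap, index_in_train, train_frequency_hz)
        return f.mean_evoked * frac * gain * float(f.depth_weights[idx].sum())

    def pd_mean() -> float:
        frac = 0.5 * (
            recruitment_fraction(fibres["Adelta"], amplitude_mA, duration_ms)
            + recruitment_fraction(fibres["C"], amplitude_mA, duration_ms)
        )
        gain = windup_gain(pd_params.windup_beta, pd_params.windup_cap, index_in_train, train_frequency_hz)
        return pd_params.mean_evoked * frac * gain * float(pd_params.depth_weights[idx].sum())

    if band in ("Abeta", "Adelta", "C"):
        return fibre_mean(band)
    if band == "PD":
        return pd_mean()
    if band == "CPD":
        return fibre_mean("C") + pd_mean()
    raise ValidationError(f"unknown band {band!r}")


def inject_pulses(
    spikes: SpikeTable,
    duration_s: float,
    sampling_rate_hz: float = 40000.0,
    noise_range_v: tuple[float, float] = (-1.0, 0.0),
    pulse_v: float = -5.0,
    pulse_ms: float = 0.2,
    baseline_quiet: bool = False,
    seed=0,
) -> "TraceSet":
    """Synthesize a wideband trace with pulses at known spike times.

    Exists solely to exercise threshold-crossing detection: each spike
    becomes a rectangular ``pulse_v`` deflection on its channel, on top of
    uniform noise (or silence outside the baseline window when
    ``baseline_quiet``).
    """
    from .io import TraceSet

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate_hz))
    lo, hi = noise_range_v
    samples = rng.uniform(lo, hi, (spikes.n_channels, n))
    if baseline_quiet:
        # noise only where the detector derives its threshold; quiet after
        samples[:, int(10.0 * sampling_rate_hz) :] = 0.0
    width = max(1, int(round(pulse_ms / 1000.0 * sampling_rate_hz)))
    for t, c in zip(spikes.time_s, spikes.channel):
        i0 = int(round(t * sampling_rate_hz))
        samples[c - 1, i0 : i0 + width] = pulse_v
    return TraceSet(samples, sampling_rate_hz, "wideband", 0.0)
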