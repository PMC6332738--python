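"""Local-field-potential conditioning and stimulus-locked averaging.

LFP channels receive a Butterworth high-pass (designed from a 0.01 Hz stop
band and a 0.5 Hz pass band) followed by a 50 Hz notch (Q = 100, order 6,
read as three cascaded order-2 biquads), both applied forward-backward so
the evoked potential incurs no phase distortion.  Averaged evoked LFPs are
baseline-corrected by the mean pre-stimulus voltage of the first 20
stimuli.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import StimulusEvent, TraceSet, ValidationError

__all__ = ["LFPFilterSpec", "filter_lfp", "average_lfp"]


@dataclass(frozen=True)
class LFPFilterSpec:
    """High-pass + notch design parameters for 5 kHz LFP traces."""

    highpass_stop_hz: float = 0.01
    highpass_pass_hz: float = 0.5
    notch_hz: float = 50.0
    notch_q: float = 100.0
    notch_order: int = 6
    sampling_rate_hz: float = 5000.0
    gpass_db: float = 3.0
    gstop_db: float = 30.0

    def __post_init__(self) -> None:
        nyq = self.sampling_rate_hz / 2
        if not 0 < self.highpass_stop_hz < self.highpass_pass_hz < nyq:
            raise ValidationError("need 0 < stop band < pass band < Nyquist")
        if self.notch_q <= 0:
            raise ValidationError("notch Q must be > 0")
        if self.notch_order < 2 or self.notch_order % 2:
            raise ValidationError("notch order must be an even integer >= 2")


def _design(spec: LFPFilterSpec) -> np.ndarray:
    """Cascade of second-order sections: Butterworth high-pass + notch."""
    fs = spec.sampling_rate_hz
    n, wn = signal.buttord(
        spec.highpass_pass_hz, spec.highpass_stop_hz, spec.gpass_db, spec.gstop_db, fs=fs
    )
    sos = signal.butter(max(n, 1), wn, btype="highpass", output="sos", fs=fs)
    b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=fs)
    notch = signal.tf2sos(b, a)
    for _ in range(spec.notch_order // 2):
        sos = np.vstack([sos, notch])
    return sos


def filter_lfp(trace: TraceSet, spec: LFPFilterSpec = LFPFilterSpec()) -> TraceSet:
    """Zero-phase high-pass + notch conditioning of an LFP trace set.

    Output length equals input length.  A warning is raised when the trace
    is shorter than ~3x the slowest filter time constant, where edge
    transients dominate.
    """
    if trace.kind != "lfp":
        raise ValidationError("filter_lfp expects an 'lfp' trace set")
    if trace.sampling_rate_hz != spec.sampling_rate_hz:
        raise ValidationError(
            f"trace sampled at {trace.sampling_rate_hz} Hz, spec expects "
            f"{spec.sampling_rate_hz} Hz"
        )
    scale_s = 3.0 / (2 * np.pi * spec.highpass_pass_hz)
    if trace.duration_s < 3 * scale_s:
        warnings.warn(
            "trace shorter than 3x the high-pass impulse-response scale; "
            "edge transients may dominate",
            stacklevel=2,
        )
    sos = _design(spec)
    out = signal.sosfiltfilt(sos, trace.samples, axis=1)
    return TraceSet(out, trace.sampling_rate_hz, "lfp", trace.start_time_s)


def average_lfp(
    trace: TraceSet,
    events: list[StimulusEvent],
    window_s: tuple[float, float] = (-0.1, 1.0),
    baseline_n_events: int = 20,
    baseline_ms: float = 300.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus-locked mean LFP per channel after whole-channel baseline.

    The baseline is each channel's mean voltage over ``baseline_ms`` before
    the first ``baseline_n_events`` stimuli (all available, with a warning,
    when fewer exist).  Returns ``(times_s, mean[channel, sample])`` with
    times relative to the stimulus.
    """
    if not events:
        raise ValidationError("events must be non-empty")
    events = sorted(events, key=lambda e: e.time_s)
    fs = trace.sampling_rate_hz
    lo_s, hi_s = window_s
    if not lo_s < hi_s:
        raise ValidationError("window must have lo < hi")
    n_out = int(round((hi_s - lo_s) * fs))
    n_base = int(round(baseline_ms / 1000.0 * fs))
    if len(events) < baseline_n_events:
        warnings.warn(
            f"only {len(events)} events available for the {baseline_n_events}-"
            "stimulus baseline; using all of them",
            stacklevel=2,
        )
    base_events = events[: min(baseline_n_events, len(events))]
    base_chunks = []
    for ev in base_events:
        i1 = int(round((ev.time_s - trace.start_time_s) * fs))
        i0 = i1 - n_base
        if i0 < 0 or i1 > trace.samples.shape[1]:
            raise ValidationError(f"baseline window of event at {ev.time_s} s leaves the trace")
        base_chunks.append(trace.samples[:, i0:i1])
    baseline = np.concatenate(base_chunks, axis=1).mean(axis=1)  # [channel]
    acc = np.zeros((trace.n_channels, n_out))
    for ev in events:
        i0 = int(round((ev.time_s + lo_s - trace.start_time_s) * fs))
        if i0 < 0 or i0 + n_out > trace.samples.shape[1]:
            raise ValidationError(f"epoch of event at {ev.time_s} s leaves the trace")
        acc += trace.samples[:, i0 : i0 + n_out]
    mean = acc / len(events) - baseline[:, None]
    times = lo_s + np.arange(n_out) / fs
    return times, mean
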