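"""From raw spikes/traces + events to the baseline-corrected epoch tensor.

The central intermediate is :class:`EpochTensor` — counts of threshold
crossings in ``values[stimulus, channel, bin]`` with 1 ms bins spanning a
1.1 s window (100 ms before to 1 s after each stimulus) by default.  The
enforced pipeline order is::

    raw -> blank_artifact -> whole_channel_baseline -> per_stimulus_baseline

tracked by the ``stage`` tag.  The per-stimulus step is deliberately
skippable: frequency (wind-up) datasets must not receive it, because it
would erase the slow growth of ongoing activity the analysis looks for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .io import SpikeTable, StimulusEvent, TraceSet, ValidationError, events_to_frame, frame_to_events

__all__ = [
    "DetectionSpec",
    "EpochSpec",
    "EpochTensor",
    "DegenerateThresholdError",
    "StageError",
    "detect_crossings",
    "extract_epochs",
    "blank_artifact",
    "whole_channel_baseline",
    "per_stimulus_baseline",
    "save_tensor",
    "load_tensor",
]

STAGES = ("raw", "channel_corrected", "stimulus_corrected")


class DegenerateThresholdError(ValueError):
    """Baseline window has zero depth (mean equals minimum)."""


class StageError(ValueError):
    """Operation applied at the wrong point of the correction pipeline."""


@dataclass(frozen=True)
class DetectionSpec:
    """Threshold-crossing capture rule.

    A spike is recorded where the voltage first crosses below
    ``mu - threshold_fraction * (mu - min)`` of its channel's baseline
    window; further crossings within ``dead_time_ms`` are suppressed.
    """

    threshold_fraction: float = 0.10
    polarity: str = "negative"
    dead_time_ms: float = 1.0
    baseline_window_s: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValidationError("threshold_fraction must lie in (0, 1)")
        if self.dead_time_ms < 0:
            raise ValidationError("dead_time_ms must be >= 0")
        if self.polarity != "negative":
            raise ValidationError("only negative-going detection is implemented")


@dataclass(frozen=True)
class EpochSpec:
    pre_ms: float = 100.0
    post_ms: float = 1000.0
    bin_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.pre_ms <= 0 or self.post_ms <= 0:
            raise ValidationError("pre_ms and post_ms must be > 0")
        n = (self.pre_ms + self.post_ms) / self.bin_ms
        if abs(n - round(n)) > 1e-9:
            raise ValidationError("(pre_ms + post_ms) / bin_ms must be an integer")

    @property
    def n_bins(self) -> int:
        return int(round((self.pre_ms + self.post_ms) / self.bin_ms))

    @property
    def n_pre_bins(self) -> int:
        return int(round(self.pre_ms / self.bin_ms))

    def bin_start_ms(self) -> np.ndarray:
        """Left edge of every bin in ms relative to the stimulus."""
        return np.arange(self.n_bins) * self.bin_ms - self.pre_ms


@dataclass
class EpochTensor:
    """Binned peristimulus counts: ``values[stimulus, channel, bin]``.

    Bin ``b`` covers ``[b*bin_ms - pre_ms, (b+1)*bin_ms - pre_ms)`` relative
    to its stimulus (half-open; a spike exactly at stimulus time falls in
    the first post-stimulus bin).
    """

    values: np.ndarray
    spec: EpochSpec
    events: list[StimulusEvent]
    stage: str = "raw"
    baseline_per_channel: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError("values must be [stimulus, channel, bin]")
        if self.values.shape[0] != len(self.events):
            raise ValidationError("first axis must match the event list")
        if self.values.shape[2] != self.spec.n_bins:
            raise ValidationError("bin axis does not match the epoch spec")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.stage == "raw":
            if not np.issubdtype(self.values.dtype, np.integer):
                raise ValidationError("raw tensors must hold integer counts")
            if (self.values < 0).any():
                raise ValidationError("raw counts must be non-negative")

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def pre_slice(self) -> slice:
        return slice(0, self.spec.n_pre_bins)

    def select(self, **kw) -> np.ndarray:
        """Boolean mask of stimuli matching the given event attributes.

        ``tensor.select(label="5mA")`` or ``select(train_id="amp_5")``.
        """
        mask = np.ones(self.n_stimuli, dtype=bool)
        for key, val in kw.items():
            mask &= np.array([getattr(e, key) == val for e in self.events])
        return mask


# ---------------------------------------------------------------------------


def detect_crossings(trace: TraceSet, spec: DetectionSpec = DetectionSpec()) -> SpikeTable:
    """Threshold-crossing spike capture on a wideband trace.

    Per channel the threshold sits ``threshold_fraction`` of the way from
    the baseline-window mean towards its minimum (a "10 % below baseline"
    rule); a crossing is the first sample below threshold, and crossings
    within ``dead_time_ms`` of an accepted one are suppressed.  The
    baseline window is a threshold-setting prelude: capture starts at its
    end, as in acquisition systems that arm the trigger after estimating
    the noise floor.
    """
    fs = trace.sampling_rate_hz
    n_base = int(round(spec.baseline_window_s * fs))
    if trace.samples.shape[1] < n_base:
        raise ValidationError("trace shorter than the baseline window")
    dead = spec.dead_time_ms / 1000.0
    times: list[np.ndarray] = []
    chans: list[np.ndarray] = []
    for c in range(trace.n_channels):
        x = trace.samples[c]
        base = x[:n_base]
        mu, mn = float(base.mean()), float(base.min())
        if mu == mn:
            raise DegenerateThresholdError(
                f"channel {c + 1}: flat baseline window, threshold undefined"
            )
        vth = mu - spec.threshold_fraction * (mu - mn)
        below = x < vth
        onset = below & ~np.concatenate(([False], below[:-1]))
        onset[:n_base] = False  # capture armed only after the baseline prelude
        idx = np.flatnonzero(onset)
        if idx.size and dead > 0:
            kept = [idx[0]]
            min_gap = dead * fs
            for i in idx[1:]:
                if i - kept[-1] >= min_gap:
                    kept.append(i)
            idx = np.asarray(kept)
        times.append(trace.start_time_s + idx / fs)
        chans.append(np.full(idx.size, c + 1, dtype=np.int64))
    return SpikeTable(
        np.concatenate(times) if times else np.empty(0),
        np.concatenate(chans) if chans else np.empty(0, dtype=np.int64),
        n_channels=trace.n_channels,
    )


def extract_epochs(
    spikes: SpikeTable, events: list[StimulusEvent], spec: EpochSpec = EpochSpec()
) -> EpochTensor:
    """Bin spikes into peristimulus epochs.

    Spikes outside every epoch are silently excluded; a spike inside two
    overlapping epochs counts once in each (epochs are self-contained).
    """
    if not events:
        raise ValidationError("events must be non-empty")
    events = sorted(events, key=lambda e: e.time_s)
    pre_s = spec.pre_ms / 1000.0
    width_s = (spec.pre_ms + spec.post_ms) / 1000.0
    bin_s = spec.bin_ms / 1000.0
    values = np.zeros((len(events), spikes.n_channels, spec.n_bins), dtype=np.int64)
    t = spikes.time_s
    ch = spikes.channel - 1
    for s, ev in enumerate(events):
        t0 = ev.time_s - pre_s
        lo, hi = np.searchsorted(t, (t0, t0 + width_s))
        if lo == hi:
            continue
        # the tiny epsilon keeps decimal boundaries half-open despite float
        # subtraction error (e.g. a spike at exactly +3 ms belongs to [3, 4))
        bins = np.floor((t[lo:hi] - t0) / bin_s + 1e-9).astype(np.int64)
        bins = np.minimum(bins, spec.n_bins - 1)  # guard float edge at the last bin
        np.add.at(values[s], (ch[lo:hi], bins), 1)
    return EpochTensor(values, spec, list(events), stage="raw")


def blank_artifact(
    tensor: EpochTensor, window_ms: tuple[float, float] = (0.0, 2.0)
) -> EpochTensor:
    """Zero all bins intersecting ``[lo, hi)`` ms — stimulus-artefact removal.

    The default 0-2 ms window sits below the 3 ms floor of the earliest
    fibre latency band, so band quantification is unaffected.
    """
    lo, hi = window_ms
    if lo == hi:
        return EpochTensor(tensor.values.copy(), tensor.spec, list(tensor.events), tensor.stage)
    if lo > hi:
        raise ValidationError("blank window must have lo <= hi")
    if lo < -tensor.spec.pre_ms or hi > tensor.spec.post_ms:
        raise ValidationError("blank window outside the epoch")
    if tensor.stage != "raw":
        raise StageError("blank_artifact must run on the raw tensor")
    starts = tensor.spec.bin_start_ms()
    ends = starts + tensor.spec.bin_ms
    mask = (ends > lo) & (starts < hi)
    values = tensor.values.copy()
    values[:, :, mask] = 0
    return EpochTensor(values, tensor.spec, list(tensor.events), stage="raw")


def whole_channel_baseline(
    tensor: EpochTensor, reference: np.ndarray
) -> tuple[EpochTensor, np.ndarray]:
    """Subtract each channel's reference-group pre-stimulus rate everywhere.

    ``reference`` is a boolean mask (or index array) selecting the stimuli
    of the reference group — the subthreshold or saline block recorded
    first.  Returns the corrected tensor (stage ``channel_corrected``) and
    the per-channel baseline in counts per bin.
    """
    if tensor.stage != "raw":
        raise StageError("whole_channel_baseline requires a raw tensor")
    reference = np.asarray(reference)
    if reference.dtype == bool:
        reference = np.flatnonzero(reference)
    if reference.size == 0:
        raise ValidationError("reference group is empty")
    baseline = tensor.values[reference][:, :, tensor.pre_slice()].mean(axis=(0, 2))
    values = tensor.values.astype(float) - baseline[None, :, None]
    out = EpochTensor(values, tensor.spec, list(tensor.events), stage="channel_corrected")
    out.baseline_per_channel = baseline
    return out, baseline


def per_stimulus_baseline(tensor: EpochTensor) -> EpochTensor:
    """Subtract each epoch's own pre-stimulus per-bin mean from all its bins.

    Removes slow within-train baseline drift.  Must NOT be applied to
    frequency-series (wind-up) datasets — the provenance tag produced here
    is checked downstream.
    """
    if tensor.stage != "channel_corrected":
        raise StageError("per_stimulus_baseline requires a channel_corrected tensor")
    if tensor.spec.n_pre_bins == 0:
        raise ValidationError("no pre-stimulus bins available for baseline")
    own = tensor.values[:, :, tensor.pre_slice()].mean(axis=2)
    values = tensor.values - own[:, :, None]
    out = EpochTensor(values, tensor.spec, list(tensor.events), stage="stimulus_corrected")
    out.baseline_per_channel = tensor.baseline_per_channel
    return out


# ---------------------------------------------------------------------------
# HDF5 serialization of the tensor (values + epoch spec + event table)


def save_tensor(path, tensor: EpochTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=tensor.values)
        f.attrs["pre_ms"] = tensor.spec.pre_ms
        f.attrs["post_ms"] = tensor.spec.post_ms
        f.attrs["bin_ms"] = tensor.spec.bin_ms
        f.attrs["stage"] = tensor.stage
        df = events_to_frame(tensor.events)
        grp = f.create_group("events")
        for col in df.columns:
            data = df[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            grp.create_dataset(col, data=data)


def load_tensor(path) -> EpochTensor:
    import pandas as pd

    with h5py.File(path, "r") as f:
        spec = EpochSpec(
            pre_ms=float(f.attrs["pre_ms"]),
            post_ms=float(f.attrs["post_ms"]),
            bin_ms=float(f.attrs["bin_ms"]),
        )
        cols = {}
        for col in f["events"]:
            data = f["events"][col][...]
            if data.dtype.kind == "S":
                data = data.astype(str)
            cols[col] = data
        events = frame_to_events(pd.DataFrame(cols))
        return EpochTensor(f["values"][...], spec, events, stage=str(f.attrs["stage"]))
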