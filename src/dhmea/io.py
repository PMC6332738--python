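"""File formats and core data containers.

Spike times and stimulus-event logs travel as plain CSV (gzip accepted
transparently); continuous voltage traces travel as HDF5.  Times are always
seconds from recording start, channels are 1-based with channel 1 the most
superficial electrode.  All readers validate; none coerce silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "SpikeTable",
    "StimulusEvent",
    "ArrayGeometry",
    "TraceSet",
    "MODALITIES",
    "REGIONS",
    "read_spikes",
    "write_spikes",
    "read_events",
    "write_events",
    "read_traces",
    "write_traces",
    "events_to_frame",
    "frame_to_events",
]

MODALITIES = ("electrical", "mechanical", "thermal", "chemical")
REGIONS = ("superficial", "intermediate", "deep")

SPIKE_COLUMNS = ["time_s", "channel"]
EVENT_COLUMNS = [
    "time_s",
    "modality",
    "amplitude",
    "duration_ms",
    "train_id",
    "index_in_train",
    "train_frequency_hz",
    "label",
]


class FormatError(ValueError):
    """A file does not match the expected layout (columns, attributes)."""


class ValidationError(ValueError):
    """Well-formed input carrying values that violate an invariant."""


@dataclass
class SpikeTable:
    """Timestamped threshold crossings (unsorted multi-unit activity).

    Parameters
    ----------
    time_s : array of float
        Spike times in seconds from recording start.
    channel : array of int
        1-based electrode index, channel 1 most superficial.
    n_channels : int
        Number of electrodes on the array (default 16).
    """

    time_s: np.ndarray
    channel: np.ndarray
    n_channels: int = 16

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.channel = np.asarray(self.channel, dtype=np.int64)
        if self.time_s.shape != self.channel.shape or self.time_s.ndim != 1:
            raise ValidationError("time_s and channel must be equal-length 1-D arrays")
        bad = ~np.isfinite(self.time_s)
        if bad.any():
            raise ValidationError(f"non-finite spike time at row {int(np.argmax(bad))}")
        bad = self.time_s < 0
        if bad.any():
            raise ValidationError(f"negative spike time at row {int(np.argmax(bad))}")
        bad = (self.channel < 1) | (self.channel > self.n_channels)
        if bad.any():
            raise ValidationError(
                f"channel out of range [1, {self.n_channels}] at row {int(np.argmax(bad))}"
            )
        order = np.lexsort((self.channel, self.time_s))
        self.time_s = self.time_s[order]
        self.channel = self.channel[order]

    def __len__(self) -> int:
        return self.time_s.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTable):
            return NotImplemented
        return (
            self.n_channels == other.n_channels
            and np.array_equal(self.time_s, other.time_s)
            and np.array_equal(self.channel, other.channel)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "channel": self.channel})


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus presentation.

    ``amplitude`` units depend on modality: mA (electrical), g (mechanical),
    degrees C (thermal), unitless (chemical).
    """

    time_s: float
    modality: str
    amplitude: float
    duration_ms: float
    train_id: str
    index_in_train: int
    train_frequency_hz: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.modality == "electrical" and not self.duration_ms > 0:
            raise ValidationError("electrical stimuli require duration_ms > 0")


@dataclass(frozen=True)
class ArrayGeometry:
    """Linear-probe geometry and the electrode-to-lamina partition.

    The default maps the paper-style 16-channel, 50 um pitch probe onto
    superficial (channels 1-3), intermediate (4-9) and deep (10-16) regions.
    Channel indices are authoritative; depths are annotation only.
    """

    n_channels: int = 16
    pitch_um: float = 50.0
    top_depth_um: float = 200.0
    region_map: dict = field(
        default_factory=lambda: {
            **{c: "superficial" for c in range(1, 4)},
            **{c: "intermediate" for c in range(4, 10)},
            **{c: "deep" for c in range(10, 17)},
        }
    )

    def __post_init__(self) -> None:
        if set(self.region_map) != set(range(1, self.n_channels + 1)):
            raise ValidationError("region_map must cover channels 1..n_channels exactly")
        bad = set(self.region_map.values()) - set(REGIONS)
        if bad:
            raise ValidationError(f"unknown regions {sorted(bad)}")

    def region_channels(self, region: str) -> list[int]:
        return [c for c in range(1, self.n_channels + 1) if self.region_map[c] == region]

    def depths_um(self) -> np.ndarray:
        return self.top_depth_um + self.pitch_um * np.arange(self.n_channels)


@dataclass
class TraceSet:
    """Continuous voltage traces: ``samples[channel, sample]`` in volts."""

    samples: np.ndarray
    sampling_rate_hz: float
    kind: str
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be 2-D [channel, sample]")
        if self.kind not in ("lfp", "wideband"):
            raise ValidationError(f"kind must be 'lfp' or 'wideband', got {self.kind!r}")
        if not np.isfinite(self.samples).all():
            raise ValidationError("trace samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.samples.shape[1]) / self.sampling_rate_hz


# ---------------------------------------------------------------------------
# spikes


def read_spikes(path, n_channels: int = 16) -> SpikeTable:
    """Read a ``time_s,channel`` CSV into a validated, time-sorted SpikeTable."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"spike file missing column(s) {missing}")
    return SpikeTable(
        df["time_s"].to_numpy(float), df["channel"].to_numpy(np.int64), n_channels
    )


def write_spikes(path, spikes: SpikeTable) -> None:
    spikes.to_frame().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# events


def events_to_frame(events: list[StimulusEvent]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in events], columns=EVENT_COLUMNS)


def frame_to_events(df: pd.DataFrame) -> list[StimulusEvent]:
    events = []
    for _, row in df.iterrows():
        events.append(
            StimulusEvent(
                time_s=float(row["time_s"]),
                modality=str(row["modality"]),
                amplitude=float(row["amplitude"]),
                duration_ms=float(row["duration_ms"]),
                train_id=str(row["train_id"]),
                index_in_train=int(row["index_in_train"]),
                train_frequency_hz=float(row["train_frequency_hz"]),
                label="" if pd.isna(row["label"]) else str(row["label"]),
            )
        )
    return sorted(events, key=lambda e: e.time_s)


def validate_trains(events: list[StimulusEvent], tol: float = 0.01) -> None:
    """Warn if within-train gaps deviate from 1/train_frequency_hz by > tol."""
    by_train: dict[str, list[StimulusEvent]] = {}
    for e in events:
        by_train.setdefault(e.train_id, []).append(e)
    for tid, evs in by_train.items():
        evs = sorted(evs, key=lambda e: e.index_in_train)
        times = np.array([e.time_s for e in evs])
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"train {tid!r}: times not strictly increasing")
        freq = evs[0].train_frequency_hz
        if freq > 0 and len(evs) > 1:
            expected = 1.0 / freq
            gaps = np.diff(times)
            if np.any(np.abs(gaps - expected) > tol * expected):
                warnings.warn(
                    f"train {tid!r}: inter-stimulus gap inconsistent with "
                    f"{freq} Hz (expected {expected:.4g} s)",
                    stacklevel=2,
                )


def read_events(path, check_trains: bool = True) -> list[StimulusEvent]:
    """Read a stimulus-event CSV; events are returned sorted by time."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event file missing column(s) {missing}")
    events = frame_to_events(df)
    if check_trains:
        validate_trains(events)
    return events


def write_events(path, events: list[StimulusEvent]) -> None:
    events_to_frame(sorted(events, key=lambda e: e.time_s)).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# traces

_TRACE_ATTRS = ("sampling_rate_hz", "start_time_s", "kind")


def write_traces(path, trace: TraceSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=trace.samples)
        f.attrs["sampling_rate_hz"] = trace.sampling_rate_hz
        f.attrs["start_time_s"] = trace.start_time_s
        f.attrs["kind"] = trace.kind


def read_traces(path, kind: str | None = None) -> TraceSet:
    """Read an HDF5 trace container; ``kind`` asserts lfp/wideband if given."""
    with h5py.File(path, "r") as f:
        if "samples" not in f:
            raise FormatError("trace file missing dataset 'samples'")
        missing = [a for a in _TRACE_ATTRS if a not in f.attrs]
        if missing:
            raise FormatError(f"trace file missing attribute(s) {missing}")
        trace = TraceSet(
            samples=f["samples"][...],
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            kind=str(f.attrs["kind"]),
            start_time_s=float(f.attrs["start_time_s"]),
        )
    if kind is not None and trace.kind != kind:
        raise ValidationError(f"expected kind {kind!r}, file holds {trace.kind!r}")
    return trace
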