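"""Pharmacology time-courses and natural-stimulus response series.

Drug studies are summarized per 10 min period anchored at the moment of
application (t = 0; the saline control occupies negative times), expressed
either as a difference from the reference-period mean or as a percentage
of it.  Mechanical and thermal responses are summed into 100 ms bins
relative to stimulus onset, chemical (capsaicin) responses into 10 s bins
relative to application.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ArrayGeometry, REGIONS, SpikeTable, StimulusEvent, ValidationError
from .laminar import RegionSummary

__all__ = [
    "TimecourseSpec",
    "NaturalStimSpec",
    "DrugTimecourse",
    "NaturalResponse",
    "drug_timecourse",
    "natural_response",
]


@dataclass(frozen=True)
class TimecourseSpec:
    """Drug-study summary: period length, reference label, normalization."""

    period_s: float = 600.0
    reference_label: str = "saline"
    normalization: str = "difference"

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValidationError("period_s must be > 0")
        if self.normalization not in ("difference", "percent"):
            raise ValidationError("normalization must be 'difference' or 'percent'")


@dataclass(frozen=True)
class NaturalStimSpec:
    """Binning for natural stimuli: 0.1 s for vFH/thermal, 10 s for chemical."""

    bin_s: float = 0.1
    pre_s: float = 1.0
    post_s: float = 10.0

    def __post_init__(self) -> None:
        if self.bin_s <= 0:
            raise ValidationError("bin_s must be > 0")
        for name, val in (("pre_s", self.pre_s), ("post_s", self.post_s)):
            k = val / self.bin_s
            if abs(k - round(k)) > 1e-9:
                raise ValidationError(f"{name} must be a whole number of bins")

    @property
    def n_bins(self) -> int:
        return int(round((self.pre_s + self.post_s) / self.bin_s))

    @property
    def n_pre_bins(self) -> int:
        return int(round(self.pre_s / self.bin_s))

    def bin_start_s(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_s - self.pre_s


@dataclass
class DrugTimecourse:
    """Per-period normalized region x band values.

    ``values[period, region, band]``; periods with no stimuli hold NaN
    (gaps are encoded, never interpolated).
    """

    period_start_s: np.ndarray
    values: np.ndarray
    reference_mean: np.ndarray  # [region, band]
    normalization: str
    bands: list
    regions: tuple = REGIONS

    def series(self, region: str, band: str) -> np.ndarray:
        return self.values[:, self.regions.index(region), self.bands.index(band)]


def drug_timecourse(
    summary: RegionSummary,
    application_time_s: float,
    spec: TimecourseSpec = TimecourseSpec(),
) -> DrugTimecourse:
    """Summarize evoked activity per period relative to the reference block.

    Periods are left-closed ``[t, t + period_s)`` anchored at the drug
    application; a stimulus exactly on a boundary goes to the later
    period.  ``difference`` subtracts the reference-period mean, per
    region and band; ``percent`` reports 100 x period mean / reference
    mean.
    """
    times = np.array([e.time_s for e in summary.events])
    ref_mask = summary.select(label=spec.reference_label)
    if not ref_mask.any():
        raise ValidationError(f"no stimuli labelled {spec.reference_label!r}")
    ref_mean = summary.values[ref_mask].mean(axis=0)  # [region, band]
    period = np.floor((times - application_time_s) / spec.period_s).astype(int)
    p_lo, p_hi = int(period.min()), int(period.max())
    periods = np.arange(p_lo, p_hi + 1)
    out = np.full((periods.size, *ref_mean.shape), np.nan)
    for i, p in enumerate(periods):
        rows = period == p
        if not rows.any():
            continue
        mean = summary.values[rows].mean(axis=0)
        if spec.normalization == "difference":
            out[i] = mean - ref_mean
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                out[i] = 100.0 * mean / ref_mean
    return DrugTimecourse(
        periods * spec.period_s,
        out,
        ref_mean,
        spec.normalization,
        list(summary.bands.names),
    )


@dataclass
class NaturalResponse:
    """Binned response to one natural stimulus application."""

    bin_start_s: np.ndarray
    per_channel: np.ndarray  # [channel, bin], baseline-corrected counts
    per_region: np.ndarray  # [region, bin], mean across member channels
    baseline_per_channel: np.ndarray
    event: StimulusEvent
    regions: tuple = REGIONS

    def region(self, name: str) -> np.ndarray:
        return self.per_region[self.regions.index(name)]


def natural_response(
    spikes: SpikeTable,
    events: list[StimulusEvent],
    geometry: ArrayGeometry = ArrayGeometry(),
    spec: NaturalStimSpec = NaturalStimSpec(),
) -> list[NaturalResponse]:
    """Bin spikes around each natural-stimulus onset.

    Counts per channel and bin are corrected by the pre-onset per-bin mean
    of that channel; region traces are the mean across member channels.
    Overlapping analysis windows are refused.
    """
    if not events:
        raise ValidationError("events must be non-empty")
    events = sorted(events, key=lambda e: e.time_s)
    for a, b in zip(events, events[1:]):
        if a.time_s + spec.post_s > b.time_s - spec.pre_s:
            raise ValidationError(
                f"analysis windows of stimuli at {a.time_s} s and {b.time_s} s overlap"
            )
    out = []
    t = spikes.time_s
    ch = spikes.channel - 1
    for ev in events:
        t0 = ev.time_s - spec.pre_s
        lo, hi = np.searchsorted(t, (t0, ev.time_s + spec.post_s))
        counts = np.zeros((spikes.n_channels, spec.n_bins))
        if hi > lo:
            # epsilon keeps decimal bin edges half-open under float error
            bins = np.floor((t[lo:hi] - t0) / spec.bin_s + 1e-9).astype(int)
            bins = np.minimum(bins, spec.n_bins - 1)
            np.add.at(counts, (ch[lo:hi], bins), 1)
        baseline = counts[:, : spec.n_pre_bins].mean(axis=1)
        corrected = counts - baseline[:, None]
        regions = np.stack(
            [
                corrected[[c - 1 for c in geometry.region_channels(r)]].mean(axis=0)
                for r in REGIONS
            ]
        )
        out.append(
            NaturalResponse(spec.bin_start_s(), corrected, regions, baseline, ev)
        )
    return out
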