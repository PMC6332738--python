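"""Latency-band decomposition and laminar aggregation.

Evoked dorsal-horn activity separates by afferent conduction velocity into
post-stimulus latency bands — Abeta 3-11 ms, Adelta 11-90 ms, C-fibre
90-300 ms, post-discharge 300-800 ms (all half-open) — and by probe depth
into superficial / intermediate / deep laminar regions.  This module sums
the epoch tensor over those bands and regions, builds per-electrode depth
profiles, coarsens 1 ms bins for heatmap display, and computes per-animal
baseline-referenced Z-score maps with cohort averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import REGIONS, ArrayGeometry, ValidationError
from .preprocess import EpochTensor

__all__ = [
    "LatencyBands",
    "BandSummary",
    "RegionSummary",
    "ZMap",
    "band_sums",
    "region_aggregate",
    "depth_profile",
    "coarsen_heatmap",
    "zscore_map",
]

DEFAULT_WINDOWS = {
    "pre": (-100.0, 0.0),
    "Abeta": (3.0, 11.0),
    "Adelta": (11.0, 90.0),
    "C": (90.0, 300.0),
    "PD": (300.0, 800.0),
    "CPD": (90.0, 800.0),
}

PRIMARY_BANDS = ("Abeta", "Adelta", "C", "PD")


@dataclass(frozen=True)
class LatencyBands:
    """Named half-open latency windows in ms relative to the stimulus."""

    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.windows.items():
            if not lo < hi:
                raise ValidationError(f"band {name!r}: need lo < hi")
        primary = [self.windows[b] for b in PRIMARY_BANDS if b in self.windows]
        for i, (lo1, hi1) in enumerate(primary):
            for lo2, hi2 in primary[i + 1 :]:
                if max(lo1, lo2) < min(hi1, hi2):
                    raise ValidationError("primary bands must be mutually disjoint")

    @property
    def names(self) -> list[str]:
        return list(self.windows)


@dataclass
class BandSummary:
    """Per-stimulus, per-channel summed counts by latency band."""

    sums: np.ndarray  # [stimulus, channel, band]
    bands: LatencyBands
    stage: str
    events: list

    @property
    def band_names(self) -> list[str]:
        return self.bands.names

    def band(self, name: str) -> np.ndarray:
        """``sums[:, :, band]`` for one named band."""
        return self.sums[:, :, self.band_names.index(name)]

    def select(self, **kw) -> np.ndarray:
        mask = np.ones(len(self.events), dtype=bool)
        for key, val in kw.items():
            mask &= np.array([getattr(e, key) == val for e in self.events])
        return mask


@dataclass
class RegionSummary:
    """Band values pooled over laminar regions (sum or mean across channels)."""

    values: np.ndarray  # [stimulus, region, band]
    bands: LatencyBands
    mode: str
    stage: str
    events: list
    regions: tuple = REGIONS

    def band(self, name: str) -> np.ndarray:
        return self.values[:, :, self.bands.names.index(name)]

    def region_band(self, region: str, band: str) -> np.ndarray:
        return self.values[:, self.regions.index(region), self.bands.names.index(band)]

    def select(self, **kw) -> np.ndarray:
        mask = np.ones(len(self.events), dtype=bool)
        for key, val in kw.items():
            mask &= np.array([getattr(e, key) == val for e in self.events])
        return mask


@dataclass
class ZMap:
    """Per-animal and cohort-averaged Z-scored mean time-courses."""

    per_animal: np.ndarray  # [animal, channel, bin]
    cohort: np.ndarray  # [channel, bin]
    baseline_mean: np.ndarray  # [animal, channel]
    baseline_sd: np.ndarray  # [animal, channel]
    excluded: np.ndarray  # [animal, channel] bool, zero-SD channels
    bin_start_ms: np.ndarray


def _band_bins(tensor: EpochTensor, lo: float, hi: float) -> slice:
    spec = tensor.spec
    if lo < -spec.pre_ms or hi > spec.post_ms:
        raise ValidationError(f"band [{lo}, {hi}) ms exceeds the epoch")
    b0 = (lo + spec.pre_ms) / spec.bin_ms
    b1 = (hi + spec.pre_ms) / spec.bin_ms
    if abs(b0 - round(b0)) > 1e-9 or abs(b1 - round(b1)) > 1e-9:
        raise ValidationError(f"band [{lo}, {hi}) ms not aligned to {spec.bin_ms} ms bins")
    return slice(int(round(b0)), int(round(b1)))


def band_sums(tensor: EpochTensor, bands: LatencyBands = LatencyBands()) -> BandSummary:
    """Total threshold crossings per stimulus, channel and latency band."""
    cols = [
        tensor.values[:, :, _band_bins(tensor, lo, hi)].sum(axis=2)
        for lo, hi in bands.windows.values()
    ]
    return BandSummary(np.stack(cols, axis=2), bands, tensor.stage, list(tensor.events))


def region_aggregate(
    summary: BandSummary, geometry: ArrayGeometry = ArrayGeometry(), mode: str = "sum"
) -> RegionSummary:
    """Pool channel band sums into laminar regions.

    ``sum`` is used for electrical band analyses; ``mean`` for
    natural-stimulus region traces.
    """
    if mode not in ("sum", "mean"):
        raise ValidationError("mode must be 'sum' or 'mean'")
    if summary.sums.shape[1] != geometry.n_channels:
        raise ValidationError("summary channel count does not match the geometry")
    out = np.empty((summary.sums.shape[0], len(REGIONS), summary.sums.shape[2]))
    for r, region in enumerate(REGIONS):
        idx = [c - 1 for c in geometry.region_channels(region)]
        if not idx:
            raise ValidationError(f"region {region!r} has no channels")
        block = summary.sums[:, idx, :]
        out[:, r, :] = block.sum(axis=1) if mode == "sum" else block.mean(axis=1)
    return RegionSummary(out, summary.bands, mode, summary.stage, list(summary.events))


def depth_profile(
    summary: BandSummary, stimulus_group: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sample SD of band sums across a stimulus group, per channel.

    Returns ``(mean, sd)``, each ``[channel, band]``.
    """
    group = np.asarray(stimulus_group)
    if group.dtype == bool:
        group = np.flatnonzero(group)
    if group.size == 0:
        raise ValidationError("stimulus group is empty")
    block = summary.sums[group]
    mean = block.mean(axis=0)
    if group.size == 1:
        warnings.warn("group of size 1: SD reported as 0", stacklevel=2)
        sd = np.zeros_like(mean)
    else:
        sd = block.std(axis=0, ddof=1)
    return mean, sd


def coarsen_heatmap(
    tensor: EpochTensor,
    factor_ms: float = 10.0,
    stimulus_group: np.ndarray | None = None,
) -> np.ndarray:
    """Mean response per channel, re-binned into ``factor_ms`` blocks.

    Consecutive 1 ms bins are summed in non-overlapping groups; the result
    is ``[channel, coarse bin]`` — the display matrix behind the heatmaps.
    """
    spec = tensor.spec
    k = factor_ms / spec.bin_ms
    if abs(k - round(k)) > 1e-9:
        raise ValidationError("factor_ms must be a multiple of bin_ms")
    k = int(round(k))
    if spec.n_bins % k:
        raise ValidationError(f"{k} bins do not tile the {spec.n_bins}-bin epoch")
    vals = tensor.values if stimulus_group is None else tensor.values[stimulus_group]
    mean = vals.mean(axis=0)  # [channel, bin]
    return mean.reshape(mean.shape[0], -1, k).sum(axis=2)


def zscore_map(
    tensors: list[EpochTensor],
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0),
    stimulus_groups: list[np.ndarray] | None = None,
) -> ZMap:
    """Per-animal Z-scored mean time-courses, averaged into a cohort map.

    For each animal and electrode the stimulus-group mean time-course is
    standardized by the mean and sample SD of its baseline-window bins;
    animal maps are then averaged.  Channels with zero baseline SD are
    flagged and excluded from the cohort mean with a warning.
    """
    if not tensors:
        raise ValidationError("need at least one animal")
    per_animal, means, sds, excl = [], [], [], []
    bins = None
    for a, tensor in enumerate(tensors):
        group = None if stimulus_groups is None else stimulus_groups[a]
        vals = tensor.values if group is None else tensor.values[group]
        x = vals.mean(axis=0)  # [channel, bin]
        bsl = x[:, _band_bins(tensor, *baseline_window_ms)]
        if bsl.shape[1] < 2:
            raise ValidationError("baseline window must span at least 2 bins")
        mu = bsl.mean(axis=1)
        sd = bsl.std(axis=1, ddof=1)
        bad = sd == 0
        if bad.any():
            warnings.warn(
                f"animal {a}: zero baseline SD on channel(s) "
                f"{list(np.flatnonzero(bad) + 1)}; excluded from cohort mean",
                stacklevel=2,
            )
        safe_sd = np.where(bad, 1.0, sd)
        per_animal.append((x - mu[:, None]) / safe_sd[:, None])
        means.append(mu)
        sds.append(sd)
        excl.append(bad)
        if bins is None:
            bins = tensor.spec.bin_start_ms()
    per_animal = np.stack(per_animal)
    excluded = np.stack(excl)
    weights = (~excluded).astype(float)[:, :, None]
    denom = weights.sum(axis=0)
    with np.errstate(invalid="ignore"):
        cohort = (per_animal * weights).sum(axis=0) / denom
    return ZMap(per_animal, cohort, np.stack(means), np.stack(sds), excluded, bins)
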