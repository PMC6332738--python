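"""Frequency-dependence (wind-up) analysis and the paired tests behind it.

Wind-up is the progressive growth of C-fibre and post-discharge responses
over a >= 0.5 Hz stimulus train.  The analysis orders per-stimulus band /
region values by position in the train, condenses each train to an area
under the curve (a plain sum over stimulus index), and compares
frequencies with a paired t test or a sign-flip permutation test.

Frequency datasets must carry only the whole-channel baseline correction:
the per-stimulus correction would subtract away exactly the ongoing
activity growth the analysis measures, so a provenance check refuses
``stimulus_corrected`` input.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .io import ValidationError
from .laminar import RegionSummary

__all__ = [
    "TrainSeries",
    "ProvenanceError",
    "train_series",
    "auc",
    "paired_t",
    "permutation_paired",
    "PairedTResult",
]


class ProvenanceError(ValueError):
    """Input carries a correction stage the analysis forbids."""


@dataclass
class TrainSeries:
    """Per-stimulus values of one train: ``values[index, region, band]``."""

    values: np.ndarray
    train_id: str
    train_frequency_hz: float
    bands: list
    regions: tuple

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    def series(self, region: str, band: str) -> np.ndarray:
        return self.values[:, self.regions.index(region), self.bands.index(band)]


def train_series(summary: RegionSummary, train_id: str) -> TrainSeries:
    """Order one train's region/band values by position in the train."""
    if summary.stage == "stimulus_corrected":
        raise ProvenanceError(
            "wind-up analysis requires channel-corrected (not per-stimulus-"
            "corrected) data: the per-stimulus baseline would erase the "
            "ongoing-activity effect"
        )
    members = [(e.index_in_train, s) for s, e in enumerate(summary.events) if e.train_id == train_id]
    if len(members) < 2:
        raise ValidationError(f"train {train_id!r} needs >= 2 stimuli")
    members.sort()
    idx = [i for i, _ in members]
    if idx != list(range(len(idx))):
        raise ValidationError(f"train {train_id!r}: missing or duplicated stimulus index")
    rows = [s for _, s in members]
    ev = summary.events[rows[0]]
    return TrainSeries(
        summary.values[rows],
        train_id,
        ev.train_frequency_hz,
        list(summary.bands.names),
        summary.regions,
    )


def auc(series: np.ndarray, method: str = "rect") -> float:
    """Area under a per-stimulus series.

    ``rect`` (default) is the plain sum over stimulus index — exact for
    constant and all-zero series and linear in the values; ``trapezoid``
    is available as an option.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("series must be a non-empty 1-D array")
    if method == "rect":
        return float(x.sum())
    if method == "trapezoid":
        return float(np.trapezoid(x))
    raise ValidationError(f"unknown AUC method {method!r}")


@functools.lru_cache(maxsize=8)
def _sign_matrix(n: int) -> np.ndarray:
    m = np.arange(2**n)[:, None]
    return np.where((m >> np.arange(n)) & 1, 1.0, -1.0)


class PairedTResult(NamedTuple):
    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_t(x, y) -> PairedTResult:
    """Classical two-sided paired Student's t on per-animal values.

    Zero-variance differences make t undefined; such results come back
    flagged ``degenerate`` with NaN statistics rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("x and y must be equal-length 1-D arrays with n >= 2")
    d = x - y
    if np.ptp(d) == 0:
        return PairedTResult(float("nan"), x.size - 1, float("nan"), degenerate=True)
    res = stats.ttest_rel(x, y)
    return PairedTResult(float(res.statistic), x.size - 1, float(res.pvalue))


def permutation_paired(x, y, n_perm: int = 9999, seed=None) -> float:
    """Two-sided sign-flip permutation p-value for the mean paired difference.

    Enumerates all ``2**n`` sign patterns whenever that is no larger than
    ``n_perm`` (exact p); otherwise Monte-Carlo with the add-one estimator
    ``(1 + hits) / (1 + n_perm)``.  Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("x and y must be equal-length 1-D arrays with n >= 2")
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    d = x - y
    n = d.size
    obs = abs(d.mean())
    tol = 1e-12 * max(1.0, obs)
    if 2**n <= n_perm:
        means = _sign_matrix(n) @ d / n
        return float(np.count_nonzero(np.abs(means) >= obs - tol) / 2**n)
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    means = signs @ d / n
    hits = int(np.count_nonzero(np.abs(means) >= obs - tol))
    return float((1 + hits) / (1 + n_perm))
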