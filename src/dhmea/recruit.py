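"""Logistic strength-duration recruitment model.

Fits the amplitude-series band sums with

    R(I) = R_max / (1 + exp(-(I - I_th) / s))

where ``I_th`` is the recruitment threshold at the tested pulse duration.
Under the Weiss law ``I_th(d) = rheobase (1 + chronaxie / d)``, so the
fitted threshold converts directly to a rheobase estimate once the
chronaxie is known.  The slope ``s`` is treated as a known acquisition
parameter by default — five test amplitudes cannot identify it — but may
be freed.

Usage follows the fit/results convention::

    res = RecruitmentModel(amps, responses, duration_ms=2.0).fit(slope=0.5)
    res.rheobase_mA(chronaxie_ms=1.5)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

from .io import ValidationError

__all__ = ["RecruitmentModel", "RecruitmentResults"]


class RecruitmentModel:
    """Logistic recruitment curve for one afferent class.

    Parameters
    ----------
    amplitude_mA : array
        Tested stimulus amplitudes.
    response : array
        Baseline-corrected band sums (any consistent unit) at each amplitude.
    duration_ms : float
        Pulse duration of the series; needed to convert threshold to rheobase.
    """

    def __init__(self, amplitude_mA, response, duration_ms: float = 2.0):
        self.amplitude = np.asarray(amplitude_mA, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.amplitude.shape != self.response.shape or self.amplitude.ndim != 1:
            raise ValidationError("amplitude and response must be equal-length 1-D")
        if self.amplitude.size < 3:
            raise ValidationError("need at least 3 amplitudes to fit")
        if duration_ms <= 0:
            raise ValidationError("duration_ms must be > 0")
        self.duration_ms = float(duration_ms)

    @classmethod
    def from_band_summary(cls, summary, band: str, amplitudes, duration_ms: float = 2.0):
        """Build from a BandSummary: cohort mean of channel-summed band sums
        per amplitude (events must carry ``{amp:g}mA`` labels)."""
        resp = []
        for amp in amplitudes:
            mask = summary.select(label=f"{amp:g}mA")
            if not mask.any():
                raise ValidationError(f"no stimuli labelled {amp:g}mA")
            resp.append(summary.band(band)[mask].sum(axis=1).mean())
        return cls(np.asarray(amplitudes, float), np.asarray(resp), duration_ms)

    def _p0(self) -> tuple[float, float]:
        rmax = max(float(self.response.max()), 1e-9)
        half = rmax / 2.0
        above = np.flatnonzero(self.response >= half)
        if above.size == 0 or above[0] == 0:
            ith = float(self.amplitude[0])
        else:
            j = above[0]
            x0, x1 = self.amplitude[j - 1], self.amplitude[j]
            y0, y1 = self.response[j - 1], self.response[j]
            ith = float(x0 + (half - y0) / max(y1 - y0, 1e-12) * (x1 - x0))
        return rmax, ith

    def fit(self, slope: float | None = None) -> "RecruitmentResults":
        """Least-squares fit; ``slope`` fixes s (recommended), None frees it."""
        rmax0, ith0 = self._p0()
        amax = float(self.amplitude.max())
        if slope is not None:
            if slope <= 0:
                raise ValidationError("slope must be > 0")

            def f(i, rmax, ith):
                return rmax * expit((i - ith) / slope)

            p0 = [rmax0, ith0]
            bounds = ([0.0, 0.0], [np.inf, 2 * amax])
        else:

            def f(i, rmax, ith, s):
                return rmax * expit((i - ith) / s)

            p0 = [rmax0, ith0, 0.3 * max(ith0, 0.1)]
            bounds = ([0.0, 0.0, 1e-3], [np.inf, 2 * amax, 2 * amax])
        popt, pcov = curve_fit(
            f, self.amplitude, self.response, p0=p0, bounds=bounds, maxfev=20000
        )
        fitted = f(self.amplitude, *popt)
        return RecruitmentResults(
            model=self,
            rmax=float(popt[0]),
            threshold_mA=float(popt[1]),
            slope_mA=float(popt[2]) if slope is None else float(slope),
            slope_fixed=slope is not None,
            cov=pcov,
            fitted=fitted,
        )


@dataclass
class RecruitmentResults:
    """Fitted recruitment curve: estimates, uncertainties, diagnostics."""

    model: RecruitmentModel
    rmax: float
    threshold_mA: float
    slope_mA: float
    slope_fixed: bool
    cov: np.ndarray
    fitted: np.ndarray

    @property
    def bse(self) -> np.ndarray:
        """Approximate standard errors of the free parameters."""
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    @property
    def resid(self) -> np.ndarray:
        return self.model.response - self.fitted

    def rheobase_mA(self, chronaxie_ms: float) -> float:
        """Weiss-law conversion of the fitted threshold to a rheobase."""
        if chronaxie_ms <= 0:
            raise ValidationError("chronaxie_ms must be > 0")
        return self.threshold_mA / (1.0 + chronaxie_ms / self.model.duration_ms)

    def predict(self, amplitude_mA) -> np.ndarray:
        i = np.asarray(amplitude_mA, dtype=float)
        return self.rmax * expit((i - self.threshold_mA) / self.slope_mA)

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Logistic recruitment fit",
            "=" * 40,
            f"n amplitudes     {self.model.amplitude.size:>10d}",
            f"pulse duration   {self.model.duration_ms:>10.3g} ms",
            f"R_max            {self.rmax:>10.4g}  (se {se[0]:.3g})",
            f"I_th             {self.threshold_mA:>10.4g} mA (se {se[1]:.3g})",
            f"slope            {self.slope_mA:>10.4g} mA"
            + ("  (fixed)" if self.slope_fixed else f" (se {se[2]:.3g})"),
            f"residual SS      {float(np.sum(self.resid ** 2)):>10.4g}",
        ]
        return "\n".join(lines)
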