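"""Univariate qNMR quantification by external calibration curves.

The reference quantification route: integrate the isolated adulterant
signals (tadalafil H1 at 5.85 and H8 at 6.22 ppm, sildenafil H15 at
8.33 ppm), fit area-vs-concentration lines on calibration standards, and
invert the lines for unknowns.  Tadalafil concentrations are reported as
the mean over the H1 and H8 curves.  Sildenafil H17/H18 are deliberately
unused: they sit next to the residual-chloroform and 5-HMF signals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .preprocess import Spectrum, integrate

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "invert_calibration",
    "quantify_by_peaks",
    "integrate_peak",
    "QUANT_PEAKS",
]

#: Default integration windows: +/- 0.05 ppm around the printed shifts.
QUANT_PEAKS = {
    "tadalafil": {"H1": (5.80, 5.90), "H8": (6.17, 6.27)},
    "sildenafil": {"H15": (8.28, 8.38)},
}


@dataclass
class CalibrationCurve:
    """Linear area-vs-concentration calibration for one quantification peak."""

    compound: str
    peak: str
    slope: float  # area per (mg/mL)
    intercept: float  # area
    r2: float
    level_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be > 0")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("R2 must lie in [0, 1]")

    def to_json(self) -> str:
        d = asdict(self)
        d["level_range"] = list(self.level_range)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "CalibrationCurve":
        d = json.loads(s)
        d["level_range"] = tuple(d["level_range"])
        return cls(**d)


def fit_calibration(
    areas: np.ndarray,
    concentrations: np.ndarray,
    compound: str = "",
    peak: str = "",
) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, area) points."""
    areas = np.asarray(areas, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if areas.shape != conc.shape:
        raise ValueError("areas and concentrations length mismatch")
    if np.unique(conc).size < 3:
        raise ValueError("calibration needs at least 3 distinct levels")
    res = stats.linregress(conc, areas)
    return CalibrationCurve(
        compound=compound,
        peak=peak,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        level_range=(float(conc.min()), float(conc.max())),
    )


def invert_calibration(curve: CalibrationCurve, area: float) -> tuple[float, dict]:
    """Concentration from an observed area: x = (area - intercept) / slope.

    Returns (concentration, flags); negative inversions are floored at 0
    and flagged, predictions outside the fitted level range are flagged as
    extrapolation.
    """
    x = (area - curve.intercept) / curve.slope
    flags = {"floored_negative": False, "extrapolated": False}
    if x < 0:
        flags["floored_negative"] = True
        x = 0.0
    lo, hi = curve.level_range
    if not lo <= x <= hi:
        flags["extrapolated"] = True
    return float(x), flags


def integrate_peak(
    spectrum: Spectrum, window: tuple[float, float], baseline: bool = True
) -> float:
    """Peak area over a window, minus a two-point linear local baseline.

    The baseline is the straight line through the spectrum values at the
    window edges (the manual-baseline surrogate); with ``baseline=False``
    the raw trapezoidal integral is returned.
    """
    lo, hi = window
    area = integrate(spectrum, lo, hi)
    if not baseline:
        return area
    y_lo = float(np.interp(lo, spectrum.ppm, spectrum.intensity))
    y_hi = float(np.interp(hi, spectrum.ppm, spectrum.intensity))
    return area - 0.5 * (y_lo + y_hi) * (hi - lo)


def quantify_by_peaks(
    spectrum: Spectrum,
    compound: str,
    curves: dict[str, CalibrationCurve],
    windows: dict[str, tuple[float, float]] | None = None,
    baseline: bool = True,
) -> tuple[float, dict]:
    """Concentration (mg/mL) of a compound from its quantification peaks.

    Each designated window is integrated, each curve inverted, and the
    mean across peaks returned (tadalafil: mean of H1 and H8; sildenafil:
    H15 alone).  Flags from the individual inversions are merged.
    """
    if compound not in QUANT_PEAKS:
        raise ValueError(f"no quantification peaks defined for {compound!r}")
    windows = windows or QUANT_PEAKS[compound]
    values = []
    flags = {"floored_negative": False, "extrapolated": False}
    for peak, window in windows.items():
        if peak not in curves:
            raise ValueError(f"missing calibration curve for {compound} {peak}")
        area = integrate_peak(spectrum, window, baseline=baseline)
        x, fl = invert_calibration(curves[peak], area)
        values.append(x)
        flags = {k: flags[k] or fl[k] for k in flags}
    return float(np.mean(values)), flags
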