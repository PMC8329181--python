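"""Curve-level biophysics: melt-curve Tm, ThT enhancement, Beer-Lambert,
and CD-based G-quadruplex topology classification.

Tm is estimated by the derivative method: the thermal denaturation profile
(normalized ellipticity at 262 nm, or absorbance at 295 nm) is smoothed,
differentiated by central differences, and Tm taken as the temperature of the
extremal |dS/dT|, refined by quadratic interpolation around the derivative
peak.  An optional two-state sigmoid fit cross-checks the estimate.

CD topology calls follow the standard band rules: a parallel G4 shows a
positive band near 260 nm and a negative band near 240 nm; an antiparallel G4
positive bands near 295 and 240 nm with a negative band near 260 nm; a hybrid
a positive band at 290 nm with a shoulder at 260 nm and a negative band near
240 nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MeltCurve",
    "Spectrum",
    "TmEstimate",
    "normalize_curve",
    "estimate_tm",
    "tht_enhancement",
    "concentration_from_absorbance",
    "classify_g4_topology",
]


@dataclass
class MeltCurve:
    """A temperature-indexed signal series (sorted by temperature on init)."""

    temperature: np.ndarray  # degrees C
    signal: np.ndarray  # ellipticity (mdeg) or absorbance (AU)
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("temperature and signal must be equal-length 1-D")
        if len(t) < 5:
            raise ValueError("need at least 5 points")
        order = np.argsort(t)
        t, s = t[order], s[order]
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly monotone")
        self.temperature, self.signal = t, s


@dataclass
class Spectrum:
    """A wavelength-indexed series (CD mdeg or fluorescence intensity)."""

    wavelength_nm: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelength_nm, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if w.shape != v.shape or w.ndim != 1:
            raise ValueError("wavelength and value must be equal-length 1-D")
        order = np.argsort(w)
        self.wavelength_nm, self.value = w[order], v[order]


@dataclass
class TmEstimate:
    tm_c: float  # NaN when no transition detected
    method: str  # derivative | sigmoid_fit
    transition_detected: bool
    derivative_peak_ratio: float = float("nan")  # peak vs baseline derivative


def normalize_curve(curve: MeltCurve) -> MeltCurve:
    """Min-max scale the signal to [0, 1]."""
    lo, hi = float(np.min(curve.signal)), float(np.max(curve.signal))
    if hi == lo:
        raise ValueError("constant signal: no transition to normalize")
    return MeltCurve(curve.temperature.copy(), (curve.signal - lo) / (hi - lo),
                     curve.wavelength_nm)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    out = np.convolve(padded, kernel, mode="valid")
    return out[: len(x)]


def estimate_tm(curve: MeltCurve, smooth_window: int = 5,
                peak_to_noise: float = 3.0) -> TmEstimate:
    """Tm by the derivative method.

    The curve is resampled to a uniform temperature grid (linear
    interpolation), smoothed with a ``smooth_window``-point moving average,
    and differentiated by central differences.  Tm is the temperature of the
    extremal |dS/dT|, refined by quadratic interpolation of the three points
    around the peak.  No transition is reported when the derivative peak is
    below ``peak_to_noise`` times the baseline derivative level (the median
    of |dS/dT|).
    """
    if len(curve.temperature) < 9:
        raise ValueError("need at least 9 points spanning the transition")
    t, s = curve.temperature, curve.signal
    step = float(np.median(np.diff(t)))
    grid = np.arange(t[0], t[-1] + step / 2, step)
    sig = np.interp(grid, t, s)
    sig = _moving_average(sig, smooth_window)
    deriv = np.gradient(sig, grid)
    mag = np.abs(deriv)
    i = int(np.argmax(mag))
    baseline = float(np.median(mag))
    ratio = mag[i] / baseline if baseline > 0 else float("inf") if mag[i] > 0 else 0.0
    detected = np.isfinite(ratio) and ratio >= peak_to_noise and mag[i] > 0
    if not detected:
        return TmEstimate(float("nan"), "derivative", False, float(ratio))
    tm = grid[i]
    if 0 < i < len(grid) - 1:
        y0, y1, y2 = mag[i - 1], mag[i], mag[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            tm = grid[i] + 0.5 * (y0 - y2) / denom * step
    tm = float(np.clip(tm, grid[0], grid[-1]))
    return TmEstimate(tm, "derivative", True, float(ratio))


def _two_state(t, tm, width, lower, upper):
    return lower + (upper - lower) / (1.0 + np.exp((tm - t) / width))


def estimate_tm_sigmoid(curve: MeltCurve) -> TmEstimate:
    """Cross-check Tm by fitting a two-state sigmoid."""
    t, s = curve.temperature, curve.signal
    p0 = [t[len(t) // 2], 5.0, float(s.min()), float(s.max())]
    try:
        popt, _ = curve_fit(_two_state, t, s, p0=p0, maxfev=5000)
    except RuntimeError:
        return TmEstimate(float("nan"), "sigmoid_fit", False)
    tm = float(popt[0])
    inside = t[0] <= tm <= t[-1]
    return TmEstimate(tm if inside else float("nan"), "sigmoid_fit", inside)


def tht_enhancement(f_with_dna: float, f_tht_alone: float) -> float:
    """Thioflavin-T fluorescence enhancement F - F0 at 488 nm.

    F0 is ThT alone, F after oligonucleotide addition.  Negative values are
    permitted (quenching) but flagged with a warning.
    """
    delta = f_with_dna - f_tht_alone
    if delta < 0:
        warnings.warn(f"negative ThT enhancement ({delta:g}): quenching?")
    return delta


def concentration_from_absorbance(
    a: float, epsilon: float = 36000.0, path_cm: float = 1.0
) -> float:
    """Beer-Lambert concentration c = A / (epsilon * l), in mol/L.

    Default epsilon is Thioflavin T's 36,000 M^-1 cm^-1 at 412 nm.
    """
    if path_cm <= 0:
        raise ValueError("path length must be > 0")
    if a < 0:
        raise ValueError("absorbance must be >= 0")
    return a / (epsilon * path_cm)


_BAND_TOL = 6.0  # nm tolerance around the nominal band positions


def _extrema(spectrum: Spectrum):
    """Local maxima/minima of the spectrum (interior points)."""
    w, v = spectrum.wavelength_nm, spectrum.value
    maxima, minima = [], []
    for i in range(1, len(v) - 1):
        if v[i] >= v[i - 1] and v[i] >= v[i + 1] and (v[i] > v[i - 1] or v[i] > v[i + 1]):
            maxima.append(i)
        if v[i] <= v[i - 1] and v[i] <= v[i + 1] and (v[i] < v[i - 1] or v[i] < v[i + 1]):
            minima.append(i)
    return maxima, minima


def _has_band(spectrum: Spectrum, indices, nominal_nm: float, sign: int) -> bool:
    w, v = spectrum.wavelength_nm, spectrum.value
    scale = float(np.max(np.abs(v)))
    if scale == 0:
        return False
    for i in indices:
        if abs(w[i] - nominal_nm) <= _BAND_TOL and sign * v[i] > 0.05 * scale:
            return True
    return False


def _has_shoulder(spectrum: Spectrum) -> bool:
    """Derivative-plateau shoulder near 260 nm while the main peak is 285-295.

    A shoulder is a stretch in 255-268 nm where |dV/dlambda| drops below 20%
    of the main peak's flank slope without forming a separate maximum.
    """
    w, v = spectrum.wavelength_nm, spectrum.value
    imax = int(np.argmax(v))
    if not 285 <= w[imax] <= 295:
        return False
    deriv = np.gradient(v, w)
    flank = (w > 268) & (w < w[imax])
    if not flank.any():
        return False
    flank_slope = float(np.max(np.abs(deriv[flank])))
    if flank_slope == 0:
        return False
    zone = (w >= 255) & (w <= 268)
    return bool(np.any(np.abs(deriv[zone]) < 0.2 * flank_slope))


def classify_g4_topology(cd: Spectrum) -> str:
    """Classify a CD spectrum as parallel, antiparallel, hybrid, or indeterminate.

    Rules (checked in order antiparallel -> hybrid -> parallel):

    * antiparallel: positive bands near 295 and 240 nm, negative near 260 nm
    * hybrid: positive band at 290 nm with a 260 nm shoulder, negative near 240 nm
    * parallel: positive band near 260 nm, negative near 240 nm

    Bands must fall within +/-6 nm of the nominal wavelength.  The call is
    invariant to uniform scaling of the spectrum.
    """
    w = cd.wavelength_nm
    if w[0] > 230 or w[-1] < 310:
        raise ValueError("spectrum must cover 230-310 nm")
    maxima, minima = _extrema(cd)
    if _has_band(cd, maxima, 295, +1) and _has_band(cd, maxima, 240, +1) and _has_band(cd, minima, 260, -1):
        return "antiparallel"
    if _has_band(cd, maxima, 290, +1) and _has_band(cd, minima, 240, -1) and _has_shoulder(cd):
        return "hybrid"
    if _has_band(cd, maxima, 260, +1) and _has_band(cd, minima, 240, -1):
        return "parallel"
    return "indeterminate"
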