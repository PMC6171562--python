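"""Chromatographic peak simulation, detection and integration.

A transparent replacement for vendor quantitation: boxcar smoothing, local
maxima, valley/baseline peak bounds, a median-absolute-deviation noise
estimate for signal-to-noise, and trapezoidal integration above a linear
local baseline.  A seeded Gaussian-peak simulator provides test chromatograms
with retention times taken from the transition library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .library import TransitionLibrary, resolve_isobars, IsobarResolutionError

__all__ = [
    "Chromatogram",
    "Peak",
    "PeakSpec",
    "simulate_chromatogram",
    "detect_peaks",
    "integrate_peak",
    "assign_peaks",
]


@dataclass(frozen=True)
class Chromatogram:
    """One transition's intensity trace over time (minutes, counts)."""

    transition_id: str
    time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("time and intensity must be equal-length 1-D arrays")
        if t.size < 8:
            raise ValueError("chromatogram needs at least 8 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("intensity must be non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", y)


@dataclass(frozen=True)
class Peak:
    """A detected peak: apex, integration bounds, area, height and SNR."""

    apex_rt: float
    left: float
    right: float
    area: float
    height: float
    snr: float

    def __post_init__(self) -> None:
        if not self.left < self.apex_rt < self.right:
            raise ValueError("need left < apex < right")
        if self.area < 0:
            raise ValueError("area must be non-negative")


@dataclass(frozen=True)
class PeakSpec:
    """A Gaussian peak to simulate: apex RT (min), height (counts), sigma (min)."""

    rt: float
    height: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.height < 0:
            raise ValueError("sigma must be > 0 and height >= 0")


def simulate_chromatogram(
    peak_specs: dict[str, Sequence[PeakSpec]],
    *,
    t_start: float = 0.0,
    t_end: float = 15.0,
    dt: float = 0.01,
    noise_sd: float = 0.0,
    baseline: float = 0.0,
    seed: int = 0,
) -> dict[str, Chromatogram]:
    """Simulate Gaussian peaks plus Gaussian baseline noise on a uniform grid.

    ``peak_specs`` maps each transition id to its peaks; ids must be unique
    (dict keys enforce this).  Output is clipped at zero and deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(t_start, t_end + dt / 2, dt)
    out: dict[str, Chromatogram] = {}
    for tid, specs in peak_specs.items():
        y = np.full_like(t, float(baseline))
        for s in specs:
            y = y + s.height * np.exp(-0.5 * ((t - s.rt) / s.sigma) ** 2)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=t.size)
        out[tid] = Chromatogram(tid, t, np.clip(y, 0.0, None))
    return out


def _mad_noise(y: np.ndarray, smooth: np.ndarray) -> float:
    """Noise scale from the median absolute deviation of the residual."""
    resid = y - smooth
    mad = np.median(np.abs(resid - np.median(resid)))
    return 1.4826 * mad


def _boxcar(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    return np.convolve(padded, kernel, mode="same")[pad : pad + y.size]


def detect_peaks(
    c: Chromatogram,
    min_snr: float = 3.0,
    min_width: float = 0.02,
    smooth_window: int = 5,
) -> list[Peak]:
    """Detect peaks as local maxima of the boxcar-smoothed trace.

    Bounds are placed at the flanking valleys or at baseline return
    (smoothed signal below the noise floor), whichever comes first; SNR is
    peak height over the MAD noise estimate.  Peaks failing ``min_snr`` or
    narrower than ``min_width`` minutes are discarded.
    """
    if min_snr <= 0 or min_width <= 0:
        raise ValueError("thresholds must be positive")
    t, y = c.time, c.intensity
    smooth = _boxcar(y, smooth_window)
    noise = _mad_noise(y, smooth)
    floor = max(noise, 1e-12 * (smooth.max() if smooth.size else 1.0), 1e-300)
    idx, _ = find_peaks(smooth, height=floor)
    peaks: list[Peak] = []
    for i in idx:
        # walk left/right to valley or baseline return
        left = i
        while left > 0 and smooth[left - 1] <= smooth[left] and smooth[left] > floor:
            left -= 1
        right = i
        while (
            right < smooth.size - 1
            and smooth[right + 1] <= smooth[right]
            and smooth[right] > floor
        ):
            right += 1
        if left == i or right == i:
            continue
        width = t[right] - t[left]
        height = y[left : right + 1].max()
        snr = height / floor if floor > 0 else np.inf
        if width < min_width or snr < min_snr:
            continue
        peak = Peak(
            apex_rt=float(t[i]),
            left=float(t[left]),
            right=float(t[right]),
            area=0.0,
            height=float(height),
            snr=float(snr),
        )
        area = integrate_peak(c, peak)
        peaks.append(
            Peak(peak.apex_rt, peak.left, peak.right, area, peak.height, peak.snr)
        )
    return peaks


def integrate_peak(c: Chromatogram, p: Peak) -> float:
    """Trapezoidal area above a linear baseline drawn between the peak bounds."""
    if p.right <= p.left:
        raise ValueError("inverted peak bounds")
    if p.left < c.time[0] or p.right > c.time[-1]:
        raise ValueError("peak bounds outside chromatogram time range")
    mask = (c.time >= p.left) & (c.time <= p.right)
    t, y = c.time[mask], c.intensity[mask]
    baseline = np.interp(t, [t[0], t[-1]], [y[0], y[-1]])
    return max(float(np.trapezoid(y - baseline, t)), 0.0)


def assign_peaks(
    peaks_by_transition: dict[tuple[float, float], list[Peak]],
    library: TransitionLibrary,
    rt_tolerance: float = 0.2,
) -> list[dict]:
    """Map detected peaks to library analytes by (Q1, Q3) and retention time.

    Returns one record per peak with the matched abbreviation or ``None``
    (unassigned); isobaric transitions are resolved by nearest RT.
    """
    records = []
    for (q1, q3), peaks in peaks_by_transition.items():
        for p in peaks:
            try:
                analyte = resolve_isobars(q1, q3, p.apex_rt, rt_tolerance, library)
                abbrev = analyte.abbreviation
            except IsobarResolutionError:
                abbrev = None
            records.append(
                {
                    "q1": q1,
                    "q3": q3,
                    "apex_rt": p.apex_rt,
                    "area": p.area,
                    "snr": p.snr,
                    "assigned": abbrev,
                }
            )
    return records
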