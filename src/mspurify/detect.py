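"""Chromatographic peak detection on single-feature EIC windows.

EICs are converted to integrated intensities by the classical
smoothing/derivative scheme: a 4th-order Savitzky–Golay filter suppresses
scan noise, successive convolution with the first derivative of a Gaussian
kernel locates peak apexes as negative-going zero crossings of the response,
and the raw (unsmoothed) signal is integrated trapezoidally between the
detected bounds.  This is the bridge that lets the intensity-level
purification model run on scan-level data, and the comparison path for the
scan-level model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "DetectedPeak",
    "savitzky_golay",
    "gaussian_derivative_detect",
    "integrate_auc",
    "eic_to_intensity",
]


@dataclass
class DetectedPeak:
    """A detected chromatographic peak: scan-index bounds, apex and area."""

    left_bound: int
    apex: int
    right_bound: int
    area: float = 0.0

    def __post_init__(self) -> None:
        if not self.left_bound <= self.apex <= self.right_bound:
            raise ValueError("require left_bound <= apex <= right_bound")
        if self.area < 0:
            raise ValueError("area must be non-negative")


def savitzky_golay(signal: np.ndarray, window: int = 25, order: int = 4) -> np.ndarray:
    """Least-squares local-polynomial (Savitzky–Golay) smoothing.

    Edges are handled by fitting the polynomial on truncated windows
    (``mode="interp"``).  An order-``order`` filter reproduces polynomials up
    to that degree exactly.
    """
    signal = np.asarray(signal, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be smaller than window")
    if signal.size < window:
        raise ValueError(
            f"signal has {signal.size} scans < window {window}; "
            "use a smaller window")
    return savgol_filter(signal, window_length=window, polyorder=order,
                         mode="interp")


def _gaussian_derivative_kernel(width: int, sigma: float) -> np.ndarray:
    """First derivative of a Gaussian, sampled on ``width`` points.

    Oriented so that correlating a rising signal gives a positive response:
    the response is the smoothed first derivative of the signal.
    """
    half = width // 2
    i = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-0.5 * (i / sigma) ** 2)
    k = (i / sigma**2) * g
    return k


def gaussian_derivative_detect(
    signal: np.ndarray,
    width: int = 25,
    sigma: float = 3.0,
    mad_factor: float = 3.0,
) -> List[DetectedPeak]:
    """Detect peaks via the first derivative of a Gaussian kernel.

    The signal is correlated with the derivative kernel (edge-padded); a peak
    apex is a negative-going zero crossing of the response flanked by a
    positive lobe before and a negative lobe after, both exceeding a
    noise-scaled threshold (``mad_factor`` × the median absolute deviation of
    the response).  Peak bounds are the nearest response sign changes beyond
    the lobes (or the signal edges).
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if not signal.any():
        return []
    kernel = _gaussian_derivative_kernel(width, sigma)
    half = kernel.size // 2
    padded = np.pad(signal, half, mode="edge")
    # correlation: response[s] = sum_i kernel[i] * signal[s + i]
    response = np.correlate(padded, kernel, mode="valid")
    mad = np.median(np.abs(response - np.median(response)))
    thr = mad_factor * mad
    if thr <= 0:
        thr = 1e-12 * max(np.abs(response).max(), 1.0)

    peaks: List[DetectedPeak] = []
    # negative-going zero crossings of the response
    for s in range(n - 1):
        if not (response[s] > 0 >= response[s + 1]):
            continue
        apex = s if abs(response[s]) <= abs(response[s + 1]) else s + 1
        # positive lobe before the crossing
        left = s
        while left > 0 and response[left] > 0:
            left -= 1
        pos_lobe = response[left:s + 1].max(initial=0.0)
        if response[left] < 0 and left < s:
            left += 1  # do not reach into a preceding peak's negative lobe
        # negative lobe after the crossing
        right = s + 1
        while right < n - 1 and response[right] < 0:
            right += 1
        neg_lobe = -response[s + 1:right + 1].min(initial=0.0)
        if pos_lobe < thr or neg_lobe < thr:
            continue
        peaks.append(DetectedPeak(left_bound=left, apex=apex,
                                  right_bound=right))
    for p in peaks:
        p.area = integrate_auc(signal, p)
    return peaks


def integrate_auc(signal: np.ndarray, peak: DetectedPeak) -> float:
    """Trapezoidal area of the raw signal between the peak bounds
    (unit scan spacing)."""
    signal = np.asarray(signal, dtype=float)
    if not (0 <= peak.left_bound <= peak.right_bound < signal.size):
        raise ValueError("peak bounds outside the signal")
    seg = signal[peak.left_bound:peak.right_bound + 1]
    if seg.size < 2:
        return 0.0
    return float(np.trapezoid(seg))


def eic_to_intensity(
    signal: np.ndarray,
    sg_window: int = 25,
    sg_order: int = 4,
    gd_width: int = 25,
    gd_sigma: float = 3.0,
    warn_multiple: bool = True,
) -> float:
    """Full smooth → detect → integrate pipeline for one EIC window.

    Detection runs on the smoothed trace; the area is taken from the raw
    signal so smoothing biases only the localisation, not the quantity.  If
    several peaks are detected the largest-area one is used (these windows
    are expected to hold a single chromatographic peak).  Returns 0.0 when
    nothing passes the threshold.
    """
    signal = np.asarray(signal, dtype=float)
    smoothed = savitzky_golay(signal, window=sg_window, order=sg_order)
    peaks = gaussian_derivative_detect(smoothed, width=gd_width, sigma=gd_sigma)
    if not peaks:
        return 0.0
    areas = [integrate_auc(signal, p) for p in peaks]
    if len(peaks) > 1 and warn_multiple:
        warnings.warn(
            f"{len(peaks)} peaks detected in a single-feature EIC window; "
            "using the largest-area peak", RuntimeWarning, stacklevel=2)
    return float(max(areas))
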