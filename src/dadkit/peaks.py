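"""Peak picking, border refinement, window merging and integration.

Detection operates on the wavelength-summed absorbance trace: the full
spectral dimension is kept for purity checking and deconvolution
downstream, but apex finding itself is one-dimensional.  Borders start
at the flanking local minima, are expanded outward down to a noise
floor, and overlapping windows are merged so the purity checker always
receives one contiguous window per (possibly coeluting) signal group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .io import Chromatogram
from .preprocess import NoiseEstimate

__all__ = ["Peak", "summed_trace", "pick_peaks", "expand_borders",
           "merge_overlapping", "integrate"]

MIN_WINDOW_POINTS = 3


@dataclass
class Peak:
    """A contiguous retention window on a chromatogram."""

    run_id: str
    apex_index: int
    left_index: int
    right_index: int
    integral: float = 0.0            # mAU*min, summed-trace trapezoid
    saturated: bool = False
    pure: Optional[bool] = None      # set by the purity checker
    assignment: Optional[str] = None # compound id or unknown label
    concentration: Optional[float] = None
    purity: object = None            # PurityReport, set later
    components: list = field(default_factory=list)  # DeconvComponents

    def __post_init__(self):
        if not (self.left_index <= self.apex_index <= self.right_index):
            raise ValueError("apex must lie within the borders")
        if self.right_index <= self.left_index:
            raise ValueError("window must span more than one point")

    @property
    def width(self) -> int:
        return self.right_index - self.left_index + 1


def summed_trace(chrom: Chromatogram) -> np.ndarray:
    """Wavelength-summed absorbance, mAU, one value per time point."""
    return chrom.absorbance.sum(axis=1)


def pick_peaks(trace: np.ndarray, noise: NoiseEstimate,
               rel_height: float = 0.01, snr_min: float = 10.0,
               run_id: str = "") -> List[Peak]:
    """Locate apexes on the summed trace and set initial borders.

    A local maximum becomes an apex when its height reaches both the
    relative threshold (fraction of the tallest maximum) and the
    signal-to-noise threshold.  Detection runs on a 3-point-smoothed
    copy of the trace with a small prominence requirement so that shot
    noise riding on a peak's crown does not spawn duplicate apexes;
    apex positions are then refined on the raw trace.  Initial borders
    sit at the nearest flanking local minima of the smoothed trace.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < MIN_WINDOW_POINTS or np.all(trace <= 0):
        return []
    smooth = uniform_filter1d(trace, size=3, mode="nearest")
    threshold = max(rel_height * float(trace.max()), snr_min * noise.sigma)
    prominence = max(3.0 * noise.sigma, 1e-12)
    apexes, _ = find_peaks(smooth, height=threshold, prominence=prominence)
    peaks: List[Peak] = []
    for apex in apexes:
        # walk down the smoothed trace to the flanking minima
        left = apex
        while left > 0 and smooth[left - 1] < smooth[left]:
            left -= 1
        right = apex
        while right < trace.size - 1 and smooth[right + 1] < smooth[right]:
            right += 1
        # refine apex on the raw trace within the window
        apex_raw = left + int(np.argmax(trace[left : right + 1]))
        if right - left < 1:
            continue
        peaks.append(Peak(run_id=run_id, apex_index=apex_raw,
                          left_index=left, right_index=right))
    peaks.sort(key=lambda p: p.apex_index)
    return peaks


def expand_borders(trace: np.ndarray, peak: Peak, noise: NoiseEstimate,
                   left_limit: int = 0, right_limit: Optional[int] = None) -> Peak:
    """Push borders outward while the trace stays above the noise floor.

    A border keeps moving away from the apex while the raw trace exceeds
    3 x sigma and the 3-point-smoothed trace keeps descending, and never
    crosses ``left_limit``/``right_limit`` (e.g. a neighboring apex or
    the inter-peak minimum).  Idempotent once the stop condition holds.
    """
    trace = np.asarray(trace, dtype=float)
    if right_limit is None:
        right_limit = trace.size - 1
    smooth = uniform_filter1d(trace, size=3, mode="nearest")
    floor = 3.0 * noise.sigma
    left = peak.left_index
    while left > left_limit and trace[left - 1] > floor and smooth[left - 1] <= smooth[left]:
        left -= 1
    right = peak.right_index
    while (right < right_limit and trace[right + 1] > floor
           and smooth[right + 1] <= smooth[right]):
        right += 1
    peak.left_index = left
    peak.right_index = right
    return peak


def merge_overlapping(peaks: List[Peak]) -> List[Peak]:
    """Merge peaks whose border windows intersect.

    Expanded borders of genuinely separated peaks stop at the noise
    floor and leave a gap, so any intersection — even a single shared
    index at the inter-peak minimum — marks real overlap and the
    windows are unioned into one whose apex is the higher of the
    constituent apexes.  The result is independent of input order and
    associative.
    """
    if not peaks:
        return []
    ordered = sorted(peaks, key=lambda p: (p.left_index, p.right_index))
    merged = [ordered[0]]
    for peak in ordered[1:]:
        last = merged[-1]
        if peak.left_index <= last.right_index:
            # union window; apex = taller apex (ties -> earlier)
            last.right_index = max(last.right_index, peak.right_index)
            if _apex_height(peak) > _apex_height(last):
                last.apex_index = peak.apex_index
                last._apex_height = peak._apex_height  # type: ignore[attr-defined]
        else:
            merged.append(peak)
    return merged


def _apex_height(peak: Peak) -> float:
    return getattr(peak, "_apex_height", 0.0)


def tag_apex_heights(trace: np.ndarray, peaks: List[Peak]) -> None:
    """Record apex heights used for merge tie-breaking."""
    for p in peaks:
        p._apex_height = float(trace[p.apex_index])  # type: ignore[attr-defined]


def integrate(trace: np.ndarray, peak: Peak, dt: float) -> float:
    """Trapezoidal area of the summed trace over the window, mAU*min.

    Small negative residues after baseline correction are clipped at 0.
    """
    if peak.width < MIN_WINDOW_POINTS:
        raise ValueError(
            f"window [{peak.left_index}, {peak.right_index}] too narrow to integrate"
        )
    segment = np.asarray(trace[peak.left_index : peak.right_index + 1], dtype=float)
    area = float(np.trapezoid(segment, dx=dt))
    return max(area, 0.0)
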