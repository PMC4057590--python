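"""Non-perfused-area scoring at peak arterial enhancement.

Regions a contrast bolus never reaches (necrotic, hence non-perfused,
tumor areas) stay at background echo power in the peak-enhancement
frame of the arterial-phase clip.  Readers score the non-enhanced
fraction of the tumor on a 10 % step scale; disagreements are settled
by consensus.  The visual scoring is operationalized here as a
threshold on linearized echo power relative to the background level
outside the ROI, with the threshold factor configurable per reader.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compression import CompressionLaw, linearize
from .containers import CineLoop
from .dte import TimeIntensityCurve, roi_tic
from .errors import MaskError, ParameterError, WindowError

__all__ = [
    "PerfusionReading",
    "peak_enhancement_frame",
    "non_enhanced_fraction",
    "quantize_step10",
    "consensus",
    "score_exam",
]

#: Arterial-phase search window for the peak-enhancement frame (s).
ARTERIAL_WINDOW = (0.0, 30.0)


def quantize_step10(raw: float) -> int:
    """Snap a raw percentage to the 10 % step scale (half rounds up)."""
    if not 0 <= raw <= 100:
        raise ParameterError(f"percentage must lie in [0, 100], got {raw}")
    return int(np.floor(raw / 10.0 + 0.5) * 10)


@dataclass(frozen=True)
class PerfusionReading:
    """One reader's non-enhanced-area score."""

    raw_fraction: float  # percent in [0, 100]
    quantized: int  # percent, multiple of 10
    reader_id: str

    def __post_init__(self) -> None:
        if not 0 <= self.raw_fraction <= 100:
            raise ParameterError("raw fraction must lie in [0, 100]")
        if self.quantized % 10 != 0 or not 0 <= self.quantized <= 100:
            raise ParameterError("quantized score must be a multiple of 10 in [0, 100]")
        if abs(self.quantized - self.raw_fraction) > 5:
            raise ParameterError("quantized score must be the nearest 10 % step")

    @classmethod
    def from_raw(cls, raw: float, reader_id: str) -> "PerfusionReading":
        return cls(float(raw), quantize_step10(raw), reader_id)


def peak_enhancement_frame(
    tic: TimeIntensityCurve, search_window: tuple = ARTERIAL_WINDOW
) -> int:
    """Index of the frame with maximal enhancement in the search window.

    The search is confined to the arterial-phase clip (first 30 s by
    default); ties resolve to the earliest frame.
    """
    lo, hi = search_window
    in_win = (tic.times >= lo) & (tic.times < hi)
    if not in_win.any():
        raise WindowError(f"search window [{lo}, {hi}) s contains no frame")
    idx = np.flatnonzero(in_win)
    return int(idx[np.argmax(tic.values[idx])])


def non_enhanced_fraction(
    frame_power: np.ndarray, roi: np.ndarray, threshold_factor: float = 2.0
) -> float:
    """Raw non-enhanced percentage of ROI pixels in a linearized frame.

    A pixel counts as non-enhanced when its echo power is below
    ``threshold_factor`` times the background level, estimated as the
    median power outside the ROI.
    """
    frame_power = np.asarray(frame_power, dtype=float)
    roi = np.asarray(roi).astype(bool)
    if roi.shape != frame_power.shape:
        raise MaskError("ROI shape must match the frame")
    if not roi.any():
        raise MaskError("ROI is empty")
    outside = frame_power[~roi]
    if outside.size == 0:
        raise MaskError("ROI covers the whole frame: no background available")
    background = float(np.median(outside))
    if background <= 0:
        raise ParameterError("degenerate background: median power outside the ROI is zero")
    frac = np.mean(frame_power[roi] < threshold_factor * background)
    return float(100.0 * frac)


def consensus(a: PerfusionReading, b: PerfusionReading) -> int:
    """Final score from two independent readings.

    Matching quantized scores stand; on mismatch the quantized mean of
    the two raw fractions is used (a deterministic stand-in for
    consensus-by-discussion).
    """
    if a.quantized == b.quantized:
        return a.quantized
    return quantize_step10((a.raw_fraction + b.raw_fraction) / 2.0)


def score_exam(
    cine: CineLoop,
    roi: np.ndarray,
    law: CompressionLaw | None = None,
    threshold_factors: tuple = (1.5, 2.5),
    search_window: tuple = ARTERIAL_WINDOW,
):
    """Two-reader scoring of one exam.

    Returns ``(readings, consensus_percent, peak_index)``; the two
    readers share the peak-enhancement frame but apply their own
    threshold factor.
    """
    if law is None:
        law = cine.law
        if law is None:
            raise ParameterError("no compression law given and none in cine metadata")
    tic = roi_tic(cine, roi, law)
    peak = peak_enhancement_frame(tic, search_window)
    frame_power = linearize(cine.frames[peak], law)
    readings = [
        PerfusionReading.from_raw(
            non_enhanced_fraction(frame_power, roi, tf), reader_id=f"reader{i + 1}"
        )
        for i, tf in enumerate(threshold_factors)
    ]
    final = readings[0].quantized
    if len(readings) >= 2:
        final = consensus(readings[0], readings[1])
    return readings, final, peak
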