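"""Tumor-to-pad strain ratio from elastography acquisitions.

Strain imaging shows relative tissue deformability under manual
compression; it carries no absolute stiffness scale, so every exam
interposes a reference pad of known, homogeneous consistency between
probe and tumor and reports the ratio of mean tumor strain to mean pad
strain.  A higher ratio means a softer (more deformable) tumor.  The
ratio is invariant to the overall compression force (which scales both
regions alike), which is what makes the manual acquisition comparable
across sessions.  Three replicate acquisitions per session are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import StrainPair
from .errors import MaskError, ParameterError

__all__ = ["StrainResult", "strain_ratio", "triplicate_mean", "analyze_pair"]


@dataclass(frozen=True)
class StrainResult:
    """Triplicate strain-ratio measurement (ELX tumor/pad)."""

    replicate_ratios: tuple
    mean_ratio: float

    def __post_init__(self) -> None:
        assert np.isclose(self.mean_ratio, np.mean(self.replicate_ratios))


def strain_ratio(strain: np.ndarray, tumor_roi: np.ndarray, pad_roi: np.ndarray) -> float:
    """Mean tumor strain over mean pad strain for one acquisition."""
    strain = np.asarray(strain, dtype=float)
    tumor_roi = np.asarray(tumor_roi).astype(bool)
    pad_roi = np.asarray(pad_roi).astype(bool)
    if tumor_roi.shape != strain.shape or pad_roi.shape != strain.shape:
        raise MaskError("ROI shapes must match the strain image")
    if not tumor_roi.any() or not pad_roi.any():
        raise MaskError("tumor and pad ROIs must both be non-empty")
    if np.any(tumor_roi & pad_roi):
        raise MaskError("tumor and pad ROIs must be disjoint")
    pad_mean = float(strain[pad_roi].mean())
    if pad_mean <= 0:
        raise ParameterError("mean pad strain must be positive")
    return float(strain[tumor_roi].mean()) / pad_mean


def triplicate_mean(ratios) -> StrainResult:
    """Arithmetic mean of the three per-session replicate ratios."""
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3:
        raise ParameterError(f"exactly 3 replicate ratios expected, got {len(ratios)}")
    if any(r <= 0 for r in ratios):
        raise ParameterError("strain ratios must be positive")
    return StrainResult(ratios, float(np.mean(ratios)))


def analyze_pair(pair: StrainPair) -> StrainResult:
    """Per-replicate ratios and their mean for one strain acquisition."""
    ratios = [strain_ratio(s, pair.tumor_mask, pair.pad_mask) for s in pair.strains]
    return triplicate_mean(ratios)
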