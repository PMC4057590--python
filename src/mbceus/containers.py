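"""In-memory containers for cine loops, phantoms and strain acquisitions.

Masks are row-major boolean images with 0-based indices; all region
definitions are pixel sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compression import CompressionLaw
from .errors import MaskError, ParameterError

__all__ = ["CineLoop", "TumorPhantom", "StrainPair", "clip_times"]


def clip_times(clips, frame_rate_hz: float) -> np.ndarray:
    """Frame timestamps (s) for a sequence of acquisition clips.

    Each clip ``(start, end)`` is sampled half-open at the given frame
    rate, so consecutive clips never duplicate a timestamp.
    """
    if frame_rate_hz <= 0:
        raise ParameterError("frame rate must be positive")
    parts = []
    for start, end in clips:
        if end <= start:
            raise ParameterError(f"clip ({start}, {end}) must have end > start")
        n = int(round((end - start) * frame_rate_hz))
        parts.append(start + np.arange(n) / frame_rate_hz)
    t = np.concatenate(parts)
    if np.any(np.diff(t) <= 0):
        raise ParameterError("clips must be disjoint and in increasing order")
    return t


@dataclass
class CineLoop:
    """Ordered 8-bit display frames with acquisition metadata.

    ``meta`` follows the JSON sidecar schema: ``frame_rate_hz``,
    ``flash_onset_s``/``flash_duration_s`` (optional), ``clips``,
    ``compression_law`` and ``pixel_size_mm``.
    """

    frames: np.ndarray  # (T, H, W) uint8
    times: np.ndarray  # (T,) seconds
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ParameterError("cine frames must be a (T, H, W) stack")
        if len(self.times) != len(self.frames):
            raise ParameterError("one timestamp per frame required")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("frame timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def law(self) -> CompressionLaw | None:
        d = self.meta.get("compression_law")
        return CompressionLaw.from_dict(d) if d else None

    @property
    def flash(self):
        from .dte import FlashInterval  # local import to avoid a cycle

        onset = self.meta.get("flash_onset_s")
        if onset is None:
            return None
        return FlashInterval(float(onset), float(onset) + float(self.meta["flash_duration_s"]))


def _as_mask(mask: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise MaskError(f"{name} must be a 2-D image")
    return m.astype(bool)


@dataclass
class TumorPhantom:
    """Digital phantom: tumor disc, necrotic core, reference pad.

    Invariants enforced at construction: the necrotic submask is a
    subset of the tumor mask, the pad is disjoint from the tumor, and
    the receptor density map vanishes on necrotic and extra-tumoral
    pixels (only perfused endothelium carries target receptor).
    """

    tumor_mask: np.ndarray
    necrotic_submask: np.ndarray
    pad_mask: np.ndarray
    receptor_map: np.ndarray

    def __post_init__(self) -> None:
        self.tumor_mask = _as_mask(self.tumor_mask, "tumor_mask")
        self.necrotic_submask = _as_mask(self.necrotic_submask, "necrotic_submask")
        self.pad_mask = _as_mask(self.pad_mask, "pad_mask")
        self.receptor_map = np.asarray(self.receptor_map, dtype=float)
        shapes = {
            self.tumor_mask.shape,
            self.necrotic_submask.shape,
            self.pad_mask.shape,
            self.receptor_map.shape,
        }
        if len(shapes) != 1:
            raise MaskError("all phantom images must share one shape")
        if not self.tumor_mask.any():
            raise MaskError("tumor mask is empty")
        if np.any(self.necrotic_submask & ~self.tumor_mask):
            raise MaskError("necrotic submask must be a subset of the tumor mask")
        if np.any(self.pad_mask & self.tumor_mask):
            raise MaskError("pad mask must be disjoint from the tumor mask")
        if np.any(self.receptor_map < 0):
            raise ParameterError("receptor density must be non-negative")
        if np.any(self.receptor_map[~self.perfused_mask] != 0):
            raise ParameterError("receptor density must vanish outside the perfused region")

    @property
    def shape(self) -> tuple:
        return self.tumor_mask.shape

    @property
    def perfused_mask(self) -> np.ndarray:
        return self.tumor_mask & ~self.necrotic_submask

    @property
    def necrotic_fraction(self) -> float:
        return float(self.necrotic_submask.sum()) / float(self.tumor_mask.sum())


@dataclass
class StrainPair:
    """Co-registered strain replicates with tumor and reference-pad masks.

    ``strains`` stacks the replicate acquisitions taken during one
    anaesthesia session (three in the standard protocol).
    """

    strains: np.ndarray  # (n_rep, H, W) float
    tumor_mask: np.ndarray
    pad_mask: np.ndarray

    def __post_init__(self) -> None:
        self.strains = np.atleast_3d(np.asarray(self.strains, dtype=float))
        if self.strains.ndim != 3:
            raise ParameterError("strain replicates must be a (n, H, W) stack")
        self.tumor_mask = _as_mask(self.tumor_mask, "tumor_mask")
        self.pad_mask = _as_mask(self.pad_mask, "pad_mask")
        if self.tumor_mask.shape != self.strains.shape[1:] or self.pad_mask.shape != self.strains.shape[1:]:
            raise MaskError("masks must match the strain image shape")
        if np.any(self.tumor_mask & self.pad_mask):
            raise MaskError("tumor and pad masks must be disjoint")

    @property
    def n_replicates(self) -> int:
        return len(self.strains)
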