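"""Logarithmic display compression and its inversion ("linearization").

Ultrasound scanners map echo power onto an 8-bit display through a
logarithmic law with a configurable dynamic range.  Quantification of
contrast agent must happen on echo power, which is proportional to the
number of microbubbles in the region, not on display intensity: the
display value of a mean is not the mean of display values.  This module
models the forward mapping (power -> display level) and its inverse
(display level -> power), which every quantification stage runs through
before averaging pixels.

The forward law maps a reference power ``e_ref`` to full scale (level
255) and the power ``dr_db`` decibels below it to level 0; everything in
between is linear in dB.  The scanner's true law is proprietary, so this
explicit form is the package's convention; round-tripping through it is
exact up to half a quantization level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = ["CompressionLaw", "log_compress", "linearize"]


@dataclass(frozen=True)
class CompressionLaw:
    """Display mapping between echo power (a.u.) and 8-bit intensity.

    Parameters
    ----------
    dr_db
        Dynamic range of the display in decibels (> 0).  Narrow ranges
        (the scanner setting used for targeted-microbubble exams is
        7 dB) spread few dB over the whole grey scale; simulations may
        prefer a conventional 40 dB.
    e_ref
        Echo power in arbitrary units mapped to full scale (level 255).
    levels
        Number of display levels; 256 for 8-bit displays.
    """

    dr_db: float = 7.0
    e_ref: float = 1.0
    levels: int = 256

    def __post_init__(self) -> None:
        if not self.dr_db > 0:
            raise ParameterError(f"dynamic range must be > 0 dB, got {self.dr_db}")
        if not self.e_ref > 0:
            raise ParameterError(f"reference power must be > 0, got {self.e_ref}")
        if self.levels < 2:
            raise ParameterError(f"need at least 2 display levels, got {self.levels}")

    @property
    def floor_power(self) -> float:
        """Echo power mapped to display level 0."""
        return self.e_ref * 10.0 ** (-self.dr_db / 10.0)

    def half_level_tolerance(self) -> float:
        """Maximum relative round-trip error for in-range powers.

        Quantization moves a value by at most half a level, i.e. by
        ``dr_db / (2 (levels-1))`` dB.
        """
        return 10.0 ** (self.dr_db / (10.0 * 2.0 * (self.levels - 1))) - 1.0

    def to_dict(self) -> dict:
        return {"dr_db": self.dr_db, "e_ref": self.e_ref, "levels": self.levels}

    @classmethod
    def from_dict(cls, d: dict) -> "CompressionLaw":
        return cls(
            dr_db=float(d["dr_db"]),
            e_ref=float(d["e_ref"]),
            levels=int(d.get("levels", 256)),
        )


def log_compress(power: np.ndarray, law: CompressionLaw) -> np.ndarray:
    """Map echo power (a.u., >= 0) to 8-bit display intensity.

    ``D = round((levels-1) * clamp(1 + 10 log10(E / e_ref) / dr_db, 0, 1))``
    with round-half-away-from-zero.  Zero power maps to level 0 (the log
    of zero falls below the display floor and is clamped).
    """
    E = np.asarray(power, dtype=float)
    if np.any(E < 0):
        raise ParameterError("echo power must be non-negative")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(np.where(E > 0, E / law.e_ref, np.nan))
    u = 1.0 + db / law.dr_db
    u = np.where(np.isnan(u), 0.0, u)
    u = np.clip(u, 0.0, 1.0)
    # round half away from zero (u >= 0 so floor(x + 0.5) suffices)
    D = np.floor((law.levels - 1) * u + 0.5)
    return D.astype(np.uint8 if law.levels <= 256 else np.uint16)


def linearize(display: np.ndarray, law: CompressionLaw) -> np.ndarray:
    """Invert the display law, recovering echo power from 8-bit intensity.

    ``E = e_ref * 10 ** (dr_db (D/(levels-1) - 1) / 10)``.  Level 0 maps
    to the display floor power, not to zero: below-range powers are not
    recoverable after clamping.
    """
    D = np.asarray(display, dtype=float)
    if np.any((D < 0) | (D > law.levels - 1)):
        raise ParameterError(f"display values must lie in [0, {law.levels - 1}]")
    return law.e_ref * 10.0 ** (law.dr_db * (D / (law.levels - 1) - 1.0) / 10.0)
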