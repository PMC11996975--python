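"""Shared containers for radial frequency curves and measurement results.

All spatial frequencies are in mm^-1, distances in mm and CT numbers in
Hounsfield units (HU); a noise power spectrum carries HU^2*mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FrequencyCurve:
    """A radially symmetric quantity sampled on a spatial-frequency grid.

    Parameters
    ----------
    f : ndarray
        Non-negative, strictly increasing frequency grid in mm^-1.
    values : ndarray
        Per-frequency magnitudes (unitless for a TTF, HU^2*mm^2 for an NPS).
    """

    f: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.f.ndim != 1 or self.values.ndim != 1:
            raise ValueError("f and values must be one-dimensional")
        if len(self.f) != len(self.values):
            raise ValueError(
                f"length mismatch: {len(self.f)} frequencies vs {len(self.values)} values"
            )
        if len(self.f) and self.f[0] < 0:
            raise ValueError("frequencies must be non-negative")
        if len(self.f) > 1 and np.any(np.diff(self.f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(~np.isfinite(self.f)) or np.any(~np.isfinite(self.values)):
            raise ValueError("curve contains non-finite entries")

    @property
    def f_max(self) -> float:
        return float(self.f[-1])

    def interp(self, f: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``f``; end values are held constant."""
        return np.interp(np.asarray(f, dtype=float), self.f, self.values)

    def scaled(self, factor: float) -> "FrequencyCurve":
        return FrequencyCurve(self.f.copy(), self.values * factor)

    def cropped(self, f_max: float) -> "FrequencyCurve":
        keep = self.f <= f_max + 1e-12
        return FrequencyCurve(self.f[keep], self.values[keep])


@dataclass
class TTFResult:
    """Task transfer function with its 50% frequency and the edge CNR used."""

    curve: FrequencyCurve
    f50: float
    cnr_used: float

    def __post_init__(self) -> None:
        if abs(self.curve.values[0] - 1.0) > 1e-9:
            raise ValueError("TTF must be normalized to 1 at zero frequency")
        if not self.f50 > 0:
            raise ValueError("f50 must be positive")


@dataclass
class NPSResult:
    """2D noise power spectrum and its radial rebin.

    ``nps2d`` is fftshifted over (fy, fx); ``fx``/``fy`` are the matching
    frequency axes in mm^-1.
    """

    nps2d: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    radial: FrequencyCurve
    n_rois: int
    roi_size_px: int


@dataclass
class SSPResult:
    """Slice sensitivity profile along z with its FWHM in mm."""

    z: np.ndarray
    profile: np.ndarray
    fwhm_mm: float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.profile = np.asarray(self.profile, dtype=float)
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z grid must be strictly increasing")
        if abs(self.profile.max() - 1.0) > 1e-9:
            raise ValueError("profile must be peak-normalized")
        if not self.fwhm_mm > 0:
            raise ValueError("FWHM must be positive")


@dataclass
class TaskSpec:
    """Detection task: a uniform disk of diameter ``diameter_mm`` and
    contrast ``delta_hu`` against the background."""

    diameter_mm: float = 5.0
    delta_hu: float = 0.0

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ValueError("task diameter must be positive")
        if not np.isfinite(self.delta_hu):
            raise ValueError("task contrast must be finite")


@dataclass
class DetectabilityResult:
    """Ideal-observer detectability and the system performance function."""

    d_prime: float
    correction_factor: float
    nps_corrected: FrequencyCurve
    spf: FrequencyCurve
    spf2: FrequencyCurve
    f_max: float
    task: TaskSpec = field(default=None)
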