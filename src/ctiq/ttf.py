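"""Task transfer function estimation by the circular-edge technique.

The TTF is the contrast- and dose-specific analogue of the MTF, measured
from the edge of a cylindrical contrast rod.  Every pixel in an annulus
around the rod edge contributes a (distance-from-center, HU) sample; the
pooled samples form a densely oversampled edge spread function (ESF),
whose derivative is the line spread function (LSF), whose Fourier
magnitude - normalized at zero frequency - is the TTF.

A contrast-to-noise ratio of at least 20 is recommended for a stable
edge; a :class:`LowCNRWarning` is emitted below that.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .curves import FrequencyCurve, TTFResult
from .phantom import ImageStack


class LowCNRWarning(UserWarning):
    """Edge contrast-to-noise ratio below the recommended minimum of 20."""


def check_cnr(image: np.ndarray, rod_roi, bg_roi) -> float:
    """CNR = |mean(rod) - mean(background)| / sd(background).

    ``rod_roi`` and ``bg_roi`` are index expressions (slice pairs or boolean
    masks) selecting disjoint regions.  With zero background noise the CNR
    is infinite for nonzero contrast and undefined (error) otherwise.
    """
    rod = np.asarray(image[rod_roi], dtype=float)
    bg = np.asarray(image[bg_roi], dtype=float)
    contrast = abs(rod.mean() - bg.mean())
    sd = bg.std()
    if sd == 0:
        if contrast == 0:
            raise ValueError("CNR undefined: zero contrast and zero noise")
        return float("inf")
    return float(contrast / sd)


def estimate_rod_center(image: np.ndarray, approx_center_mm: Tuple[float, float],
                        rod_diameter_mm: float,
                        pixel_spacing_mm: Tuple[float, float]) -> Tuple[float, float]:
    """Subpixel rod center: intensity-weighted centroid of the half-contrast mask.

    The local background is taken from an annulus just outside the rod and
    the threshold is set halfway between background and rod plateau.
    """
    dx, dy = pixel_spacing_mm
    ny, nx = image.shape
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    ax, ay = approx_center_mm
    r = np.hypot(x[None, :] - ax, y[:, None] - ay)
    rod_r = rod_diameter_mm / 2.0
    inner = r < 0.5 * rod_r
    ring = (r > 1.4 * rod_r) & (r < 1.9 * rod_r)
    if not inner.any() or not ring.any():
        raise ValueError("rod neighborhood does not fit inside the image")
    bg = float(np.median(image[ring]))
    plateau = float(image[inner].mean())
    delta = plateau - bg
    if delta == 0:
        raise ValueError("no contrast detected at the approximate rod position")
    sign = np.sign(delta)
    v = (image - bg) * sign
    mask = (v > 0.5 * abs(delta)) & (r < 1.2 * rod_r)
    if not mask.any():
        raise ValueError("no pixels above the half-contrast threshold")
    w = v[mask]
    cx = float(np.sum(w * np.broadcast_to(x[None, :], image.shape)[mask]) / w.sum())
    cy = float(np.sum(w * np.broadcast_to(y[:, None], image.shape)[mask]) / w.sum())
    return cx, cy


def radial_esf(image: np.ndarray, center_mm: Tuple[float, float],
               pixel_spacing_mm: Tuple[float, float],
               r_range_mm: Tuple[float, float],
               bin_width_px: float = 0.1,
               max_empty_fraction: float = 0.05
               ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool annulus pixels into a radially binned, oversampled ESF.

    Returns (bin center distances mm, mean HU per bin, sample counts), with
    empty bins dropped.  Raises if more than ``max_empty_fraction`` of the
    bins are empty, which indicates the bin width is too fine.
    """
    dx, dy = pixel_spacing_mm
    r_lo, r_hi = r_range_mm
    if not 0 <= r_lo < r_hi:
        raise ValueError("invalid radial range")
    ny, nx = image.shape
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    r = np.hypot(x[None, :] - center_mm[0], y[:, None] - center_mm[1])
    sel = (r >= r_lo) & (r < r_hi)
    if not sel.any():
        raise ValueError("annulus contains no pixels")
    w = bin_width_px * dx
    idx = np.floor((r[sel] - r_lo) / w).astype(int)
    n_bins = int(np.ceil((r_hi - r_lo) / w))
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    sums = np.bincount(idx, weights=image[sel], minlength=n_bins)[:n_bins]
    empty = counts == 0
    if empty.mean() > max_empty_fraction:
        raise ValueError(
            f"{empty.sum()} of {n_bins} ESF bins are empty; "
            f"increase bin_width_px (currently {bin_width_px})")
    dist = (np.arange(n_bins) + 0.5) * w + r_lo
    keep = ~empty
    return dist[keep], sums[keep] / counts[keep], counts[keep]


def _first_crossing(f: np.ndarray, v: np.ndarray, level: float) -> float:
    """First downward crossing of ``level``, by linear interpolation."""
    below = v < level
    if not below.any() or below[0]:
        raise ValueError(f"curve never crosses {level} downward")
    i = int(np.argmax(below))
    f0, f1, v0, v1 = f[i - 1], f[i], v[i - 1], v[i]
    return float(f0 + (v0 - level) * (f1 - f0) / (v0 - v1))


def _half_max_width(x: np.ndarray, v: np.ndarray) -> float:
    """Width between the outermost half-maximum crossings of ``v``."""
    vmax = v.max()
    above = v >= vmax / 2.0
    i0, i1 = int(np.argmax(above)), len(v) - 1 - int(np.argmax(above[::-1]))
    left = x[i0] if i0 == 0 else float(np.interp(
        vmax / 2, [v[i0 - 1], v[i0]], [x[i0 - 1], x[i0]]))
    right = x[i1] if i1 == len(v) - 1 else float(np.interp(
        vmax / 2, [v[i1 + 1], v[i1]], [x[i1 + 1], x[i1]]))
    return right - left


def esf_to_ttf(dist: np.ndarray, esf: np.ndarray, *,
               window: str = "hann", pad_length: int = 4096,
               window_width_factor: float = 16.0,
               f_max_report: Optional[float] = None,
               cnr_used: float = float("inf")) -> TTFResult:
    """Differentiate an ESF, window the LSF and Fourier-transform to a TTF.

    The ESF is resampled onto a uniform grid (its median bin spacing), the
    LSF is the central finite difference, an optional Hann window centered
    on the LSF peak (width = ``window_width_factor`` x the LSF's FWHM)
    suppresses noisy tails, and TTF = |DFT(LSF)| normalized to one at zero
    frequency.  f50 is the first downward 0.5 crossing, linearly
    interpolated.
    """
    dist = np.asarray(dist, dtype=float)
    esf = np.asarray(esf, dtype=float)
    if len(dist) < 8:
        raise ValueError("ESF too short")
    step = float(np.median(np.diff(dist)))
    grid = np.arange(dist[0], dist[-1] + step / 2, step)
    esf_u = np.interp(grid, dist, esf)
    lsf = np.gradient(esf_u, step)
    if window == "hann":
        peak = int(np.argmax(np.abs(lsf)))
        width = window_width_factor * _half_max_width(grid, np.abs(lsf))
        u = (grid - grid[peak]) / max(width, step)
        w = np.where(np.abs(u) <= 0.5, 0.5 * (1 + np.cos(2 * np.pi * u)), 0.0)
        lsf = lsf * w
    elif window != "none":
        raise ValueError(f"unknown window {window!r}")
    n = max(pad_length, len(lsf))
    spectrum = np.abs(np.fft.rfft(lsf, n=n))
    if spectrum[0] == 0:
        raise ValueError("flat ESF: TTF undefined (zero area LSF)")
    ttf = spectrum / spectrum[0]
    f = np.fft.rfftfreq(n, step)
    curve = FrequencyCurve(f, ttf)
    if f_max_report is not None:
        curve = curve.cropped(f_max_report)
    f50 = _first_crossing(curve.f, curve.values, 0.5)
    return TTFResult(curve=curve, f50=f50, cnr_used=cnr_used)


class TTFEstimator(BaseEstimator):
    """Circular-edge TTF estimator for a contrast-rod image stack.

    Parameters
    ----------
    approx_center_mm : (x, y) tuple
        Approximate rod center; refined to subpixel accuracy during fit.
    rod_diameter_mm : float
        Nominal rod diameter (30 mm for the phantom emulated here).
    annulus_halfwidth_mm : float
        Half-width of the edge annulus around the nominal rod radius.
    bin_width_px : float
        ESF bin width as a fraction of the pixel pitch.
    window : {"hann", "none"}
        LSF windowing before the Fourier transform.
    pad_length : int
        Zero-padded DFT length (controls frequency sampling only).

    Attributes
    ----------
    center_ : refined rod center (mm)
    cnr_ : measured edge CNR
    esf_distance_, esf_ : oversampled edge spread function
    result_ : :class:`~ctiq.curves.TTFResult`
    curve_, f50_ : convenience views of ``result_``
    """

    def __init__(self, approx_center_mm=None, rod_diameter_mm: float = 30.0,
                 annulus_halfwidth_mm: float = 5.0, bin_width_px: float = 0.1,
                 window: str = "hann", window_width_factor: float = 16.0,
                 pad_length: int = 4096, cnr_warn_threshold: float = 20.0):
        self.approx_center_mm = approx_center_mm
        self.rod_diameter_mm = rod_diameter_mm
        self.annulus_halfwidth_mm = annulus_halfwidth_mm
        self.bin_width_px = bin_width_px
        self.window = window
        self.window_width_factor = window_width_factor
        self.pad_length = pad_length
        self.cnr_warn_threshold = cnr_warn_threshold

    def _cnr(self, image: np.ndarray, stack: ImageStack,
             center: Tuple[float, float]) -> float:
        dx, dy = stack.pixel_spacing_mm
        half = max(2, int(round(0.15 * self.rod_diameter_mm / dx)))
        pcx, pcy = stack.center_mm
        # background box placed radially outward from the phantom center
        vx, vy = center[0] - pcx, center[1] - pcy
        norm = np.hypot(vx, vy)
        ux, uy = (vx / norm, vy / norm) if norm > 0 else (1.0, 0.0)
        bgc = (center[0] + 2.0 * self.rod_diameter_mm * ux,
               center[1] + 2.0 * self.rod_diameter_mm * uy)

        def box(c):
            j = int(round(c[0] / dx))
            i = int(round(c[1] / dy))
            return (slice(i - half, i + half + 1), slice(j - half, j + half + 1))

        return check_cnr(image, box(center), box(bgc))

    def fit(self, stack: ImageStack, y=None) -> "TTFEstimator":
        if self.approx_center_mm is None:
            raise ValueError("approx_center_mm is required")
        image = stack.voxels.mean(axis=0)
        self.center_ = estimate_rod_center(
            image, self.approx_center_mm, self.rod_diameter_mm,
            stack.pixel_spacing_mm)
        self.cnr_ = self._cnr(image, stack, self.center_)
        if self.cnr_ < self.cnr_warn_threshold:
            warnings.warn(
                f"edge CNR {self.cnr_:.1f} is below the recommended "
                f"{self.cnr_warn_threshold}; TTF may be noisy", LowCNRWarning,
                stacklevel=2)
        rod_r = self.rod_diameter_mm / 2.0
        dist, esf, counts = radial_esf(
            image, self.center_, stack.pixel_spacing_mm,
            (rod_r - self.annulus_halfwidth_mm, rod_r + self.annulus_halfwidth_mm),
            bin_width_px=self.bin_width_px)
        self.esf_distance_, self.esf_, self.esf_counts_ = dist, esf, counts
        nyquist = 1.0 / (2.0 * stack.pixel_spacing_mm[0])
        self.result_ = esf_to_ttf(
            dist, esf, window=self.window,
            window_width_factor=self.window_width_factor,
            pad_length=self.pad_length, f_max_report=nyquist,
            cnr_used=self.cnr_)
        self.curve_ = self.result_.curve
        self.f50_ = self.result_.f50
        return self
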