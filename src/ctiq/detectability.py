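"""Ideal-observer detectability index and system performance function.

The detectability index d' for a radially symmetric detection task is

    d'^2 = 2 pi * integral  f * TTF(f)^2 / NPS_c(f) * W(f)^2  df ,

where W(f) is the Fourier transform of the task object - for a uniform
disk of diameter d and contrast dHU,

    W(f) = (pi / 2) |dHU| d^2 * J1(pi d f) / (pi d f) ,

with J1 the first-order Bessel function (W(0) = pi |dHU| d^2 / 4 by the
small-argument limit J1(x)/x -> 1/2).  NPS_c is the measured NPS scaled
by a slice-thickness correction factor: image noise variance scales
inversely with slice thickness, so a system with a thicker effective
slice (larger SSP FWHM) has its NPS multiplied by
FWHM_other / FWHM_reference (> 1) to compare it at the reference
thickness.

The system performance function SPF(f) = TTF(f)^2 / NPS_c(f) is the
task-independent frequency-resolved figure of merit; SPF^2 is reported
alongside.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple, Union

import numpy as np
from scipy.integrate import trapezoid
from scipy.special import j1

from .curves import DetectabilityResult, FrequencyCurve, TaskSpec, TTFResult
from .phantom import ImageStack


def correction_factor(fwhm_reference_mm: float, fwhm_other_mm: float) -> float:
    """NPS slice-thickness correction: FWHM_other / FWHM_reference.

    The thicker-slice system's NPS is scaled *up* to the reference
    thickness (noise variance is inversely proportional to slice
    thickness), so the factor exceeds 1 when the other system's effective
    slice is thicker than the reference's.
    """
    if not (fwhm_reference_mm > 0 and fwhm_other_mm > 0):
        raise ValueError("FWHMs must be positive")
    return fwhm_other_mm / fwhm_reference_mm


def correct_nps(nps: FrequencyCurve, factor: float) -> FrequencyCurve:
    """Binwise NPS scaling by the slice-thickness correction factor."""
    if not factor > 0:
        raise ValueError("correction factor must be positive")
    return nps.scaled(factor)


def task_function(f: np.ndarray, task: TaskSpec) -> FrequencyCurve:
    """Disk task function W(f) in HU*mm^2 on the given frequency grid."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    x = np.pi * task.diameter_mm * f
    jinc = np.full_like(x, 0.5)
    nz = x != 0
    jinc[nz] = j1(x[nz]) / x[nz]
    w = (np.pi / 2.0) * abs(task.delta_hu) * task.diameter_mm ** 2 * jinc
    return FrequencyCurve(f, w)


def measure_delta_hu(stack: ImageStack, rod_center_mm: Tuple[float, float],
                     bg_center_mm: Tuple[float, float], roi_px: int = 25,
                     n_slices: int = 10,
                     rod_diameter_mm: Optional[float] = None) -> float:
    """Task contrast: rod-minus-background ROI means, averaged over slices.

    Square ROIs of ``roi_px`` pixels are placed at the given centers; the
    difference of means is averaged over the first ``n_slices`` slices.
    When the rod geometry is known the rod ROI is checked to lie fully
    inside the rod.
    """
    dx, dy = stack.pixel_spacing_mm
    if rod_diameter_mm is not None:
        half_diag = math.hypot(roi_px * dx, roi_px * dy) / 2.0
        if half_diag > rod_diameter_mm / 2.0:
            raise ValueError(
                f"{roi_px}-px ROI (half-diagonal {half_diag:.1f} mm) overlaps "
                f"the edge of a {rod_diameter_mm}-mm rod")
    n = min(n_slices, stack.n_slices)

    def box(center):
        j = int(round(center[0] / dx))
        i = int(round(center[1] / dy))
        h0, h1 = roi_px // 2, roi_px - roi_px // 2
        return (slice(i - h0, i + h1), slice(j - h0, j + h1))

    rod_b, bg_b = box(rod_center_mm), box(bg_center_mm)
    diffs = [stack.voxels[k][rod_b].mean() - stack.voxels[k][bg_b].mean()
             for k in range(n)]
    return float(np.mean(diffs))


def _common_grid(ttf_curve: FrequencyCurve, nps_c: FrequencyCurve,
                 f_max: Optional[float], n_grid: int) -> np.ndarray:
    extent = min(ttf_curve.f_max, nps_c.f_max)
    if f_max is None:
        f_max = extent
    elif f_max > extent + 1e-9:
        raise ValueError(
            f"f_max {f_max:.3g} mm^-1 exceeds the measured curves "
            f"(available up to {extent:.3g} mm^-1)")
    return np.linspace(0.0, f_max, n_grid)


def system_performance(ttf: Union[TTFResult, FrequencyCurve],
                       nps_c: FrequencyCurve,
                       f_max: Optional[float] = None, n_grid: int = 512
                       ) -> Tuple[FrequencyCurve, FrequencyCurve]:
    """SPF(f) = TTF^2 / NPS_c and its square on a common grid (DC omitted)."""
    ttf_curve = ttf.curve if isinstance(ttf, TTFResult) else ttf
    f = _common_grid(ttf_curve, nps_c, f_max, n_grid)[1:]
    t = ttf_curve.interp(f)
    s = nps_c.interp(f)
    ok = s > 0
    if not ok.all():
        import warnings
        warnings.warn("zero NPS bins omitted from the SPF", UserWarning,
                      stacklevel=2)
    spf = FrequencyCurve(f[ok], t[ok] ** 2 / s[ok])
    return spf, FrequencyCurve(spf.f.copy(), spf.values ** 2)


def detectability_index(ttf: Union[TTFResult, FrequencyCurve],
                        nps: FrequencyCurve, task: TaskSpec,
                        f_max: Optional[float] = None, n_grid: int = 512,
                        correction: float = 1.0) -> DetectabilityResult:
    """Ideal-observer d' by trapezoidal quadrature on a uniform grid.

    ``ttf`` and the corrected NPS are linearly interpolated onto
    ``n_grid`` points spanning [0, f_max] (default: the common extent of
    both curves); the integrand vanishes at f = 0 so the NPS DC bin never
    enters.  The NPS must be strictly positive at every interior grid
    point.
    """
    ttf_curve = ttf.curve if isinstance(ttf, TTFResult) else ttf
    nps_c = correct_nps(nps, correction)
    f = _common_grid(ttf_curve, nps_c, f_max, n_grid)
    t = ttf_curve.interp(f)
    s = nps_c.interp(f)
    if np.any(s[1:] <= 0):
        raise ValueError("corrected NPS must be positive on the integration grid")
    w = task_function(f, task).values
    integrand = np.zeros_like(f)
    integrand[1:] = f[1:] * t[1:] ** 2 / s[1:] * w[1:] ** 2
    d2 = 2.0 * np.pi * trapezoid(integrand, f)
    spf = FrequencyCurve(f[1:], t[1:] ** 2 / s[1:])
    spf2 = FrequencyCurve(f[1:], spf.values ** 2)
    return DetectabilityResult(
        d_prime=float(np.sqrt(d2)), correction_factor=correction,
        nps_corrected=nps_c, spf=spf, spf2=spf2, f_max=float(f[-1]), task=task)
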