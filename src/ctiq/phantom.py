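"""Synthetic CT phantom image stacks with known ground truth.

Emulates a QA acquisition: a 300-mm water bath (the adult-abdomen
surrogate) containing iodine-equivalent rods, imaged on a 512x512 grid
with a 300-mm display field of view and 1.0-mm nominal slices.  The
generator lets every estimator in this package be validated by parameter
recovery: the in-plane blur, the noise power spectrum and the slice
sensitivity profile are all analytic models whose parameters are known.

Synthesis conventions
---------------------
* Voxel centers sit at ``(i + 0.5) * spacing`` with the origin at the
  volume corner; all physical positions are in mm.
* Blurred sections are synthesized from the disks' analytic Fourier
  transforms multiplied by the MTF, so voxel values are exact point
  samples of the blurred object function band-limited to the grid and
  the stack's end-to-end in-plane transfer equals the configured MTF.
  With no blur configured the geometry is rasterized with 4x
  supersampling and block-averaged, so edge voxels carry area-coverage
  fractions.
* Noise is stationary, Gaussian and independent across slices: a white
  field is spectrally shaped by sqrt(NPS)/sqrt(dx*dy) in the frequency
  domain.  Real CT noise is non-stationary across the FOV and correlated
  along z; both simplifications are deliberate and documented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import j1, ndtr

HU_AIR = -1000.0
_SQRT_2LN2 = math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# Parametric truth models (frozen -> hashable -> cache keys)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IdentityMTF:
    """No in-plane blur: MTF(f) = 1 for all f."""

    def __call__(self, f: np.ndarray) -> np.ndarray:
        return np.ones_like(np.asarray(f, dtype=float))

    @property
    def is_identity(self) -> bool:
        return True


@dataclass(frozen=True)
class GaussianMTF:
    """Gaussian modulation transfer function parameterized by its 50% point.

    MTF(f) = exp(-f^2 / (2 sigma_f^2)) with sigma_f = f50 / sqrt(2 ln 2),
    so MTF(f50) = 0.5 and MTF(0) = 1.
    """

    f50_mm: float

    def __post_init__(self) -> None:
        if not self.f50_mm > 0:
            raise ValueError("f50 must be positive")

    @property
    def sigma_f(self) -> float:
        return self.f50_mm / _SQRT_2LN2

    @property
    def psf_sigma_mm(self) -> float:
        """Std dev of the equivalent spatial-domain Gaussian PSF."""
        return 1.0 / (2.0 * math.pi * self.sigma_f)

    def __call__(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        return np.exp(-0.5 * (f / self.sigma_f) ** 2)

    @property
    def is_identity(self) -> bool:
        return False


@dataclass(frozen=True)
class FlatNPS:
    """White noise: NPS(f) = n0 (HU^2*mm^2) at every frequency."""

    n0: float

    def __post_init__(self) -> None:
        if self.n0 < 0:
            raise ValueError("NPS level must be non-negative")

    def __call__(self, f: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(f, dtype=float), self.n0)


@dataclass(frozen=True)
class RampLowpassNPS:
    """Ramp x low-pass radial NPS typical of filtered backprojection.

    NPS(f) = peak * (f/f_peak) * exp((1 - (f/f_peak)^2) / 2), which rises
    linearly from zero, peaks at ``f_peak`` with value ``peak`` and rolls
    off like a Gaussian beyond.
    """

    peak: float
    f_peak: float

    def __post_init__(self) -> None:
        if self.peak < 0:
            raise ValueError("NPS level must be non-negative")
        if not self.f_peak > 0:
            raise ValueError("f_peak must be positive")

    def __call__(self, f: np.ndarray) -> np.ndarray:
        u = np.asarray(f, dtype=float) / self.f_peak
        return self.peak * u * np.exp(0.5 * (1.0 - u * u))


@dataclass(frozen=True)
class GaussianSSP:
    """Gaussian slice sensitivity profile with the given FWHM (mm)."""

    fwhm_mm: float

    def __post_init__(self) -> None:
        if not self.fwhm_mm > 0:
            raise ValueError("SSP FWHM must be positive")

    @property
    def sigma(self) -> float:
        return self.fwhm_mm / (2.0 * _SQRT_2LN2)

    def profile(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return np.exp(-0.5 * (z / self.sigma) ** 2) / (self.sigma * math.sqrt(2 * math.pi))

    def edge_response(self, u: np.ndarray) -> np.ndarray:
        """Integral of the SSP from -inf to u (the z-edge spread function)."""
        return ndtr(np.asarray(u, dtype=float) / self.sigma)


@dataclass(frozen=True)
class RectangularSSP:
    """Rectangular SSP of width = FWHM (an idealized non-helical slice)."""

    fwhm_mm: float

    def __post_init__(self) -> None:
        if not self.fwhm_mm > 0:
            raise ValueError("SSP FWHM must be positive")

    def profile(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return np.where(np.abs(z) <= self.fwhm_mm / 2, 1.0 / self.fwhm_mm, 0.0)

    def edge_response(self, u: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(u, dtype=float) / self.fwhm_mm + 0.5, 0.0, 1.0)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth models attached to a generated stack."""

    mtf_model: object = field(default_factory=IdentityMTF)
    nps_model: object = field(default_factory=lambda: FlatNPS(0.0))
    ssp_model: Optional[object] = None
    seed: int = 0


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and contrasts of the physical phantom being emulated.

    ``rod_offsets_mm`` are in-plane (x, y) displacements of each rod center
    from the phantom center; ``rod_contrasts_hu`` are the corresponding
    CT-number contrasts against the water background.
    """

    background_diameter_mm: float = 300.0
    rod_diameter_mm: float = 30.0
    rod_offsets_mm: Tuple[Tuple[float, float], ...] = ((50.0, 0.0), (-50.0, 0.0))
    rod_contrasts_hu: Tuple[float, ...] = (300.0, 50.0)
    background_hu: float = 0.0
    air_hu: float = HU_AIR
    tilt_deg: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.background_diameter_mm > 0 or not self.rod_diameter_mm > 0:
            raise ValueError("diameters must be positive")
        if len(self.rod_offsets_mm) != len(self.rod_contrasts_hu):
            raise ValueError("one contrast per rod offset required")
        bg_r = self.background_diameter_mm / 2.0
        rod_r = self.rod_diameter_mm / 2.0
        for (ox, oy) in self.rod_offsets_mm:
            if math.hypot(ox, oy) + rod_r > bg_r + 1e-9:
                raise ValueError(
                    f"rod at offset ({ox}, {oy}) mm extends outside the "
                    f"{self.background_diameter_mm}-mm background disk"
                )
        if self.tilt_deg is not None and not (0.0 < self.tilt_deg < 15.0):
            raise ValueError("tilt_deg must lie in (0, 15) degrees")


@dataclass
class ImageStack:
    """A 3D HU volume (z, y, x) with physical spacing metadata."""

    voxels: np.ndarray
    pixel_spacing_mm: Tuple[float, float]
    slice_spacing_mm: float
    nominal_slice_thickness_mm: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (z, y, x) array")
        dx, dy = self.pixel_spacing_mm
        if not (dx > 0 and dy > 0 and self.slice_spacing_mm > 0):
            raise ValueError("spacings must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_yx(self) -> Tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]

    @property
    def center_mm(self) -> Tuple[float, float]:
        """In-plane (x, y) position of the volume center in mm."""
        ny, nx = self.shape_yx
        dx, dy = self.pixel_spacing_mm
        return nx * dx / 2.0, ny * dy / 2.0

    def pixel_centers_mm(self) -> Tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape_yx
        dx, dy = self.pixel_spacing_mm
        x = (np.arange(nx) + 0.5) * dx
        y = (np.arange(ny) + 0.5) * dy
        return x, y


# ---------------------------------------------------------------------------
# Rasterization and blur
# ---------------------------------------------------------------------------

def _block_mean(a: np.ndarray, s: int) -> np.ndarray:
    ny, nx = a.shape
    return a.reshape(ny // s, s, nx // s, s).mean(axis=(1, 3))


@lru_cache(maxsize=64)
def _disk_coverage(nx: int, ny: int, dx: float, dy: float,
                   cx: float, cy: float, radius: float, supersample: int) -> np.ndarray:
    """Fractional pixel coverage of a disk, from supersampled rasterization."""
    s = supersample
    xs = (np.arange(nx * s) + 0.5) * (dx / s)
    ys = (np.arange(ny * s) + 0.5) * (dy / s)
    mask = ((xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2) <= radius ** 2
    cov = _block_mean(mask.astype(float), s)
    cov.setflags(write=False)
    return cov


def _aperture(fx: np.ndarray, fy: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Transfer of the full-pixel sampling aperture (separable sinc)."""
    return np.sinc(fx[None, :] * dx) * np.sinc(fy[:, None] * dy)


def _blur_filter(mtf_model, fx: np.ndarray, fy: np.ndarray,
                 dx: float, dy: float, eps: float = 1e-3) -> np.ndarray:
    """MTF filter with the pixel aperture divided out (regularized)."""
    fr = np.hypot(fx[None, :], fy[:, None])
    a = _aperture(fx, fy, dx, dy)
    return mtf_model(fr) * a / (a * a + eps * eps)


@lru_cache(maxsize=32)
def _noiseless_axial_slice(spec: PhantomSpec, mtf_model, mode: str,
                           nx: int, ny: int, dx: float, dy: float,
                           supersample: int) -> np.ndarray:
    """Noiseless HU slice of the disk (+ rods) phantom.

    With no blur the geometry is rasterized at ``supersample``x and
    block-averaged, so edge voxels carry area-coverage fractions.  With a
    blur model the slice is synthesized directly from the disks' analytic
    Fourier transforms (pi R^2 jinc) multiplied by the MTF and evaluated
    at the voxel centers: the voxels are exact point samples of the
    blurred object function band-limited to the sampling grid, and the
    stack's end-to-end in-plane transfer equals the configured MTF.
    """
    s = supersample
    cx, cy = nx * dx / 2.0, ny * dy / 2.0
    if mtf_model.is_identity:
        img = spec.air_hu + (spec.background_hu - spec.air_hu) * np.asarray(
            _disk_coverage(nx, ny, dx, dy, cx, cy, spec.background_diameter_mm / 2, s))
        if mode == "rod_section":
            for (ox, oy), dhu in zip(spec.rod_offsets_mm, spec.rod_contrasts_hu):
                img = img + dhu * np.asarray(_disk_coverage(
                    nx, ny, dx, dy, cx + ox, cy + oy, spec.rod_diameter_mm / 2, s))
        img.setflags(write=False)
        return img
    fx = np.fft.rfftfreq(nx, dx)
    fy = np.fft.fftfreq(ny, dy)
    fr = np.hypot(fx[None, :], fy[:, None])

    def disk(radius, cxy, amplitude):
        x = 2.0 * np.pi * radius * fr
        jinc = np.full_like(x, 0.5)
        nz = x != 0
        jinc[nz] = j1(x[nz]) / x[nz]
        phase = np.exp(-2j * np.pi * (fx[None, :] * cxy[0] + fy[:, None] * cxy[1]))
        return amplitude * 2.0 * np.pi * radius ** 2 * jinc * phase

    spectrum = disk(spec.background_diameter_mm / 2, (cx, cy),
                    spec.background_hu - spec.air_hu)
    if mode == "rod_section":
        for (ox, oy), dhu in zip(spec.rod_offsets_mm, spec.rod_contrasts_hu):
            spectrum = spectrum + disk(spec.rod_diameter_mm / 2,
                                       (cx + ox, cy + oy), dhu)
    spectrum *= mtf_model(fr)
    # evaluate at voxel centers (n + 0.5) * spacing
    spectrum *= np.exp(2j * np.pi * (fx[None, :] * dx / 2 + fy[:, None] * dy / 2))
    img = spec.air_hu + np.fft.irfft2(spectrum, s=(ny, nx)) / (dx * dy)
    img.setflags(write=False)
    return img


# ---------------------------------------------------------------------------
# Noise synthesis
# ---------------------------------------------------------------------------

def generate_correlated_noise(shape: Tuple[int, int], nps_model,
                              pixel_spacing_mm: Tuple[float, float],
                              rng) -> np.ndarray:
    """One zero-mean noise field whose ensemble NPS equals ``nps_model``.

    A white standard-normal field is filtered by sqrt(NPS/(dx*dy)) in the
    frequency domain, so the 2D periodogram estimate
    (dx*dy/N) |DFT|^2 has expectation ``nps_model`` at every frequency.

    ``rng`` may be a ``numpy.random.Generator`` or an integer seed.
    """
    dx, dy = pixel_spacing_mm
    if not (dx > 0 and dy > 0):
        raise ValueError("pixel spacing must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ny, nx = shape
    fx = np.fft.rfftfreq(nx, dx)
    fy = np.fft.fftfreq(ny, dy)
    s = nps_model(np.hypot(fx[None, :], fy[:, None]))
    if np.any(s < 0):
        raise ValueError("NPS model is negative at some frequency")
    if np.all(s == 0):
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    filt = np.sqrt(s / (dx * dy))
    return np.fft.irfft2(np.fft.rfft2(white) * filt, s=shape)


# ---------------------------------------------------------------------------
# Stack generators
# ---------------------------------------------------------------------------

def generate_axial_stack(spec: PhantomSpec, truth: SyntheticTruth,
                         n_slices: int = 1, mode: str = "rod_section",
                         grid: Tuple[int, int] = (512, 512),
                         fov_mm: float = 300.0,
                         slice_spacing_mm: float = 1.0,
                         nominal_slice_thickness_mm: float = 1.0,
                         supersample: int = 4) -> ImageStack:
    """Generate an axial stack of the water or two-rod phantom section.

    The noiseless geometry is shared by all slices; correlated noise from
    ``truth.nps_model`` is drawn independently per slice with
    ``truth.seed`` fixing the stream (same seed => bit-identical stack).
    """
    if mode not in ("rod_section", "water_section"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    ny, nx = grid
    dx = dy = fov_mm / nx
    noiseless = np.asarray(_noiseless_axial_slice(
        spec, truth.mtf_model, mode, nx, ny, dx, dy, supersample))
    rng = np.random.default_rng(truth.seed)
    voxels = np.empty((n_slices, ny, nx))
    for k in range(n_slices):
        voxels[k] = noiseless + generate_correlated_noise(
            (ny, nx), truth.nps_model, (dx, dy), rng)
    return ImageStack(voxels, (dx, dy), slice_spacing_mm,
                      nominal_slice_thickness_mm,
                      meta={"spec": spec, "truth": truth, "mode": mode})


def generate_tilted_rod_stack(spec: PhantomSpec, truth: SyntheticTruth,
                              slice_spacing_mm: float = 0.2,
                              n_slices: Optional[int] = None,
                              grid: Tuple[int, int] = (512, 512),
                              fov_mm: float = 300.0,
                              supersample: int = 4) -> ImageStack:
    """Generate the tilted-rod volume used for SSP measurement.

    The rod's top surface is a plane tilted by ``spec.tilt_deg`` about the
    x axis, so in a sagittal (z, y) view the edge advances in z by
    tan(tilt) per mm of lateral (y) offset.  Each slice samples the tilted
    slab through the z edge response of ``truth.ssp_model`` and is blurred
    in-plane by ``truth.mtf_model``, then noise is added.
    """
    if spec.tilt_deg is None:
        raise ValueError("PhantomSpec.tilt_deg must be set for the SSP phantom")
    if truth.ssp_model is None:
        raise ValueError("SyntheticTruth.ssp_model must be set for the SSP phantom")
    fwhm = truth.ssp_model.fwhm_mm
    if slice_spacing_mm > fwhm / 2.0 + 1e-12:
        raise ValueError(
            f"slice spacing {slice_spacing_mm} mm undersamples an SSP with "
            f"FWHM {fwhm} mm (need <= FWHM/2 per the sampling theorem)")
    ny, nx = grid
    dx = dy = fov_mm / nx
    cx, cy = nx * dx / 2.0, ny * dy / 2.0
    (ox, oy), dhu = spec.rod_offsets_mm[0], spec.rod_contrasts_hu[0]
    slope = math.tan(math.radians(spec.tilt_deg))
    span = slope * spec.rod_diameter_mm + 8.0 * fwhm
    if n_slices is None:
        n_slices = int(math.ceil(span / slice_spacing_mm))
    z = (np.arange(n_slices) + 0.5) * slice_spacing_mm
    z_mid = n_slices * slice_spacing_mm / 2.0

    bg_cov = np.asarray(_disk_coverage(
        nx, ny, dx, dy, cx, cy, spec.background_diameter_mm / 2, supersample))
    rod_cov = np.asarray(_disk_coverage(
        nx, ny, dx, dy, cx + ox, cy + oy, spec.rod_diameter_mm / 2, supersample))
    base = spec.air_hu + (spec.background_hu - spec.air_hu) * bg_cov

    _, y = (np.arange(nx) + 0.5) * dx, (np.arange(ny) + 0.5) * dy
    z_edge = z_mid + slope * (y - (cy + oy))          # per-row edge height

    blur = not truth.mtf_model.is_identity
    if blur:
        fx_g = np.fft.rfftfreq(nx, dx)
        fy_g = np.fft.fftfreq(ny, dy)
        h = _blur_filter(truth.mtf_model, fx_g, fy_g, dx, dy)

    rng = np.random.default_rng(truth.seed)
    voxels = np.empty((n_slices, ny, nx))
    for k, zk in enumerate(z):
        frac = truth.ssp_model.edge_response(z_edge - zk)  # rod below the plane
        slab = rod_cov * (dhu * frac[:, None])
        if blur:
            slab = np.fft.irfft2(np.fft.rfft2(slab) * h, s=slab.shape)
        voxels[k] = base + slab + generate_correlated_noise(
            (ny, nx), truth.nps_model, (dx, dy), rng)
    return ImageStack(voxels, (dx, dy), slice_spacing_mm,
                      meta={"spec": spec, "truth": truth, "mode": "tilted_rod",
                            "rod_center_mm": (cx + ox, cy + oy),
                            "z_edge_mid_mm": z_mid, "tilt_deg": spec.tilt_deg})


def average_repeats(stacks: Sequence[ImageStack]) -> ImageStack:
    """Voxelwise mean of repeated acquisitions of the same geometry."""
    stacks = list(stacks)
    if not stacks:
        raise ValueError("no stacks to average")
    first = stacks[0]
    for s in stacks[1:]:
        if (s.voxels.shape != first.voxels.shape
                or s.pixel_spacing_mm != first.pixel_spacing_mm
                or s.slice_spacing_mm != first.slice_spacing_mm):
            raise ValueError("stacks to average must share geometry")
    mean = np.mean([s.voxels for s in stacks], axis=0)
    meta = dict(first.meta)
    meta["n_averaged"] = len(stacks)
    return ImageStack(mean, first.pixel_spacing_mm, first.slice_spacing_mm,
                      first.nominal_slice_thickness_mm, meta=meta)
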