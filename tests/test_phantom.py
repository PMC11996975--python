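"""Generator validation: geometry, noise statistics and determinism."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import i0e

from ctiq import (FlatNPS, GaussianMTF, GaussianSSP, IdentityMTF, ImageStack,
                  PhantomSpec, RampLowpassNPS, RectangularSSP, SyntheticTruth,
                  average_repeats, generate_axial_stack,
                  generate_correlated_noise, generate_tilted_rod_stack)

from conftest import PIXEL


def disk_blur_oracle(r, radius, sigma, contrast):
    """Analytic disk (x) isotropic-Gaussian convolution, radial profile.

    Independent of the generator's FFT path: the Rice/Marcum-Q integral
    A(r) = int_0^R r'/s^2 exp(-(r-r')^2/(2 s^2)) I0(r r'/s^2) dr'
    evaluated by adaptive quadrature with the exponentially scaled I0.
    """
    val, _ = quad(lambda rp: rp / sigma ** 2
                  * np.exp(-(r - rp) ** 2 / (2 * sigma ** 2))
                  * i0e(r * rp / sigma ** 2),
                  max(0.0, r - 8 * sigma), radius, limit=200)
    return contrast * val


class TestPhantomSpecValidation:
    def test_rod_outside_background_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            PhantomSpec(rod_offsets_mm=((140.0, 0.0),), rod_contrasts_hu=(100.0,))

    def test_tilt_range_enforced(self):
        with pytest.raises(ValueError, match="tilt"):
            PhantomSpec(tilt_deg=20.0)

    def test_contrast_count_must_match_offsets(self):
        with pytest.raises(ValueError):
            PhantomSpec(rod_offsets_mm=((0.0, 0.0),), rod_contrasts_hu=(1.0, 2.0))


class TestAxialStack:
    def test_zero_noise_water_section_is_uniform_inside(self, two_rod_spec):
        stack = generate_axial_stack(two_rod_spec, SyntheticTruth(seed=0),
                                     mode="water_section")
        cx, cy = stack.center_mm
        x, y = stack.pixel_centers_mm()
        r = np.hypot(x[None, :] - cx, y[:, None] - cy)
        inside = stack.voxels[0][r < 140]
        assert np.all(inside == 0.0)

    def test_sharp_rod_partial_volume_by_area_coverage(self, sharp_rod_stack):
        img = sharp_rod_stack.voxels[0]
        cx, cy = sharp_rod_stack.center_mm
        x, y = sharp_rod_stack.pixel_centers_mm()
        r = np.hypot(x[None, :] - (cx + 50), y[:, None] - cy)
        assert np.allclose(img[r < 13], 300.0)
        ring = img[(r > 17) & (r < 25)]
        assert np.allclose(ring, 0.0)
        edge = img[(r > 14.7) & (r < 15.3)]
        fractional = edge[(edge > 0.0) & (edge < 300.0)]
        assert len(fractional) > 20   # many edge pixels carry area fractions
        assert np.all((edge >= 0.0) & (edge <= 300.0))

    def test_blurred_edge_matches_analytic_convolution(self, noiseless_rod_stack):
        """Radial edge profile agrees with the spatial-domain oracle < 0.5 HU.

        The oracle is the disk (x) Gaussian Rice integral; the generated
        pixels are pooled into 0.1-mm radial bins across the rod edge.
        Individual pixels may differ by up to ~0.6 HU (the out-of-band
        tail a sampled grid cannot carry); the binned profile averages
        that angular ripple out.
        """
        stack = noiseless_rod_stack
        img = stack.voxels[0]
        cx, cy = stack.center_mm
        sigma = GaussianMTF(0.41).psf_sigma_mm
        x, y = stack.pixel_centers_mm()
        r = np.hypot(x[None, :] - (cx + 50), y[:, None] - cy)
        sel = (r > 11.0) & (r < 19.0)
        idx = np.floor((r[sel] - 11.0) / 0.1).astype(int)
        sums = np.bincount(idx, weights=img[sel])
        radii = np.bincount(idx, weights=r[sel])
        counts = np.bincount(idx)
        keep = counts > 0
        profile = sums[keep] / counts[keep]
        mean_r = radii[keep] / counts[keep]
        for rr, v in zip(mean_r, profile):
            assert abs(v - disk_blur_oracle(rr, 15.0, sigma, 300.0)) < 0.5

    def test_mean_hu_conserved_under_blur(self, two_rod_spec, sharp_rod_stack):
        """Blur is normalized: large-ROI mean is invariant under the MTF."""
        blurred = generate_axial_stack(
            two_rod_spec, SyntheticTruth(mtf_model=GaussianMTF(0.41), seed=0))
        cx, cy = blurred.center_mm
        x, y = blurred.pixel_centers_mm()
        r = np.hypot(x[None, :] - (cx + 50), y[:, None] - cy)
        roi = r < 25
        # residual ~0.01 HU is the representation difference between the
        # area-coverage (sharp) and band-limited (blurred) syntheses, not
        # energy loss: MTF(0) = 1 preserves the disk's integral exactly
        assert blurred.voxels[0][roi].mean() == pytest.approx(
            sharp_rod_stack.voxels[0][roi].mean(), abs=0.05)

    def test_same_seed_bit_identical(self, two_rod_spec):
        truth = SyntheticTruth(nps_model=FlatNPS(100.0), seed=42)
        a = generate_axial_stack(two_rod_spec, truth, n_slices=2)
        b = generate_axial_stack(two_rod_spec, truth, n_slices=2)
        assert np.array_equal(a.voxels, b.voxels)

    def test_histogram_of_sharp_rod_only_plateau_and_edges(self, sharp_rod_stack):
        vals = np.unique(sharp_rod_stack.voxels[0])
        assert vals.min() >= -1000.0 and vals.max() <= 300.0 + 1e-9


class TestCorrelatedNoise:
    def test_flat_nps_variance_matches_parseval(self, rng):
        """Sample variance over 100 fields ~ N0/(dx dy) within 3%."""
        n0, d = 100.0, PIXEL
        fields = [generate_correlated_noise((512, 512), FlatNPS(n0), (d, d), rng)
                  for _ in range(100)]
        var = np.mean([f.var() for f in fields])
        assert var == pytest.approx(n0 / d ** 2, rel=0.03)

    def test_zero_level_gives_zeros(self, rng):
        f = generate_correlated_noise((64, 64), FlatNPS(0.0), (1.0, 1.0), rng)
        assert np.all(f == 0.0)

    def test_seed_determinism(self):
        a = generate_correlated_noise((64, 64), FlatNPS(5.0), (1.0, 1.0), 7)
        b = generate_correlated_noise((64, 64), FlatNPS(5.0), (1.0, 1.0), 7)
        assert np.array_equal(a, b)

    def test_nonpositive_spacing_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_correlated_noise((8, 8), FlatNPS(1.0), (0.0, 1.0), rng)

    def test_mean_is_near_zero(self, rng):
        f = generate_correlated_noise((256, 256), RampLowpassNPS(500.0, 0.2),
                                      (PIXEL, PIXEL), rng)
        assert abs(f.mean()) < 1.0


class TestTiltedRodStack:
    def test_zprofile_matches_gaussian_edge_response(self, tilted_spec):
        """Center-column z profile equals the analytic Gaussian CDF < 0.5 HU."""
        ssp = GaussianSSP(1.3)
        truth = SyntheticTruth(mtf_model=GaussianMTF(0.41), ssp_model=ssp, seed=0)
        stack = generate_tilted_rod_stack(tilted_spec, truth)
        cx, cy = stack.meta["rod_center_mm"]
        j = int(cx / stack.pixel_spacing_mm[0])
        i = int(cy / stack.pixel_spacing_mm[1])
        z = (np.arange(stack.n_slices) + 0.5) * stack.slice_spacing_mm
        profile = stack.voxels[:, i, j]
        # the edge height at this row's y position (tilt advances it in z)
        y_row = (i + 0.5) * stack.pixel_spacing_mm[1]
        z_edge = stack.meta["z_edge_mid_mm"] + np.tan(np.radians(5.0)) * (y_row - cy)
        expected = 300.0 * ssp.edge_response(z_edge - z)
        assert np.abs(profile - expected).max() < 0.5

    def test_fwhm_to_zero_limit_is_a_step(self, tilted_spec):
        truth = SyntheticTruth(mtf_model=IdentityMTF(),
                               ssp_model=RectangularSSP(0.02), seed=0)
        stack = generate_tilted_rod_stack(tilted_spec, truth,
                                          slice_spacing_mm=0.01, n_slices=40)
        cx, cy = stack.meta["rod_center_mm"]
        j = int(cx / stack.pixel_spacing_mm[0])
        i = int(cy / stack.pixel_spacing_mm[1])
        p = stack.voxels[:, i, j]
        interior = (p > 1.0) & (p < 299.0)
        assert interior.sum() <= 2   # at most one transition sample per flank

    def test_undersampled_slice_spacing_rejected(self, tilted_spec):
        truth = SyntheticTruth(ssp_model=GaussianSSP(1.0), seed=0)
        with pytest.raises(ValueError, match="undersamples"):
            generate_tilted_rod_stack(tilted_spec, truth, slice_spacing_mm=0.6)

    def test_tilt_required(self, two_rod_spec):
        truth = SyntheticTruth(ssp_model=GaussianSSP(1.0), seed=0)
        with pytest.raises(ValueError, match="tilt"):
            generate_tilted_rod_stack(two_rod_spec, truth)


class TestAverageRepeats:
    def test_identity_on_identical_noiseless_stacks(self, sharp_rod_stack):
        out = average_repeats([sharp_rod_stack] * 3)
        assert np.array_equal(out.voxels, sharp_rod_stack.voxels)

    def test_variance_scales_inversely_with_repeats(self, two_rod_spec):
        n0, n_rep = 200.0, 8
        stacks = [generate_axial_stack(
            two_rod_spec, SyntheticTruth(nps_model=FlatNPS(n0), seed=k),
            mode="water_section") for k in range(n_rep)]
        avg = average_repeats(stacks)
        cx, cy = avg.center_mm
        x, y = avg.pixel_centers_mm()
        r = np.hypot(x[None, :] - cx, y[:, None] - cy)
        var = avg.voxels[0][r < 100].var()
        assert var == pytest.approx(n0 / (n_rep * PIXEL ** 2), rel=0.10)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_repeats([])

    def test_mismatched_geometry_rejected(self, sharp_rod_stack):
        other = ImageStack(np.zeros((1, 64, 64)), (1.0, 1.0), 1.0)
        with pytest.raises(ValueError, match="geometry"):
            average_repeats([sharp_rod_stack, other])
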