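"""Forward model: PSF overlaps, computation basis, probability tensors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from mospade.fisher import crb_from_factor, fisher_factor, floor_coefficients
from mospade.optics import (
    ConfigurationError,
    HermiteGaussianBasis,
    ImagingModeSet,
    PSFModel,
    detection_probabilities,
    direct_imaging_modes,
    probability_tensor,
    psf_overlap,
)
from mospade.sources import SourceBasis, SourceModel, make_discretized_extended, make_point_comb


class TestPsfOverlap:
    def test_self_overlap_is_unity(self, psf1):
        assert psf_overlap(0.0, 0.0, psf1) == pytest.approx(1.0)

    def test_closed_form_matches_dense_quadrature(self, psf1):
        val, _ = integrate.quad(
            lambda x: psf1.field(x, 0.0) * psf1.field(x, 2.0), -30, 30
        )
        assert psf_overlap(0.0, 2.0, psf1) == pytest.approx(np.exp(-0.5), abs=1e-10)
        assert psf_overlap(0.0, 2.0, psf1) == pytest.approx(val, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    def test_symmetry(self, a, b):
        psf = PSFModel(1, 1.0)
        assert psf_overlap(a, b, psf) == psf_overlap(b, a, psf)

    def test_2d_overlap_factorizes(self):
        psf2 = PSFModel(2, 1.3)
        r1, r2 = np.array([0.2, -0.4]), np.array([1.0, 0.7])
        expect = np.exp(-np.sum((r1 - r2) ** 2) / (8 * 1.3**2))
        assert psf_overlap(r1, r2, psf2) == pytest.approx(expect, rel=1e-12)


class TestComputationBasis:
    def test_gram_matrix_is_identity(self, basis40):
        x = np.linspace(-30, 30, 6001)
        V = basis40.values_1d(x)
        gram = V @ V.T * (x[1] - x[0])
        assert np.max(np.abs(gram - np.eye(40))) < 1e-10

    def test_point_overlaps_match_quadrature(self, psf1, basis40):
        x = np.linspace(-30, 30, 6001)
        num = basis40.values_1d(x) @ psf1.field(x, 1.3) * (x[1] - x[0])
        np.testing.assert_allclose(
            basis40.point_overlaps(np.array([1.3]))[:, 0], num, atol=1e-10
        )

    def test_captured_energy_complete_near_origin(self, basis40):
        assert basis40.captured_energy(np.array([0.0, 2.0, 3.0])).min() > 1 - 1e-10

    def test_2d_overlaps_are_axis_products(self):
        b2 = HermiteGaussianBasis(1.0, 6, 2)
        b1 = HermiteGaussianBasis(1.0, 6, 1)
        R = np.array([[0.7, -1.1]])
        g2 = b2.point_overlaps(R)[:, 0].reshape(6, 6)
        gx = b1.point_overlaps(np.array([0.7]))[:, 0]
        gy = b1.point_overlaps(np.array([-1.1]))[:, 0]
        np.testing.assert_allclose(g2, np.outer(gx, gy), rtol=1e-12)


class TestProbabilityTensor:
    def test_matched_filter_single_point(self, basis40):
        modes = ImagingModeSet(basis40, np.eye(40)[:, :1])
        pt = probability_tensor(
            SourceBasis("delta-comb", positions=np.array([0.0])), modes
        )
        assert pt.p[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_completeness_recovers_captured_weight(self, basis40):
        src = make_discretized_extended("uniform", 0.8, 4.0)
        modes = ImagingModeSet(basis40, np.eye(40))
        pt = probability_tensor(src.basis, modes)
        np.testing.assert_allclose(pt.p.sum(axis=0), pt.captured, atol=1e-6)
        # interior bins capture their full 0.8-sigma measure
        assert pt.captured[4] == pytest.approx(0.8, abs=1e-6)

    def test_rect_bin_matches_double_quadrature_oracle(self, psf1, basis40):
        """p_jk for the fundamental mode vs brute-force nested quadrature."""
        modes = ImagingModeSet(basis40, np.eye(40)[:, :1])
        src = make_discretized_extended("uniform", 0.8, 2.0)
        pt = probability_tensor(src.basis, modes)
        k = 2  # bin [-0.4, 0.4)
        lo, hi = src.basis.edges[k], src.basis.edges[k + 1]
        oracle, _ = integrate.quad(
            lambda R: np.exp(-(R**2) / (4 * psf1.sigma**2)), lo, hi,
            epsabs=1e-13,
        )
        assert pt.p[0, k] == pytest.approx(oracle, abs=1e-8)

    def test_quadrature_self_consistency(self, basis40):
        src = make_discretized_extended("bump", 0.8, 4.0)
        modes = ImagingModeSet(basis40, np.eye(40)[:, :10])
        p1 = probability_tensor(src.basis, modes).p
        p2 = probability_tensor(src.basis, modes, nodes_per_bin=48).p
        assert np.max(np.abs(p1 - p2)) < 1e-6

    def test_small_basis_rejected_for_wide_scene(self):
        basis = HermiteGaussianBasis(1.0, 12, 1)
        modes = ImagingModeSet(basis, np.eye(12))
        src = make_discretized_extended("uniform", 0.8, 12.0)
        with pytest.raises(ConfigurationError):
            probability_tensor(src.basis, modes)


class TestDetectionProbabilities:
    def test_linearity_and_zero_source(self, basis40):
        src = make_point_comb(3, 0.5)
        modes = ImagingModeSet(basis40, np.eye(40)[:, :4])
        pt = probability_tensor(src.basis, modes)
        zero = SourceModel(src.basis, np.zeros(3))
        np.testing.assert_array_equal(detection_probabilities(zero, pt), 0.0)
        for k in range(3):
            ek = np.zeros(3)
            ek[k] = 1.0
            np.testing.assert_allclose(
                detection_probabilities(SourceModel(src.basis, ek), pt), pt.p[:, k]
            )

    def test_incomplete_modes_capture_at_most_total_flux(self, basis40):
        src = make_point_comb(5, 0.3)
        modes = ImagingModeSet(basis40, np.eye(40)[:, :5])
        pt = probability_tensor(src.basis, modes)
        P = detection_probabilities(src, pt)
        assert np.all(P >= 0)
        assert P.sum() <= src.c.sum() + 1e-12


class TestDirectImagingModes:
    def test_pixel_modes_are_orthonormal(self, basis40):
        dm = direct_imaging_modes(0.5, 4.0, basis40)
        assert dm.orthonormality_defect() < 1e-10

    def test_one_huge_pixel_is_rank_one_gaussian_field_mode(self, basis40):
        """A single pixel is one *field* mode: the FIM is rank 1 and the
        captured flux of a central point equals the closed-form overlap
        (integral of the PSF over the pixel, squared) — not ~1, which would
        require an intensity bucket over many modes."""
        dm = direct_imaging_modes(16.0, 8.0, basis40)
        assert dm.J == 1
        src = make_point_comb(1, 1.0, [1.0])
        pt = probability_tensor(src.basis, dm)
        # |<pixel|psi_0>|^2 = (int psi_0 / sqrt(16))^2 = sqrt(8 pi) / 16,
        # up to ~1% renormalization from truncating the indicator's tails
        assert pt.p[0, 0] == pytest.approx(np.sqrt(8 * np.pi) / 16, rel=1e-2)
        I = pt.p[:, :1].T @ pt.p[:, :1]
        assert np.linalg.matrix_rank(I) == 1

    def test_crb_converges_to_continuum_direct_imaging(self, psf1, basis40):
        """Halving the pixel width converges the pixel-mode CRB onto the
        analytic fine-pixel limit (within 1%)."""
        from mospade.fisher import direct_imaging_factor

        src = make_point_comb(3, 0.6)
        c = floor_coefficients(src.c)
        _, d_cont = crb_from_factor(direct_imaging_factor(src, psf1))
        means = []
        for w in (2.0, 1.0, 0.5):
            dm = direct_imaging_modes(w, 5.0, basis40)
            pt = probability_tensor(src.basis, dm)
            _, diag = crb_from_factor(fisher_factor(c, pt))
            means.append(diag.mean())
        errs = [abs(m - d_cont.mean()) / d_cont.mean() for m in means]
        assert errs[-1] < 0.01
        assert errs[0] > errs[-1]  # refinement actually helps

    def test_too_many_pixels_for_basis_rejected(self, basis40):
        with pytest.raises(ConfigurationError):
            direct_imaging_modes(0.1, 5.0, basis40)
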