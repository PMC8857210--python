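"""Classical Fisher information, CRBs and sweep summaries."""

import numpy as np
import pytest

from mospade.fisher import (
    CrbCurve,
    SingularFisherError,
    crb_from_factor,
    crb_objective,
    direct_imaging_factor,
    direct_imaging_fim,
    fisher_factor,
    fisher_matrix,
    floor_coefficients,
    resolution_gain,
)
from mospade.optics import ImagingModeSet, ProbabilityTensor, probability_tensor
from mospade.sources import make_point_comb


def random_tensor(rng, J, K):
    p = rng.uniform(0.01, 0.5, size=(J, K))
    return ProbabilityTensor(p=p, captured=p.sum(axis=0))


class TestFisherMatrix:
    def test_single_point_matched_mode_closed_form(self):
        """K=1 with a perfectly matched mode: I = 1/c (hand evaluation)."""
        pt = ProbabilityTensor(p=np.array([[1.0]]), captured=np.array([1.0]))
        for c1 in (0.3, 1.0, 2.5):
            I = fisher_matrix(np.array([c1]), pt)
            assert I[0, 0] == pytest.approx(1.0 / c1, rel=1e-12)

    def test_symmetry_and_permutation_equivariance(self, rng):
        pt = random_tensor(rng, 6, 4)
        c = rng.uniform(0.1, 1.0, 4)
        I = fisher_matrix(c, pt)
        np.testing.assert_array_equal(I, I.T)
        perm = rng.permutation(4)
        Ip = fisher_matrix(c[perm], ProbabilityTensor(pt.p[:, perm], pt.captured[perm]))
        np.testing.assert_allclose(Ip, I[np.ix_(perm, perm)], rtol=1e-12)

    @pytest.mark.parametrize("trial", range(3))
    def test_matches_poisson_curvature_oracle(self, rng, trial):
        """FIM equals the finite-difference Hessian of the expected Poisson
        negative log-likelihood, an independent route through P_j(c) only."""
        J, K = rng.integers(3, 5), rng.integers(2, 5)
        pt = random_tensor(rng, J, K)
        c0 = rng.uniform(0.3, 1.0, K)
        P0 = pt.p @ c0

        def expected_nll(c):
            P = pt.p @ c
            return np.sum(P - P0 * np.log(P))

        h = 1e-4
        H = np.zeros((K, K))
        for i in range(K):
            for j in range(K):
                ei, ej = np.eye(K)[i] * h, np.eye(K)[j] * h
                H[i, j] = (
                    expected_nll(c0 + ei + ej)
                    - expected_nll(c0 + ei - ej)
                    - expected_nll(c0 - ei + ej)
                    + expected_nll(c0 - ei - ej)
                ) / (4 * h * h)
        I = fisher_matrix(c0, pt)
        np.testing.assert_allclose(I, H, rtol=1e-5, atol=1e-8)

    def test_information_monotone_in_added_modes(self, rng):
        pt = random_tensor(rng, 6, 4)
        c = rng.uniform(0.2, 1.0, 4)
        for J in range(2, 6):
            I_small = fisher_matrix(c, ProbabilityTensor(pt.p[:J], pt.captured))
            I_big = fisher_matrix(c, ProbabilityTensor(pt.p[: J + 1], pt.captured))
            v = rng.standard_normal(4)
            assert v @ I_big @ v >= v @ I_small @ v - 1e-12


class TestCrbObjective:
    def test_identity_case(self):
        L, diag = crb_objective(np.eye(5))
        assert L == pytest.approx(5.0)
        np.testing.assert_allclose(diag, 1.0)

    def test_diagonal_closed_form(self):
        L, diag = crb_objective(np.diag([4.0, 1.0]))
        assert L == pytest.approx(1.25)
        np.testing.assert_allclose(diag, [0.25, 1.0])

    def test_crb_dominates_inverse_diagonal(self, rng):
        A = rng.standard_normal((8, 5))
        I = A.T @ A + 0.1 * np.eye(5)
        _, diag = crb_objective(I)
        assert np.all(diag >= 1.0 / np.diag(I) - 1e-12)

    def test_singular_matrix_raises_with_deficiency(self):
        I = np.zeros((3, 3))
        I[0, 0] = 1.0
        with pytest.raises(SingularFisherError):
            crb_objective(I)

    def test_factor_route_agrees_with_matrix_route(self, rng):
        F = rng.standard_normal((9, 4))
        L1, d1 = crb_objective(F.T @ F)
        L2, d2 = crb_from_factor(F)
        assert L1 == pytest.approx(L2, rel=1e-9)
        np.testing.assert_allclose(d1, d2, rtol=1e-9)

    def test_factor_resolves_extreme_conditioning(self):
        """Eigenvalue ratios far beyond 1e16 survive the factor route."""
        s = np.array([1.0, 1e-12])
        F = np.diag(s)
        _, diag = crb_from_factor(F)
        np.testing.assert_allclose(diag, [1.0, 1e24], rtol=1e-10)


class TestFloor:
    def test_floor_only_raises_zeros(self):
        c = np.array([0.0, 0.5, 1.0])
        out = floor_coefficients(c)
        assert out[0] == pytest.approx(1e-6)
        np.testing.assert_array_equal(out[1:], c[1:])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            floor_coefficients(np.zeros(3))


class TestDirectImaging:
    def test_well_separated_points_decouple(self, psf1):
        """At large spacing each point behaves as an isolated source."""
        iso = make_point_comb(1, 1.0, [0.2])
        _, d_iso = crb_from_factor(direct_imaging_factor(iso, psf1))
        # intensity-metric cross-talk decays slowly: ~6% at 4 sigma,
        # ~1.6% at 5 sigma; the decoupling trend is what matters
        comb4 = make_point_comb(5, 4.0)
        _, d4 = crb_from_factor(direct_imaging_factor(comb4, psf1))
        comb5 = make_point_comb(5, 5.0)
        _, d5 = crb_from_factor(direct_imaging_factor(comb5, psf1))
        assert d5.mean() == pytest.approx(d_iso.mean(), rel=0.05)
        assert abs(d5.mean() - d_iso.mean()) < abs(d4.mean() - d_iso.mean())

    def test_factor_and_fim_agree(self, psf1):
        src = make_point_comb(3, 1.0)
        F = direct_imaging_factor(src, psf1)
        I = direct_imaging_fim(src, psf1)
        np.testing.assert_allclose(F.T @ F, I, rtol=1e-10, atol=1e-12)


class TestResolutionGain:
    def test_identical_curves_give_unit_gain(self):
        s = np.array([0.2, 0.3, 0.5, 0.8])
        v = np.array([100.0, 30.0, 5.0, 1.0])
        c = CrbCurve(s, v)
        assert resolution_gain(c, c) == pytest.approx(1.0, rel=1e-9)

    def test_half_shifted_curve_gives_factor_two(self):
        s = np.array([0.2, 0.3, 0.5, 0.8])
        v = np.array([100.0, 30.0, 5.0, 1.0])
        direct = CrbCurve(s, v)
        mo = CrbCurve(s / 2.0, v)
        assert resolution_gain(direct, mo, regime_max=0.4) == pytest.approx(
            2.0, rel=1e-9
        )

    def test_disjoint_ranges_raise(self):
        a = CrbCurve(np.array([0.2, 0.4]), np.array([10.0, 5.0]))
        b = CrbCurve(np.array([0.2, 0.4]), np.array([0.2, 0.1]))
        with pytest.raises(ValueError):
            resolution_gain(a, b)
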