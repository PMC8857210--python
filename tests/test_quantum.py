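"""Quantum Fisher information, SLDs and the quantum bound orderings."""

import numpy as np
import pytest

from mospade.fisher import crb_from_factor, fisher_factor, floor_coefficients
from mospade.optics import HermiteGaussianBasis, ImagingModeSet, probability_tensor
from mospade.quantum import (
    BasisTruncationError,
    assemble_density,
    quantum_bundle,
    sld_and_qfim,
)
from mospade.sources import make_discretized_extended, make_point_comb
from mospade.stiefel import _qr_retract


class TestDensityAssembly:
    def test_single_point_is_pure(self, psf1, basis40):
        src = make_point_comb(1, 1.0, [1.0])
        rho, drho, S = assemble_density(src, psf1, basis40, floor_frac=0.0)
        assert np.trace(rho) == pytest.approx(1.0, abs=1e-10)
        assert np.trace(rho @ rho) == pytest.approx(1.0, abs=1e-10)
        assert S == pytest.approx(1.0, abs=1e-10)

    def test_two_point_eigenvalues_match_gram_oracle(self, psf1, basis40):
        """Eigenvalues of a two-point mixture follow the 2x2 Gram
        diagonalization: (1 ± exp(-d^2/8 sigma^2)) / 2."""
        d = 1.4
        src = make_point_comb(2, d, [0.5, 0.5])
        rho, _, _ = assemble_density(src, psf1, basis40, floor_frac=0.0)
        lam = np.sort(np.linalg.eigvalsh(rho))[-2:]
        ov = np.exp(-d * d / 8.0)
        np.testing.assert_allclose(
            lam, [(1 - ov) / 2, (1 + ov) / 2], atol=1e-10
        )

    def test_hermitian_unit_trace_psd(self, psf1, basis40):
        src = make_discretized_extended("bump", 0.8, 4.0)
        rho, _, _ = assemble_density(src, psf1, basis40)
        np.testing.assert_allclose(rho, rho.T, atol=1e-14)
        assert np.trace(rho) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.eigvalsh(rho)[0] > -1e-12

    def test_truncation_error_raised(self, psf1):
        tiny = HermiteGaussianBasis(1.0, 6, 1)
        src = make_point_comb(2, 6.0)
        with pytest.raises(BasisTruncationError):
            assemble_density(src, psf1, tiny)


class TestSldAndQfim:
    def test_pure_state_closed_form(self, rng):
        """For rho = |psi><psi| with drho = |psi><dpsi| + h.c., the QFIM
        equals 4 Re(<dpsi_k|dpsi_l> - <dpsi_k|psi><psi|dpsi_l>) and the SLD
        is 2 drho."""
        M, K = 12, 3
        psi = rng.standard_normal(M)
        psi /= np.linalg.norm(psi)
        dpsi = rng.standard_normal((K, M)) * 0.3
        # keep normalization: d<psi|psi> = 0
        dpsi -= np.outer(dpsi @ psi, psi)
        rho = np.outer(psi, psi)
        drho = np.array([np.outer(d, psi) + np.outer(psi, d) for d in dpsi])
        slds, qfim, qcrb, diag = sld_and_qfim(rho, drho, captured_flux=1.0)
        expect = 4.0 * (dpsi @ dpsi.T - np.outer(dpsi @ psi, dpsi @ psi))
        np.testing.assert_allclose(qfim, expect, atol=1e-9)
        for k in range(K):
            resid = drho[k] - 0.5 * (slds[k] @ rho + rho @ slds[k])
            # residual vanishes on the support of rho
            assert np.abs(psi @ resid) .max() < 1e-9

    def test_sld_equation_residual_small(self, psf1, basis40):
        src = make_discretized_extended("bump", 0.8, 4.0)
        qb = quantum_bundle(src, psf1, basis40)
        assert qb.sld_residual < 1e-8

    def test_weak_commutativity_holds(self, psf1, basis40):
        src = make_discretized_extended("bump", 0.8, 4.0)
        qb = quantum_bundle(src, psf1, basis40)
        scale = np.abs(qb.qfim).max()
        assert qb.weak_commutativity <= 1e-8 * scale

    def test_slds_are_symmetric(self, psf1, basis40):
        src = make_point_comb(3, 0.8)
        qb = quantum_bundle(src, psf1, basis40)
        for L in qb.slds:
            np.testing.assert_allclose(L, L.T, atol=1e-10)


class TestQuantumDominance:
    @pytest.mark.parametrize("J", [3, 5, 8])
    def test_qfim_dominates_classical_fim(self, psf1, basis40, rng, J):
        """Quantum bound dominates the FIM of any modal measurement:
        random-vector quadratic forms of (QFIM - FIM) are non-negative."""
        src = make_point_comb(3, 0.6, [0.5, 0.3, 0.2])
        qb = quantum_bundle(src, psf1, basis40)
        c = floor_coefficients(src.c)
        V = _qr_retract(rng.standard_normal((40, J)))
        pt = probability_tensor(src.basis, ImagingModeSet(basis40, V))
        from mospade.fisher import fisher_matrix

        gap = qb.qfim - fisher_matrix(c, pt)
        scale = np.abs(qb.qfim).max()
        for _ in range(20):
            v = rng.standard_normal(3)
            assert v @ gap @ v >= -1e-8 * scale * (v @ v)

    def test_crb_never_beats_qcrb(self, psf1):
        """Mean optimized CRB >= mean QCRB across discretization widths."""
        from mospade.stiefel import default_basis_for, design_modes
        from mospade.fisher import FisherBundle

        for a in (1.5, 3.0):
            src = make_discretized_extended("bump", a, 6.0)
            basis = default_basis_for(src, psf1, src.K + 1)
            qb = quantum_bundle(src, psf1, basis)
            modes, _ = design_modes(src, src.K + 1, psf1, basis=basis)
            fb = FisherBundle.from_source(src, modes)
            assert fb.mean_crb >= qb.mean_qcrb * (1 - 1e-6)

    def test_basis_truncation_converged(self, psf1):
        """Enlarging the basis by 10 modes changes the mean QCRB < 0.5%."""
        src = make_discretized_extended("bump", 1.0, 4.0)
        v = []
        for M in (30, 40):
            basis = HermiteGaussianBasis(1.0, M, 1)
            v.append(quantum_bundle(src, psf1, basis).mean_qcrb)
        assert abs(v[1] - v[0]) / v[0] < 0.005


def test_qcrb_sweep_ratio_attached_and_bounded(psf1):
    """qcrb_vs_sweep returns a mean-QCRB curve and, given an optimized-CRB
    curve, a ratio that never drops below 1."""
    from mospade.fisher import mean_crb_vs_separation
    from mospade.quantum import qcrb_vs_sweep
    from mospade.sources import make_discretized_extended

    sweep = [1.5, 3.0]
    mk = lambda a: make_discretized_extended("bump", a, 6.0)
    mo = mean_crb_vs_separation(mk, "optimized", sweep, psf1)
    q = qcrb_vs_sweep(mk, sweep, psf1, mo_curve=mo)
    ratio = q.extras["ratio"]
    assert np.all(np.isfinite(q.mean_crb)) and np.all(q.mean_crb > 0)
    assert np.all(ratio >= 1 - 1e-6)
    # mean QCRB decreases as the discretization coarsens
    assert q.mean_crb[1] < q.mean_crb[0]
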