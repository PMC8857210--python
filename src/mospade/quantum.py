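"""Quantum Fisher information and the quantum Cramér-Rao bound.

A photon from source mode k arrives in the mixed state
rho_k = (1/s_k) ∫_bin_k |psi_R><psi_R| dR (a pure shifted-PSF state for a
delta mode), and the one-photon state of the scene is the incoherent mixture
rho = sum_k c_k s_k rho_k / S with captured flux S = sum_k c_k s_k.

The symmetric logarithmic derivatives (SLDs) are built from the
eigendecomposition of rho,

    L_k = sum_{q,p: lam_q + lam_p > eps} 2 <e_q|d rho/d c_k|e_p>
                                           / (lam_q + lam_p) |e_q><e_p|,

and the quantum Fisher information is K_kl = Re tr(L_k L_l rho).  To compare
like-for-like with the per-photon classical FIM of the (unconditioned)
Poisson detection model — whose modal probabilities P_j = sum_k c_k p_jk do
not sum to one — the QFIM reported here is the per-mean-photon information
of the full Poisson quantum channel,

    K_tot = S * K(rho) + s s^T / S,

which is what one obtains by applying the SLD construction directly to the
unnormalized mixture sum_k c_k T_k.  With this convention the quantum bound
dominates the classical FIM of *any* modal measurement exactly (quantum
data-processing for Poisson channels), so CRB >= QCRB holds to round-off.

Everything is real: the PSF is real, so rho is a real symmetric matrix in
the Hermite-Gaussian basis and the SLDs are real symmetric.  The weak
commutativity residual tr(rho [L_i, L_j]) is then the antisymmetric part of
tr(rho L_i L_j), available for free from the QFIM assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .fisher import COEFF_FLOOR_FRAC, floor_coefficients
from .optics import HermiteGaussianBasis, PSFModel, recommended_nodes_per_bin
from .sources import SourceModel

__all__ = [
    "QuantumBundle",
    "BasisTruncationError",
    "assemble_density",
    "sld_and_qfim",
    "quantum_bundle",
    "qcrb_vs_sweep",
]

EIG_SUPPORT_FLOOR = 1e-12  # pairs with lam_q + lam_p below this are excluded


class BasisTruncationError(ValueError):
    """Truncated computation basis loses too much of the state's trace."""


@dataclass
class QuantumBundle:
    """Density operator, SLDs and QCRB summary for one source model."""

    rho: np.ndarray
    drho: np.ndarray  # (K, M, M), derivative of the trace-1 state at fixed S
    eigvals: np.ndarray
    eigvecs: np.ndarray
    slds: np.ndarray  # (K, M, M)
    qfim: np.ndarray  # per-mean-photon, Poisson-channel convention
    qcrb_diag: np.ndarray
    captured_flux: float
    weak_commutativity: float  # max_|ij| |tr(rho [L_i, L_j])|
    sld_residual: float  # max_k ||drho_k - (L_k rho + rho L_k)/2|| on support
    max_commutator_norm: float = np.nan

    @property
    def mean_qcrb(self) -> float:
        return float(self.qcrb_diag.mean())


def _bin_states(source: SourceModel, basis: HermiteGaussianBasis):
    """Unnormalized bin states T_k = ∫_bin_k |psi_R><psi_R| dR, (K, M, M)."""
    sb = source.basis
    width = float(sb.widths.max(initial=0.0))
    if sb.dimension == 2:
        width = math.sqrt(width)
    npb = recommended_nodes_per_bin(width, basis) if width > 0 else 1
    nodes, wts, idx = sb.quadrature(npb)
    G = basis.point_overlaps(nodes)  # (M, N)
    M = basis.size
    T = np.empty((sb.K, M, M))
    starts = np.searchsorted(idx, np.arange(sb.K))
    ends = np.append(starts[1:], idx.size)
    for k in range(sb.K):
        sl = slice(starts[k], ends[k])
        Gk = G[:, sl]
        T[k] = (Gk * wts[sl][None, :]) @ Gk.T
    return T


def assemble_density(
    source: SourceModel,
    psf: PSFModel,
    basis: HermiteGaussianBasis,
    *,
    floor_frac: float = COEFF_FLOOR_FRAC,
    max_trace_deficit: float = 1e-4,
):
    """One-photon density matrix, its coefficient derivatives and flux.

    Returns ``(rho, drho, S)`` with rho trace-1 and drho_k = T_k / S the
    fixed-normalization derivative.  Raises :class:`BasisTruncationError`
    when the truncated basis captures less than ``1 - max_trace_deficit`` of
    the source's flux (relative to the untruncated bin measures).
    """
    if not math.isclose(psf.sigma, basis.sigma):
        raise ValueError("PSF width does not match the computation basis")
    c = floor_coefficients(source.c, floor_frac)
    T = _bin_states(source, basis)
    s_k = np.trace(T, axis1=1, axis2=2)
    S = float(c @ s_k)
    measures = source.basis.widths
    full = float(c @ measures) if measures.any() else float(c.sum())
    deficit = 1.0 - S / full
    if deficit > max_trace_deficit:
        raise BasisTruncationError(
            f"basis truncation loses {deficit:.2e} of the captured flux "
            f"(> {max_trace_deficit:g}); increase n_modes"
        )
    rho_un = np.tensordot(c, T, axes=(0, 0))
    rho = 0.5 * (rho_un + rho_un.T) / S
    drho = T / S
    return rho, drho, S


def sld_and_qfim(
    rho: np.ndarray,
    drho: np.ndarray,
    *,
    captured_flux: float = 1.0,
    eig_floor: float = EIG_SUPPORT_FLOOR,
    commutator_pairs: int = 6,
):
    """SLD operators, per-mean-photon QFIM and QCRB diagonal.

    ``drho`` has shape (K, M, M).  The eigen-pair sum excludes
    lam_q + lam_p < ``eig_floor`` (the numerical form of the support
    restriction).  The QFIM is scaled by ``captured_flux`` to the
    Poisson-channel per-mean-photon convention described in the module
    docstring; pass 1.0 for a bare normalized-state QFIM.
    """
    rho = 0.5 * (rho + rho.T)
    lam, E = np.linalg.eigh(rho)
    lam = np.clip(lam, 0.0, None)
    K = drho.shape[0]
    denom = lam[:, None] + lam[None, :]
    mask = denom > eig_floor
    inv2 = np.where(mask, 2.0 / np.where(mask, denom, 1.0), 0.0)
    delta = np.einsum("qm,kmn,np->kqp", E.T, drho, E, optimize=True)
    Lt = delta * inv2[None, :, :]  # SLDs in the rho eigenbasis
    # qfim raw (before symmetrization): Mraw_kl = tr(rho L_k L_l)
    Mraw = np.einsum("kqp,lpq,q->kl", Lt, Lt, lam, optimize=True)
    weak = float(np.max(np.abs(Mraw - Mraw.T))) if K > 1 else 0.0
    qfim = captured_flux * 0.5 * (Mraw + Mraw.T)
    # square-root factor: rows are retained (q <= p) pairs, so that
    # qfim = Phi^T Phi exactly; its SVD keeps the small quantum-information
    # eigenvalues accurate in the deep sub-Rayleigh regime.
    iu, ju = np.triu_indices(lam.size)
    pair_ok = mask[iu, ju]
    iu, ju = iu[pair_ok], ju[pair_ok]
    # ordered-pair weight 2/(lam_q+lam_p): unordered off-diagonal pairs are
    # counted twice (-> 4/(lam_q+lam_p)), diagonal pairs once (-> 1/lam_q)
    wpair = np.where(iu == ju, 2.0, 4.0) / (lam[iu] + lam[ju])
    phi = delta[:, iu, ju].T * np.sqrt(captured_flux * wpair)[:, None]  # (npair, K)
    slds = np.einsum("mq,kqp,np->kmn", E, Lt, E, optimize=True)
    # SLD defining-equation residual, restricted to the retained pair support
    resid = 0.0
    recon = 0.5 * (
        np.einsum("kqp,p->kqp", Lt, lam) + np.einsum("q,kqp->kqp", lam, Lt)
    )
    target = np.where(mask[None, :, :], delta, 0.0)
    resid = float(np.max(np.abs(recon - target)))
    # spot-check commutator norms on a few index pairs
    maxcomm = 0.0
    if K > 1:
        rng = np.random.default_rng(0)
        for _ in range(min(commutator_pairs, K * (K - 1) // 2)):
            i, j = rng.choice(K, size=2, replace=False)
            Cij = slds[i] @ slds[j] - slds[j] @ slds[i]
            maxcomm = max(maxcomm, float(np.max(np.abs(Cij))))
    from .fisher import crb_from_factor

    _, qcrb_diag = crb_from_factor(phi)
    return slds, qfim, qcrb_diag, {
        "eigvals": lam,
        "eigvecs": E,
        "weak_commutativity": weak,
        "sld_residual": resid,
        "max_commutator_norm": maxcomm,
    }


def quantum_bundle(
    source: SourceModel,
    psf: PSFModel,
    basis: HermiteGaussianBasis,
    *,
    floor_frac: float = COEFF_FLOOR_FRAC,
) -> QuantumBundle:
    """Assemble the density matrix and compute SLDs, QFIM and QCRB."""
    rho, drho, S = assemble_density(source, psf, basis, floor_frac=floor_frac)
    slds, qfim, qcrb, diag = sld_and_qfim(rho, drho, captured_flux=S)
    return QuantumBundle(
        rho=rho,
        drho=drho,
        eigvals=diag["eigvals"],
        eigvecs=diag["eigvecs"],
        slds=slds,
        qfim=qfim,
        qcrb_diag=qcrb,
        captured_flux=S,
        weak_commutativity=diag["weak_commutativity"],
        sld_residual=diag["sld_residual"],
        max_commutator_norm=diag["max_commutator_norm"],
    )


def qcrb_vs_sweep(
    make_scene: Callable[[float], SourceModel],
    sweep: Sequence[float],
    psf: PSFModel,
    *,
    n_basis: int | None = None,
    floor_frac: float = COEFF_FLOOR_FRAC,
    mo_curve=None,
):
    """Mean QCRB per sweep value, optionally with the C^MO / C^Q ratio.

    Returns a :class:`mospade.fisher.CrbCurve` labelled ``"qcrb"``; when an
    optimized-CRB curve is supplied, the ratio curve is stored under
    ``extras["ratio"]`` (the quantity plotted above the CRB sweeps).
    """
    from .fisher import CrbCurve
    from .stiefel import default_basis_for

    sweep = np.asarray(list(sweep), dtype=float)
    vals = np.full(sweep.size, np.nan)
    for i, sv in enumerate(sweep):
        scene = make_scene(float(sv))
        basis = default_basis_for(scene, psf, scene.K + 1, n_basis)
        vals[i] = quantum_bundle(
            scene, psf, basis, floor_frac=floor_frac
        ).mean_qcrb
    curve = CrbCurve(sweep=sweep, mean_crb=vals, label="qcrb")
    if mo_curve is not None:
        curve.extras["ratio"] = np.asarray(mo_curve.mean_crb, float) / vals
    return curve
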