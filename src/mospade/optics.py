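"""Incoherent-imaging forward model.

The imaging system has a shift-invariant Gaussian *field* PSF

    psi_R(x) = (2 pi sigma^2)^{-1/4} exp[-(x - R)^2 / (4 sigma^2)],

so the *intensity* PSF is a Gaussian of width sigma; sigma relates to an Airy
radius r_c roughly as sigma ≈ r_c / 3.  Imaging modes phi_j are orthonormal
functions at the image plane; a photon emitted at R is detected in mode j
with probability |<phi_j|psi_R>|^2, and for a source F(R) = sum_k c_k f_k(R)
the modal detection probability is linear in the coefficients,

    P_j = sum_k c_k p_jk,     p_jk = ∫_{f_k} |<phi_j|psi_R>|^2 dR.

Everything is represented over a truncated Hermite-Gaussian (HG) computation
basis matched to the PSF width (tensor products in 2D), for which the
shifted-PSF overlaps have the exact closed form of coherent-state amplitudes,

    <HG_n | psi_R> = e^{-alpha^2/2} alpha^n / sqrt(n!),  alpha = R / (2 sigma).

Orthonormality of a mode set is then exact matrix orthonormality of its
coefficient matrix V (a Stiefel point), and only the object-plane bin
integrals require quadrature (per-bin Gauss-Legendre, with the node count
scaled to the phase span of the most oscillatory basis mode).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .sources import SourceBasis, SourceModel

__all__ = [
    "PSFModel",
    "HermiteGaussianBasis",
    "ImagingModeSet",
    "ProbabilityTensor",
    "psf_overlap",
    "probability_tensor",
    "detection_probabilities",
    "direct_imaging_modes",
    "recommended_nodes_per_bin",
]

ORTHONORMALITY_TOL = 1e-10


class ConfigurationError(ValueError):
    """Forward-model configuration cannot represent the requested scene."""


@dataclass(frozen=True)
class PSFModel:
    """Gaussian field PSF of width ``sigma`` in 1 or 2 dimensions."""

    dimension: int = 1
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2):
            raise ConfigurationError("PSF dimension must be 1 or 2")
        if not (self.sigma > 0):
            raise ConfigurationError("sigma must be positive")

    def field(self, x: np.ndarray, R: float = 0.0) -> np.ndarray:
        """Field amplitude psi_R(x) (1D)."""
        s2 = self.sigma**2
        return (2 * np.pi * s2) ** (-0.25) * np.exp(-((x - R) ** 2) / (4 * s2))


def psf_overlap(R1, R2, psf: PSFModel) -> float | np.ndarray:
    """Field overlap ∫ psi_R1 psi_R2 = exp(-|R1-R2|^2 / (8 sigma^2)).

    Symmetric in its arguments; in 2D the positions are length-2 vectors and
    the overlap factorizes over axes.
    """
    d2 = np.sum((np.asarray(R1, float) - np.asarray(R2, float)) ** 2, axis=-1) \
        if psf.dimension == 2 else (np.asarray(R1, float) - np.asarray(R2, float)) ** 2
    if not np.all(np.isfinite(d2)):
        raise ConfigurationError("non-finite source positions")
    return np.exp(-d2 / (8.0 * psf.sigma**2))


# ---------------------------------------------------------------------------
# computation basis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HermiteGaussianBasis:
    """Truncated HG basis matched to the PSF width (tensor product in 2D).

    ``n_modes`` is the per-axis truncation order M; the total basis size is
    M in 1D and M^2 in 2D, with 2D flat index n_x * M + n_y.
    """

    sigma: float
    n_modes: int
    dimension: int = 1

    def __post_init__(self) -> None:
        if self.n_modes < 1:
            raise ConfigurationError("need at least one basis mode")
        if self.dimension not in (1, 2):
            raise ConfigurationError("dimension must be 1 or 2")
        if not (self.sigma > 0):
            raise ConfigurationError("sigma must be positive")

    @property
    def size(self) -> int:
        return self.n_modes**self.dimension

    # -- pointwise values (1D axis factor) --------------------------------

    def values_1d(self, x: np.ndarray) -> np.ndarray:
        """HG function values, shape (n_modes, len(x)).

        phi_n(x) = (2 pi sigma^2)^{-1/4} H_n(u) e^{-u^2/2} / sqrt(2^n n!),
        u = x / (sigma sqrt 2), evaluated with the stable normalized
        three-term recurrence.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        u = x / (self.sigma * math.sqrt(2.0))
        scale = 1.0 / math.sqrt(self.sigma * math.sqrt(2.0))
        out = np.empty((self.n_modes, x.size))
        h_prev = np.pi ** (-0.25) * np.exp(-0.5 * u * u)
        out[0] = h_prev
        if self.n_modes > 1:
            h = math.sqrt(2.0) * u * h_prev
            out[1] = h
            for n in range(2, self.n_modes):
                h, h_prev = (
                    math.sqrt(2.0 / n) * u * h - math.sqrt((n - 1) / n) * h_prev,
                    h,
                )
                out[n] = h
        return out * scale

    def _alpha_overlaps(self, R: np.ndarray) -> np.ndarray:
        """<HG_n|psi_R> for one axis, shape (n_modes, len(R)); exact."""
        alpha = np.asarray(R, dtype=float) / (2.0 * self.sigma)
        out = np.empty((self.n_modes, alpha.size))
        t = np.exp(-0.5 * alpha * alpha)
        out[0] = t
        for n in range(1, self.n_modes):
            t = t * alpha / math.sqrt(n)
            out[n] = t
        return out

    def point_overlaps(self, R: np.ndarray) -> np.ndarray:
        """Overlaps of basis modes with shifted PSFs, shape (size, N).

        ``R`` has shape (N,) in 1D or (N, 2) in 2D.
        """
        R = np.asarray(R, dtype=float)
        if self.dimension == 1:
            return self._alpha_overlaps(np.atleast_1d(R))
        R = np.atleast_2d(R)
        gx = self._alpha_overlaps(R[:, 0])  # (M, N)
        gy = self._alpha_overlaps(R[:, 1])
        return (gx[:, None, :] * gy[None, :, :]).reshape(self.size, -1)

    def captured_energy(self, R: np.ndarray) -> np.ndarray:
        """Fraction of a shifted PSF's energy inside the truncated basis."""
        g = self.point_overlaps(R)
        return np.sum(g * g, axis=0)


def recommended_nodes_per_bin(width: float, basis: HermiteGaussianBasis) -> int:
    """Gauss-Legendre node count resolving |<HG_n|psi_R>|^2 across a bin.

    The most oscillatory integrand varies with spatial frequency
    ~ sqrt(2 M) / sigma; half the phase span plus a safety margin of GL
    nodes integrates it to near machine precision.
    """
    span = width * math.sqrt(2.0 * basis.n_modes) / basis.sigma
    return max(8, int(math.ceil(0.55 * span)) + 8)


# ---------------------------------------------------------------------------
# imaging mode sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImagingModeSet:
    """J orthonormal imaging modes as columns of V over the HG basis."""

    basis: HermiteGaussianBasis
    V: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        if V.ndim != 2 or V.shape[0] != self.basis.size:
            raise ConfigurationError(
                f"V must be ({self.basis.size}, J); got {V.shape}"
            )
        if V.shape[1] > V.shape[0]:
            raise ConfigurationError("cannot have more modes than basis functions")
        defect = np.max(np.abs(V.T @ V - np.eye(V.shape[1])))
        if defect > ORTHONORMALITY_TOL:
            raise ConfigurationError(
                f"mode set is not orthonormal (defect {defect:.2e})"
            )
        object.__setattr__(self, "V", V)

    @property
    def J(self) -> int:
        return int(self.V.shape[1])

    def orthonormality_defect(self) -> float:
        return float(np.max(np.abs(self.V.T @ self.V - np.eye(self.J))))


@dataclass(frozen=True)
class ProbabilityTensor:
    """Per-coefficient modal detection probabilities.

    ``p[j, k]`` is the probability that a photon from source mode k (per unit
    coefficient, times the bin measure for rectangles) is detected in imaging
    mode j.  ``captured[k]`` is the total weight of source mode k inside the
    computation basis (the column sum over a *complete* mode set).
    """

    p: np.ndarray
    captured: np.ndarray

    @property
    def J(self) -> int:
        return int(self.p.shape[0])

    @property
    def K(self) -> int:
        return int(self.p.shape[1])


def probability_tensor(
    source_basis: SourceBasis,
    modes: ImagingModeSet,
    psf: PSFModel | None = None,
    *,
    nodes_per_bin: int | None = None,
    min_captured: float = 0.98,
) -> ProbabilityTensor:
    """Modal detection probability tensor p_jk for a source basis.

    For rectangle bins, p_jk = ∫_bin_k |<phi_j|psi_R>|^2 dR by per-bin
    Gauss-Legendre quadrature; for delta combs the integral collapses to a
    point evaluation.  Raises :class:`ConfigurationError` when the truncated
    computation basis does not contain the shifted PSFs over the source
    support (captured energy below ``min_captured`` at the worst node).
    """
    if psf is not None and not math.isclose(psf.sigma, modes.basis.sigma):
        raise ConfigurationError("PSF width does not match the mode basis")
    basis = modes.basis
    if source_basis.dimension != basis.dimension:
        raise ConfigurationError("source and imaging dimensions differ")
    if nodes_per_bin is None:
        widths = source_basis.widths
        w = float(widths.max()) if widths.size else 0.0
        if source_basis.dimension == 2:
            w = math.sqrt(w)  # per-axis width of square bins
        nodes_per_bin = recommended_nodes_per_bin(w, basis) if w > 0 else 1
    nodes, wts, idx = source_basis.quadrature(nodes_per_bin)
    G = basis.point_overlaps(nodes)  # (size, N)
    cap_node = np.sum(G * G, axis=0)
    worst = float(cap_node.min()) if cap_node.size else 1.0
    if worst < min_captured:
        raise ConfigurationError(
            f"computation basis too small for the source extent: captured "
            f"energy {worst:.4f} < {min_captured} at the farthest node; "
            "increase n_modes"
        )
    A = modes.V.T @ G  # (J, N) mode amplitudes at the nodes
    starts = np.searchsorted(idx, np.arange(source_basis.K))
    pw = (A * A) * wts[None, :]
    p = np.add.reduceat(pw, starts, axis=1)
    captured = np.add.reduceat(cap_node * wts, starts)
    return ProbabilityTensor(p=p, captured=captured)


def detection_probabilities(source: SourceModel, pt: ProbabilityTensor) -> np.ndarray:
    """Modal detection probabilities P_j = sum_k c_k p_jk."""
    c = np.asarray(source.c, dtype=float)
    if c.shape != (pt.K,):
        raise ConfigurationError(
            f"coefficient length {c.size} does not match tensor K={pt.K}"
        )
    if np.any(c < 0):
        raise ConfigurationError("source coefficients must be non-negative")
    return pt.p @ c


# ---------------------------------------------------------------------------
# direct-imaging (pixel) mode sets
# ---------------------------------------------------------------------------


def _pixel_projection_1d(
    edges: np.ndarray, basis: HermiteGaussianBasis
) -> np.ndarray:
    """Project unit-norm pixel indicators onto the HG basis, (M, n_pix)."""
    from numpy.polynomial.legendre import leggauss

    n = recommended_nodes_per_bin(float(np.diff(edges).max()), basis)
    x, w = leggauss(n)
    lo, hi = edges[:-1], edges[1:]
    half, mid = 0.5 * (hi - lo), 0.5 * (hi + lo)
    nodes = (mid[:, None] + half[:, None] * x[None, :]).ravel()
    wts = (half[:, None] * w[None, :]).ravel()
    vals = basis.values_1d(nodes)  # (M, n_pix*n)
    U = (vals * wts[None, :]).reshape(basis.n_modes, lo.size, n).sum(axis=2)
    return U / np.sqrt(hi - lo)[None, :]


def _loewdin(U: np.ndarray) -> np.ndarray:
    """Symmetric (Loewdin) orthonormalization: closest orthonormal frame."""
    S = U.T @ U
    lam, E = np.linalg.eigh(S)
    if lam[0] <= 1e-10 * lam[-1]:
        # near-degenerate pixel projections: fall back to QR on the span
        Q, _ = np.linalg.qr(U)
        return Q
    return U @ (E / np.sqrt(lam)[None, :]) @ E.T


def direct_imaging_modes(
    pixel_width: float,
    extent: float,
    basis: HermiteGaussianBasis,
) -> ImagingModeSet:
    """Orthonormalized pixel-indicator modes: the direct-imaging basis.

    Pixels of ``pixel_width`` tile ±extent (squares in 2D); each indicator is
    projected onto the computation basis and the frame is symmetrically
    orthonormalized, staying as close as possible to true position-basis
    detection within the truncated representation.
    """
    if pixel_width <= 0:
        raise ConfigurationError("pixel width must be positive")
    if extent < 2.0 * basis.sigma:
        warnings.warn(
            "direct-imaging extent is smaller than the PSF support; "
            "flux will leak outside the pixel array",
            stacklevel=2,
        )
    edges = _tiling(pixel_width, extent)
    if edges.size - 1 > basis.n_modes:
        raise ConfigurationError(
            f"{edges.size - 1} pixels cannot be represented in a basis of "
            f"{basis.n_modes} modes per axis; enlarge the basis or the pixels"
        )
    ax = HermiteGaussianBasis(basis.sigma, basis.n_modes, 1)
    U1 = _pixel_projection_1d(edges, ax)
    V1 = _loewdin(U1)
    if basis.dimension == 1:
        return ImagingModeSet(basis, V1, label=f"direct[{pixel_width:g}]")
    V2 = np.kron(V1, V1)
    return ImagingModeSet(basis, V2, label=f"direct2d[{pixel_width:g}]")


def _tiling(width: float, extent: float) -> np.ndarray:
    n = max(1, int(round(2.0 * extent / width)))
    half = 0.5 * n * width
    return -half + width * np.arange(n + 1)
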