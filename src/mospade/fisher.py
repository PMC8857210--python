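"""Classical Fisher information and Cramér-Rao bounds for modal imaging.

For independent Poisson counts with per-photon modal probabilities
P_j(c) = sum_k c_k p_jk, the per-photon Fisher information matrix is

    I(c; Phi)_kl = sum_j p_jk p_jl / P_j,

and the mean squared error of any unbiased estimate of c_k is bounded by
[I^-1]_kk / <N> for <N> detected-photon budget.  The scalar design objective
is L(Phi) = tr(W I^-1) with W the identity by default, i.e. K times the mean
CRB over coefficients.

Zero true coefficients are floored at a small fraction of the maximum before
evaluating I: a strictly zero bin makes any mode looking only at that bin
infinitely informative (an empty Poisson channel has vanishing variance),
which is an artefact of evaluating the bound exactly on the boundary of the
parameter space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg, special

from .optics import (
    ImagingModeSet,
    PSFModel,
    ProbabilityTensor,
    probability_tensor,
)
from .sources import DELTA_COMB, RECT_2D, SourceModel

__all__ = [
    "FisherBundle",
    "SingularFisherError",
    "floor_coefficients",
    "fisher_matrix",
    "fisher_factor",
    "crb_objective",
    "crb_from_factor",
    "direct_imaging_fim",
    "direct_imaging_factor",
    "CrbCurve",
    "mean_crb_vs_separation",
    "resolution_gain",
]

P_FLOOR = 1e-15  # modes with P_j below this are dropped from the information sum
COEFF_FLOOR_FRAC = 1e-6


class SingularFisherError(np.linalg.LinAlgError):
    """Fisher matrix has an unidentifiable subspace."""

    def __init__(self, n_deficient: int, size: int):
        self.n_deficient = n_deficient
        super().__init__(
            f"Fisher matrix is singular: {n_deficient} of {size} directions "
            "carry no information (J < K without accumulated prior data?)"
        )


def floor_coefficients(c: np.ndarray, floor_frac: float = COEFF_FLOOR_FRAC) -> np.ndarray:
    """Floor zero entries at ``floor_frac * max(c)`` for bound evaluation."""
    c = np.asarray(c, dtype=float)
    top = c.max() if c.size else 0.0
    if top <= 0:
        raise ValueError("cannot evaluate information for an all-zero source")
    return np.maximum(c, floor_frac * top)


def fisher_matrix(
    c: np.ndarray, pt: ProbabilityTensor, *, p_floor: float = P_FLOOR
) -> np.ndarray:
    """Per-photon Fisher information matrix, shape (K, K).

    ``c`` is the evaluation point (true coefficients or a running estimate,
    already floored if it contains zeros).  Modes with P_j < ``p_floor`` are
    dropped; their contribution scales as p^2/P and is either negligible or
    an artefact of an exactly-dark mode.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (pt.K,):
        raise ValueError(f"coefficient length {c.size} != K={pt.K}")
    if np.any(c < 0):
        raise ValueError("coefficients must be non-negative")
    P = pt.p @ c
    keep = P > p_floor
    if not np.any(keep):
        raise ValueError("no imaging mode receives any light at this c")
    pk = pt.p[keep]
    scaled = pk / np.sqrt(P[keep])[:, None]
    I = scaled.T @ scaled
    return 0.5 * (I + I.T)


def fisher_factor(
    c: np.ndarray, pt: ProbabilityTensor, *, p_floor: float = P_FLOOR
) -> np.ndarray:
    """Square-root factor F with I(c; Phi) = F^T F, shape (J_kept, K).

    Rows are p_jk / sqrt(P_j) over the modes receiving light.  CRBs computed
    from an SVD of this factor stay accurate for extreme information dynamic
    range (eigenvalue ratios far below machine epsilon of the Gram matrix),
    which matters in the deep sub-Rayleigh regime.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (pt.K,):
        raise ValueError(f"coefficient length {c.size} != K={pt.K}")
    P = pt.p @ c
    keep = P > p_floor
    return pt.p[keep] / np.sqrt(P[keep])[:, None]


def crb_from_factor(F: np.ndarray, W: np.ndarray | None = None):
    """Weighted CRB objective and diagonal from a square-root factor.

    ``F`` is any matrix with I = F^T F (modal probability rows, continuum
    intensity rows, quantum pair rows); the SVD route resolves the small
    information eigenvalues that a formed Gram matrix would lose.
    """
    F = np.asarray(F, dtype=float)
    K = F.shape[1]
    if F.shape[0] < K:
        raise SingularFisherError(K - F.shape[0], K)
    _, s, Vt = np.linalg.svd(F, full_matrices=False)
    if s[-1] <= 0.0:
        raise SingularFisherError(int(np.sum(s <= 0)), K)
    lam = s * s
    if W is None:
        diag = np.einsum("ik,i->k", Vt * Vt, 1.0 / lam)
        return float(np.sum(1.0 / lam)), diag
    inv = (Vt.T / lam[None, :]) @ Vt
    return float(np.sum(np.asarray(W, float) * inv.T)), np.diag(inv)


def _inverse_diag(I: np.ndarray, rcond: float = 1e-13):
    """(I^-1, diag) via eigendecomposition; raises on numerically singular I."""
    lam, E = np.linalg.eigh(I)
    bad = int(np.sum(lam <= rcond * max(lam[-1], 0.0)))
    if bad or lam[-1] <= 0:
        raise SingularFisherError(max(bad, I.shape[0]), I.shape[0])
    inv = (E / lam[None, :]) @ E.T
    return inv, np.diag(inv)


def crb_objective(I: np.ndarray, W: np.ndarray | None = None):
    """Weighted CRB objective L = tr(W I^-1) and the CRB diagonal.

    With W = identity (the default), L equals K times the mean CRB.
    """
    inv, diag = _inverse_diag(np.asarray(I, dtype=float))
    if W is None:
        return float(np.trace(inv)), diag
    return float(np.sum(np.asarray(W, float) * inv.T)), diag


@dataclass(frozen=True)
class FisherBundle:
    """Fisher matrix with its CRB summary at one evaluation point."""

    I: np.ndarray
    crb_diag: np.ndarray
    mean_crb: float
    W: np.ndarray | None = None
    regularization: float = 0.0

    @classmethod
    def from_source(
        cls,
        source: SourceModel,
        modes: ImagingModeSet,
        *,
        W: np.ndarray | None = None,
        floor_frac: float = COEFF_FLOOR_FRAC,
        pt: ProbabilityTensor | None = None,
    ) -> "FisherBundle":
        if pt is None:
            pt = probability_tensor(source.basis, modes)
        c = floor_coefficients(source.c, floor_frac)
        I = fisher_matrix(c, pt)
        _, diag = crb_from_factor(fisher_factor(c, pt), W)
        return cls(I=I, crb_diag=diag, mean_crb=float(diag.mean()), W=W)


# ---------------------------------------------------------------------------
# continuum (fine-pixel) direct imaging
# ---------------------------------------------------------------------------


def _bin_intensity_1d(x: np.ndarray, lo: float, hi: float, sigma: float) -> np.ndarray:
    """∫_lo^hi N(x - R; sigma^2) dR — intensity of a unit-height bin."""
    z = 1.0 / (sigma * np.sqrt(2.0))
    return 0.5 * (special.erf((x - lo) * z) - special.erf((x - hi) * z))


def _intensity_components(source: SourceModel, psf: PSFModel, x: np.ndarray):
    """Per-mode intensity profiles d_k(x) on the grid, shape (K, len(x))."""
    basis = source.basis
    s = psf.sigma
    if basis.kind == DELTA_COMB:
        norm = 1.0 / (s * np.sqrt(2.0 * np.pi))
        d = norm * np.exp(-((x[None, :] - basis.positions[:, None]) ** 2) / (2 * s * s))
        return d
    lo, hi = basis.edges[:-1], basis.edges[1:]
    return np.stack([_bin_intensity_1d(x, a, b, s) for a, b in zip(lo, hi)])


def direct_imaging_fim(
    source: SourceModel,
    psf: PSFModel,
    *,
    floor_frac: float = COEFF_FLOOR_FRAC,
    dx: float | None = None,
    margin: float = 6.0,
) -> np.ndarray:
    """Per-photon FIM of ideal (continuum, fine-pixel) direct imaging.

    The fine-pixel limit of the modal FIM is
    I_kl = ∫ d_k(x) d_l(x) / I(x) dx with I(x) the image-plane intensity and
    d_k its per-coefficient components; the intensity PSF is a Gaussian of
    width sigma so everything reduces to erf factors.  Supports 1D and 2D
    (tensor-product) source bases.
    """
    c = floor_coefficients(source.c, floor_frac)
    s = psf.sigma
    if dx is None:
        dx = s / 16.0
    basis = source.basis
    if basis.kind == RECT_2D:
        edges = basis.edges
        span = (edges[0] - margin * s, edges[-1] + margin * s)
        x = np.arange(span[0], span[1] + dx, dx)
        lo, hi = edges[:-1], edges[1:]
        ax = np.stack([_bin_intensity_1d(x, a, b, s) for a, b in zip(lo, hi)])
        n = lo.size
        # d_(kx,ky)(x,y) = ax[kx](x) * ax[ky](y); accumulate FIM over y-slices
        K = n * n
        I_fim = np.zeros((K, K))
        cg = c.reshape(n, n)
        inten_y = np.zeros((x.size, x.size))  # (ix, iy)
        # intensity at (x_i, y_j) = sum_kx ax[kx,i] * (sum_ky c[kx,ky] ax[ky,j])
        right = cg @ ax  # (n_kx, n_y)
        inten = ax.T @ right  # (n_x, n_y)
        inten = np.maximum(inten, 1e-300)
        # FIM_{(kx ky),(lx ly)} = sum_ij ax[kx,i]ax[ky,j]ax[lx,i]ax[ly,j]/inten_ij * dx^2
        # contract via D_{(kx ky), (lx ly)} = sum_i ax[kx,i]ax[lx,i] * M_{..}
        # do it as: for each i, B = ax[:,i]; weight W_j = 1/inten[i,j]
        for i in range(x.size):
            Bx = ax[:, i]  # (n,)
            Wy = (ax / np.sqrt(inten[i])[None, :]) * np.sqrt(dx * dx)
            # columns over j; component matrix C = outer(Bx, ax[:,j])
            Myy = Wy @ Wy.T  # (n, n): sum_j ax[ky,j]ax[ly,j]/inten
            I_fim += np.einsum("k,l,ab->kalb", Bx, Bx, Myy, optimize=True).reshape(K, K)
        return 0.5 * (I_fim + I_fim.T)
    F = direct_imaging_factor(source, psf, floor_frac=floor_frac, dx=dx, margin=margin)
    I_fim = F.T @ F
    return 0.5 * (I_fim + I_fim.T)


def direct_imaging_factor(
    source: SourceModel,
    psf: PSFModel,
    *,
    floor_frac: float = COEFF_FLOOR_FRAC,
    dx: float | None = None,
    margin: float = 6.0,
) -> np.ndarray:
    """Square-root factor of the continuum direct-imaging FIM (1D bases).

    Rows are d_k(x_i) sqrt(dx / I(x_i)) over the image-plane grid, so
    I_direct = F^T F; use :func:`crb_from_factor` on it for accurate CRBs in
    the deep sub-Rayleigh regime.
    """
    if source.basis.kind == RECT_2D:
        raise ValueError("factor form is available for 1D source bases only")
    c = floor_coefficients(source.c, floor_frac)
    s = psf.sigma
    if dx is None:
        dx = s / 16.0
    span = source.basis.extent + margin * s
    x = np.arange(-span, span + dx, dx)
    d = _intensity_components(source, psf, x)
    inten = np.maximum(c @ d, 1e-300)
    return (d / np.sqrt(inten)[None, :]).T * math.sqrt(dx)


# ---------------------------------------------------------------------------
# CRB sweep curves and the resolution-gain summary
# ---------------------------------------------------------------------------


@dataclass
class CrbCurve:
    """Mean-CRB curve over a sweep of a scene-family parameter."""

    sweep: np.ndarray
    mean_crb: np.ndarray
    label: str = ""
    extras: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.sweep, self.mean_crb]),
            delimiter=",",
            header=f"sweep,mean_crb_{self.label or 'curve'}",
            comments="",
        )


def mean_crb_vs_separation(
    make_scene: Callable[[float], SourceModel],
    strategy: str,
    sweep: Sequence[float],
    psf: PSFModel,
    *,
    J: int | None = None,
    n_basis: int | None = None,
    W: np.ndarray | None = None,
    floor_frac: float = COEFF_FLOOR_FRAC,
    optimizer_config=None,
) -> CrbCurve:
    """Per-photon mean CRB at each sweep value for one imaging strategy.

    ``strategy`` is ``"direct"`` (ideal fine-pixel direct imaging) or
    ``"optimized"`` (manifold-optimized modes with ``J`` modes; defaults to
    J = K + 1).  Failed optimizations are recorded as NaN with diagnostics in
    ``extras`` rather than silently interpolated.
    """
    sweep = np.asarray(list(sweep), dtype=float)
    if np.any(sweep <= 0):
        raise ValueError("sweep values must be positive")
    vals = np.full(sweep.size, np.nan)
    extras: dict = {"modes": [], "traces": [], "errors": {}}
    for i, sv in enumerate(sweep):
        scene = make_scene(float(sv))
        if strategy == "direct":
            try:
                F = direct_imaging_factor(scene, psf, floor_frac=floor_frac)
                _, diag = crb_from_factor(F, W)
                vals[i] = diag.mean()
            except SingularFisherError as err:  # pragma: no cover - diagnostics
                extras["errors"][float(sv)] = str(err)
        elif strategy == "optimized":
            from .stiefel import design_modes

            Ji = scene.K + 1 if J is None else J
            try:
                modes, trace = design_modes(
                    scene,
                    Ji,
                    psf,
                    n_basis=n_basis,
                    W=W,
                    floor_frac=floor_frac,
                    config=optimizer_config,
                )
                bundle = FisherBundle.from_source(
                    scene, modes, W=W, floor_frac=floor_frac
                )
                vals[i] = bundle.mean_crb
                extras["modes"].append(modes)
                extras["traces"].append(trace)
            except SingularFisherError as err:
                extras["errors"][float(sv)] = str(err)
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
    return CrbCurve(sweep=sweep, mean_crb=vals, label=strategy, extras=extras)


def _monotone_interp_inverse(sweep, crb, level):
    """Separation at which a decreasing CRB(sweep) curve reaches ``level``.

    Log-log linear interpolation after enforcing a monotone envelope
    (running minimum from the left, i.e. CRB never increases with
    separation)."""
    order = np.argsort(sweep)
    s, v = np.asarray(sweep)[order], np.asarray(crb)[order]
    v = np.minimum.accumulate(v)  # enforce: CRB non-increasing in separation
    if not (v.min() <= level <= v.max()):
        raise ValueError("CRB level outside curve range")
    # xp must increase for interpolation: reverse so log-CRB ascends
    return float(
        np.exp(np.interp(np.log(level), np.log(v[::-1]), np.log(s[::-1])))
    )


def resolution_gain(
    curve_direct: CrbCurve,
    curve_mo: CrbCurve,
    *,
    regime_max: float = 0.5,
) -> float:
    """Equal-CRB separation ratio dx_direct / dx_mo in the deep sub-Rayleigh regime.

    For each optimized sweep point with separation <= ``regime_max`` (in
    sigma) whose CRB level is attainable on the direct curve, the separation
    at which direct imaging reaches the same mean CRB is found by monotone
    log-log interpolation; the largest ratio is returned.  A ratio > 1 means
    optimized modes resolve proportionally finer spacings at equal accuracy.
    """
    s_mo = np.asarray(curve_mo.sweep, float)
    v_mo = np.asarray(curve_mo.mean_crb, float)
    s_d = np.asarray(curve_direct.sweep, float)
    v_d = np.asarray(curve_direct.mean_crb, float)
    ok = np.isfinite(v_mo) & (s_mo <= regime_max + 1e-12)
    lo, hi = np.nanmin(v_d), np.nanmax(v_d)
    ratios = []
    for s, lvl in zip(s_mo[ok], v_mo[ok]):
        if lo <= lvl <= hi:
            ratios.append(_monotone_interp_inverse(s_d, v_d, lvl) / s)
    if not ratios:
        raise ValueError(
            "no overlap between the optimized and direct CRB ranges in the "
            "requested regime"
        )
    return float(max(ratios))
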