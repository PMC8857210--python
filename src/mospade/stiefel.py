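"""CRB minimization over the Stiefel manifold of orthonormal mode sets.

The design objective L(V) = tr(W [I_base + w_N I(c; V)]^-1) is minimized
over M x J matrices V with orthonormal columns (the imaging modes expressed
in the Hermite-Gaussian computation basis).  ``I_base`` is an optional
constant information matrix accumulated from earlier measurement periods
(zero for the single-shot design problem) and ``w_N`` the photon weight of
the period being designed.

The optimizer is a retraction-based Riemannian descent: Euclidean gradient
of L chained through the quadratic dependence of the modal probabilities on
V, projection onto the tangent space, QR retraction back to the manifold,
Barzilai-Borwein step sizes safeguarded by a monotone Armijo backtracking
line search.  Every accepted iterate is feasible to ~1e-15 and the objective
sequence is non-increasing by construction.

Because L depends on V only through the probabilities p_jk, right-multiplying
V by a signed permutation leaves L unchanged; returned mode sets are put in a
canonical gauge (modes sorted by decreasing P_j, sign fixed) so serialized
results are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fisher import (
    COEFF_FLOOR_FRAC,
    P_FLOOR,
    SingularFisherError,
    floor_coefficients,
)
from .optics import (
    HermiteGaussianBasis,
    ImagingModeSet,
    PSFModel,
    recommended_nodes_per_bin,
)
from .sources import SourceModel

__all__ = [
    "OptimizerConfig",
    "OptimizationTrace",
    "CrbObjective",
    "euclidean_gradient",
    "optimize_modes",
    "design_modes",
    "default_basis_for",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Riemannian descent settings.

    Convergence: relative objective change below ``rel_ftol`` over
    ``patience`` consecutive iterations, or Riemannian gradient norm below
    ``gtol``, up to ``max_iters`` iterations.  ``n_restarts`` seeded random
    orthonormal starts are tried in addition to the structured
    initializations; the best final point wins.
    """

    max_iters: int = 2000
    gtol: float = 1e-6
    rel_ftol: float = 1e-8
    patience: int = 5
    armijo_c1: float = 1e-4
    backtrack: float = 0.5
    max_linesearch: int = 40
    n_restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if min(self.gtol, self.rel_ftol) <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class OptimizationTrace:
    objective: list = field(default_factory=list)
    grad_norm: list = field(default_factory=list)
    final_defect: float = np.nan
    converged: bool = False
    n_iters: int = 0
    init_label: str = ""


class CrbObjective:
    """tr(W [I_base + w_N I(c; V)]^-1) and its Euclidean V-gradient.

    Precomputes the node overlap matrix G (N x M), quadrature weights and the
    node->source-mode map; each evaluation is two small GEMMs plus a K x K
    eigen-solve.  Modes whose P_j falls below ``p_floor`` are dropped from
    the information sum (and contribute zero gradient), mirroring the
    classical FIM convention.
    """

    def __init__(
        self,
        G: np.ndarray,
        weights: np.ndarray,
        bin_index: np.ndarray,
        c: np.ndarray,
        *,
        W: np.ndarray | None = None,
        base_fim: np.ndarray | None = None,
        photon_weight: float = 1.0,
        p_floor: float = P_FLOOR,
        ridge: float = 0.0,
    ):
        self.G = np.ascontiguousarray(G)  # (N, M) node overlaps
        self.w = np.asarray(weights, float)
        self.bin_index = np.asarray(bin_index)
        self.K = int(self.bin_index.max()) + 1
        self.starts = np.searchsorted(self.bin_index, np.arange(self.K))
        self.c = np.asarray(c, float)
        if np.any(self.c < 0):
            raise ValueError("evaluation coefficients must be non-negative")
        self.W = W
        self.base = None if base_fim is None else np.asarray(base_fim, float)
        self.photon_weight = float(photon_weight)
        self.p_floor = p_floor
        # fixed Tikhonov ridge on the information matrix: keeps the inverse
        # well defined along badly conditioned transit iterates without
        # biasing the optimum (choose ridge << smallest attainable
        # information eigenvalue; see set_default_ridge)
        self.ridge = float(ridge)

    def set_default_ridge(self, V_ref: np.ndarray, rel: float = 3e-14) -> None:
        """Fix the ridge at ``rel`` times the largest information eigenvalue
        seen at a reference (well-behaved) mode set."""
        I = self.fisher(V_ref)
        lam_max = float(np.linalg.eigvalsh(self._total(I))[-1])
        self.ridge = rel * lam_max

    @property
    def M(self) -> int:
        return self.G.shape[1]

    # -- forward pieces ----------------------------------------------------

    def _p_tensor(self, V: np.ndarray):
        A = self.G @ V  # (N, J)
        pw = (A * A) * self.w[:, None]
        p = np.add.reduceat(pw, self.starts, axis=0)  # (K, J)
        return A, p

    def fisher(self, V: np.ndarray) -> np.ndarray:
        _, p = self._p_tensor(V)
        I, _, _ = self._fisher_from_p(p)
        return I

    def _factor(self, p: np.ndarray):
        """Square-root factor F (J_kept, K) with I = F^T F, plus P and mask.

        Working with the factor instead of the Gram matrix keeps the tiny
        information eigenvalues accurate: an SVD of F resolves
        sigma_min/sigma_max down to round-off, i.e. eigenvalue ratios of
        I down to ~1e-30, where forming I directly floors them at
        ~1e-16 * lambda_max.
        """
        P = self.c @ p  # (J,)
        keep = P > self.p_floor
        F = p[:, keep].T / np.sqrt(P[keep])[:, None]  # (J_kept, K)
        return F, P, keep

    def _fisher_from_p(self, p: np.ndarray):
        F, P, keep = self._factor(p)
        I = F.T @ F
        return 0.5 * (I + I.T), P, keep

    def _total(self, I: np.ndarray) -> np.ndarray:
        It = self.photon_weight * I
        if self.base is not None:
            It = It + self.base
        if self.ridge > 0.0:
            It = It + self.ridge * np.eye(It.shape[0])
        return It

    def _spectral(self, p: np.ndarray):
        """Eigen-pairs (lam, E) of the total information matrix.

        Without accumulated prior information the eigen-pairs come from an
        SVD of the square-root factor (accurate for extreme conditioning);
        with a base FIM the matrices are well conditioned by construction
        and a plain symmetric eigendecomposition is used.
        """
        F, P, keep = self._factor(p)
        if self.base is None:
            # I_tot = w * F^T F + ridge: eigenvectors from the SVD of F
            _, s, Vt = np.linalg.svd(F, full_matrices=False)
            lam = self.photon_weight * s * s
            E = Vt.T
            if lam.size < self.K:  # rank-deficient factor: pad the nullspace
                lamf = np.zeros(self.K)
                lamf[: lam.size] = lam
                Q, _ = np.linalg.qr(
                    np.eye(self.K) - E @ E.T if E.size else np.eye(self.K)
                )
                E = np.column_stack([E, Q[:, : self.K - lam.size]])
                lam = lamf
            lam = lam + self.ridge
        else:
            I, _, _ = self._fisher_from_p(p)
            lam, E = np.linalg.eigh(self._total(I))
        if lam.min() <= 0:
            raise SingularFisherError(int(np.sum(lam <= 0)), self.K)
        return lam, E, P, keep

    def value(self, V: np.ndarray) -> float:
        _, p = self._p_tensor(V)
        lam, E, _, _ = self._spectral(p)
        if self.W is None:
            return float(np.sum(1.0 / lam))
        return float(np.sum((E.T @ self.W @ E).diagonal() / lam))

    def value_and_grad(self, V: np.ndarray):
        A, p = self._p_tensor(V)
        lam, E, P, keep = self._spectral(p)
        if self.W is None:
            L = float(np.sum(1.0 / lam))
            B = (E / (lam * lam)[None, :]) @ E.T
        else:
            inv = (E / lam[None, :]) @ E.T
            L = float(np.sum(self.W * inv.T))
            B = inv @ self.W @ inv
        B = 0.5 * (B + B.T)
        # dL/dp_kj = w_N * (-2 (B p)_kj / P_j + c_k beta_j / P_j^2), beta_j = p_j^T B p_j
        q = np.zeros_like(p)  # (K, J)
        Pk = P[keep]
        pk = p[:, keep]
        Bp = B @ pk
        beta = np.sum(pk * Bp, axis=0)
        qk = -2.0 * Bp / Pk[None, :] + np.outer(self.c, beta / (Pk * Pk))
        q[:, keep] = qk
        q *= self.photon_weight
        # chain to V: grad[:, j] = 2 sum_n w_n q_{k(n), j} A_nj g_n
        R = (self.w[:, None]) * q[self.bin_index, :]  # (N, J)
        grad = 2.0 * self.G.T @ (A * R)
        return L, grad


def euclidean_gradient(V: np.ndarray, objective: CrbObjective) -> np.ndarray:
    """Euclidean gradient dL/dV at a Stiefel point (chained through the
    modal-probability dependence of the Fisher matrix)."""
    return objective.value_and_grad(V)[1]


# ---------------------------------------------------------------------------
# manifold machinery
# ---------------------------------------------------------------------------


def _tangent_project(V: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Project an ambient matrix onto the Stiefel tangent space at V."""
    VtE = V.T @ E
    return E - V @ (0.5 * (VtE + VtE.T))


def _qr_retract(Y: np.ndarray) -> np.ndarray:
    """QR retraction with a sign-fixed R so the map is deterministic."""
    Q, R = np.linalg.qr(Y)
    sgn = np.sign(np.diag(R))
    sgn[sgn == 0] = 1.0
    return Q * sgn[None, :]


def _canonical_gauge(V: np.ndarray, objective: CrbObjective) -> np.ndarray:
    """Sort modes by decreasing P_j and fix each column's sign."""
    _, p = objective._p_tensor(V)
    P = objective.c @ p
    order = np.argsort(-P, kind="stable")
    V = V[:, order]
    peak = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[peak, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs[None, :]


def optimize_modes(
    objective: CrbObjective,
    V0: np.ndarray,
    config: OptimizerConfig | None = None,
    *,
    init_label: str = "",
) -> tuple[np.ndarray, OptimizationTrace]:
    """Monotone Riemannian descent from one feasible starting point.

    Returns a feasible point with objective <= objective(V0) and the
    iteration trace.  If the objective is singular at V0 the start is
    perturbed by a small random tangent step (a handful of attempts) before
    giving up.
    """
    cfg = config or OptimizerConfig()
    V = _qr_retract(np.asarray(V0, float).copy())
    rng = np.random.default_rng(cfg.seed + 99991)
    for attempt in range(6):
        try:
            f, g = objective.value_and_grad(V)
            break
        except SingularFisherError:
            if attempt == 5:
                raise
            V = _qr_retract(V + 1e-3 * rng.standard_normal(V.shape))
    trace = OptimizationTrace(init_label=init_label)
    gr = _tangent_project(V, g)
    gnorm = float(np.linalg.norm(gr))
    trace.objective.append(f)
    trace.grad_norm.append(gnorm)
    step = 1.0 / max(gnorm, 1e-30)
    stall = 0
    for it in range(cfg.max_iters):
        if gnorm <= cfg.gtol:
            trace.converged = True
            break
        accepted = False
        t = step
        for _ in range(cfg.max_linesearch):
            Vn = _qr_retract(V - t * gr)
            try:
                fn = objective.value(Vn)
            except SingularFisherError:
                t *= cfg.backtrack
                continue
            if fn <= f - cfg.armijo_c1 * t * gnorm * gnorm:
                accepted = True
                break
            t *= cfg.backtrack
        if not accepted:
            trace.converged = True  # no descent possible at line-search floor
            break
        _, gn = objective.value_and_grad(Vn)
        grn = _tangent_project(Vn, gn)
        # Barzilai-Borwein step for the next iteration (ambient differences)
        S = Vn - V
        Y = grn - gr
        sy = float(np.sum(S * Y))
        ss = float(np.sum(S * S))
        step = ss / sy if sy > 1e-30 else t * 2.0
        step = float(np.clip(step, 1e-12, 1e6))
        rel = (f - fn) / max(abs(f), 1e-300)
        V, f, gr = Vn, fn, grn
        gnorm = float(np.linalg.norm(gr))
        trace.objective.append(f)
        trace.grad_norm.append(gnorm)
        stall = stall + 1 if rel < cfg.rel_ftol else 0
        if stall >= cfg.patience:
            trace.converged = True
            break
    trace.n_iters = len(trace.objective) - 1
    trace.final_defect = float(np.max(np.abs(V.T @ V - np.eye(V.shape[1]))))
    return V, trace


# ---------------------------------------------------------------------------
# quasi-Newton stage on the polar parametrization
# ---------------------------------------------------------------------------


def _polar_pieces(W: np.ndarray):
    """V = W (W^T W)^{-1/2} together with the eigen-data needed for the
    gradient pullback."""
    S = W.T @ W
    lam, Q = np.linalg.eigh(S)
    lam = np.maximum(lam, 1e-300)
    A = (Q / np.sqrt(lam)[None, :]) @ Q.T  # S^{-1/2}
    return W @ A, A, lam, Q


def _polar_grad(W: np.ndarray, V: np.ndarray, A, lam, Q, E: np.ndarray):
    """Pull the Euclidean gradient E = dL/dV back through V(W).

    Uses the divided-difference (Daleckii-Krein) formula for the derivative
    of S^{-1/2} in the eigenbasis of S = W^T W.
    """
    r = 1.0 / np.sqrt(lam)
    dif = lam[:, None] - lam[None, :]
    ddf = np.where(
        np.abs(dif) > 1e-12 * lam.max(),
        (r[:, None] - r[None, :]) / np.where(dif == 0, 1.0, dif),
        -0.5 * lam[:, None] ** -1.5,
    )
    C = Q.T @ (W.T @ E) @ Q
    Mid = Q @ (ddf * (C + C.T)) @ Q.T
    return E @ A + W @ (0.5 * (Mid + Mid.T))


def _lbfgs_stage(
    objective: CrbObjective,
    V0: np.ndarray,
    max_iters: int,
) -> np.ndarray:
    """Minimize log L over the unconstrained polar parametrization.

    A quasi-Newton stage that copes with the very stiff curvature of CRB
    objectives in the deep sub-Rayleigh regime; the result is re-polished on
    the manifold by the monotone Riemannian descent afterwards.
    """
    from scipy.optimize import minimize

    shape = V0.shape

    def fun(wflat):
        W = wflat.reshape(shape)
        V, A, lam, Q = _polar_pieces(W)
        try:
            f, E = objective.value_and_grad(V)
        except SingularFisherError:
            return np.inf, np.zeros(W.size)
        g = _polar_grad(W, V, A, lam, Q, E)
        return math.log(f), (g / f).ravel()

    res = minimize(
        fun,
        V0.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iters, "maxcor": 30, "ftol": 1e-14, "gtol": 1e-12},
    )
    V, _, _, _ = _polar_pieces(res.x.reshape(shape))
    return _qr_retract(V)


# ---------------------------------------------------------------------------
# initialization and the high-level design entry point
# ---------------------------------------------------------------------------


def default_basis_for(
    source: SourceModel, psf: PSFModel, J: int, n_basis: int | None = None
) -> HermiteGaussianBasis:
    """Computation basis sized for the source extent and mode count.

    Per-axis truncation covers the shifted PSFs over the source support
    (captured energy ~1 - 1e-6 needs M ≳ mu + 7 sqrt(mu), mu = (extent/2s)^2)
    and always exceeds the requested number of modes.
    """
    extent = source.basis.extent
    s = psf.sigma
    mu = (extent / (2.0 * s)) ** 2
    m_extent = int(math.ceil(mu + 7.0 * math.sqrt(mu) + 8))
    if psf.dimension == 1:
        m = max(m_extent, J + 8, 24)
    else:
        m = max(m_extent, int(math.ceil(math.sqrt(J))) + 4, 10)
    if n_basis is not None:
        m = int(n_basis)
    return HermiteGaussianBasis(psf.sigma, m, psf.dimension)


def _init_candidates(source, basis, J, objective, rng, n_restarts):
    """Structured + random orthonormal starting frames, as (label, V0)."""
    M = basis.size
    cands = []
    # density eigenmodes: top-J eigenvectors of the (unnormalized) one-photon state
    Gw = objective.G * (objective.w * objective.c[objective.bin_index])[:, None]
    rho = objective.G.T @ Gw
    lam, E = np.linalg.eigh(0.5 * (rho + rho.T))
    cands.append(("density-eig", E[:, ::-1][:, :J]))
    # PSF-adapted low-order HG modes (the known near-optimal basis for
    # centred sub-Rayleigh scenes)
    cands.append(("hermite", np.eye(M)[:, :J]))
    # matched modes: shifted PSFs at the source-mode centres, QR-completed
    centers = source.basis.centers()
    Gm = basis.point_overlaps(centers)  # (M, K)
    pad = J - Gm.shape[1]
    if pad > 0:
        Gm = np.column_stack([Gm, E[:, ::-1][:, : max(pad, 0)]])
    Q = _qr_retract(Gm[:, :J]) if Gm.shape[1] >= J else None
    if Q is not None and np.linalg.matrix_rank(Gm[:, :J], tol=1e-8) >= J:
        cands.append(("matched", Q))
    for r in range(n_restarts):
        X = rng.standard_normal((M, J))
        cands.append((f"random{r}", _qr_retract(X)))
    return cands


def design_modes(
    source: SourceModel,
    J: int,
    psf: PSFModel,
    *,
    n_basis: int | None = None,
    W: np.ndarray | None = None,
    base_fim: np.ndarray | None = None,
    photon_weight: float = 1.0,
    floor_frac: float = COEFF_FLOOR_FRAC,
    c_eval: np.ndarray | None = None,
    config: OptimizerConfig | None = None,
    basis: HermiteGaussianBasis | None = None,
) -> tuple[ImagingModeSet, OptimizationTrace]:
    """Design a manifold-optimized imaging mode set for a source estimate.

    ``c_eval`` overrides the evaluation coefficients (e.g. a running
    estimate); by default the source's own coefficients, floored, are used.
    Several structured initializations (density eigenmodes, matched shifted
    PSFs) plus seeded random restarts are descended; the best feasible end
    point, in canonical gauge, is returned.
    """
    cfg = config or OptimizerConfig()
    if basis is None:
        basis = default_basis_for(source, psf, J, n_basis)
    if J > basis.size:
        raise ValueError(f"J={J} exceeds basis size {basis.size}")
    c = floor_coefficients(source.c if c_eval is None else c_eval, floor_frac)
    npb = recommended_nodes_per_bin(
        float(source.basis.widths.max(initial=0.0))
        if source.basis.dimension == 1
        else math.sqrt(float(source.basis.widths.max(initial=0.0))),
        basis,
    )
    nodes, wts, idx = source.basis.quadrature(npb)
    G = basis.point_overlaps(nodes).T  # (N, M)
    objective = CrbObjective(
        G,
        wts,
        idx,
        c,
        W=W,
        base_fim=base_fim,
        photon_weight=photon_weight,
    )
    rng = np.random.default_rng(cfg.seed)
    candidates = _init_candidates(source, basis, J, objective, rng, cfg.n_restarts)
    objective.set_default_ridge(candidates[0][1])
    best = None
    polish_cfg = OptimizerConfig(
        max_iters=min(cfg.max_iters, 400),
        gtol=cfg.gtol,
        rel_ftol=cfg.rel_ftol,
        patience=cfg.patience,
        seed=cfg.seed,
    )
    for label, V0 in candidates:
        try:
            V1 = _lbfgs_stage(objective, V0, cfg.max_iters)
            V, trace = optimize_modes(objective, V1, polish_cfg, init_label=label)
        except SingularFisherError:
            continue
        if best is None or trace.objective[-1] < best[1].objective[-1]:
            best = (V, trace)
    if best is None:
        raise SingularFisherError(source.K, source.K)
    V, trace = best
    V = _canonical_gauge(V, objective)
    return ImagingModeSet(basis, V, label=f"mo-spade[J={J}]"), trace
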