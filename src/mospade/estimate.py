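"""Source reconstruction from photon counts by non-negative least squares.

The stacked linear model for an experiment log with records m = 1..R is

    E[n_j^(m)] = N_m sum_k p_jk^(m) c_k,

so the design matrix rows are N_m * p^(m) and the estimate is
c_est = argmin_{c >= 0} || D (A c - y) ||^2 over the stacked counts y, with
D an optional Poisson-variance weighting.  Plain (unweighted) NNLS is the
default estimator; it is biased at low photon numbers — its MSE can fall
below the CRB and saturates at the scale of the source amplitudes — and
tracks the CRB at high photon numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .simulate import ExperimentLog

__all__ = ["Reconstruction", "ErrorReport", "nnls_reconstruct", "mse_report"]


@dataclass(frozen=True)
class Reconstruction:
    """NNLS estimate of the source coefficients."""

    c_est: np.ndarray
    residual_norm: float
    n_records: int
    weighting: str = "none"

    def __post_init__(self) -> None:
        if np.any(self.c_est < 0):
            raise ValueError("NNLS estimates must be non-negative")


@dataclass(frozen=True)
class ErrorReport:
    """Per-coefficient squared error averaged over Monte-Carlo trials."""

    mse_per_coefficient: np.ndarray
    mse: float
    n_trials: int


def nnls_reconstruct(log: ExperimentLog, weighting: str = "none") -> Reconstruction:
    """Estimate source coefficients from all records of an experiment log.

    ``weighting`` is ``"none"`` (plain NNLS) or ``"poisson"``
    (rows scaled by 1/sqrt(max(y, 1)), the usual variance stabilization).
    A rank-deficient stacked design produces a warning naming the
    unidentifiable dimension; the minimum-norm NNLS solution is returned.
    """
    if not log.records:
        raise ValueError("experiment log holds no measurement records")
    blocks = []
    ys = []
    for rec in log.records:
        pt = rec.pt
        if pt is None:
            from .optics import probability_tensor

            pt = probability_tensor(log.source.basis, rec.modes)
        blocks.append(rec.budget * pt.p)
        ys.append(rec.counts.astype(float))
    A = np.vstack(blocks)
    y = np.concatenate(ys)
    if weighting == "poisson":
        d = 1.0 / np.sqrt(np.maximum(y, 1.0))
        A = A * d[:, None]
        y = y * d
    elif weighting != "none":
        raise ValueError(f"unknown weighting {weighting!r}")
    K = A.shape[1]
    rank = np.linalg.matrix_rank(A)
    if rank < K:
        warnings.warn(
            f"stacked design is rank deficient: {K - rank} source-mode "
            "directions are unidentifiable from the measured modes",
            stacklevel=2,
        )
    c_est, rnorm = nnls(A, y)
    return Reconstruction(
        c_est=c_est,
        residual_norm=float(rnorm),
        n_records=len(log.records),
        weighting=weighting,
    )


def mse_report(trials: list[Reconstruction] | list[np.ndarray], c_true: np.ndarray) -> ErrorReport:
    """Mean squared error per coefficient over reconstruction trials."""
    if not trials:
        raise ValueError("need at least one trial")
    c_true = np.asarray(c_true, dtype=float)
    errs = []
    for t in trials:
        c = t.c_est if isinstance(t, Reconstruction) else np.asarray(t, float)
        if c.shape != c_true.shape:
            raise ValueError("estimate/truth dimension mismatch")
        errs.append((c - c_true) ** 2)
    per = np.mean(errs, axis=0)
    return ErrorReport(mse_per_coefficient=per, mse=float(per.mean()), n_trials=len(errs))
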