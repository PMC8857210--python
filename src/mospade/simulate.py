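"""Poisson photon-counting measurement simulation.

Photon detection through a mode sorter is an independent Poisson process per
channel: over a period with mean photon budget N, channel j records
n_j ~ Poisson(N * P_j) with P_j the modal detection probability.  Every
record stores its own seed so a measurement can be replayed bit-exactly; no
global RNG state is used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import ImagingModeSet, ProbabilityTensor, detection_probabilities, probability_tensor
from .sources import SourceModel

__all__ = ["MeasurementRecord", "ExperimentLog", "simulate_counts"]

GAUSSIAN_APPROX_ABOVE = 1e12  # expected counts beyond integer-safe Poisson sampling


@dataclass(frozen=True)
class MeasurementRecord:
    """One measurement period: mode set, counts n_j, photon budget, seed."""

    modes: ImagingModeSet
    counts: np.ndarray
    budget: float
    seed: int
    pt: ProbabilityTensor | None = None  # cached forward tensor for estimation

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (self.modes.J,):
            raise ValueError("one count per imaging mode required")
        if np.any(counts < 0):
            raise ValueError("negative photon counts")
        if not self.budget > 0:
            raise ValueError("photon budget must be positive")
        object.__setattr__(self, "counts", counts.astype(np.int64, copy=False))


@dataclass
class ExperimentLog:
    """Ordered measurement records sharing one scene and PSF context."""

    source: SourceModel
    records: list[MeasurementRecord] = field(default_factory=list)

    def append(self, record: MeasurementRecord) -> None:
        if self.records and not np.isclose(
            record.modes.basis.sigma, self.records[0].modes.basis.sigma
        ):
            raise ValueError("all records must share the same PSF width")
        self.records.append(record)

    @property
    def total_budget(self) -> float:
        return float(sum(r.budget for r in self.records))


def simulate_counts(
    source: SourceModel,
    modes: ImagingModeSet,
    N: float,
    seed: int,
    *,
    pt: ProbabilityTensor | None = None,
) -> MeasurementRecord:
    """Draw one period of Poisson channel counts with mean N * P_j.

    ``N`` is the mean photon number reaching the image plane during the
    period.  Expected counts above 1e12 per channel are drawn from the
    matched Gaussian approximation (rounded, clipped at zero) to stay
    integer-safe.
    """
    if not N > 0:
        raise ValueError("mean photon number must be positive")
    if pt is None:
        pt = probability_tensor(source.basis, modes)
    mean = N * detection_probabilities(source, pt)
    rng = np.random.default_rng(seed)
    counts = np.empty(mean.size, dtype=np.int64)
    small = mean <= GAUSSIAN_APPROX_ABOVE
    counts[small] = rng.poisson(mean[small])
    if np.any(~small):
        big = mean[~small]
        counts[~small] = np.maximum(
            np.rint(rng.normal(big, np.sqrt(big))), 0.0
        ).astype(np.int64)
    return MeasurementRecord(modes=modes, counts=counts, budget=float(N), seed=int(seed), pt=pt)
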