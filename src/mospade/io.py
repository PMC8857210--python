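"""Serialization: HDF5 containers for mode sets and experiment logs, CSV curves.

The HDF5 layout is flat and self-describing so optimized mode sets can be
reloaded bit-exactly:

    /modes/<name>/V          (M, J) coefficient matrix
    /modes/<name>@sigma, @dimension, @n_modes, @label
    /log/record<i>/counts    (J,) int64
    /log/record<i>@budget, @seed, @modes -> name of the mode group
"""

from __future__ import annotations

import numpy as np

from .optics import HermiteGaussianBasis, ImagingModeSet
from .simulate import ExperimentLog

__all__ = [
    "save_modes",
    "load_modes",
    "save_log",
    "modes_to_csv",
    "curves_to_csv",
]


def save_modes(path, modes: ImagingModeSet, name: str = "modes") -> None:
    import h5py

    with h5py.File(path, "a") as fh:
        grp = fh.require_group("modes")
        if name in grp:
            del grp[name]
        ds = grp.create_dataset(name, data=modes.V)
        ds.attrs["sigma"] = modes.basis.sigma
        ds.attrs["dimension"] = modes.basis.dimension
        ds.attrs["n_modes"] = modes.basis.n_modes
        ds.attrs["label"] = modes.label


def load_modes(path, name: str = "modes") -> ImagingModeSet:
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["modes"][name]
        basis = HermiteGaussianBasis(
            float(ds.attrs["sigma"]),
            int(ds.attrs["n_modes"]),
            int(ds.attrs["dimension"]),
        )
        return ImagingModeSet(basis, ds[()], label=str(ds.attrs.get("label", "")))


def save_log(path, log: ExperimentLog) -> None:
    import h5py

    with h5py.File(path, "a") as fh:
        if "log" in fh:
            del fh["log"]
        grp = fh.create_group("log")
        modes_grp = fh.require_group("modes")
        for i, rec in enumerate(log.records):
            name = f"record{i}"
            if name in modes_grp:
                del modes_grp[name]
            md = modes_grp.create_dataset(name, data=rec.modes.V)
            md.attrs["sigma"] = rec.modes.basis.sigma
            md.attrs["dimension"] = rec.modes.basis.dimension
            md.attrs["n_modes"] = rec.modes.basis.n_modes
            md.attrs["label"] = rec.modes.label
            ds = grp.create_dataset(name, data=rec.counts)
            ds.attrs["budget"] = rec.budget
            ds.attrs["seed"] = rec.seed
            ds.attrs["modes"] = name


def modes_to_csv(path, modes: ImagingModeSet) -> None:
    """Small mode sets as CSV: one column per mode over the HG basis."""
    header = ",".join(f"mode{j}" for j in range(modes.J))
    np.savetxt(path, modes.V, delimiter=",", header=header, comments="")


def curves_to_csv(path, sweep, columns: dict) -> None:
    """Sweep curves (mean CRBs, QCRB, ratios ...) as one CSV table."""
    names = list(columns)
    data = np.column_stack([np.asarray(sweep, float)] + [
        np.asarray(columns[n], float) for n in names
    ])
    np.savetxt(
        path, data, delimiter=",", header=",".join(["sweep"] + names), comments=""
    )
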