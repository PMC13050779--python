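"""HDF5 serialization for parameter checkpoints and simulated cohorts."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np

from .core import BIRNNParameters
from .parcel_pipeline import NetworkProjection, ParcelTimeSeries, build_network_projection
from .synthetic import Cohort, CohortSpec

__all__ = [
    "save_checkpoint",
    "load_checkpoint",
    "save_cohort_series",
    "load_cohort_series",
]

_SCALARS = ("beta", "dt")


def save_checkpoint(params: BIRNNParameters, path: str | Path, **attrs) -> None:
    """Write all parameter arrays and scalars to one HDF5 file.

    Extra keyword attributes (seed, config hash, ...) are stored as root
    attributes.
    """
    with h5py.File(path, "w") as f:
        for fld in dataclasses.fields(params):
            v = getattr(params, fld.name)
            if isinstance(v, np.ndarray):
                f.create_dataset(fld.name, data=v)
            else:
                f.attrs[fld.name] = v
        for k, v in attrs.items():
            f.attrs[k] = v


def load_checkpoint(path: str | Path) -> BIRNNParameters:
    with h5py.File(path, "r") as f:
        kw = {}
        for fld in dataclasses.fields(BIRNNParameters):
            if fld.name in f:
                kw[fld.name] = f[fld.name][...]
            else:
                kw[fld.name] = float(f.attrs[fld.name])
    return BIRNNParameters(**kw)


def save_cohort_series(cohort: Cohort, path: str | Path) -> None:
    """Bundle a cohort's series (one dataset per subject/condition, with
    sampling metadata as attributes) plus the membership table."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = cohort.spec.seed
        f.attrs["n_subjects"] = cohort.spec.n_subjects
        mem = f.create_group("membership")
        proj = cohort.projection
        mem.create_dataset(
            "parcel_id", data=np.array(proj.parcel_ids, dtype="S")
        )
        mem.create_dataset(
            "network_name",
            data=np.array([proj.membership[p] for p in proj.parcel_ids], dtype="S"),
        )
        g = f.create_group("series")
        for (sid, condition), ts in cohort.series.items():
            d = g.create_dataset(f"{sid}/{condition}", data=ts.values)
            d.attrs["sampling_rate"] = ts.sampling_rate
            d.attrs["condition"] = condition
            d.attrs["subject_id"] = sid


def load_cohort_series(
    path: str | Path,
) -> tuple[dict[tuple[str, str], ParcelTimeSeries], NetworkProjection]:
    with h5py.File(path, "r") as f:
        pids = [p.decode() for p in f["membership/parcel_id"][...]]
        nets = [n.decode() for n in f["membership/network_name"][...]]
        projection = build_network_projection(dict(zip(pids, nets)))
        out = {}
        for sid in f["series"]:
            for condition in f[f"series/{sid}"]:
                d = f[f"series/{sid}/{condition}"]
                out[(sid, condition)] = ParcelTimeSeries(
                    d[...],
                    tuple(pids),
                    float(d.attrs["sampling_rate"]),
                    sid,
                    condition,
                )
    return out, projection
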