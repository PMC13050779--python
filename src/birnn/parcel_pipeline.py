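"""Parcel-level time series containers, aggregation, and network projections.

The analysis operates on source-localized activity that has already been
reduced to one representative signal per cortical parcel (an atlas-defined
region).  This module provides the container for those series, the
voxel-to-parcel averaging step, the fixed parcel-to-network projection used
by the recurrent model, and a small helper relating the inverse-solution
signal-to-noise assumption to its Tikhonov regularization constant.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "CANONICAL_NETWORKS",
    "ParcelTimeSeries",
    "NetworkProjection",
    "load_parcel_timeseries",
    "write_parcel_timeseries",
    "aggregate_voxels_to_parcels",
    "build_network_projection",
    "aggregate_parcels_to_networks",
    "segment_by_events",
    "inverse_regularization_from_snr",
]

#: Recording conditions recognised by the pipeline: eyes-open rest, the full
#: encoding task, and its two stimulus sub-blocks.
CONDITIONS = ("rest", "task", "task_shapes", "task_words")

#: Canonical ordering of the four large-scale networks.
CANONICAL_NETWORKS = ("DMN", "TPN", "SN", "Other")


class ParcelParseError(ValueError):
    """Raised when a parcel series file contains non-numeric data."""


class ParcelShapeError(ValueError):
    """Raised on parcel-count or ordering mismatches."""


class EmptyParcelError(ValueError):
    """Raised when a parcel has no member voxels."""


@dataclasses.dataclass
class ParcelTimeSeries:
    """Matrix of parcel activities over time with sampling metadata.

    Parameters
    ----------
    values
        Array of shape ``(n_parcels, T)`` in arbitrary source-amplitude units.
    parcel_ids
        Ordered parcel labels, one per row of ``values``.
    sampling_rate
        Samples per second.
    subject_id, condition
        Cohort bookkeeping; ``condition`` must be one of :data:`CONDITIONS`.
    """

    values: np.ndarray
    parcel_ids: tuple[str, ...]
    sampling_rate: float = 1000.0
    subject_id: str = ""
    condition: str = "rest"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.parcel_ids = tuple(str(p) for p in self.parcel_ids)
        if self.values.ndim != 2:
            raise ParcelShapeError("values must be a 2-D (n_parcels, T) array")
        if self.values.shape[0] != len(self.parcel_ids):
            raise ParcelShapeError(
                f"{self.values.shape[0]} rows but {len(self.parcel_ids)} parcel ids"
            )
        if self.values.shape[1] < 2:
            raise ParcelShapeError("need at least two time samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("parcel values must be finite")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class NetworkProjection:
    """Fixed parcel-to-network assignment matrices.

    ``W_in`` (shape ``(n_networks, n_parcels)``) averages member parcels into
    a network signal: row ``k`` holds ``1/|members(k)|`` on member columns and
    zero elsewhere, so each row sums to one and a constant parcel field maps
    to the same constant at network level.  ``W_out_pattern`` is the 0/1
    membership indicator transpose, the template through which network states
    feed back to parcels with uniform within-network weights.
    """

    membership: dict[str, str]
    parcel_ids: tuple[str, ...]
    network_names: tuple[str, ...]
    W_in: np.ndarray
    W_out_pattern: np.ndarray

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def n_networks(self) -> int:
        return len(self.network_names)


def load_parcel_timeseries(
    path: str | Path,
    subject_id: str = "",
    condition: str = "rest",
    sampling_rate: float = 1000.0,
    parcel_ids: Sequence[str] | None = None,
) -> ParcelTimeSeries:
    """Read a parcel series from CSV/TSV (first column ``parcel_id``).

    When ``parcel_ids`` is given the file's rows must match that ordering;
    a mismatch raises :class:`ParcelShapeError`.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError:
        # locate the offending cell so the error is actionable
        for i, (row_label, row) in enumerate(frame.iterrows()):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParcelParseError(
                        f"non-numeric value {cell!r} at row {row_label!r} "
                        f"(index {i}), sample column {j}"
                    ) from None
        raise
    file_ids = tuple(str(i) for i in frame.index)
    if parcel_ids is not None and tuple(parcel_ids) != file_ids:
        raise ParcelShapeError("file parcel ids do not match the expected atlas order")
    return ParcelTimeSeries(values, file_ids, sampling_rate, subject_id, condition)


def write_parcel_timeseries(series: ParcelTimeSeries, path: str | Path) -> None:
    """Write to CSV/TSV; floats use shortest round-trip repr so that
    write-then-read restores values bit exactly."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path, "w") as fh:
        cols = sep.join(str(t) for t in range(series.n_samples))
        fh.write(f"parcel_id{sep}{cols}\n")
        for pid, row in zip(series.parcel_ids, series.values):
            fh.write(pid + sep + sep.join(repr(float(v)) for v in row) + "\n")


def aggregate_voxels_to_parcels(
    voxel_values: np.ndarray,
    voxel_to_parcel: Mapping[int, str] | Sequence[str],
    parcel_ids: Sequence[str] | None = None,
    **series_kwargs,
) -> ParcelTimeSeries:
    """Average member-voxel series into one signal per parcel.

    The parcel signal is the unweighted arithmetic mean of its member voxels
    at every time point.

    Parameters
    ----------
    voxel_values
        ``(n_voxels, T)`` array of voxel-level source time courses.
    voxel_to_parcel
        Either a sequence of parcel labels aligned with voxel rows, or a
        mapping from voxel row index to parcel label.
    parcel_ids
        Output parcel ordering.  Defaults to order of first appearance.
        A listed parcel with no member voxels raises :class:`EmptyParcelError`.
    """
    voxel_values = np.asarray(voxel_values, dtype=float)
    n_voxels = voxel_values.shape[0]
    if isinstance(voxel_to_parcel, Mapping):
        labels = [voxel_to_parcel[v] for v in range(n_voxels)]
    else:
        labels = list(voxel_to_parcel)
    if len(labels) != n_voxels:
        raise ParcelShapeError("voxel_to_parcel length does not match voxel count")
    if parcel_ids is None:
        parcel_ids = list(dict.fromkeys(labels))
    labels_arr = np.asarray(labels)
    rows = []
    for pid in parcel_ids:
        members = labels_arr == pid
        if not members.any():
            raise EmptyParcelError(f"parcel {pid!r} has no member voxels")
        rows.append(voxel_values[members].mean(axis=0))
    return ParcelTimeSeries(np.vstack(rows), tuple(parcel_ids), **series_kwargs)


def build_network_projection(
    membership: Mapping[str, str] | pd.DataFrame,
    network_names: Sequence[str] | None = None,
) -> NetworkProjection:
    """Construct the fixed parcel-to-network projection from a membership table.

    ``membership`` maps parcel id -> network name (or is a two-column frame
    ``parcel_id, network_name``).  Every parcel must be assigned to exactly
    one network; when ``network_names`` is supplied any label outside it is
    rejected.
    """
    if isinstance(membership, pd.DataFrame):
        cols = list(membership.columns)
        membership = dict(
            zip(membership[cols[0]].astype(str), membership[cols[1]].astype(str))
        )
    membership = dict(membership)
    parcel_ids = tuple(membership)
    seen = list(dict.fromkeys(membership.values()))
    if network_names is None:
        if set(seen) <= set(CANONICAL_NETWORKS):
            network_names = tuple(n for n in CANONICAL_NETWORKS if n in seen)
        else:
            network_names = tuple(seen)
    else:
        network_names = tuple(network_names)
        unknown = set(seen) - set(network_names)
        if unknown:
            raise ValueError(f"unknown network label(s): {sorted(unknown)}")
    missing = [p for p, n in membership.items() if n is None or n == ""]
    if missing:
        raise ValueError(f"unassigned parcel(s): {missing}")
    n_par, n_net = len(parcel_ids), len(network_names)
    W_in = np.zeros((n_net, n_par))
    W_out_pattern = np.zeros((n_par, n_net))
    net_index = {n: k for k, n in enumerate(network_names)}
    for p, pid in enumerate(parcel_ids):
        k = net_index[membership[pid]]
        W_in[k, p] = 1.0
        W_out_pattern[p, k] = 1.0
    sizes = W_in.sum(axis=1)
    if np.any(sizes == 0):
        empty = [network_names[k] for k in np.flatnonzero(sizes == 0)]
        raise ValueError(f"network(s) with no member parcels: {empty}")
    W_in /= sizes[:, None]
    return NetworkProjection(membership, parcel_ids, network_names, W_in, W_out_pattern)


def aggregate_parcels_to_networks(
    series: ParcelTimeSeries, projection: NetworkProjection
) -> np.ndarray:
    """Project a parcel series to network space: returns ``(n_networks, T)``.

    Row ``k`` at time ``t`` is the mean over network ``k``'s member parcels.
    """
    if series.parcel_ids != projection.parcel_ids:
        raise ParcelShapeError("series parcel ordering does not match projection")
    return projection.W_in @ series.values


def segment_by_events(
    series: ParcelTimeSeries, events: pd.DataFrame
) -> dict[str, ParcelTimeSeries]:
    """Cut a recording into condition segments from an events table.

    ``events`` has columns ``onset_s, offset_s, label``; segments with the
    same label are concatenated in temporal order.
    """
    out: dict[str, list[np.ndarray]] = {}
    fs = series.sampling_rate
    for _, ev in events.sort_values("onset_s").iterrows():
        a = int(round(ev["onset_s"] * fs))
        b = int(round(ev["offset_s"] * fs))
        out.setdefault(str(ev["label"]), []).append(series.values[:, a:b])
    return {
        label: ParcelTimeSeries(
            np.concatenate(chunks, axis=1),
            series.parcel_ids,
            fs,
            series.subject_id,
            label if label in CONDITIONS else series.condition,
        )
        for label, chunks in out.items()
    }


def inverse_regularization_from_snr(snr: float) -> float:
    """Tikhonov regularization constant for a linear distributed inverse
    solution assuming a given amplitude signal-to-noise ratio: ``1 / snr**2``.

    An assumed SNR of 3.0 yields 0.111 (to three decimals).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    return 1.0 / (snr * snr)
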