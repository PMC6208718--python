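"""Readers and writers for geometries, transfer matrices and recordings.

Canonical internal units are mV and ms.  Recordings round-trip through
HDF5 losslessly and through CSV to 12 significant digits; unit
conversion (mV vs uV) happens only at the I/O boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .geometry import TorsoHeartGeometry, TransferMatrix
from .recording import PotentialRecording

__all__ = [
    "RunConfig",
    "read_recording",
    "write_recording",
    "read_transfer_matrix",
    "write_transfer_matrix",
    "read_geometry",
    "write_geometry",
    "write_isochrones_csv",
]

_UNIT_SCALE = {"mV": 1.0, "uV": 1e-3, "µV": 1e-3}


def _unit_factor(units: str) -> float:
    if units not in _UNIT_SCALE:
        raise ValueError(f"unknown units {units!r}; use 'mV' or 'uV'")
    return _UNIT_SCALE[units]


def write_recording(rec: PotentialRecording, path: str | Path,
                    units: str = "mV") -> None:
    """Write a recording as HDF5 (.h5/.hdf5) or CSV (anything else).

    CSV layout: header row of sample times in ms, then one row per node.
    Values are scaled from internal mV to ``units`` on write.
    """
    path = Path(path)
    scale = 1.0 / _unit_factor(units)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("potentials", data=rec.data * scale)
            f.attrs["fs"] = rec.fs
            f.attrs["units"] = units
    else:
        header = ",".join(f"{t:.6f}" for t in rec.times_ms)
        np.savetxt(path, rec.data * scale, delimiter=",", header=header,
                   comments="", fmt="%.12g")


def read_recording(path: str | Path, units: str = "mV",
                   fs: float | None = None,
                   expected_nodes: int | None = None) -> PotentialRecording:
    """Read a recording written by :func:`write_recording`.

    ``units`` declares the on-disk units (CSV has no metadata); HDF5
    files carry their own units and sampling rate.  Values are converted
    to internal mV.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = f["potentials"][()]
            fs_read = float(f.attrs["fs"])
            factor = _unit_factor(str(f.attrs.get("units", units)))
        rec = PotentialRecording(data * factor, fs=fs_read)
    else:
        raw = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        times = np.loadtxt(path, delimiter=",", max_rows=1)
        if fs is None:
            dt = float(np.diff(np.atleast_1d(times)).mean()) if np.size(times) > 1 else 1.0
            fs = 1000.0 / dt
        rec = PotentialRecording(raw * _unit_factor(units), fs=fs)
    if expected_nodes is not None and rec.n_nodes != expected_nodes:
        raise ValueError(
            f"recording has {rec.n_nodes} rows, expected {expected_nodes}"
        )
    return rec


def write_transfer_matrix(A: TransferMatrix | np.ndarray,
                          path: str | Path) -> None:
    """Write a transfer matrix as HDF5 (.h5/.hdf5) or CSV."""
    entries = A.entries if isinstance(A, TransferMatrix) else np.asarray(A, float)
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("transfer", data=entries)
    else:
        np.savetxt(path, entries, delimiter=",", fmt="%.17g")


def read_transfer_matrix(path: str | Path,
                         geometry: TorsoHeartGeometry | None = None
                         ) -> TransferMatrix:
    """Read a transfer matrix; validates finiteness and geometry shape."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            entries = f["transfer"][()]
    else:
        entries = np.loadtxt(path, delimiter=",", ndmin=2)
    return TransferMatrix(entries=entries, geometry=geometry)


def write_geometry(geom: TorsoHeartGeometry, path: str | Path) -> None:
    """Write a geometry as a JSON sidecar with explicit node arrays."""
    payload = {
        "heart_nodes": geom.heart_nodes.tolist(),
        "torso_nodes": geom.torso_nodes.tolist(),
        "heart_faces": geom.heart_faces.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_geometry(path: str | Path) -> TorsoHeartGeometry:
    payload = json.loads(Path(path).read_text())
    return TorsoHeartGeometry(
        heart_nodes=np.asarray(payload["heart_nodes"], dtype=float),
        torso_nodes=np.asarray(payload["torso_nodes"], dtype=float),
        heart_faces=np.asarray(payload["heart_faces"], dtype=int),
    )


def write_isochrones_csv(iso, geometry: TorsoHeartGeometry,
                         path: str | Path) -> None:
    """Export an isochrone map as CSV (node, x, y, z, AT, RT, quality)."""
    q = iso.activation_ms.size
    rt = iso.recovery_ms if iso.recovery_ms is not None else np.full(q, np.nan)
    at_q = (iso.activation_quality if iso.activation_quality is not None
            else np.full(q, np.nan))
    rt_q = (iso.recovery_quality if iso.recovery_quality is not None
            else np.full(q, np.nan))
    rows = np.column_stack([
        np.arange(q), geometry.heart_nodes, iso.activation_ms, rt, at_q, rt_q,
    ])
    header = "node_id,x_mm,y_mm,z_mm,activation_ms,recovery_ms,at_slope_mv_ms,rt_slope_mv_ms"
    np.savetxt(path, rows, delimiter=",", header=header, comments="",
               fmt=["%d"] + ["%.12g"] * 7)


@dataclass
class RunConfig:
    """Configuration for a CLI run (paths, parameters, seeds, units)."""

    geometry: str | None = None
    transfer: str | None = None
    recording: str | None = None
    output_dir: str = "."
    units: str = "mV"
    wavelet: str = "db2"
    levels: int = 3
    lam: float = 100.0
    alpha: float = 0.9
    grouping: str = "node-rows"
    tol: float = 1e-8
    max_iter: int = 10000
    alpha_grid: list = field(default_factory=lambda: [0.0, 0.25, 0.5, 0.75, 1.0])
    lambda_grid: list = field(default_factory=lambda: [0.1, 1.0, 10.0, 100.0, 1000.0])
    smoothing: float | None = None
    qrs_window: tuple | None = None
    t_window: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        _unit_factor(self.units)
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        for name in ("geometry", "transfer", "recording"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)
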