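"""File I/O: volumetric maps (TIFF / NIfTI), traces (CSV + JSON sidecar), YAML.

Volumes round-trip losslessly with their voxel size; a volume file without
voxel-size metadata is rejected explicitly rather than silently defaulted.
Traces are two-column CSV (time, value) with a JSON sidecar carrying the
sampling rate and any protocol metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

from .signals import TimeSeries


class VolumeFormatError(ValueError):
    """A volume file is malformed or lacks required metadata."""


class TraceFormatError(ValueError):
    """A trace file or its sidecar is malformed."""


def write_volume(path, data: np.ndarray, voxel_edge_um: float) -> Path:
    """Write a 3-D map as a multi-page TIFF (.tif) or NIfTI (.nii/.nii.gz).

    The voxel edge (um) is stored in the file metadata and restored by
    :func:`read_volume`.
    """
    path = Path(path)
    data = np.asarray(data)
    if data.ndim != 3:
        raise VolumeFormatError("volume must be a 3-D array")
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, data, metadata={"voxel_edge_um": float(voxel_edge_um)})
    elif path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        edge_mm = voxel_edge_um / 1000.0
        affine = np.diag([edge_mm, edge_mm, edge_mm, 1.0])
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
        img.header.set_zooms((edge_mm, edge_mm, edge_mm))
        nib.save(img, path)
    else:
        raise VolumeFormatError(f"unsupported volume format: {path.name}")
    return path


def read_volume(path) -> tuple[np.ndarray, float]:
    """Read a volume written by :func:`write_volume`; returns (data, edge_um)."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if "voxel_edge_um" not in meta:
            raise VolumeFormatError(f"{path.name}: missing voxel_edge_um metadata")
        return np.asarray(data), float(meta["voxel_edge_um"])
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        img = nib.load(path)
        zooms = img.header.get_zooms()[:3]
        if not zooms or zooms[0] <= 0:
            raise VolumeFormatError(f"{path.name}: missing or invalid voxel size")
        return np.asarray(img.get_fdata()), float(zooms[0] * 1000.0)
    raise VolumeFormatError(f"unsupported volume format: {path.name}")


def write_trace(path_csv, ts: TimeSeries, metadata: dict | None = None) -> Path:
    """Write a trace as (time, value) CSV plus a JSON sidecar (same stem)."""
    path_csv = Path(path_csv)
    t = ts.times()
    np.savetxt(path_csv, np.column_stack([t, ts.samples]), delimiter=",",
               header="time_s,value", comments="")
    sidecar = {"rate_hz": ts.rate_hz, "start_time_s": ts.start_time_s,
               "channel_label": ts.channel_label}
    if metadata:
        sidecar.update(metadata)
    path_csv.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path_csv


def read_trace(path_csv) -> tuple[TimeSeries, dict]:
    """Read a CSV + sidecar trace; returns (TimeSeries, full sidecar dict)."""
    path_csv = Path(path_csv)
    sidecar_path = path_csv.with_suffix(".json")
    if not sidecar_path.exists():
        raise TraceFormatError(f"missing sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("rate_hz",):
        if key not in meta:
            raise TraceFormatError(f"{sidecar_path.name}: missing field {key!r}")
    arr = np.loadtxt(path_csv, delimiter=",", skiprows=1, ndmin=2)
    if arr.shape[1] != 2:
        raise TraceFormatError(f"{path_csv.name}: expected two columns (time, value)")
    ts = TimeSeries(samples=arr[:, 1], rate_hz=float(meta["rate_hz"]),
                    start_time_s=float(meta.get("start_time_s", 0.0)),
                    channel_label=str(meta.get("channel_label", "")))
    return ts, meta


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def dump_yaml(path, data: dict) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path
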