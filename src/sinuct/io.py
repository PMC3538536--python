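"""TIFF / JSON / HDF5 serialization helpers.

All volumes and image stacks travel as multipage TIFF plus JSON sidecars so
every artifact of a run is inspectable with standard imaging tools.  A full
projection set can also be bundled into a single HDF5 container.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

__all__ = [
    "write_stack",
    "read_stack",
    "write_json",
    "read_json",
    "write_projection_set",
    "read_projection_set",
    "write_projection_set_hdf5",
    "read_projection_set_hdf5",
]


def write_stack(path: str | Path, array: np.ndarray) -> Path:
    """Write a 2D image or 3D stack as (multipage) TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array), photometric="minisblack")
    return path


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _geometry_to_dict(geometry) -> dict:
    return dataclasses.asdict(geometry)


def write_projection_set(pset, directory: str | Path) -> Path:
    """Write projections/flats/darks TIFF stacks + geometry JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_stack(directory / "projections.tif", pset.projections.astype(np.float32))
    write_stack(directory / "flats.tif", pset.flats.astype(np.float32))
    write_stack(directory / "darks.tif", pset.darks.astype(np.float32))
    write_json(
        directory / "geometry.json",
        {"geometry": _geometry_to_dict(pset.geometry), "angles_deg": list(map(float, pset.angles))},
    )
    return directory


def read_projection_set(directory: str | Path):
    from .optics import AcquisitionGeometry, ProjectionSet

    directory = Path(directory)
    meta = read_json(directory / "geometry.json")
    geometry = AcquisitionGeometry(**meta["geometry"])
    return ProjectionSet(
        projections=read_stack(directory / "projections.tif").astype(np.float64),
        flats=read_stack(directory / "flats.tif").astype(np.float64),
        darks=read_stack(directory / "darks.tif").astype(np.float64),
        angles=np.asarray(meta["angles_deg"], dtype=np.float64),
        geometry=geometry,
    )


def write_projection_set_hdf5(pset, path: str | Path) -> Path:
    """Single-file HDF5 container for a full projection set."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("projections", data=pset.projections, compression="gzip")
        f.create_dataset("flats", data=pset.flats, compression="gzip")
        f.create_dataset("darks", data=pset.darks, compression="gzip")
        f.create_dataset("angles_deg", data=np.asarray(pset.angles, dtype=np.float64))
        f.attrs["geometry"] = json.dumps(_geometry_to_dict(pset.geometry))
    return path


def read_projection_set_hdf5(path: str | Path):
    from .optics import AcquisitionGeometry, ProjectionSet

    with h5py.File(path, "r") as f:
        geometry = AcquisitionGeometry(**json.loads(f.attrs["geometry"]))
        return ProjectionSet(
            projections=f["projections"][...],
            flats=f["flats"][...],
            darks=f["darks"][...],
            angles=f["angles_deg"][...],
            geometry=geometry,
        )
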