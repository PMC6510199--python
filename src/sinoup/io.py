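"""Tomogram containers, projection/sinogram conversion, and HDF5/TIFF I/O.

A tomogram can be held either as a stack of projections — one transmission
image per rotation angle, array axes ``(angle, height, width)`` — or as a
stack of sinograms — one angle-vs-detector image per sample height, axes
``(height, angle, width)``.  Both hold the same pixels; converting between
them is a lossless axis permutation.  Sinogram space is the working
representation for angular upsampling, since the axis being upsampled (the
projection angle) is then a plain image axis.

Files follow the NeXus-flavoured HDF5 layout used at synchrotron beamlines:
a single 3-D dataset (default ``/entry/data/data``) plus a 1-D ``angles``
dataset in degrees.  The reader supports height-sliced partial reads so a
full volume never has to be memory-resident.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

DEFAULT_DATASET = "/entry/data/data"
ANGLES_DATASET = "/entry/data/angles"

#: Allowed provenance tags for a sinogram stack.
PROVENANCES = ("noiseless", "noisy", "upscaled", "downscaled")


def _check_3d_finite(data: np.ndarray, what: str) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"{what} must be a 3-D array, got rank {data.ndim}")
    if not np.isfinite(data).all():
        raise ValueError(f"{what} contains non-finite values")
    return data


@dataclass
class ProjectionStack:
    """Projection-ordered tomogram: ``data[t]`` is the image at ``angles[t]``.

    Axes are ``(angle, height, width)``; values are attenuation line
    integrals or normalized transmission intensities — the toolkit treats
    them as given.
    """

    data: np.ndarray
    angles: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = _check_3d_finite(self.data, "projection stack")
        if self.angles is None:
            self.angles = np.linspace(0.0, 180.0, self.data.shape[0])
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.angles.shape != (self.data.shape[0],):
            raise ValueError(
                f"angles has length {self.angles.size}, expected one per "
                f"projection ({self.data.shape[0]})"
            )

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]


@dataclass
class SinogramStack:
    """Sinogram-ordered tomogram: ``data[h]`` is the (angle × width) sinogram
    at sample height ``h``."""

    data: np.ndarray
    angles: np.ndarray = field(default=None)  # type: ignore[assignment]
    provenance: str = "noiseless"

    def __post_init__(self) -> None:
        self.data = _check_3d_finite(self.data, "sinogram stack")
        if self.angles is None:
            self.angles = np.linspace(0.0, 180.0, self.data.shape[1])
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.angles.shape != (self.data.shape[1],):
            raise ValueError(
                f"angles has length {self.angles.size}, expected one per "
                f"sinogram row ({self.data.shape[1]})"
            )
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_heights(self) -> int:
        return self.data.shape[0]

    @property
    def n_angles(self) -> int:
        return self.data.shape[1]


def projections_to_sinograms(p: ProjectionStack, provenance: str = "noiseless") -> SinogramStack:
    """Permute ``(angle, height, width)`` to ``(height, angle, width)``.

    Sinogram ``h`` collects, over all projections in capture order, the
    detector row at height ``h``; the permutation is lossless.
    """
    return SinogramStack(np.ascontiguousarray(p.data.transpose(1, 0, 2)),
                         angles=p.angles.copy(), provenance=provenance)


def sinograms_to_projections(s: SinogramStack) -> ProjectionStack:
    """Inverse of :func:`projections_to_sinograms` (bit-exact round trip)."""
    return ProjectionStack(np.ascontiguousarray(s.data.transpose(1, 0, 2)),
                           angles=s.angles.copy())


def write_tomogram_hdf5(stack: ProjectionStack | SinogramStack, path: str | Path,
                        dataset_path: str = DEFAULT_DATASET,
                        angles_path: str = ANGLES_DATASET) -> None:
    """Store a stack as 32-bit floats plus its per-projection angles.

    The dataset attribute ``layout`` records the axis order (``"proj"`` or
    ``"sino"``) so the file is self-describing.
    """
    layout = "proj" if isinstance(stack, ProjectionStack) else "sino"
    with h5py.File(path, "w") as f:
        d = f.create_dataset(dataset_path, data=stack.data.astype(np.float32))
        d.attrs["layout"] = layout
        if layout == "sino":
            d.attrs["provenance"] = stack.provenance
        f.create_dataset(angles_path, data=np.asarray(stack.angles, dtype=np.float64))


def read_tomogram_hdf5(path: str | Path, dataset_path: str = DEFAULT_DATASET,
                       layout: str | None = None,
                       angles_path: str = ANGLES_DATASET,
                       heights: slice | None = None,
                       skip_first_row: bool = False) -> ProjectionStack | SinogramStack:
    """Load a tomogram (or a height slice of one) from HDF5.

    Parameters
    ----------
    layout
        ``"proj"`` or ``"sino"``; if ``None`` the dataset's ``layout``
        attribute is used (default ``"sino"`` when absent).
    heights
        Optional slice of sample heights to read; only the selected
        hyperslab is fetched from disk.
    skip_first_row
        Drop the first height.  Real beamline files sometimes carry
        metadata in their first sinogram; this flag excludes it instead of
        hard-coding that convention.  Ignored when ``heights`` is given
        (explicit slices are taken literally).
    """
    with h5py.File(path, "r") as f:
        if dataset_path not in f:
            raise KeyError(f"dataset {dataset_path!r} not found in {path}")
        ds = f[dataset_path]
        if ds.ndim != 3:
            raise ValueError(f"dataset {dataset_path!r} has rank {ds.ndim}, expected 3")
        if layout is None:
            layout = ds.attrs.get("layout", "sino")
        if layout not in ("proj", "sino"):
            raise ValueError(f"unknown layout {layout!r}")
        height_axis = 1 if layout == "proj" else 0
        sel: list[slice] = [slice(None)] * 3
        if heights is not None:
            sel[height_axis] = heights
        data = ds[tuple(sel)]
        if skip_first_row and heights is None:
            sel2: list[slice] = [slice(None)] * 3
            sel2[height_axis] = slice(1, None)
            data = data[tuple(sel2)]
        provenance = ds.attrs.get("provenance", "noiseless")
        angles = f[angles_path][()] if angles_path in f else None
    if layout == "proj":
        return ProjectionStack(data, angles=angles)
    return SinogramStack(data, angles=angles, provenance=provenance)


def export_tiff(image: np.ndarray, path: str | Path) -> None:
    """Write a single 2-D image (sinogram or reconstruction) as float32 TIFF."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got rank {image.ndim}")
    tifffile.imwrite(path, image.astype(np.float32))


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
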