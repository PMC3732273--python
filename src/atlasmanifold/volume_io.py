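"""Volumetric containers and NIfTI-1 I/O.

Label maps are binary 3-D volumes; displacement fields are stored as 4-D
volumes whose last axis holds a 3-vector per voxel, in millimetres, in the
image's physical axis frame.  The mid-sagittal flip used to mirror an atlas
library lives here too: it reverses voxel order along the sagittal
(left-right) axis and, for a displacement field, additionally negates the
vector component along that axis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterator, List, Optional, Sequence, Tuple, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import GridMismatchError

__all__ = [
    "VoxelGrid",
    "LabelMap",
    "DisplacementField",
    "AtlasEntry",
    "AtlasLibrary",
    "read_label_map",
    "write_label_map",
    "read_displacement_field",
    "write_displacement_field",
    "flip_mid_sagittal",
    "load_library_dir",
    "save_library_dir",
]

_SPACING_TOL_MM = 1e-6


@dataclass(frozen=True)
class VoxelGrid:
    """A regular voxel grid with physical spacing.

    ``sagittal_axis`` designates the voxel axis that runs left-right; the
    mid-sagittal flip operates along it.  ``None`` means no axis is
    designated and flipping raises.
    """

    dims: Tuple[int, int, int]
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    sagittal_axis: Optional[int] = 0

    def __post_init__(self):
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        if self.sagittal_axis is not None and self.sagittal_axis not in (0, 1, 2):
            raise ValueError("sagittal_axis must be 0, 1, 2 or None")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def matches(self, other: "VoxelGrid", spacing_tol: float = _SPACING_TOL_MM) -> bool:
        return self.dims == other.dims and all(
            abs(a - b) <= spacing_tol for a, b in zip(self.spacing, other.spacing)
        )

    def require_match(self, other: "VoxelGrid") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"grids differ: dims {self.dims} vs {other.dims}, "
                f"spacing {self.spacing} vs {other.spacing}"
            )


@dataclass(frozen=True)
class LabelMap:
    """Binary 3-D segmentation on a voxel grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.shape != self.grid.dims:
            raise ValueError(f"values shape {v.shape} != grid dims {self.grid.dims}")
        u = np.unique(v)
        if not np.isin(u, (0, 1)).all():
            raise ValueError(f"label values must be 0/1, found {u[:10]}")
        object.__setattr__(self, "values", v.astype(np.uint8))

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class DisplacementField:
    """Per-voxel 3-vector (mm) relating an image to the average atlas."""

    grid: VoxelGrid
    vectors: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.shape != self.grid.dims + (3,):
            raise ValueError(
                f"vectors shape {v.shape} != grid dims + (3,) = {self.grid.dims + (3,)}"
            )
        if not np.isfinite(v).all():
            raise ValueError("displacement field contains non-finite entries")
        object.__setattr__(self, "vectors", v)


def _grid_from_nifti(img: nib.Nifti1Image) -> VoxelGrid:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    sag = 0
    try:
        codes = nib.orientations.aff2axcodes(img.affine)
        for i, c in enumerate(codes[:3]):
            if c in ("L", "R"):
                sag = i
                break
    except Exception:  # malformed affine: fall back to the first axis
        sag = 0
    return VoxelGrid(dims=img.shape[:3], spacing=zooms, origin=origin, sagittal_axis=sag)


def read_label_map(path: Union[str, os.PathLike], reference_grid: Optional[VoxelGrid] = None) -> LabelMap:
    """Read a 3-D NIfTI volume and binarize it (any nonzero voxel -> 1)."""
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D label volume, got shape {data.shape}")
    grid = _grid_from_nifti(img)
    if reference_grid is not None:
        reference_grid.require_match(grid)
        grid = reference_grid
    return LabelMap(grid=grid, values=(data != 0).astype(np.uint8))


def write_label_map(lm: LabelMap, path: Union[str, os.PathLike]) -> None:
    img = nib.Nifti1Image(lm.values.astype(np.uint8), lm.grid.affine)
    img.header.set_zooms(lm.grid.spacing)
    nib.save(img, os.fspath(path))


def read_displacement_field(
    path: Union[str, os.PathLike], reference_grid: Optional[VoxelGrid] = None
) -> DisplacementField:
    """Read a 4-D NIfTI volume (last axis length 3) as a displacement field."""
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI "vector" convention (x,y,z,1,3)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"expected a 4-D volume with a length-3 component axis, got shape {data.shape}"
        )
    grid = _grid_from_nifti(img)
    if reference_grid is not None:
        reference_grid.require_match(grid)
        grid = reference_grid
    return DisplacementField(grid=grid, vectors=np.asarray(data, dtype=np.float64))


def write_displacement_field(f: DisplacementField, path: Union[str, os.PathLike]) -> None:
    img = nib.Nifti1Image(f.vectors.astype(np.float64), f.grid.affine)
    img.header.set_zooms(f.grid.spacing + (1.0,))
    nib.save(img, os.fspath(path))


def flip_mid_sagittal(x: Union[LabelMap, DisplacementField]):
    """Mirror a volume across the mid-sagittal plane.

    Voxel order is reversed along the grid's sagittal axis; a displacement
    field additionally has its sagittal vector component negated so the
    mirrored field is geometrically consistent.  Involution: applying the
    flip twice returns the original object.
    """
    axis = x.grid.sagittal_axis
    if axis is None:
        raise ValueError("grid designates no sagittal axis; cannot flip")
    if isinstance(x, LabelMap):
        return LabelMap(grid=x.grid, values=np.flip(x.values, axis=axis).copy())
    if isinstance(x, DisplacementField):
        v = np.flip(x.vectors, axis=axis).copy()
        v[..., axis] *= -1.0
        return DisplacementField(grid=x.grid, vectors=v)
    raise TypeError(f"cannot flip object of type {type(x).__name__}")


@dataclass(frozen=True)
class AtlasEntry:
    id: str
    label_map: LabelMap
    field: DisplacementField
    laterality: str = "native"  # "native" | "flipped"
    subject_id: Optional[str] = None

    def __post_init__(self):
        if self.laterality not in ("native", "flipped"):
            raise ValueError(f"laterality must be 'native' or 'flipped', got {self.laterality!r}")
        self.label_map.grid.require_match(self.field.grid)


@dataclass
class AtlasLibrary:
    """A set of atlases (label map + displacement field) on one shared grid."""

    entries: List[AtlasEntry] = field(default_factory=list)

    def __post_init__(self):
        entries = list(self.entries)
        self.entries = []
        for e in entries:
            self.add(e)

    @property
    def grid(self) -> VoxelGrid:
        if not self.entries:
            raise ValueError("empty library has no grid")
        return self.entries[0].label_map.grid

    @property
    def ids(self) -> List[str]:
        return [e.id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[AtlasEntry]:
        return iter(self.entries)

    def __getitem__(self, i: int) -> AtlasEntry:
        return self.entries[i]

    def add(self, entry: AtlasEntry) -> None:
        if self.entries:
            if not self.grid.matches(entry.label_map.grid):
                raise GridMismatchError(
                    f"entry {entry.id!r} is not on the library grid "
                    f"({entry.label_map.grid.dims} vs {self.grid.dims})"
                )
            if entry.id in set(self.ids):
                raise ValueError(f"duplicate atlas id {entry.id!r}")
        self.entries.append(entry)

    def index_of(self, atlas_id: str) -> int:
        for i, e in enumerate(self.entries):
            if e.id == atlas_id:
                return i
        raise KeyError(atlas_id)

    def subset(self, indices: Sequence[int]) -> "AtlasLibrary":
        return AtlasLibrary(entries=[self.entries[i] for i in indices])

    def with_flipped(self, suffix: str = "_flipped") -> "AtlasLibrary":
        """Return a library doubled by appending mid-sagittally flipped copies.

        Flipped entries inherit the native sibling's ``subject_id`` so a
        leave-one-out fold can exclude both sides of one subject.
        """
        lib = AtlasLibrary(entries=list(self.entries))
        for e in list(self.entries):
            lib.add(
                AtlasEntry(
                    id=e.id + suffix,
                    label_map=flip_mid_sagittal(e.label_map),
                    field=flip_mid_sagittal(e.field),
                    laterality="flipped",
                    subject_id=e.subject_id,
                )
            )
        return lib

    def fields_array(self) -> np.ndarray:
        """All displacement fields stacked as an (n, nx, ny, nz, 3) array."""
        return np.stack([e.field.vectors for e in self.entries])

    def labels_array(self) -> np.ndarray:
        return np.stack([e.label_map.values for e in self.entries])


_MANIFEST = "manifest.tsv"


def save_library_dir(library: AtlasLibrary, out_dir: Union[str, os.PathLike]) -> None:
    """Write a library as NIfTI files plus a manifest.tsv index."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for e in library:
        lbl = f"{e.id}_label.nii.gz"
        fld = f"{e.id}_field.nii.gz"
        write_label_map(e.label_map, os.path.join(out_dir, lbl))
        write_displacement_field(e.field, os.path.join(out_dir, fld))
        rows.append(
            {
                "id": e.id,
                "subject_id": e.subject_id if e.subject_id is not None else "",
                "laterality": e.laterality,
                "label_path": lbl,
                "field_path": fld,
            }
        )
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, _MANIFEST), sep="\t", index=False)


def load_library_dir(in_dir: Union[str, os.PathLike]) -> AtlasLibrary:
    in_dir = os.fspath(in_dir)
    df = pd.read_csv(os.path.join(in_dir, _MANIFEST), sep="\t", keep_default_na=False)
    lib = AtlasLibrary()
    ref = None
    for _, row in df.iterrows():
        lm = read_label_map(os.path.join(in_dir, row["label_path"]), reference_grid=ref)
        if ref is None:
            ref = lm.grid
        fld = read_displacement_field(os.path.join(in_dir, row["field_path"]), reference_grid=ref)
        lib.add(
            AtlasEntry(
                id=str(row["id"]),
                label_map=lm,
                field=fld,
                laterality=str(row["laterality"]) or "native",
                subject_id=str(row["subject_id"]) or None,
            )
        )
    return lib
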