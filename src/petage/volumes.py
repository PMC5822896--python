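"""Volume/atlas data model, NIfTI and tabular I/O, mask algebra and region statistics.

All images in a run are assumed co-registered to a single common grid (the
analysis operates entirely post spatial normalisation), so no world-space
affine math is performed: voxel indices are 0-based array indices and the
only geometric metadata kept is the voxel spacing in millimetres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "Volume",
    "Mask",
    "RegionInfo",
    "LabelAtlas",
    "SubjectRecord",
    "Cohort",
    "GridMismatchError",
    "EmptyMaskError",
    "read_volume_stack",
    "write_volume_stack",
    "read_atlas",
    "write_atlas",
    "read_subjects_table",
    "write_subjects_table",
    "region_mask",
    "mean_in_mask",
    "gaussian_smooth",
    "fwhm_to_sigma",
]

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian kernel.
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


class GridMismatchError(ValueError):
    """Two objects that must share a voxel grid do not."""


class EmptyMaskError(ValueError):
    """An operation that needs at least one masked voxel got an empty mask."""


@dataclass(frozen=True)
class VolumeGrid:
    """A regular 3D voxel grid: shape in voxels and isotropic-or-not spacing in mm."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be 3 positive reals, got {self.spacing_mm}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def affine(self) -> np.ndarray:
        """Diagonal voxel-to-mm affine (no rotation; all inputs share one grid)."""
        return np.diag([*self.spacing_mm, 1.0])


def _check_same_grid(a: VolumeGrid, b: VolumeGrid, what: str) -> None:
    if a != b:
        raise GridMismatchError(f"{what}: grids differ ({a} vs {b})")


@dataclass
class Volume:
    """A scalar field on a :class:`VolumeGrid` (image intensity, arbitrary units)."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    def copy(self) -> "Volume":
        return Volume(self.grid, self.values.copy())


@dataclass
class Mask:
    """A binary {0,1} indicator on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    indicator: np.ndarray

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator)
        if ind.shape != self.grid.shape:
            raise ValueError(f"indicator shape {ind.shape} does not match grid {self.grid.shape}")
        if ind.dtype != bool:
            uniq = np.unique(ind)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask indicator must contain only 0/1 values")
            ind = ind.astype(bool)
        self.indicator = ind

    @property
    def voxel_count(self) -> int:
        return int(self.indicator.sum())

    def __and__(self, other: "Mask") -> "Mask":
        _check_same_grid(self.grid, other.grid, "mask intersection")
        return Mask(self.grid, self.indicator & other.indicator)

    def __or__(self, other: "Mask") -> "Mask":
        _check_same_grid(self.grid, other.grid, "mask union")
        return Mask(self.grid, self.indicator | other.indicator)

    def issubset(self, other: "Mask") -> bool:
        _check_same_grid(self.grid, other.grid, "mask comparison")
        return bool(np.all(~self.indicator | other.indicator))

    def dice(self, other: "Mask") -> float:
        """Dice overlap coefficient 2|A∩B| / (|A|+|B|)."""
        _check_same_grid(self.grid, other.grid, "Dice")
        denom = self.voxel_count + other.voxel_count
        if denom == 0:
            return 0.0
        return 2.0 * float((self.indicator & other.indicator).sum()) / denom


@dataclass(frozen=True)
class RegionInfo:
    region_id: int
    name: str
    is_reference_candidate: bool = False


@dataclass
class LabelAtlas:
    """Integer-labelled parcellation (0 = background) with a region table."""

    grid: VolumeGrid
    labels: np.ndarray
    regions: list[RegionInfo]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.shape != self.grid.shape:
            raise ValueError(f"labels shape {lab.shape} does not match grid {self.grid.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("atlas labels must be integers")
            lab = np.round(lab).astype(np.int32)
        if lab.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        self.labels = lab
        ids = [r.region_id for r in self.regions]
        if len(ids) != len(set(ids)):
            raise ValueError("region ids must be unique")
        declared = set(ids)
        present = set(int(v) for v in np.unique(lab)) - {0}
        missing = present - declared
        if missing:
            raise ValueError(f"labels present in volume but not declared: {sorted(missing)}")

    @property
    def region_ids(self) -> set[int]:
        return {r.region_id for r in self.regions}

    def region_name(self, region_id: int) -> str:
        for r in self.regions:
            if r.region_id == region_id:
                return r.name
        raise KeyError(region_id)

    def brain_mask(self) -> Mask:
        return Mask(self.grid, self.labels > 0)


_MISSING_OK = ("edu", "apoe4", "mmse", "cdrsb", "fdg")


@dataclass
class SubjectRecord:
    """One row of the subjects table; clinical fields may be missing (NaN) for
    healthy-control-only cohorts."""

    id: str
    age: float
    sex: str
    group: str = "HC"
    edu: float = np.nan
    apoe4: float = np.nan
    mmse: float = np.nan
    cdrsb: float = np.nan
    fdg: float = np.nan

    def __post_init__(self) -> None:
        self.age = float(self.age)
        if not np.isfinite(self.age) or self.age < 0:
            raise ValueError(f"age must be finite and non-negative, got {self.age}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.group not in ("HC", "AD"):
            raise ValueError(f"group must be 'HC' or 'AD', got {self.group!r}")


@dataclass
class Cohort:
    """Subjects table aligned 1:1 with a stack of same-grid volumes.

    The image stack is held as one (n_subjects, *grid.shape) float array;
    ``images`` exposes per-subject :class:`Volume` views onto it.
    """

    subjects: list[SubjectRecord]
    grid: VolumeGrid
    stack: np.ndarray

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=np.float64)
        if self.stack.ndim != 4 or self.stack.shape[1:] != self.grid.shape:
            raise ValueError(
                f"stack shape {self.stack.shape} incompatible with grid {self.grid.shape}"
            )
        if len(self.subjects) != self.stack.shape[0]:
            raise ValueError(
                f"{len(self.subjects)} subjects but {self.stack.shape[0]} volumes"
            )
        ids = [s.id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValueError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def images(self) -> list[Volume]:
        return [Volume(self.grid, v) for v in self.stack]

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects], dtype=float)

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.subjects])

    def subset(self, index: np.ndarray) -> "Cohort":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        subs = [self.subjects[int(i)] for i in index]
        return Cohort(subs, self.grid, self.stack[index])


# ---------------------------------------------------------------------------
# NIfTI I/O


def _grid_from_nifti(img: nib.Nifti1Image) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(tuple(img.shape[:3]), tuple(float(z) for z in zooms))


def read_volume_stack(path: str | Path) -> list[Volume]:
    """Read a 3D or 4D NIfTI file as an ordered list of same-grid volumes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # nibabel raises several format-specific types
        raise ValueError(f"could not read NIfTI file {path}: {exc}") from exc
    grid = _grid_from_nifti(img)
    if data.ndim == 3:
        return [Volume(grid, data)]
    if data.ndim == 4:
        return [Volume(grid, data[..., i]) for i in range(data.shape[3])]
    raise ValueError(f"{path}: expected 3D or 4D image, got {data.ndim}D")


def read_stack_array(path: str | Path) -> tuple[VolumeGrid, np.ndarray]:
    """Like :func:`read_volume_stack` but returns (grid, (n, x, y, z) array)."""
    vols = read_volume_stack(path)
    grid = vols[0].grid
    return grid, np.stack([v.values for v in vols], axis=0)


def write_volume_stack(path: str | Path, volumes: list[Volume] | np.ndarray,
                       grid: VolumeGrid | None = None) -> None:
    """Write volumes as a single-file .nii/.nii.gz (float32 on disk)."""
    if isinstance(volumes, np.ndarray):
        if grid is None:
            raise ValueError("grid required when writing a bare array")
        data = volumes
    else:
        grids = {v.grid for v in volumes}
        if len(grids) != 1:
            raise GridMismatchError("volumes in a stack must share one grid")
        grid = volumes[0].grid
        data = np.stack([v.values for v in volumes], axis=0)
    arr = np.moveaxis(np.asarray(data, dtype=np.float32), 0, -1)
    if arr.shape[-1] == 1:
        arr = arr[..., 0]
    img = nib.Nifti1Image(arr, grid.affine())
    img.header.set_zooms(grid.spacing_mm + ((1.0,) if arr.ndim == 4 else ()))
    nib.save(img, str(Path(path)))


def write_atlas(nii_path: str | Path, tsv_path: str | Path, atlas: LabelAtlas) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), atlas.grid.affine())
    img.header.set_zooms(atlas.grid.spacing_mm)
    nib.save(img, str(Path(nii_path)))
    df = pd.DataFrame(
        {
            "region_id": [r.region_id for r in atlas.regions],
            "name": [r.name for r in atlas.regions],
            "is_reference_candidate": [int(r.is_reference_candidate) for r in atlas.regions],
        }
    )
    df.to_csv(tsv_path, sep="\t", index=False)


def read_atlas(nii_path: str | Path, tsv_path: str | Path) -> LabelAtlas:
    img = nib.load(str(nii_path))
    labels = np.asarray(img.dataobj)
    grid = _grid_from_nifti(img)
    df = pd.read_csv(tsv_path, sep="\t")
    # iterate rows explicitly: a column literally named "name" collides with
    # the namedtuple attribute in itertuples()
    regions = [
        RegionInfo(int(r["region_id"]), str(r["name"]),
                   bool(int(r.get("is_reference_candidate", 0))))
        for _, r in df.iterrows()
    ]
    return LabelAtlas(grid, labels, regions)


# ---------------------------------------------------------------------------
# Subjects table I/O

_TABLE_COLUMNS = ["id", "age", "sex", "group", "edu", "apoe4", "mmse", "cdrsb", "fdg"]


def write_subjects_table(path: str | Path, subjects: list[SubjectRecord] | pd.DataFrame) -> None:
    """TSV with header; missing values written as empty fields."""
    if isinstance(subjects, pd.DataFrame):
        df = subjects[_TABLE_COLUMNS]
    else:
        df = pd.DataFrame([dataclasses.asdict(s) for s in subjects])[_TABLE_COLUMNS]
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_subjects_table(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subjects table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in _TABLE_COLUMNS}
        for c in _MISSING_OK:
            if pd.isna(kwargs[c]):
                kwargs[c] = np.nan
        records.append(SubjectRecord(**kwargs))
    return records


# ---------------------------------------------------------------------------
# Mask algebra and region statistics


def region_mask(atlas: LabelAtlas, region_ids: set[int] | list[int] | tuple[int, ...]) -> Mask:
    """Binary mask of all voxels whose label is in ``region_ids``."""
    region_ids = set(int(i) for i in region_ids)
    unknown = region_ids - atlas.region_ids
    if unknown:
        raise KeyError(f"unknown atlas region id(s): {sorted(unknown)}")
    if not region_ids:
        return Mask(atlas.grid, np.zeros(atlas.grid.shape, dtype=bool))
    ind = np.isin(atlas.labels, sorted(region_ids))
    return Mask(atlas.grid, ind)


def mean_in_mask(img: Volume, m: Mask) -> float:
    """Arithmetic mean of image intensity over the masked voxels."""
    _check_same_grid(img.grid, m.grid, "mean_in_mask")
    if m.voxel_count == 0:
        raise EmptyMaskError("mean over an empty mask is undefined")
    return float(img.values[m.indicator].mean())


def fwhm_to_sigma(fwhm_mm: float, spacing_mm: float) -> float:
    """Convert a kernel FWHM in mm to a Gaussian sigma in voxel units."""
    return fwhm_mm / FWHM_FACTOR / spacing_mm


def gaussian_smooth(img: Volume, fwhm_mm: float | tuple[float, float, float]) -> Volume:
    """Separable Gaussian smoothing with per-axis FWHM given in millimetres.

    sigma = FWHM / (2*sqrt(2 ln 2)) per axis, converted to voxel units via the
    grid spacing. Boundaries are mirrored (reflect); fwhm 0 is the identity.
    """
    if np.isscalar(fwhm_mm):
        fwhm = (float(fwhm_mm),) * 3
    else:
        fwhm = tuple(float(f) for f in fwhm_mm)
    if len(fwhm) != 3 or any(f < 0 for f in fwhm):
        raise ValueError(f"fwhm must be 3 non-negative reals, got {fwhm_mm}")
    sigmas = [fwhm_to_sigma(f, s) for f, s in zip(fwhm, img.grid.spacing_mm)]
    if all(s == 0 for s in sigmas):
        return img.copy()
    smoothed = ndimage.gaussian_filter(img.values, sigma=sigmas, mode="reflect")
    return Volume(img.grid, smoothed)
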