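"""Reading and writing SLI image stacks and parameter maps.

An SLI stack is a series of 2D images, one per illumination azimuth, stored
here in the canonical in-memory layout ``(row, column, angle)``.  Angular
metadata (step between azimuths, azimuth of the first image, rotation
sense) travels in a JSON sidecar ``<stem>.meta.json`` next to the image
file; defaults match the standard measurement: 15-deg steps starting at
twelve o'clock, rotating clockwise.

Supported stack containers: multi-page TIFF (pages are angles in
acquisition order), NIfTI-1, and HDF5 (dataset ``/stack``).  Parameter maps
are written as 32-bit float single-page TIFFs (optionally NIfTI), with
sentinel values (-1 for direction maps, NaN elsewhere) preserved
bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "BadInputError",
    "StackMetadata",
    "SLIStack",
    "MapImage",
    "DIRECTION_SENTINEL",
    "sidecar_path",
    "read_stack",
    "write_stack",
    "write_maps",
    "read_map",
]

#: Sentinel for undefined pixels in direction maps (valid directions live in
#: [0, 180), so -1 is unambiguous and survives float I/O exactly).
DIRECTION_SENTINEL = -1.0


class BadInputError(ValueError):
    """Raised for unreadable, malformed, or inconsistent input files."""


@dataclass(frozen=True)
class StackMetadata:
    """Angular and spatial metadata of an SLI stack.

    ``step_deg`` is the azimuth increment between consecutive images,
    ``start_deg`` the azimuth of the first image (0 = twelve o'clock) and
    ``clockwise`` the rotation sense of the illumination.  ``pixel_size_um``
    is the physical pixel size in object space, if known.
    """

    step_deg: float = 15.0
    start_deg: float = 0.0
    clockwise: bool = True
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if self.step_deg <= 0:
            raise BadInputError("step_deg must be positive")
        ratio = 360.0 / self.step_deg
        if abs(ratio - round(ratio)) > 1e-9:
            raise BadInputError(f"360 is not divisible by step {self.step_deg}")

    @property
    def n_angles(self) -> int:
        return int(round(360.0 / self.step_deg))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StackMetadata":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class SLIStack:
    """A full SLI measurement: intensities with axes (row, column, angle)."""

    data: np.ndarray
    meta: StackMetadata

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", arr)
        if arr.ndim != 3:
            raise BadInputError(f"stack must be 3D, got shape {arr.shape}")
        n_ang = arr.shape[2]
        if n_ang < 6:
            raise BadInputError(f"angle count < 6 (got {n_ang})")
        if abs(n_ang * self.meta.step_deg - 360.0) > 1e-9:
            raise BadInputError(
                f"{n_ang} angles x {self.meta.step_deg} deg step != 360 deg"
            )
        if not np.all(np.isfinite(arr)):
            raise BadInputError("stack contains non-finite intensities")
        if arr.min() < 0:
            raise BadInputError("stack contains negative intensities")

    @property
    def shape_spatial(self) -> tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]

    @property
    def n_angles(self) -> int:
        return self.data.shape[2]


@dataclass
class MapImage:
    """One named 2D parameter map with an explicit undefined-value sentinel."""

    data: np.ndarray
    name: str
    undefined_sentinel: float = float("nan")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ValueError(f"map '{self.name}' must be 2D")

    @property
    def defined_mask(self) -> np.ndarray:
        if np.isnan(self.undefined_sentinel):
            return ~np.isnan(self.data)
        return self.data != self.undefined_sentinel


def sidecar_path(path: Path | str) -> Path:
    """Path of the JSON metadata sidecar for a stack file.

    ``stack.tif -> stack.meta.json``; the double suffix of ``.nii.gz`` is
    stripped as one.
    """
    path = Path(path)
    stem = path.name
    for suffix in (".nii.gz", ".tif", ".tiff", ".nii", ".h5", ".hdf5"):
        if stem.lower().endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    else:
        stem = path.stem
    return path.with_name(stem + ".meta.json")


def _load_volume(path: Path) -> np.ndarray:
    """Read a 3D volume in canonical (row, column, angle) order."""
    name = path.name.lower()
    try:
        if name.endswith((".tif", ".tiff")):
            pages = tifffile.imread(path)  # (angle, row, col) for multi-page
            if pages.ndim == 2:
                raise BadInputError(f"{path}: single-page TIFF is not a stack")
            return np.moveaxis(pages, 0, -1)
        if name.endswith((".nii", ".nii.gz")):
            img = nib.load(str(path))
            return np.asarray(img.dataobj)
        if name.endswith((".h5", ".hdf5")):
            with h5py.File(path, "r") as f:
                if "stack" not in f:
                    raise BadInputError(f"{path}: no '/stack' dataset")
                return f["stack"][()]
    except (OSError, ValueError) as exc:
        if isinstance(exc, BadInputError):
            raise
        raise BadInputError(f"cannot read stack from {path}: {exc}") from exc
    raise BadInputError(f"unsupported stack format: {path}")


def read_stack(
    path: Path | str, meta_override: StackMetadata | None = None
) -> SLIStack:
    """Read an SLI stack with its angular metadata.

    Metadata precedence: JSON sidecar if present, else ``meta_override``,
    else the defaults (15-deg steps from twelve o'clock, clockwise).

    Raises
    ------
    BadInputError
        For unreadable files, fewer than 6 angles, an angle count that does
        not tile 360 deg at the metadata step, or negative intensities.
    """
    path = Path(path)
    if not path.exists():
        raise BadInputError(f"no such file: {path}")
    data = _load_volume(path)
    side = sidecar_path(path)
    if side.exists():
        try:
            meta = StackMetadata.from_dict(json.loads(side.read_text()))
        except (json.JSONDecodeError, TypeError) as exc:
            raise BadInputError(f"bad metadata sidecar {side}: {exc}") from exc
    elif meta_override is not None:
        meta = meta_override
    else:
        meta = StackMetadata()
    return SLIStack(data=data, meta=meta)


def write_stack(stack: SLIStack, path: Path | str) -> Path:
    """Write a stack (and its metadata sidecar) to TIFF, NIfTI, or HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = path.name.lower()
    data32 = stack.data.astype(np.float32)
    if name.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, np.moveaxis(data32, -1, 0),
                         photometric="minisblack")
    elif name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(data32, affine=np.eye(4)), str(path))
    elif name.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("stack", data=data32)
    else:
        raise BadInputError(f"unsupported stack format: {path}")
    sidecar_path(path).write_text(
        json.dumps(stack.meta.to_dict(), indent=1, sort_keys=True)
    )
    return path


def write_maps(
    maps: dict[str, MapImage] | list[MapImage],
    out_dir: Path | str,
    prefix: str = "slix",
    also_nifti: bool = False,
) -> list[Path]:
    """Write parameter maps as float32 single-page TIFFs.

    Files are named ``<prefix>_<mapname>.tif``; sentinel values pass
    through bit-exactly.  With ``also_nifti`` each map is additionally
    written as NIfTI-1.
    """
    if isinstance(maps, dict):
        maps = list(maps.values())
    if not maps:
        raise ValueError("no maps to write")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise BadInputError(f"cannot create output directory {out_dir}: {exc}")
    paths: list[Path] = []
    for m in maps:
        target = out_dir / f"{prefix}_{m.name}.tif"
        tifffile.imwrite(target, m.data.astype(np.float32),
                         photometric="minisblack")
        paths.append(target)
        if also_nifti:
            nii = out_dir / f"{prefix}_{m.name}.nii"
            nib.save(nib.Nifti1Image(m.data.astype(np.float32), np.eye(4)), str(nii))
            paths.append(nii)
    return paths


def read_map(path: Path | str, name: str | None = None,
             undefined_sentinel: float = float("nan")) -> MapImage:
    """Read a single-page float map written by :func:`write_maps`."""
    path = Path(path)
    if not path.exists():
        raise BadInputError(f"no such file: {path}")
    name_l = path.name.lower()
    if name_l.endswith((".tif", ".tiff")):
        data = tifffile.imread(path)
    elif name_l.endswith((".nii", ".nii.gz")):
        data = np.asarray(nib.load(str(path)).dataobj)
    else:
        raise BadInputError(f"unsupported map format: {path}")
    return MapImage(data=data, name=name or path.stem,
                    undefined_sentinel=undefined_sentinel)
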