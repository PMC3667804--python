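"""Volumetric I/O and voxel/atlas-coordinate geometry.

All images are NIfTI-1 with a *diagonal* affine: millimetre coordinate =
``origin + index * voxel_size`` with 0-based voxel indices (corner
convention).  Oblique affines are out of scope — the synthetic generator
controls its own geometry and writes axis-aligned grids only.

The repetition time is carried in the NIfTI header time-axis spacing
(``pixdim[4]``), seconds.  Per-run labels (rat id, condition, dummy-scan
count) travel in the cohort manifest CSV, not in the image header.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DimensionalityError, GeometryError, MetadataError

__all__ = [
    "VolumeGeometry",
    "BoldRun",
    "RoiSpec",
    "default_seeds",
    "read_run",
    "write_run",
    "read_labels",
    "write_labels",
    "read_manifest",
    "write_manifest",
    "roi_to_voxels",
]

#: Tolerance (in voxel units) when flooring a mm coordinate to an index, so
#: that coordinates lying exactly on a voxel boundary land deterministically
#: in the voxel that starts there despite float rounding.
_EDGE_TOL = 1e-6


@dataclass(frozen=True)
class VolumeGeometry:
    """Axis-aligned voxel grid embedded in atlas millimetre space."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise GeometryError(f"grid shape must be 3 positive integers, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise GeometryError(f"voxel sizes must be positive, got {self.voxel_size_mm}")

    def voxel_to_mm(self, ijk) -> np.ndarray:
        """Millimetre coordinate of voxel corner ``origin + ijk * voxel_size``."""
        return np.asarray(self.origin_mm) + np.asarray(ijk) * np.asarray(self.voxel_size_mm)

    def mm_to_voxel(self, xyz_mm) -> tuple[int, int, int]:
        """0-based index of the voxel containing a mm coordinate (floor rule)."""
        u = (np.asarray(xyz_mm, dtype=float) - np.asarray(self.origin_mm)) / np.asarray(
            self.voxel_size_mm
        )
        idx = np.floor(u + _EDGE_TOL).astype(int)
        return tuple(int(i) for i in idx)

    def contains_index(self, ijk) -> bool:
        return all(0 <= int(i) < int(s) for i, s in zip(ijk, self.shape))

    def contains_mm(self, xyz_mm) -> bool:
        return self.contains_index(self.mm_to_voxel(xyz_mm))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff


@dataclass
class BoldRun:
    """One rat-session 4D BOLD time series with its grid geometry.

    ``data`` is ``(x, y, z, t)`` in arbitrary signal units.  The first
    ``n_dummy`` frames are pre-steady-state volumes still present in the
    array; :func:`lffconn.preprocess.drop_dummies` removes them.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    tr_s: float
    n_dummy: int = 0
    rat_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DimensionalityError(
                f"BOLD run must be 4D (x, y, z, t), got {self.data.ndim}D"
            )
        if self.tr_s <= 0:
            raise MetadataError(f"repetition time must be positive, got {self.tr_s}")
        if self.n_dummy < 0:
            raise MetadataError(f"dummy-scan count must be >= 0, got {self.n_dummy}")
        if self.data.shape[3] < self.n_dummy + 2:
            raise DimensionalityError(
                f"time axis ({self.data.shape[3]}) must be >= n_dummy + 2 "
                f"({self.n_dummy + 2})"
            )

    @property
    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(self.data.shape[:3], self.voxel_size_mm, self.origin_mm)

    @property
    def n_volumes(self) -> int:
        """Number of steady-state (non-dummy) volumes."""
        return self.data.shape[3] - self.n_dummy

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    def replace(self, **kw) -> "BoldRun":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class RoiSpec:
    """A small seed region: atlas-space centre plus in-plane pixel extent.

    The default extent is the study convention of a 2x2-pixel, single-slice
    seed block.
    """

    name: str
    center_mm: tuple[float, float, float]
    extent_px: tuple[int, int, int] = (2, 2, 1)
    hemisphere: str = "L"
    region: str = "SI"

    def __post_init__(self) -> None:
        if any(int(e) < 1 for e in self.extent_px):
            raise GeometryError(f"ROI extent must be >= 1 per axis, got {self.extent_px}")
        if self.hemisphere not in ("L", "R"):
            raise GeometryError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")

    def mirrored(self) -> "RoiSpec":
        """Homotopic partner: X negated, hemisphere flipped."""
        x, y, z = self.center_mm
        hemi = "R" if self.hemisphere == "L" else "L"
        name = self.name.replace(f"_{self.hemisphere}", f"_{hemi}")
        if name == self.name:
            name = f"{self.name}_{hemi}"
        return RoiSpec(name, (-x, y, z), self.extent_px, hemi, self.region)


#: Stereotaxic seed coordinates (mm): left primary somatosensory cortex and
#: left hippocampus.
SI_SEED_MM = (-4.2, -2.2, -0.2)
HP_SEED_MM = (-4.8, -2.4, -0.4)


def default_seeds() -> dict[str, RoiSpec]:
    """The two left-hemisphere 2x2-pixel seeds used throughout the pipeline."""
    return {
        "SI_L": RoiSpec("SI_L", SI_SEED_MM, (2, 2, 1), "L", "SI"),
        "Hp_L": RoiSpec("Hp_L", HP_SEED_MM, (2, 2, 1), "L", "Hp"),
    }


def roi_to_voxels(roi: RoiSpec, geometry: VolumeGeometry) -> np.ndarray:
    """Voxel indices of an ROI block, shape ``(n, 3)``.

    The block's corner is the voxel containing ``center_mm`` (floor rule).
    Along X the block extends *medially* — toward the midline — from the seed
    voxel (+x for a left seed, -x for a right seed), so that negating the X
    coordinate of a seed on a left/right symmetric grid yields exactly the
    mirrored voxel set.  Along Y and Z it extends in +index direction.
    """
    if not geometry.contains_mm(roi.center_mm):
        raise GeometryError(
            f"ROI {roi.name!r} centre {roi.center_mm} mm falls outside the grid"
        )
    vx, vy, vz = geometry.mm_to_voxel(roi.center_mm)
    ex, ey, ez = (int(e) for e in roi.extent_px)
    if roi.hemisphere == "L":
        xs = range(vx, vx + ex)
    else:
        xs = range(vx - ex + 1, vx + 1)
    idx = np.array([(x, y, z) for x in xs for y in range(vy, vy + ey) for z in range(vz, vz + ez)])
    for ijk in idx:
        if not geometry.contains_index(ijk):
            raise GeometryError(
                f"ROI {roi.name!r} block extends outside the grid at index {tuple(ijk)}"
            )
    return idx


# ---------------------------------------------------------------------------
# NIfTI-1 reading/writing


def _check_diagonal_affine(affine: np.ndarray, path) -> None:
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0):
        raise GeometryError(f"{path}: oblique affines are not supported")
    if np.any(np.diag(rot) <= 0):
        raise GeometryError(f"{path}: affine must have positive diagonal voxel sizes")


def write_run(run: BoldRun, path) -> Path:
    """Write a 4D run as NIfTI-1, with TR in the header time-axis spacing.

    The array dtype is preserved, so write/read round trips are bit-exact.
    """
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(run.data), run.geometry.affine)
    img.header.set_zooms(tuple(run.voxel_size_mm) + (float(run.tr_s),))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def read_run(
    path,
    rat_id: str = "",
    condition: str = "",
    n_dummy: int = 0,
    scale10: bool = False,
) -> BoldRun:
    """Read a 4D NIfTI run.

    Parameters
    ----------
    scale10
        Apply the rodent-to-human-template size convention: voxel sizes and
        origin are multiplied by 10 on read.  Correlation statistics are
        unchanged; only mm-denominated quantities (kernel widths, ROI
        coordinates) are reinterpreted.  Off by default.
    """
    path = Path(path)
    img = nib.load(str(path))
    if img.ndim != 4:
        raise DimensionalityError(f"{path}: expected a 4D time series, got {img.ndim}D")
    _check_diagonal_affine(img.affine, path)
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if not np.isfinite(tr) or tr <= 0:
        raise MetadataError(
            f"{path}: repetition time missing or invalid in header field pixdim[4]"
        )
    scale = 10.0 if scale10 else 1.0
    voxel = tuple(float(v) * scale for v in np.diag(img.affine)[:3])
    origin = tuple(float(o) * scale for o in img.affine[:3, 3])
    data = np.asarray(img.dataobj)
    return BoldRun(
        data=data,
        voxel_size_mm=voxel,
        origin_mm=origin,
        tr_s=tr,
        n_dummy=n_dummy,
        rat_id=rat_id,
        condition=condition,
    )


def write_labels(labels: np.ndarray, geometry: VolumeGeometry, path) -> Path:
    """Write an integer label/mask volume as 3D NIfTI-1."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), geometry.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def read_labels(path) -> tuple[np.ndarray, VolumeGeometry]:
    path = Path(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D label volume, got {img.ndim}D")
    _check_diagonal_affine(img.affine, path)
    geometry = VolumeGeometry(
        tuple(int(s) for s in img.shape),
        tuple(float(v) for v in np.diag(img.affine)[:3]),
        tuple(float(o) for o in img.affine[:3, 3]),
    )
    return np.asarray(img.dataobj).astype(int), geometry


# ---------------------------------------------------------------------------
# Session manifest

MANIFEST_COLUMNS = ["rat_id", "condition", "path", "is_outlier", "n_dummy", "groundtruth_path"]


def write_manifest(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"manifest is missing columns {missing}")
    df.loc[:, MANIFEST_COLUMNS].to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"rat_id": str, "condition": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"{path}: manifest is missing columns {missing}")
    df["is_outlier"] = df["is_outlier"].astype(bool)
    df["n_dummy"] = df["n_dummy"].astype(int)
    return df
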