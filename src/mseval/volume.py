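"""Binary segmentation volumes on a shared voxel grid.

All masks evaluated together (manual raters, automatic algorithms, the
consensus) must live on the same grid — the reference space in which
delineation happened. No resampling is ever performed: a grid mismatch is
an error, never silently fixed, because interpolating a binary mask would
change the very overlap quantities being measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "BinaryVolume",
    "GridMismatchError",
    "MaskFormatError",
    "read_mask",
    "write_mask",
    "assert_same_grid",
]

#: relative tolerance for spacing equality between volumes of one case
SPACING_RTOL = 1e-5


class MaskFormatError(ValueError):
    """The file is not a readable 3-D segmentation volume."""


class GridMismatchError(ValueError):
    """Volumes of one case do not share dimensions and voxel spacing."""


@dataclass
class BinaryVolume:
    """A 3-D boolean occupancy grid with physical voxel spacing in mm.

    Parameters
    ----------
    occupancy
        3-D boolean array; any truthy voxel is lesion (foreground).
    spacing
        Voxel size in mm along each axis, all strictly positive.
    affine
        4x4 voxel-to-physical mapping. Defaults to a diagonal scaling by
        ``spacing``; only the spacing enters distance computations.
    case_id, performer_id
        Free-text provenance labels carried through reports.
    """

    occupancy: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    case_id: str = ""
    performer_id: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy)
        if self.occupancy.ndim != 3:
            raise MaskFormatError(
                f"expected a 3-D occupancy grid, got ndim={self.occupancy.ndim}"
            )
        self.occupancy = self.occupancy != 0
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_foreground(self) -> int:
        return int(self.occupancy.sum())

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()

    def volume_mm3(self) -> float:
        """Total foreground volume in mm^3."""
        return self.n_foreground * self.voxel_volume_mm3

    def with_occupancy(self, occupancy: np.ndarray, **meta) -> "BinaryVolume":
        """A copy of this volume carrying a new occupancy grid."""
        kwargs = dict(
            spacing=self.spacing,
            affine=self.affine.copy(),
            case_id=self.case_id,
            performer_id=self.performer_id,
        )
        kwargs.update(meta)
        return BinaryVolume(occupancy=occupancy, **kwargs)


def read_mask(path: str | Path, case_id: str = "", performer_id: str = "") -> BinaryVolume:
    """Read a NIfTI mask; any nonzero voxel becomes foreground.

    Annotation tools save lesion labels with varying conventions (1, 255,
    per-lesion integers); all nonzero values are treated as lesion.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise MaskFormatError(f"cannot read {path}: {exc}") from exc
    if data.ndim != 3:
        raise MaskFormatError(
            f"{path}: expected a 3-D volume, got shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return BinaryVolume(
        occupancy=data != 0,
        spacing=spacing,
        affine=np.asarray(img.affine, dtype=float),
        case_id=case_id or path.parent.name,
        performer_id=performer_id or path.name.split(".")[0],
    )


def write_mask(vol: BinaryVolume, path: str | Path) -> None:
    """Write a mask as NIfTI with values {0, 1} and the volume's spacing."""
    path = Path(path)
    img = nib.Nifti1Image(vol.occupancy.astype(np.uint8), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def assert_same_grid(vols: list[BinaryVolume]) -> None:
    """Check that all volumes share dimensions and voxel spacing.

    Raises
    ------
    GridMismatchError
        Naming the first offending volume. Spacings are compared with a
        relative tolerance of ``SPACING_RTOL``; dimensions must be exact.
    """
    if not vols:
        raise ValueError("empty volume list")
    ref = vols[0]
    for v in vols[1:]:
        who = v.performer_id or v.case_id or "<unnamed>"
        if v.shape != ref.shape:
            raise GridMismatchError(
                f"volume {who!r}: shape {v.shape} != reference {ref.shape}"
            )
        if not np.allclose(v.spacing, ref.spacing, rtol=SPACING_RTOL, atol=0.0):
            raise GridMismatchError(
                f"volume {who!r}: spacing {v.spacing} != reference {ref.spacing}"
            )
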