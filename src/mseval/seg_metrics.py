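"""Voxel-overlap and surface-distance segmentation metrics.

Overlap scores (Dice, positive predictive value, sensitivity, specificity)
compare an evaluated segmentation A against a reference G voxelwise.
Specificity needs a bounded evaluation region B: on a whole head volume the
overwhelming background would pin every specificity at ~1. B is built as
the union of all available segmentations of the case dilated three times
with the 6-connectivity (face-neighbour) kernel, so true negatives are
counted only in the neighbourhood where anyone marked lesion.

The average symmetric surface distance (ASSD) averages, over both boundary
point sets, the minimal Euclidean distance to the other boundary:

    S = ( sum_{i in A_S} d(x_i, G_S) + sum_{j in G_S} d(x_j, A_S) ) / (N_A + N_G)

with distances in physical mm (voxel anisotropy folded into the distance
transform). Boundary voxels are foreground voxels with at least one
background 6-neighbour or grid-edge contact; distances are between voxel
centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volume import BinaryVolume, assert_same_grid

__all__ = [
    "ConfusionCounts",
    "OverlapReport",
    "SurfacePointSet",
    "build_eval_region",
    "overlap_counts",
    "overlap_metrics",
    "extract_surface",
    "average_surface_distance",
    "evaluate_pair",
]

#: 6-connectivity structuring element (face neighbours only)
CROSS_6 = ndi.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel counts underlying the overlap metrics."""

    n_intersection: int  # |A ∩ G|
    n_a_only: int        # |A \ G|
    n_g_only: int        # |G \ A|
    n_region: int        # |B|

    @property
    def n_union(self) -> int:
        # |A ∪ G| = |A ∩ G| + |A \ G| + |G \ A|
        return self.n_intersection + self.n_a_only + self.n_g_only

    @property
    def n_a(self) -> int:
        return self.n_intersection + self.n_a_only

    @property
    def n_g(self) -> int:
        return self.n_intersection + self.n_g_only


@dataclass
class OverlapReport:
    """Overlap scores in [0, 1] plus the surface distance in mm.

    Undefined quantities (empty A or G) are NaN with an entry in ``flags``.
    """

    dice: float
    ppv: float
    sensitivity: float
    specificity: float
    assd_mm: float = float("nan")
    flags: list[str] = field(default_factory=list)


@dataclass
class SurfacePointSet:
    """Physical-space coordinates (mm) of the boundary voxel centers."""

    points: np.ndarray       # (n_points, 3) in mm
    mask: np.ndarray         # boolean grid of surface voxels

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


def build_eval_region(all_masks: list[BinaryVolume], n_dilations: int = 3) -> BinaryVolume:
    """Evaluation region B: union of all masks, dilated ``n_dilations`` times
    with the 6-connectivity cross (three successive applications, not one
    radius-3 element)."""
    assert_same_grid(all_masks)
    union = np.zeros(all_masks[0].shape, dtype=bool)
    for m in all_masks:
        union |= m.occupancy
    if n_dilations > 0 and union.any():
        union = ndi.binary_dilation(union, structure=CROSS_6, iterations=n_dilations)
    return all_masks[0].with_occupancy(union, performer_id="eval_region")


def overlap_counts(a: BinaryVolume, g: BinaryVolume, region: BinaryVolume) -> ConfusionCounts:
    """Exact voxel counts of A∩G, A\\G, G\\A and the region B."""
    assert_same_grid([a, g, region])
    A, G, B = a.occupancy, g.occupancy, region.occupancy
    if ((A | G) & ~B).any():
        raise ValueError("evaluation region must contain the union of A and G")
    return ConfusionCounts(
        n_intersection=int((A & G).sum()),
        n_a_only=int((A & ~G).sum()),
        n_g_only=int((G & ~A).sum()),
        n_region=int(B.sum()),
    )


def overlap_metrics(c: ConfusionCounts) -> OverlapReport:
    """Dice, PPV, sensitivity and specificity from voxel counts.

    D  = 2|A∩G| / (|A| + |G|)
    P  = |A∩G| / |A|
    Se = |A∩G| / |G|
    Sp = (|B| − |A∪G|) / (|B| − |G|)

    A = G = ∅ yields Dice 1.0 with a ``both_empty`` flag (perfect agreement
    on nothing); such cases belong on the no-consensus path. |A| = 0 flags
    PPV undefined; |G| = 0 flags Se/Sp undefined (no-consensus case).
    """
    flags: list[str] = []
    n_a, n_g, n_i = c.n_a, c.n_g, c.n_intersection

    if n_a == 0 and n_g == 0:
        flags.append("both_empty")
        return OverlapReport(1.0, float("nan"), float("nan"), float("nan"), flags=flags)

    dice = 2.0 * n_i / (n_a + n_g)
    if n_a == 0:
        flags.append("ppv_undefined_empty_a")
        ppv = float("nan")
    else:
        ppv = n_i / n_a
    if n_g == 0:
        flags.append("empty_reference_route_to_no_consensus")
        se = sp = float("nan")
    else:
        se = n_i / n_g
        denom = c.n_region - n_g
        sp = (c.n_region - c.n_union) / denom if denom > 0 else float("nan")
        if denom <= 0:
            flags.append("specificity_undefined_region_equals_g")
    return OverlapReport(dice, ppv, se, sp, flags=flags)


def extract_surface(m: BinaryVolume) -> SurfacePointSet:
    """Boundary voxels of a nonempty mask as physical-space points.

    A foreground voxel is on the surface iff at least one of its six face
    neighbours is background, or it touches the grid boundary (outside the
    grid counts as background).
    """
    if m.is_empty:
        raise ValueError("cannot extract the surface of an empty mask")
    interior = ndi.binary_erosion(m.occupancy, structure=CROSS_6, border_value=0)
    surf = m.occupancy & ~interior
    idx = np.argwhere(surf)
    points = idx * np.asarray(m.spacing)[None, :]
    return SurfacePointSet(points=points, mask=surf)


def average_surface_distance(a: BinaryVolume, g: BinaryVolume) -> float:
    """Average symmetric surface distance between two nonempty masks, in mm.

    Minimal distances are obtained from an exact Euclidean distance
    transform with the voxel spacing as sampling, so anisotropic grids are
    measured in physical units.
    """
    assert_same_grid([a, g])
    surf_a = extract_surface(a)
    surf_g = extract_surface(g)
    spacing = a.spacing
    # distance from every voxel center to the nearest surface voxel center
    dt_to_g = ndi.distance_transform_edt(~surf_g.mask, sampling=spacing)
    dt_to_a = ndi.distance_transform_edt(~surf_a.mask, sampling=spacing)
    total = dt_to_g[surf_a.mask].sum() + dt_to_a[surf_g.mask].sum()
    return float(total / (surf_a.n_points + surf_g.n_points))


def evaluate_pair(
    a: BinaryVolume,
    g: BinaryVolume,
    region: BinaryVolume | None = None,
) -> OverlapReport:
    """Full segmentation report for one (evaluated, reference) pair.

    When no challenge-wide region is supplied, B defaults to
    ``build_eval_region([a, g])`` — the union of the pair dilated 3x. In a
    challenge context pass the region built from *all* segmentations of the
    case so specificity is comparable across performers.
    """
    if region is None:
        region = build_eval_region([a, g])
    report = overlap_metrics(overlap_counts(a, g, region))
    if a.is_empty or g.is_empty:
        report.flags.append("assd_undefined_empty_mask")
        report.assd_mm = float("nan")
        if not (a.is_empty and g.is_empty):
            warnings.warn(
                "surface distance undefined for an empty mask; excluded from averages",
                stacklevel=2,
            )
    else:
        report.assd_mm = average_surface_distance(a, g)
    return report
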