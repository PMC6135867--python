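"""Lesion identification and lesion-level detection scoring.

Detection asks a different question than voxel overlap: did the method find
each lesion at all, regardless of how precisely its contour was drawn?
Lesions are the 18-connected components (faces and edges, no corners) of a
mask after removing components below a minimum physical volume (3 mm^3 by
default — sub-resolution specks are annotation noise).

A reference lesion G̃_j counts as detected by the evaluated map Ã when

  1. its voxels are covered by Ã lesions at a rate of at least α%, and
  2. every Ã lesion in the minimal contributor set — the largest overlaps,
     taken in decreasing order until they account for γ% of the total
     overlap on G̃_j — lies outside G̃_j by at most β% of its own volume.

Rule 2 rejects detections that are artefacts of one overly large component
sprawling across many lesions. TP_G counts detected reference lesions;
TP_A is the same procedure with the roles of the two maps reversed. The
per-case summary is

  Se_L = TP_G / M,   P_L = TP_A / N,   F1 = 2 Se_L P_L / (Se_L + P_L).

Defaults α = 10%, γ = 65%, β = 70%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .volume import BinaryVolume, GridMismatchError

__all__ = [
    "DetectionParams",
    "LesionLabelMap",
    "JointHistogram",
    "DetectionReport",
    "NoConsensusReport",
    "label_lesions",
    "joint_histogram",
    "count_detected",
    "detection_metrics",
    "no_consensus_metrics",
    "per_lesion_detection_rates",
]

_STRUCTURES = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class DetectionParams:
    """Matching-rule parameters (percentages in (0, 100])."""

    alpha_pct: float = 10.0      # minimum coverage of the reference lesion
    gamma_pct: float = 65.0      # overlap mass defining the contributor set
    beta_pct: float = 70.0       # maximum outside fraction per contributor
    min_volume_mm3: float = 3.0  # size filter for retained components
    connectivity: int = 18
    strict_size: bool = False    # False: keep >= min volume; True: keep >
    beta_on_union: bool = False  # apply rule 2 to the contributors' union

    def __post_init__(self) -> None:
        for name in ("alpha_pct", "gamma_pct", "beta_pct"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must be in (0, 100], got {v}")
        if self.min_volume_mm3 < 0:
            raise ValueError("min_volume_mm3 must be >= 0")
        if self.connectivity not in _STRUCTURES:
            raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")


@dataclass
class LesionLabelMap:
    """Integer-labelled lesions: 0 = background, 1..K in decreasing volume."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    lesion_volumes_mm3: np.ndarray  # index l-1 holds the volume of label l
    case_id: str = ""
    performer_id: str = ""

    @property
    def n_lesions(self) -> int:
        return int(self.lesion_volumes_mm3.shape[0])

    @property
    def lesion_sizes_vox(self) -> np.ndarray:
        voxel = float(np.prod(self.spacing))
        return np.round(self.lesion_volumes_mm3 / voxel).astype(int)


@dataclass(frozen=True)
class JointHistogram:
    """Co-occurrence counts of two label maps, background included.

    ``counts[i, j]`` is the number of voxels carrying label i in the
    evaluated map and label j in the reference map; row/column 0 is
    background, so the grand total equals the grid voxel count.
    """

    counts: np.ndarray  # shape (N + 1, M + 1)


@dataclass
class DetectionReport:
    tp_g: int
    tp_a: int
    m: int
    n: int
    lesion_sensitivity: float
    lesion_ppv: float
    f1: float
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class NoConsensusReport:
    """Fallback metrics for a case whose consensus is empty: lesion count
    and total lesion load (cm^3) of the evaluated mask. Perfect value 0."""

    n_lesions: int
    total_volume_cm3: float


def _keep(volumes: np.ndarray, min_volume_mm3: float, strict: bool) -> np.ndarray:
    return volumes > min_volume_mm3 if strict else volumes >= min_volume_mm3


def label_lesions(m: BinaryVolume, params: DetectionParams = DetectionParams()) -> LesionLabelMap:
    """Connected-component lesion labelling with the physical size filter.

    Components are found with the requested connectivity (18 by default),
    those below ``min_volume_mm3`` are dropped, and survivors are
    renumbered 1..K in decreasing volume (ties keep scan order).
    """
    raw, n_raw = ndi.label(m.occupancy, structure=_STRUCTURES[params.connectivity])
    out = np.zeros_like(raw)
    if n_raw == 0:
        return LesionLabelMap(out, m.spacing, np.empty(0), m.case_id, m.performer_id)
    sizes = np.bincount(raw.ravel(), minlength=n_raw + 1)[1:]
    volumes = sizes * m.voxel_volume_mm3
    kept = np.flatnonzero(_keep(volumes, params.min_volume_mm3, params.strict_size))
    # decreasing volume; mergesort keeps original label order on ties
    order = kept[np.argsort(-volumes[kept], kind="stable")]
    relabel = np.zeros(n_raw + 1, dtype=raw.dtype)
    relabel[order + 1] = np.arange(1, len(order) + 1)
    out = relabel[raw]
    return LesionLabelMap(
        labels=out,
        spacing=m.spacing,
        lesion_volumes_mm3=volumes[order],
        case_id=m.case_id,
        performer_id=m.performer_id,
    )


def joint_histogram(la: LesionLabelMap, lg: LesionLabelMap) -> JointHistogram:
    """Joint histogram H of an evaluated map (rows) vs a reference map
    (columns), including the background row/column 0."""
    if la.labels.shape != lg.labels.shape:
        raise GridMismatchError(
            f"label maps differ in shape: {la.labels.shape} vs {lg.labels.shape}"
        )
    n, m = la.n_lesions, lg.n_lesions
    flat = la.labels.ravel().astype(np.int64) * (m + 1) + lg.labels.ravel()
    counts = np.bincount(flat, minlength=(n + 1) * (m + 1)).reshape(n + 1, m + 1)
    return JointHistogram(counts=counts)


def count_detected(
    lg: LesionLabelMap,
    la: LesionLabelMap,
    h: JointHistogram | None = None,
    params: DetectionParams = DetectionParams(),
) -> tuple[int, np.ndarray]:
    """Number of reference lesions detected, with per-lesion flags.

    Implements the α/γ/β matching rules on the joint histogram of the two
    label maps. Returns ``(tp, detected)`` where ``detected[j-1]`` tells
    whether reference lesion j passed both rules.
    """
    if h is None:
        h = joint_histogram(la, lg)
    counts = h.counts
    n = la.n_lesions
    m = lg.n_lesions
    if counts.shape != (n + 1, m + 1):
        raise ValueError("joint histogram does not match the two label maps")
    a_sizes = counts.sum(axis=1)          # |Ã_i| for i = 0..N
    detected = np.zeros(m, dtype=bool)
    for j in range(1, m + 1):
        col = counts[:, j]
        size_g = int(col.sum())           # |G̃_j|
        overlap = int(col[1:].sum())      # voxels of G̃_j covered by any Ã lesion
        if size_g == 0 or overlap * 100.0 < params.alpha_pct * size_g:
            continue  # rule 1 fails
        contributors = [i for i in range(1, n + 1) if col[i] > 0]
        # decreasing overlap; equal overlaps break toward the smaller label
        contributors.sort(key=lambda i: (-col[i], i))
        acc = 0
        selected: list[int] = []
        for i in contributors:
            selected.append(i)
            acc += int(col[i])
            if acc * 100.0 >= params.gamma_pct * overlap:
                break
        if params.beta_on_union:
            tot = int(a_sizes[selected].sum())
            ins = int(col[selected].sum())
            ok = (tot - ins) * 100.0 <= params.beta_pct * tot
        else:
            ok = all(
                (a_sizes[i] - col[i]) * 100.0 <= params.beta_pct * a_sizes[i]
                for i in selected
            )
        detected[j - 1] = ok
    return int(detected.sum()), detected


def detection_metrics(
    lg: LesionLabelMap,
    la: LesionLabelMap,
    params: DetectionParams = DetectionParams(),
) -> DetectionReport:
    """Se_L, P_L and F1 for one (reference, evaluated) pair of label maps.

    Degenerate conventions: N = 0 with M > 0 gives P_L = 0 (no predictions
    score worst); Se_L + P_L = 0 gives F1 = 0. M = 0 means the case has no
    reference lesions — the report is flagged for the no-consensus path and
    Se_L/F1 are NaN.
    """
    flags: list[str] = []
    m, n = lg.n_lesions, la.n_lesions
    h = joint_histogram(la, lg)
    tp_g, _ = count_detected(lg, la, h, params)
    # reversed roles: the transposed histogram is the joint histogram of (lg, la)
    tp_a, _ = count_detected(la, lg, JointHistogram(h.counts.T), params)
    if m == 0:
        flags.append("empty_reference_route_to_no_consensus")
        return DetectionReport(tp_g, tp_a, m, n, float("nan"), float("nan"),
                               float("nan"), flags)
    se = tp_g / m
    ppv = tp_a / n if n > 0 else 0.0
    if n == 0:
        flags.append("empty_evaluated_mask")
    f1 = 2 * se * ppv / (se + ppv) if (se + ppv) > 0 else 0.0
    return DetectionReport(tp_g, tp_a, m, n, se, ppv, f1, flags)


def no_consensus_metrics(
    m: BinaryVolume,
    params: DetectionParams = DetectionParams(),
) -> NoConsensusReport:
    """Lesion count and total lesion load (cm^3) of a mask, for cases where
    the consensus is empty and overlap/detection scores are undefined."""
    lm = label_lesions(m, params)
    return NoConsensusReport(
        n_lesions=lm.n_lesions,
        total_volume_cm3=float(lm.lesion_volumes_mm3.sum()) / 1000.0,
    )


def per_lesion_detection_rates(
    cases: list[tuple[LesionLabelMap, list[LesionLabelMap]]],
    params: DetectionParams = DetectionParams(),
) -> pd.DataFrame:
    """Per-lesion detection rate across performers, paired with lesion volume.

    For every reference lesion the rate is the percentage of evaluated maps
    whose matcher flags it as detected (0% = nobody found it, 100% =
    everybody did). Returns columns case_id, lesion_id, volume_mm3,
    detection_rate_pct.
    """
    rows = []
    for lg, evaluated in cases:
        if not evaluated:
            raise ValueError("each case needs at least one evaluated label map")
        hits = np.zeros(lg.n_lesions)
        for la in evaluated:
            _, det = count_detected(lg, la, params=params)
            hits += det
        rates = 100.0 * hits / len(evaluated)
        for j in range(lg.n_lesions):
            rows.append(
                {
                    "case_id": lg.case_id,
                    "lesion_id": j + 1,
                    "volume_mm3": float(lg.lesion_volumes_mm3[j]),
                    "detection_rate_pct": float(rates[j]),
                }
            )
    return pd.DataFrame(rows, columns=["case_id", "lesion_id", "volume_mm3",
                                       "detection_rate_pct"])
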