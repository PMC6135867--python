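"""Synthetic lesion phantoms and simulated raters.

Ground truth is a union of non-overlapping digitized spheres on the voxel
grid — lesion realism is irrelevant to the evaluation machinery being
tested, while spheres give analytic control of lesion count, volume and
separation. Simulated raters corrupt the truth with the three error modes
that matter to the metric families:

* boundary jitter — each lesion is re-drawn with its radius perturbed by a
  per-lesion uniform draw in ±boundary_jitter_mm, degrading overlap scores
  while leaving detection intact as long as the jitter stays inside the
  α/β matching regime;
* misses — each lesion is deleted independently with ``miss_prob``,
  hitting lesion sensitivity while the surviving lesions keep their exact
  contours;
* false positives — Poisson(``fp_rate``) spurious spheres are placed at
  least ``min_separation`` away from every true lesion, so each one is
  unambiguously a detection false positive.

All geometry is computed on the integer grid from seeded draws, so masks
are bit-identical across runs and platforms for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .volume import BinaryVolume, write_mask

__all__ = [
    "PhantomConfig",
    "RaterProfile",
    "LesionSpec",
    "generate_phantom",
    "simulate_rater",
    "simulate_challenge",
    "generate_challenge",
    "graded_algorithm_profiles",
]

MAX_ATTEMPTS = 10_000
#: smallest admissible sphere radius: keeps at least the center voxel, so a
#: jittered lesion can shrink but never vanish unless explicitly missed
_MIN_RADIUS_FACTOR = 0.55


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry of one synthetic ground-truth case."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lesions: int = 8
    radius_range: tuple[float, float] = (1.5, 6.0)   # mm
    min_separation: float = 3.0                      # mm of clearance between lesion surfaces
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError(f"invalid radius_range {self.radius_range}")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")


@dataclass(frozen=True)
class RaterProfile:
    """Error structure of one simulated rater or algorithm."""

    boundary_jitter_mm: float = 0.0
    miss_prob: float = 0.0
    fp_rate: float = 0.0                              # expected spurious lesions per case
    fp_radius_range: tuple[float, float] = (1.5, 3.0)
    name: str = "rater"

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must be in [0, 1]")
        if self.boundary_jitter_mm < 0 or self.fp_rate < 0:
            raise ValueError("jitter and fp_rate must be >= 0")


@dataclass
class LesionSpec:
    """One digitized sphere: integer-grid center, radius and realized volume."""

    center: tuple[int, int, int]
    radius_mm: float
    volume_mm3: float
    n_voxels: int


def _sphere_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center: tuple[int, int, int],
    radius_mm: float,
) -> np.ndarray:
    """Voxels whose centers lie within radius_mm of the center voxel."""
    lo, hi = [], []
    for c, s, n in zip(center, spacing, shape):
        half = int(np.ceil(radius_mm / s))
        lo.append(max(c - half, 0))
        hi.append(min(c + half + 1, n))
    grid = np.zeros(shape, dtype=bool)
    ax = [np.arange(lo[d], hi[d]) for d in range(3)]
    dist2 = (
        ((ax[0] - center[0]) * spacing[0])[:, None, None] ** 2
        + ((ax[1] - center[1]) * spacing[1])[None, :, None] ** 2
        + ((ax[2] - center[2]) * spacing[2])[None, None, :] ** 2
    )
    grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = dist2 <= radius_mm ** 2
    return grid


def _centers_mm(specs: list[LesionSpec], spacing) -> np.ndarray:
    if not specs:
        return np.empty((0, 3))
    return np.array([s.center for s in specs], dtype=float) * np.asarray(spacing)


def generate_phantom(
    cfg: PhantomConfig,
    rng: np.random.Generator | None = None,
) -> tuple[BinaryVolume, list[LesionSpec]]:
    """Ground-truth mask plus per-lesion metadata.

    Lesion centers are rejection-sampled (bounded at ``MAX_ATTEMPTS``) so
    every sphere fits fully inside the grid and any two sphere surfaces
    are at least ``min_separation`` mm apart — guaranteeing lesions stay
    distinct connected components under any voxel connectivity.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    spacing = np.asarray(cfg.spacing)
    shape = cfg.grid_shape
    specs: list[LesionSpec] = []
    occ = np.zeros(shape, dtype=bool)
    attempts = 0
    while len(specs) < cfg.n_lesions:
        if attempts >= MAX_ATTEMPTS:
            raise RuntimeError(
                f"could not place {cfg.n_lesions} lesions in {shape} after "
                f"{MAX_ATTEMPTS} attempts; loosen the packing constraints"
            )
        attempts += 1
        r = float(rng.uniform(*cfg.radius_range))
        center = []
        feasible = True
        for s, n in zip(spacing, shape):
            half = int(np.ceil(r / s))
            if 2 * half + 1 > n:
                feasible = False
                break
            center.append(int(rng.integers(half, n - half)))
        if not feasible:
            continue
        center = tuple(center)
        pos = np.asarray(center) * spacing
        ok = True
        for other in specs:
            gap = np.linalg.norm(pos - np.asarray(other.center) * spacing)
            if gap < r + other.radius_mm + cfg.min_separation:
                ok = False
                break
        if not ok:
            continue
        mask = _sphere_mask(shape, cfg.spacing, center, r)
        n_vox = int(mask.sum())
        occ |= mask
        specs.append(
            LesionSpec(center, r, n_vox * float(np.prod(spacing)), n_vox)
        )
    vol = BinaryVolume(occ, spacing=cfg.spacing, performer_id="ground_truth")
    return vol, specs


def simulate_rater(
    gt: BinaryVolume,
    specs: list[LesionSpec],
    profile: RaterProfile,
    seed: int | np.random.Generator = 0,
    min_separation: float = 3.0,
) -> BinaryVolume:
    """A simulated segmentation of a phantom under a rater error profile.

    A zero-error profile reproduces the ground truth bit-exactly. Jittered
    radii are clamped from below so a lesion can only disappear through an
    explicit miss. False-positive spheres are rejection-sampled off-lesion
    (surface clearance >= ``min_separation`` mm from every true lesion and
    previously placed false positive); placement failures after the
    attempt bound are silently skipped, keeping the FP count <= the
    Poisson draw.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spacing = np.asarray(gt.spacing)
    min_radius = _MIN_RADIUS_FACTOR * float(spacing.min())
    occ = np.zeros(gt.shape, dtype=bool)
    # draw per-lesion randomness unconditionally: reproducible structure
    misses = rng.random(len(specs)) < profile.miss_prob
    jitters = rng.uniform(-profile.boundary_jitter_mm, profile.boundary_jitter_mm,
                          size=len(specs))
    for spec, missed, jitter in zip(specs, misses, jitters):
        if missed:
            continue
        if profile.boundary_jitter_mm == 0.0:
            r = spec.radius_mm
        else:
            r = max(spec.radius_mm + float(jitter), min_radius)
        occ |= _sphere_mask(gt.shape, gt.spacing, spec.center, r)

    n_fp = int(rng.poisson(profile.fp_rate))
    placed: list[LesionSpec] = list(specs)
    for _ in range(n_fp):
        for _attempt in range(MAX_ATTEMPTS // 10):
            r = float(rng.uniform(*profile.fp_radius_range))
            center = []
            feasible = True
            for s, n in zip(spacing, gt.shape):
                half = int(np.ceil(r / s))
                if 2 * half + 1 > n:
                    feasible = False
                    break
                center.append(int(rng.integers(half, n - half)))
            if not feasible:
                continue
            pos = np.asarray(center) * spacing
            clear = all(
                np.linalg.norm(pos - np.asarray(o.center) * spacing)
                >= r + o.radius_mm + min_separation
                for o in placed
            )
            if clear:
                mask = _sphere_mask(gt.shape, gt.spacing, tuple(center), r)
                occ |= mask
                placed.append(
                    LesionSpec(tuple(center), r, int(mask.sum()) * gt.voxel_volume_mm3,
                               int(mask.sum()))
                )
                break
    return gt.with_occupancy(occ, performer_id=profile.name)


@dataclass
class ChallengeCase:
    """One in-memory synthetic case: truth, expert masks, algorithm masks."""

    case_id: str
    ground_truth: BinaryVolume
    lesions: list[LesionSpec]
    experts: dict[str, BinaryVolume] = field(default_factory=dict)
    algorithms: dict[str, BinaryVolume] = field(default_factory=dict)


def graded_algorithm_profiles(n: int = 4) -> list[RaterProfile]:
    """Algorithm error profiles of strictly decreasing quality.

    Jitter, miss probability and false-positive rate all grow with the
    index, and even the best profile errs distinctly more than the expert
    profile — automatic methods trail trained raters on every metric
    family, which is the structure the cohort analyses are built to
    resolve.
    """
    return [
        RaterProfile(
            boundary_jitter_mm=0.8 + 0.4 * k,
            miss_prob=0.10 + 0.07 * k,
            fp_rate=1.0 + 0.75 * k,
            name=f"team_{k + 1}",
        )
        for k in range(n)
    ]


#: trained raters agree closely with the truth: sub-voxel boundary jitter,
#: rare misses, occasional spurious finding
DEFAULT_EXPERT_PROFILE = RaterProfile(
    boundary_jitter_mm=0.2, miss_prob=0.01, fp_rate=0.1, name="expert"
)


def simulate_challenge(
    n_cases: int = 10,
    n_raters: int = 7,
    algorithm_profiles: list[RaterProfile] | None = None,
    base_config: PhantomConfig = PhantomConfig(),
    expert_profile: RaterProfile = DEFAULT_EXPERT_PROFILE,
    n_lesions_range: tuple[int, int] = (3, 12),
    seed: int = 0,
) -> list[ChallengeCase]:
    """A full in-memory synthetic challenge: per case, a phantom truth,
    ``n_raters`` expert-profile segmentations and one segmentation per
    algorithm profile. Lesion counts vary per case within
    ``n_lesions_range`` (inclusive), emulating variable lesion burden.
    Deterministic for a given seed."""
    if algorithm_profiles is None:
        algorithm_profiles = graded_algorithm_profiles()
    ss = np.random.SeedSequence(seed)
    cases: list[ChallengeCase] = []
    for c, case_ss in enumerate(ss.spawn(n_cases), start=1):
        streams = case_ss.spawn(1 + n_raters + len(algorithm_profiles))
        rng_gt = np.random.default_rng(streams[0])
        n_les = int(rng_gt.integers(n_lesions_range[0], n_lesions_range[1] + 1))
        cfg = PhantomConfig(
            grid_shape=base_config.grid_shape,
            spacing=base_config.spacing,
            n_lesions=n_les,
            radius_range=base_config.radius_range,
            min_separation=base_config.min_separation,
        )
        gt, specs = generate_phantom(cfg, rng=rng_gt)
        case = ChallengeCase(case_id=f"case_{c:02d}", ground_truth=gt, lesions=specs)
        gt.case_id = case.case_id
        for r in range(n_raters):
            name = f"expert_{r + 1}"
            prof = RaterProfile(**{**asdict(expert_profile), "name": name})
            mask = simulate_rater(gt, specs, prof,
                                  seed=np.random.default_rng(streams[1 + r]),
                                  min_separation=cfg.min_separation)
            mask.case_id = case.case_id
            case.experts[name] = mask
        for t, prof in enumerate(algorithm_profiles):
            mask = simulate_rater(gt, specs, prof,
                                  seed=np.random.default_rng(streams[1 + n_raters + t]),
                                  min_separation=cfg.min_separation)
            mask.case_id = case.case_id
            case.algorithms[prof.name] = mask
        cases.append(case)
    return cases


def generate_challenge(
    out_dir: str | Path,
    n_cases: int = 10,
    n_raters: int = 7,
    algorithm_profiles: list[RaterProfile] | None = None,
    base_config: PhantomConfig = PhantomConfig(),
    seed: int = 0,
    **kwargs,
) -> Path:
    """Write a synthetic challenge tree to disk.

    Layout: ``<out>/case_XX/{gt.nii.gz, expert_R.nii.gz, team_T.nii.gz,
    manifest.json}``; the manifest records the seed, the profiles and the
    per-lesion metadata. Same seed, same tree.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if algorithm_profiles is None:
        algorithm_profiles = graded_algorithm_profiles()
    cases = simulate_challenge(
        n_cases=n_cases,
        n_raters=n_raters,
        algorithm_profiles=algorithm_profiles,
        base_config=base_config,
        seed=seed,
        **kwargs,
    )
    for case in cases:
        cdir = out / case.case_id
        cdir.mkdir(exist_ok=True)
        write_mask(case.ground_truth, cdir / "gt.nii.gz")
        for name, mask in {**case.experts, **case.algorithms}.items():
            write_mask(mask, cdir / f"{name}.nii.gz")
        manifest = {
            "case_id": case.case_id,
            "seed": seed,
            "grid_shape": list(case.ground_truth.shape),
            "spacing": list(case.ground_truth.spacing),
            "experts": sorted(case.experts),
            "algorithms": [asdict(p) for p in algorithm_profiles],
            "lesions": [asdict(s) for s in case.lesions],
        }
        (cdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
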