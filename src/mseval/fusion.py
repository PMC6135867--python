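"""Multi-rater consensus fusion by performance-weighted EM (STAPLE).

Given R binary segmentations of the same case, STAPLE treats the unknown
true segmentation T as a latent voxelwise variable and each rater r as a
noisy channel with sensitivity p_r = P(D_r = 1 | T = 1) and specificity
q_r = P(D_r = 0 | T = 0). EM alternates:

  E-step   W_v = P(T_v = 1 | D, p, q) from the prior and the rater terms
  M-step   p_r = Σ_v W_v D_rv / Σ_v W_v
           q_r = Σ_v (1 − W_v)(1 − D_rv) / Σ_v (1 − W_v)

In the log-opinion-pool variant (``mode="lop_staple"``) the per-rater
likelihood factors are pooled as a normalized weighted geometric mean
(equal weights 1/R by default) before the prior is applied, which softens
the penalty for a single rater deviating from the group's agreement.

Computation is restricted to an evaluation region (union of the inputs
dilated 3x with the 6-connectivity kernel by default): on a whole image
grid the vast all-background exterior would saturate every q_r at 1 and
carry no information about rater behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seg_metrics import build_eval_region
from .volume import BinaryVolume, assert_same_grid

__all__ = ["FusionResult", "majority_vote", "fuse"]

_EPS = 1e-7


@dataclass
class FusionResult:
    posterior: np.ndarray                 # voxelwise P(lesion), full grid
    sensitivities: np.ndarray             # p_r per rater
    specificities: np.ndarray             # q_r per rater
    n_iterations: int
    converged: bool
    consensus: BinaryVolume
    objective_trace: list[float] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def rater_performance(self) -> list[tuple[float, float]]:
        return list(zip(self.sensitivities.tolist(), self.specificities.tolist()))


def majority_vote(masks: list[BinaryVolume]) -> BinaryVolume:
    """Voxelwise majority: foreground iff strictly more than half of the
    inputs mark it (an exact half vote is background)."""
    if not masks:
        raise ValueError("majority_vote needs at least one mask")
    assert_same_grid(masks)
    votes = np.zeros(masks[0].shape, dtype=np.int32)
    for m in masks:
        votes += m.occupancy
    return masks[0].with_occupancy(votes * 2 > len(masks), performer_id="majority_vote")


def fuse(
    masks: list[BinaryVolume],
    mode: str = "lop_staple",
    max_iter: int = 100,
    tol: float = 1e-6,
    threshold: float = 0.5,
    region: BinaryVolume | None = None,
    weights: np.ndarray | None = None,
    initial_p: float = 0.9,
    initial_q: float = 0.9,
) -> FusionResult:
    """Fuse binary segmentations into a consensus with rater performance.

    Parameters
    ----------
    masks
        At least two segmentations on a shared grid.
    mode
        ``"staple"`` (classical product of rater likelihoods) or
        ``"lop_staple"`` (normalized weighted geometric-mean pool).
    region
        Voxels over which the EM runs; defaults to the union of the inputs
        dilated 3x with the 6-connectivity kernel. Voxels outside are
        background with posterior 0.
    weights
        Pool weights per rater for ``lop_staple`` (normalized internally);
        equal weights by default.
    threshold
        Posterior cut for the binary consensus.

    Returns
    -------
    FusionResult with the voxelwise posterior, per-rater (p_r, q_r), the
    thresholded consensus, and the observed-data log-likelihood trace.
    """
    if len(masks) < 2:
        raise ValueError("fusion needs at least two masks")
    if mode not in ("staple", "lop_staple"):
        raise ValueError(f"unknown fusion mode {mode!r}")
    assert_same_grid(masks)
    R = len(masks)
    shape = masks[0].shape

    union = np.zeros(shape, dtype=bool)
    for m in masks:
        union |= m.occupancy
    if not union.any():
        empty = masks[0].with_occupancy(np.zeros(shape, bool), performer_id="consensus")
        return FusionResult(
            posterior=np.zeros(shape),
            sensitivities=np.full(R, np.nan),
            specificities=np.full(R, np.nan),
            n_iterations=0,
            converged=True,
            consensus=empty,
            flags=["degenerate_all_empty_inputs"],
        )

    if region is None:
        region = build_eval_region(masks)
    sel = region.occupancy
    if (union & ~sel).any():
        raise ValueError("fusion region must contain the union of the inputs")

    D = np.stack([m.occupancy[sel] for m in masks]).astype(float)  # (R, V)
    V = D.shape[1]
    if weights is None:
        w = np.full(R, 1.0 / R)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (R,) or (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be R nonnegative values, not all zero")
        w = w / w.sum()
    # pool exponents: classical STAPLE multiplies raw likelihoods (exponent 1);
    # the log-opinion pool raises each factor to its normalized weight.
    expo = np.ones(R) if mode == "staple" else w

    prior = np.clip(D.mean(axis=0), 0.01, 0.99)
    log_prior1 = np.log(prior)
    log_prior0 = np.log1p(-prior)

    p = np.full(R, float(initial_p))
    q = np.full(R, float(initial_q))
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pc = np.clip(p, _EPS, 1 - _EPS)
        qc = np.clip(q, _EPS, 1 - _EPS)
        # per-rater log-likelihood of the observation under T=1 and T=0
        ll1 = D * np.log(pc)[:, None] + (1 - D) * np.log1p(-pc)[:, None]
        ll0 = D * np.log1p(-qc)[:, None] + (1 - D) * np.log(qc)[:, None]
        la = log_prior1 + (expo[:, None] * ll1).sum(axis=0)
        lb = log_prior0 + (expo[:, None] * ll0).sum(axis=0)
        W = 1.0 / (1.0 + np.exp(lb - la))
        trace.append(float(np.logaddexp(la, lb).sum()))

        sw = W.sum()
        sc = V - sw
        new_p = (D @ W) / sw if sw > 0 else p
        new_q = ((1 - D) @ (1 - W)) / sc if sc > 0 else q
        delta = max(np.abs(new_p - p).max(), np.abs(new_q - q).max())
        p, q = new_p, new_q
        if delta < tol:
            converged = True
            break

    posterior = np.zeros(shape)
    posterior[sel] = W
    consensus = masks[0].with_occupancy(posterior >= threshold, performer_id="consensus")
    flags = [] if converged else ["not_converged"]
    return FusionResult(
        posterior=posterior,
        sensitivities=p,
        specificities=q,
        n_iterations=it,
        converged=converged,
        consensus=consensus,
        objective_trace=trace,
        flags=flags,
    )
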