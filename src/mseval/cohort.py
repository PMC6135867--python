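"""Challenge-level analytics over per-case score tables.

A score table is a tidy DataFrame with one row per (case_id, performer_id)
and one column per metric. On top of it this module provides:

* rank-then-average method comparison — within each case the performers
  are ranked on one metric (1 = best, average ranks on ties) and each
  performer's ranks are averaged over cases, which is robust to a method
  scoring a few extreme values;
* performer summaries as bivariate Gaussians (mean and covariance of a
  metric pair over cases) compared with the closed-form 2-Wasserstein
  (Bures) distance, and spectral clustering of those Gaussians into k
  groups;
* score-vs-lesion-burden log-linear regressions reporting the squared
  Spearman rank correlation;
* per-lesion detection rate vs lesion volume, binned on a log scale, with
  a log-linear regression;
* paired Wilcoxon signed-rank comparison of two score vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "PerformerSummary",
    "RankResult",
    "RegressionSummary",
    "BinnedCurve",
    "GroupComparison",
    "rank_methods",
    "summarize_performers",
    "gaussian_distance",
    "cluster_performers",
    "score_vs_burden",
    "detection_rate_vs_size",
    "compare_groups",
]

CLUSTER_SEED = 12345


@dataclass
class PerformerSummary:
    """A performer's behaviour over cases for one metric pair, viewed as a
    bivariate Gaussian (mean vector, covariance matrix)."""

    performer_id: str
    mean: np.ndarray            # (2,)
    covariance: np.ndarray      # (2, 2), symmetric PSD
    n_cases: int
    cluster_label: int | None = None


@dataclass
class RankResult:
    per_case_ranks: pd.DataFrame   # index case_id, columns performer_id
    average_rank: pd.Series        # per performer, ascending = better
    dropped_cases: list[str] = field(default_factory=list)


@dataclass
class RegressionSummary:
    r2: float          # squared Spearman rank correlation
    slope: float       # least-squares slope on log10(burden)
    intercept: float
    n: int
    flags: list[str] = field(default_factory=list)


@dataclass
class BinnedCurve:
    bin_centers: np.ndarray    # geometric centers of nonempty volume bins
    bin_means: np.ndarray      # mean detection rate (%) per nonempty bin
    r2: float                  # squared correlation of the log-linear fit
    slope: float               # rate change per decade of volume
    flags: list[str] = field(default_factory=list)


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    n: int
    flags: list[str] = field(default_factory=list)


def rank_methods(
    table: pd.DataFrame,
    metric: str,
    higher_is_better: bool = True,
) -> RankResult:
    """Rank-then-average comparison of performers on one metric.

    Within each case performers are ranked from 1 (best) to N (worst);
    ties receive the average of the tied positions, so each case's ranks
    sum to N(N+1)/2. Cases missing any performer's score are dropped with
    a warning. The final ordering is by average rank over cases.
    """
    wide = table.pivot(index="case_id", columns="performer_id", values=metric)
    if wide.shape[1] < 2:
        raise ValueError("ranking needs at least two performers")
    complete = wide.dropna(axis=0, how="any")
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        warnings.warn(f"dropping cases with missing scores: {dropped}", stacklevel=2)
    if complete.empty:
        raise ValueError("no case has a complete set of scores")
    ranks = complete.rank(axis=1, method="average", ascending=not higher_is_better)
    return RankResult(
        per_case_ranks=ranks,
        average_rank=ranks.mean(axis=0).sort_values(),
        dropped_cases=[str(c) for c in dropped],
    )


def summarize_performers(
    table: pd.DataFrame,
    metrics: tuple[str, str],
) -> list[PerformerSummary]:
    """Per-performer mean and covariance of a metric pair over cases.

    Rows with a NaN in either metric (flagged/undefined cases) are
    excluded from that performer's summary; a single remaining case gives
    a zero covariance.
    """
    out = []
    for pid, grp in table.groupby("performer_id", sort=True):
        vals = grp[list(metrics)].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            warnings.warn(f"performer {pid!r} has no finite scores; skipped",
                          stacklevel=2)
            continue
        mean = vals.mean(axis=0)
        cov = np.cov(vals, rowvar=False) if len(vals) >= 2 else np.zeros((2, 2))
        out.append(PerformerSummary(str(pid), mean, np.atleast_2d(cov), len(vals)))
    return out


def _check_psd(cov: np.ndarray, who: str) -> None:
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError(f"covariance of {who} is not symmetric")
    if np.linalg.eigvalsh(cov).min() < -1e-9:
        raise ValueError(f"covariance of {who} is not positive semi-definite")


def gaussian_distance(a: PerformerSummary, b: PerformerSummary) -> float:
    """2-Wasserstein (Bures) distance between two Gaussian summaries.

    d^2 = ||mu_a − mu_b||^2 + tr(Σ_a + Σ_b − 2 (Σ_b^{1/2} Σ_a Σ_b^{1/2})^{1/2})

    Symmetric, zero iff the means and covariances coincide; reduces to the
    Euclidean mean distance when both covariances vanish.
    """
    _check_psd(a.covariance, a.performer_id)
    _check_psd(b.covariance, b.performer_id)
    dmu2 = float(np.sum((a.mean - b.mean) ** 2))
    sb = _psd_sqrt(b.covariance)
    cross = _psd_sqrt(sb @ a.covariance @ sb)
    bures = float(np.trace(a.covariance) + np.trace(b.covariance) - 2.0 * np.trace(cross))
    return float(np.sqrt(max(dmu2 + bures, 0.0)))


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    # eigendecomposition of the symmetrized matrix: exact for PSD inputs and
    # robust to the singular covariances of near-deterministic performers
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    return (vecs * np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T


def cluster_performers(
    summaries: list[PerformerSummary],
    k: int = 3,
    seed: int = CLUSTER_SEED,
    bandwidth: float | None = None,
) -> np.ndarray:
    """Spectral clustering of performer Gaussians into k groups.

    The affinity is exp(−d²/(2σ²)) on the pairwise Bures–Wasserstein
    distances, σ defaulting to the median nonzero distance. Labels are
    renumbered so cluster 1 has the highest mean on the first metric
    (best-performing group first). ``cluster_label`` is set on each
    summary; the label array is also returned.
    """
    if len(summaries) < k:
        raise ValueError(f"need at least k={k} summaries, got {len(summaries)}")
    n = len(summaries)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = gaussian_distance(summaries[i], summaries[j])
    nonzero = d[d > 0]
    if nonzero.size == 0:
        warnings.warn("all summaries identical; single-cluster result", stacklevel=2)
        for s in summaries:
            s.cluster_label = 1
        return np.ones(n, dtype=int)
    sigma = float(bandwidth) if bandwidth is not None else float(np.median(nonzero))
    affinity = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    # normalized spectral clustering: embed on the k smallest eigenvectors of
    # the symmetric normalized Laplacian, row-normalize, k-means
    deg = affinity.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(n) - (inv_sqrt[:, None] * affinity * inv_sqrt[None, :])
    _, vecs = np.linalg.eigh(lap)
    emb = vecs[:, :k]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.where(norms > 0, norms, 1.0)
    raw = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(emb)
    # relabel by descending cluster mean on the first metric: 1 = best group
    first = np.array([s.mean[0] for s in summaries])
    means = {lab: first[raw == lab].mean() for lab in np.unique(raw)}
    order = sorted(means, key=means.get, reverse=True)
    remap = {lab: rank + 1 for rank, lab in enumerate(order)}
    labels = np.array([remap[lab] for lab in raw], dtype=int)
    for s, lab in zip(summaries, labels):
        s.cluster_label = int(lab)
    return labels


def score_vs_burden(scores: np.ndarray, burdens: np.ndarray) -> RegressionSummary:
    """Log-linear regression of per-case mean scores on lesion burden.

    The slope and intercept come from least squares on log10(burden); the
    reported R² is the squared Spearman rank correlation between score and
    burden (rank-based, hence identical for burden and log burden).
    """
    scores = np.asarray(scores, dtype=float)
    burdens = np.asarray(burdens, dtype=float)
    if scores.shape != burdens.shape or scores.ndim != 1:
        raise ValueError("scores and burdens must be equal-length 1-D arrays")
    if len(scores) < 3:
        raise ValueError("regression needs at least 3 cases")
    if (burdens <= 0).any():
        raise ValueError("burdens must be strictly positive (log scale)")
    flags: list[str] = []
    x = np.log10(burdens)
    slope, intercept = np.polyfit(x, scores, 1)
    if np.ptp(scores) == 0:
        flags.append("r2_undefined_constant_scores")
        r2 = float("nan")
    else:
        rho = stats.spearmanr(scores, burdens).statistic
        r2 = float(rho ** 2)
    return RegressionSummary(r2, float(slope), float(intercept), len(scores), flags)


def detection_rate_vs_size(
    per_lesion: pd.DataFrame,
    n_bins: int = 10,
) -> BinnedCurve:
    """Binned lesion-size curve of detection rates with a log-linear fit.

    Lesion volumes are split into ``n_bins`` log-spaced bins; the mean
    detection rate of each nonempty bin is regressed on log10 of the bin's
    geometric center. R² is the squared Pearson correlation of that fit
    (NaN-flagged when the binned rates are constant).
    """
    if len(per_lesion) == 0:
        raise ValueError("need at least one lesion")
    vol = per_lesion["volume_mm3"].to_numpy(dtype=float)
    rate = per_lesion["detection_rate_pct"].to_numpy(dtype=float)
    lo, hi = np.log10(vol.min()), np.log10(vol.max())
    if lo == hi:
        edges = np.array([vol.min() * 0.999, vol.max() * 1.001])
    else:
        edges = np.logspace(lo, hi, n_bins + 1)
        edges[-1] *= 1 + 1e-12  # keep the max-volume lesion in the last bin
    which = np.clip(np.digitize(vol, edges) - 1, 0, len(edges) - 2)
    centers, means = [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.any():
            centers.append(np.sqrt(edges[b] * edges[b + 1]))
            means.append(rate[sel].mean())
    centers = np.asarray(centers)
    means = np.asarray(means)
    flags: list[str] = []
    if len(centers) < 2 or np.ptp(means) == 0:
        flags.append("r2_undefined_degenerate_curve")
        slope = 0.0 if len(centers) < 2 else float(
            np.polyfit(np.log10(centers), means, 1)[0]
        )
        return BinnedCurve(centers, means, float("nan"), slope, flags)
    x = np.log10(centers)
    slope, _ = np.polyfit(x, means, 1)
    r = stats.pearsonr(x, means).statistic
    return BinnedCurve(centers, means, float(r ** 2), float(slope), flags)


def compare_groups(scores_a: np.ndarray, scores_b: np.ndarray) -> GroupComparison:
    """Two-sided paired Wilcoxon signed-rank test between two performers'
    per-case scores. All-zero differences yield p = 1 with a degenerate
    flag rather than an error."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if len(a) < 5:
        raise ValueError("paired test needs at least 5 cases")
    if np.all(a == b):
        return GroupComparison(0.0, 1.0, len(a), ["degenerate_all_ties"])
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return GroupComparison(float(res.statistic), float(res.pvalue), len(a), [])
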