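"""End-to-end challenge evaluation: per-case metrics to cohort reports.

Walks a case tree (one directory per case holding a reference mask named
``consensus.nii.gz`` or ``gt.nii.gz`` plus one mask per performer),
computes the segmentation and detection reports of every performer
against the reference, then assembles cohort-level products: average-rank
tables, performer clustering on a metric pair, score-vs-burden
regressions, and the per-lesion detection-rate-vs-size curve.

Cases whose reference is empty carry no usable overlap or detection
scores; they are routed to the no-consensus report (lesion count and
total lesion load per performer, perfect value 0) and excluded from every
average.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import EvalConfig
from .detection import (
    detection_metrics,
    label_lesions,
    no_consensus_metrics,
    per_lesion_detection_rates,
)
from .seg_metrics import build_eval_region, evaluate_pair
from .volume import BinaryVolume, assert_same_grid, read_mask

__all__ = ["CaseInputs", "ReportBundle", "discover_cases", "evaluate_case", "run_evaluation"]

logger = logging.getLogger("mseval")

REFERENCE_NAMES = ("consensus.nii.gz", "consensus.nii", "gt.nii.gz", "gt.nii")


@dataclass
class CaseInputs:
    case_id: str
    reference: BinaryVolume
    performers: dict[str, BinaryVolume]


@dataclass
class ReportBundle:
    """All evaluation products of one run, as DataFrames keyed by name."""

    segmentation: pd.DataFrame
    detection: pd.DataFrame
    no_consensus: pd.DataFrame
    per_lesion: pd.DataFrame
    ranks: dict[str, pd.Series] = field(default_factory=dict)
    clusters: pd.DataFrame | None = None
    regressions: pd.DataFrame | None = None
    size_curve: pd.DataFrame | None = None
    config: EvalConfig = field(default_factory=EvalConfig)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.segmentation.to_csv(out / "segmentation.csv", index=False)
        self.detection.to_csv(out / "detection.csv", index=False)
        self.no_consensus.to_csv(out / "no_consensus.csv", index=False)
        self.per_lesion.to_csv(out / "per_lesion.csv", index=False)
        for metric, avg in self.ranks.items():
            avg.rename("average_rank").to_csv(out / f"ranks_{metric}.csv")
        if self.clusters is not None:
            self.clusters.to_csv(out / "clusters.csv", index=False)
        if self.regressions is not None:
            self.regressions.to_csv(out / "regressions.csv", index=False)
        if self.size_curve is not None:
            self.size_curve.to_csv(out / "size_curve.csv", index=False)
        log = {"package_version": __version__, "config": self.config.to_dict()}
        (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
        return out


def discover_cases(root: str | Path) -> list[CaseInputs]:
    """Load a challenge case tree; errors name every offending case."""
    root = Path(root)
    case_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not case_dirs:
        raise FileNotFoundError(f"no case directories under {root}")
    cases, problems = [], []
    for cdir in case_dirs:
        ref_path = next((cdir / n for n in REFERENCE_NAMES if (cdir / n).exists()), None)
        if ref_path is None:
            problems.append(f"{cdir.name}: no reference mask ({'/'.join(REFERENCE_NAMES)})")
            continue
        reference = read_mask(ref_path, case_id=cdir.name, performer_id="consensus")
        performers = {}
        for f in sorted(cdir.glob("*.nii*")):
            if f == ref_path:
                continue
            pid = f.name.split(".")[0]
            performers[pid] = read_mask(f, case_id=cdir.name, performer_id=pid)
        if not performers:
            problems.append(f"{cdir.name}: no performer masks")
            continue
        try:
            assert_same_grid([reference, *performers.values()])
        except Exception as exc:
            problems.append(f"{cdir.name}: {exc}")
            continue
        cases.append(CaseInputs(cdir.name, reference, performers))
    if problems:
        raise ValueError("malformed case tree:\n  " + "\n  ".join(problems))
    return cases


def evaluate_case(
    case: CaseInputs, config: EvalConfig
) -> tuple[list[dict], list[dict], list[dict], list]:
    """Segmentation rows, detection rows and no-consensus rows for one case.

    Also returns ``(lg, [la...])`` material for the per-lesion rate table
    (empty when the case has no reference lesions).
    """
    seg_rows: list[dict] = []
    det_rows: list[dict] = []
    nc_rows: list[dict] = []
    params = config.detection
    if case.reference.is_empty:
        for pid, mask in sorted(case.performers.items()):
            rep = no_consensus_metrics(mask, params)
            nc_rows.append(
                {
                    "case_id": case.case_id,
                    "performer_id": pid,
                    "n_lesions": rep.n_lesions,
                    "total_volume_cm3": rep.total_volume_cm3,
                }
            )
        return seg_rows, det_rows, nc_rows, []

    region = build_eval_region([case.reference, *case.performers.values()])
    lg = label_lesions(case.reference, params)
    lesion_material = [lg, []]
    for pid, mask in sorted(case.performers.items()):
        seg = evaluate_pair(mask, case.reference, region=region)
        seg_rows.append(
            {
                "case_id": case.case_id,
                "performer_id": pid,
                "dice": seg.dice,
                "ppv": seg.ppv,
                "sensitivity": seg.sensitivity,
                "specificity": seg.specificity,
                "assd_mm": seg.assd_mm,
                "flags": ";".join(seg.flags),
            }
        )
        la = label_lesions(mask, params)
        det = detection_metrics(lg, la, params)
        det_rows.append(
            {
                "case_id": case.case_id,
                "performer_id": pid,
                "m": det.m,
                "n": det.n,
                "tp_g": det.tp_g,
                "tp_a": det.tp_a,
                "se_l": det.lesion_sensitivity,
                "p_l": det.lesion_ppv,
                "f1": det.f1,
                "flags": ";".join(det.flags),
            }
        )
        lesion_material[1].append(la)
    return seg_rows, det_rows, nc_rows, lesion_material


def run_evaluation(
    root: str | Path,
    config: EvalConfig | None = None,
    out_dir: str | Path | None = None,
) -> ReportBundle:
    """Evaluate a whole case tree and assemble the cohort reports.

    Per-case failures are logged and skipped so one bad case cannot sink a
    run; reruns with the same inputs and config are bit-identical.
    """
    from .cohort import (  # local import: cohort pulls in sklearn
        cluster_performers,
        detection_rate_vs_size,
        rank_methods,
        score_vs_burden,
        summarize_performers,
    )

    config = config or EvalConfig()
    cases = discover_cases(root)
    seg_rows: list[dict] = []
    det_rows: list[dict] = []
    nc_rows: list[dict] = []
    rate_cases: list = []
    burdens: list[dict] = []
    for case in cases:
        try:
            s, d, nc, material = evaluate_case(case, config)
        except Exception:
            logger.exception("case %s failed; continuing", case.case_id)
            continue
        seg_rows += s
        det_rows += d
        nc_rows += nc
        if material:
            rate_cases.append(tuple(material))
            lg = material[0]
            burdens.append(
                {
                    "case_id": case.case_id,
                    "n_lesions": lg.n_lesions,
                    "total_load_cm3": float(lg.lesion_volumes_mm3.sum()) / 1000.0,
                }
            )

    seg = pd.DataFrame(seg_rows)
    det = pd.DataFrame(det_rows)
    nc = pd.DataFrame(nc_rows, columns=["case_id", "performer_id", "n_lesions",
                                        "total_volume_cm3"])
    per_lesion = (
        per_lesion_detection_rates(rate_cases, config.detection)
        if rate_cases
        else pd.DataFrame(columns=["case_id", "lesion_id", "volume_mm3",
                                   "detection_rate_pct"])
    )
    bundle = ReportBundle(seg, det, nc, per_lesion, config=config)

    if not seg.empty:
        scores = seg.merge(det[["case_id", "performer_id", "se_l", "p_l", "f1"]],
                           on=["case_id", "performer_id"])
        n_performers = scores["performer_id"].nunique()
        if n_performers >= 2:
            for metric in ("dice", "f1", "assd_mm"):
                try:
                    res = rank_methods(scores, metric,
                                       higher_is_better=metric not in config.lower_is_better)
                    bundle.ranks[metric] = res.average_rank
                except ValueError as exc:
                    logger.warning("ranking on %s skipped: %s", metric, exc)
        if n_performers >= config.cluster_k:
            summaries = summarize_performers(scores, config.cluster_metrics)
            labels = cluster_performers(summaries, k=config.cluster_k,
                                        seed=config.cluster_seed)
            bundle.clusters = pd.DataFrame(
                {
                    "performer_id": [s.performer_id for s in summaries],
                    "mean_1": [s.mean[0] for s in summaries],
                    "mean_2": [s.mean[1] for s in summaries],
                    "n_cases": [s.n_cases for s in summaries],
                    "cluster": labels,
                }
            )
        burden_df = pd.DataFrame(burdens)
        if len(burden_df) >= 3:
            reg_rows = []
            per_case = scores.groupby("case_id")[["dice", "f1", "assd_mm"]].mean()
            per_case = per_case.join(burden_df.set_index("case_id"))
            for metric in ("dice", "f1", "assd_mm"):
                for burden in ("n_lesions", "total_load_cm3"):
                    sub = per_case[[metric, burden]].dropna()
                    if len(sub) < 3 or (sub[burden] <= 0).any():
                        continue
                    r = score_vs_burden(sub[metric].to_numpy(), sub[burden].to_numpy())
                    reg_rows.append(
                        {
                            "metric": metric,
                            "burden": burden,
                            "r2_spearman": r.r2,
                            "slope": r.slope,
                            "n_cases": r.n,
                            "flags": ";".join(r.flags),
                        }
                    )
            if reg_rows:
                bundle.regressions = pd.DataFrame(reg_rows)
        if len(per_lesion) > 0:
            curve = detection_rate_vs_size(per_lesion)
            bundle.size_curve = pd.DataFrame(
                {
                    "bin_center_mm3": curve.bin_centers,
                    "mean_rate_pct": curve.bin_means,
                    "r2": curve.r2,
                    "slope_per_decade": curve.slope,
                }
            )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
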