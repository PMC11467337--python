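"""Patient-level mutation screening from single-cell predictions.

A patient's screening statistic is the positive prediction ratio
r = (#cells called mutant) / (#cells imaged).  Sweeping a threshold t over
r (a patient is called mutant when r >= t) yields a patient-wise ROC curve;
the area under it summarizes how well the single-cell classifier separates
genotypes at the patient level.  The AUC is computed by trapezoidal
integration over the step curve and cross-checked against the
pair-concordance statistic (ties counted 1/2), which is mathematically
identical for this construction.

Thresholds between two adjacent distinct ratios all induce the same
confusion table, so each ROC point is annotated with the half-open interval
``(t_low, t_high]`` of thresholds that achieve it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PatientScreeningResult", "RocPoint", "RocResult", "OperatingPoints",
           "patient_ratio", "patient_ratios", "roc_auc", "concordance_auc",
           "operating_points"]


@dataclass
class PatientScreeningResult:
    patient_id: str
    genotype: str           # "WT" or "MUT" (ground truth)
    n_cells: int
    positive_ratio: float   # fraction of cells predicted MUT

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("a screening result needs at least one cell")
        if not (0.0 <= self.positive_ratio <= 1.0):
            raise ValueError("positive_ratio must lie in [0, 1]")


def patient_ratio(patient_id: str, genotype: str, predicted_labels) -> PatientScreeningResult:
    """Positive prediction ratio of one patient from per-cell labels.

    ``predicted_labels`` is a sequence of "WT"/"MUT" strings (or 0/1 ints).
    """
    labels = list(predicted_labels)
    if len(labels) == 0:
        raise ValueError(f"patient {patient_id!r}: empty prediction set")
    pos = sum(1 for v in labels if v in ("MUT", 1))
    return PatientScreeningResult(
        patient_id=patient_id, genotype=genotype, n_cells=len(labels),
        positive_ratio=pos / len(labels),
    )


def patient_ratios(predictions, manifest) -> list[PatientScreeningResult]:
    """Group a prediction table by patient (via the manifest) into ratios.

    ``predictions`` needs columns image_id, predicted_label; ``manifest``
    (images table) needs image_id, patient_id, genotype.
    """
    merged = predictions.merge(
        manifest[["image_id", "patient_id", "genotype"]], on="image_id", how="inner"
    )
    if len(merged) == 0:
        raise ValueError("no predictions match the manifest")
    out = []
    for pid, sub in merged.groupby("patient_id", sort=True):
        out.append(patient_ratio(str(pid), str(sub["genotype"].iloc[0]),
                                 sub["predicted_label"].tolist()))
    return out


@dataclass
class RocPoint:
    threshold_low: float   # exclusive
    threshold_high: float  # inclusive (math.inf for the all-negative point)
    fpr: float
    tpr: float


@dataclass
class OperatingPoints:
    tpr_at_zero_fpr: float
    tpr_at_zero_fpr_thresholds: tuple[float, float]  # (low, high]
    fpr_at_full_tpr: float
    fpr_at_full_tpr_thresholds: tuple[float, float]


@dataclass
class RocResult:
    points: list[RocPoint]
    auc: float
    auc_concordance: float
    n_wt: int
    n_mut: int

    def operating_points(self) -> OperatingPoints:
        return operating_points(self)


def concordance_auc(results) -> float:
    """AUC as the (MUT, WT) pair-concordance statistic, ties counted 1/2."""
    wt = np.array([r.positive_ratio for r in results if r.genotype == "WT"])
    mut = np.array([r.positive_ratio for r in results if r.genotype == "MUT"])
    if len(wt) == 0 or len(mut) == 0:
        raise ValueError("both genotypes must be present")
    gt = (mut[:, None] > wt[None, :]).sum()
    eq = (mut[:, None] == wt[None, :]).sum()
    return float((gt + 0.5 * eq) / (len(mut) * len(wt)))


def roc_auc(results) -> RocResult:
    """Patient-wise ROC over positive-ratio thresholds (rule: call MUT if r >= t).

    The threshold sweep visits every distinct ratio plus +inf (nobody called
    mutant); AUC is the trapezoid over the resulting step curve and is
    verified against the pair-concordance statistic.
    """
    results = list(results)
    wt = [r for r in results if r.genotype == "WT"]
    mut = [r for r in results if r.genotype == "MUT"]
    if not wt or not mut:
        raise ValueError("ROC needs patients of both genotypes")
    ratios = np.array([r.positive_ratio for r in results])
    genos = np.array([r.genotype for r in results])
    distinct = np.unique(ratios)[::-1]  # descending
    points = []
    prev_hi = math.inf
    # all-negative point first (thresholds above every ratio)
    points.append(RocPoint(threshold_low=float(distinct[0]), threshold_high=math.inf,
                           fpr=0.0, tpr=0.0))
    for i, t in enumerate(distinct):
        called = ratios >= t
        tpr = float(called[genos == "MUT"].sum() / len(mut))
        fpr = float(called[genos == "WT"].sum() / len(wt))
        lo = float(distinct[i + 1]) if i + 1 < len(distinct) else -math.inf
        points.append(RocPoint(threshold_low=lo, threshold_high=float(t), fpr=fpr, tpr=tpr))
    fprs = np.array([p.fpr for p in points])
    tprs = np.array([p.tpr for p in points])
    order = np.argsort(fprs, kind="stable")
    auc = float(np.trapezoid(tprs[order], fprs[order]))
    auc_pc = concordance_auc(results)
    if abs(auc - auc_pc) > 1e-9:
        raise AssertionError(
            f"trapezoid AUC {auc} disagrees with pair concordance {auc_pc}"
        )
    return RocResult(points=points, auc=auc, auc_concordance=auc_pc,
                     n_wt=len(wt), n_mut=len(mut))


def operating_points(roc: RocResult) -> OperatingPoints:
    """Best achievable corners of the ROC: max TPR at FPR = 0 and min FPR at
    TPR = 1, each with the half-open threshold interval achieving it."""
    zero_fpr = [p for p in roc.points if p.fpr == 0.0]
    best_tpr = max(p.tpr for p in zero_fpr)
    cand = [p for p in zero_fpr if p.tpr == best_tpr]
    lo = min(p.threshold_low for p in cand)
    hi = max(p.threshold_high for p in cand)
    tpr_interval = (lo, hi)

    full_tpr = [p for p in roc.points if p.tpr == 1.0]
    best_fpr = min(p.fpr for p in full_tpr)
    cand = [p for p in full_tpr if p.fpr == best_fpr]
    lo = min(p.threshold_low for p in cand)
    hi = max(p.threshold_high for p in cand)
    return OperatingPoints(
        tpr_at_zero_fpr=best_tpr, tpr_at_zero_fpr_thresholds=tpr_interval,
        fpr_at_full_tpr=best_fpr, fpr_at_full_tpr_thresholds=(lo, hi),
    )
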