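"""Lesion-activity evaluation suite.

Voxel metrics (DSC, PPV, sensitivity, specificity), lesion-wise detection
metrics on 26-connected components (lesion sensitivity S, lesion positive
predictive value P, their harmonic mean F1), no-new-lesion metrics (count
and volume of predicted lesions, optimal value zero), and the symmetric
mean surface distance in millimetres.

Metrics whose denominator is empty (DSC with empty ground truth, surface
distance with an empty mask, ...) are reported as explicit ``None`` with a
flag, never silently as 0: cohort means skip flagged cases, mirroring how
lesion-activity challenges split scoring between lesion and no-lesion
cases.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import GridMismatchError
from .volio import BinaryMask

#: full 3D neighbourhood -> 26-connectivity components
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)
CONNECTIVITY_6 = ndimage.generate_binary_structure(3, 1)


@dataclasses.dataclass
class EvalReport:
    """Per-case metric bundle; ``None`` plus a flag marks undefined values."""

    dsc: float | None
    lesion_sensitivity: float | None
    lesion_ppv: float | None
    f1: float | None
    voxel_ppv: float | None
    sensitivity: float | None
    specificity: float | None
    msd: float | None
    n_lesions_pred: int
    lesion_volume_pred: float
    flags: dict[str, str] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_grids(a: BinaryMask, g: BinaryMask):
    if a.shape != g.shape:
        raise GridMismatchError(f"grids differ: {a.shape} vs {g.shape}")


def confusion_counts(a: BinaryMask, g: BinaryMask) -> tuple[int, int, int, int]:
    """Voxelwise (TP, FP, FN, TN)."""
    _check_grids(a, g)
    am = a.data.astype(bool)
    gm = g.data.astype(bool)
    tp = int(np.count_nonzero(am & gm))
    fp = int(np.count_nonzero(am & ~gm))
    fn = int(np.count_nonzero(~am & gm))
    tn = int(am.size - tp - fp - fn)
    return tp, fp, fn, tn


def dsc(a: BinaryMask, g: BinaryMask) -> float | None:
    """Dice similarity 2TP/(2TP+FP+FN); None when both masks are empty."""
    tp, fp, fn, _ = confusion_counts(a, g)
    denom = 2 * tp + fp + fn
    if denom == 0:
        return None
    return 2.0 * tp / denom


def label_lesions(mask: BinaryMask,
                  connectivity: np.ndarray = CONNECTIVITY_26
                  ) -> tuple[np.ndarray, int]:
    """Label connected components; returns (label volume, count)."""
    labels, count = ndimage.label(mask.data, structure=connectivity)
    return labels, int(count)


def lesion_detection(a: BinaryMask, g: BinaryMask,
                     connectivity: np.ndarray = CONNECTIVITY_26
                     ) -> tuple[float | None, float | None, float | None]:
    """Lesion-wise (S, P, F1) on connected components.

    A ground-truth lesion counts as detected when it shares at least one
    voxel with the prediction, and symmetrically for predicted lesions.
    With no ground-truth lesions the triple is undefined (None); such cases
    belong to the no-lesion track. An empty prediction against a non-empty
    ground truth scores S = P = F1 = 0.
    """
    _check_grids(a, g)
    gt_labels, m = label_lesions(g, connectivity)
    pred_labels, n = label_lesions(a, connectivity)
    if m == 0:
        return None, None, None
    am = a.data.astype(bool)
    gm = g.data.astype(bool)
    tp_g = len(np.unique(gt_labels[gm & am]))
    s = tp_g / m
    if n == 0:
        p = 0.0
    else:
        tp_a = len(np.unique(pred_labels[am & gm]))
        p = tp_a / n
    f1 = 2 * s * p / (s + p) if s + p > 0 else 0.0
    return s, p, f1


def no_lesion_metrics(a: BinaryMask,
                      connectivity: np.ndarray = CONNECTIVITY_26
                      ) -> tuple[int, float]:
    """(number of predicted lesions, their total volume in mm^3)."""
    _, count = label_lesions(a, connectivity)
    voxel_volume = float(np.prod(a.spacing))
    return count, float(np.count_nonzero(a.data)) * voxel_volume


def overlap_rates(a: BinaryMask, g: BinaryMask
                  ) -> tuple[float | None, float | None, float | None]:
    """(PPV, Se, Sp): |A∩G|/|A|, |A∩G|/|G|, TN/(TN+FP).

    Each rate is None when its denominator is zero.
    """
    tp, fp, fn, tn = confusion_counts(a, g)
    ppv = tp / (tp + fp) if tp + fp > 0 else None
    se = tp / (tp + fn) if tp + fn > 0 else None
    sp = tn / (tn + fp) if tn + fp > 0 else None
    return ppv, se, sp


def surface_voxels(mask: BinaryMask) -> np.ndarray:
    """Boolean map of mask voxels with >= 1 background 6-neighbour.

    Voxels on the grid border count as surface (outside the grid is
    background).
    """
    m = mask.data.astype(bool)
    interior = ndimage.binary_erosion(m, structure=CONNECTIVITY_6,
                                      border_value=0)
    return m & ~interior


def mean_surface_distance(a: BinaryMask, g: BinaryMask) -> float | None:
    """Symmetric mean surface distance in mm; None if either mask is empty."""
    _check_grids(a, g)
    if not a.data.any() or not g.data.any():
        return None
    spacing = np.asarray(a.spacing)
    pa = np.argwhere(surface_voxels(a)) * spacing
    pg = np.argwhere(surface_voxels(g)) * spacing
    d_ag = cKDTree(pg).query(pa)[0]
    d_ga = cKDTree(pa).query(pg)[0]
    return float((d_ag.sum() + d_ga.sum()) / (len(pa) + len(pg)))


def evaluate_case(a: BinaryMask, g: BinaryMask,
                  connectivity: np.ndarray = CONNECTIVITY_26) -> EvalReport:
    """Full per-case evaluation of prediction ``a`` against ground truth ``g``."""
    flags: dict[str, str] = {}
    d = dsc(a, g)
    if d is None:
        flags["dsc"] = "both masks empty"
    s, p, f1 = lesion_detection(a, g, connectivity)
    if s is None:
        flags["f1"] = "no ground-truth lesions (no-lesion case)"
    ppv, se, sp = overlap_rates(a, g)
    if ppv is None:
        flags["voxel_ppv"] = "empty prediction"
    if se is None:
        flags["sensitivity"] = "empty ground truth"
    if sp is None:
        flags["specificity"] = "no true-negative voxels possible"
    msd = mean_surface_distance(a, g)
    if msd is None:
        flags["msd"] = "empty mask surface"
    count, volume = no_lesion_metrics(a, connectivity)
    return EvalReport(dsc=d, lesion_sensitivity=s, lesion_ppv=p, f1=f1,
                      voxel_ppv=ppv, sensitivity=se, specificity=sp,
                      msd=msd, n_lesions_pred=count,
                      lesion_volume_pred=volume, flags=flags)


_NUMERIC_FIELDS = ("dsc", "lesion_sensitivity", "lesion_ppv", "f1",
                   "voxel_ppv", "sensitivity", "specificity", "msd",
                   "n_lesions_pred", "lesion_volume_pred")


def aggregate_reports(reports: dict[str, EvalReport]) -> dict[str, float | None]:
    """Cohort means per metric, skipping cases where the metric is flagged."""
    means: dict[str, float | None] = {}
    for field in _NUMERIC_FIELDS:
        values = [getattr(r, field) for r in reports.values()
                  if getattr(r, field) is not None]
        means[field] = float(np.mean(values)) if values else None
    return means


def reports_to_frame(reports: dict[str, EvalReport]) -> pd.DataFrame:
    rows = []
    for patient_id, rep in reports.items():
        row = {"patient_id": patient_id}
        row.update({f: getattr(rep, f) for f in _NUMERIC_FIELDS})
        row["flags"] = ";".join(f"{k}:{v}" for k, v in rep.flags.items())
        rows.append(row)
    return pd.DataFrame(rows)


def write_reports(reports: dict[str, EvalReport], out_dir) -> None:
    """Per-case CSV plus cohort-aggregate JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports_to_frame(reports).to_csv(out_dir / "per_case.csv", index=False)
    (out_dir / "cohort.json").write_text(
        json.dumps(aggregate_reports(reports), indent=1))
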