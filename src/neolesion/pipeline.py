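"""End-to-end inference: normalize -> slice -> predict -> reassemble -> vote.

A *predictor* maps a list of SliceRecords to one probability map per record
(2D arrays on the padded canvas). ``model_predictor`` wraps a trained
network; ``oracle_predictor`` returns the ground-truth labels and is used
to verify that the geometric pipeline is the identity end to end.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .errors import MissingLabelError
from .model import UNet
from .normalize import normalize_volume
from .reconstruct import majority_vote, reassemble_view
from .slicer import PLANES, SliceRecord, extract_plane_slices
from .volio import BinaryMask, LongitudinalCase

Predictor = Callable[[list[SliceRecord]], list[np.ndarray]]


def model_predictor(model: UNet, batch_size: int = 8) -> Predictor:
    def predict(records: list[SliceRecord]) -> list[np.ndarray]:
        x = np.stack([rec.image.transpose(2, 0, 1) for rec in records])
        probs = model.predict(x.astype(np.float32), batch_size=batch_size)
        return [p[0] for p in probs]

    return predict


def oracle_predictor(records: list[SliceRecord]) -> list[np.ndarray]:
    """Ground-truth stub predictor (pipeline self-check)."""
    out = []
    for rec in records:
        if rec.label is None:
            raise MissingLabelError(
                "oracle predictor requires labelled records")
        out.append(rec.label.astype(np.float32))
    return out


def normalize_case(case: LongitudinalCase, percentile: float = 99.0
                   ) -> LongitudinalCase:
    """Normalize both time points independently; ground truth untouched."""
    return LongitudinalCase(
        patient_id=case.patient_id,
        baseline=normalize_volume(case.baseline, percentile),
        followup=normalize_volume(case.followup, percentile),
        gt_new_lesions=case.gt_new_lesions)


def predict_case(case: LongitudinalCase, predictor: Predictor,
                 canvas: int, normalize: bool = True,
                 threshold: float = 0.5) -> BinaryMask:
    """Full three-view segmentation of one longitudinal case."""
    work = normalize_case(case) if normalize else case
    view_masks = {}
    for plane in PLANES:
        records = extract_plane_slices(work, plane, canvas)
        probs = predictor(records)
        view_masks[plane] = reassemble_view(
            list(zip(records, probs)), plane, case.followup,
            threshold=threshold)
    return majority_vote(view_masks["axial"], view_masks["sagittal"],
                         view_masks["coronal"])
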