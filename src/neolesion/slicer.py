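"""Slice decomposition of paired volumes into padded two-channel 2D samples.

Each 3D case is cut along the three orthogonal planes. Under the canonical
axis order, axis 0 is the sagittal slicing axis, axis 1 coronal, axis 2
axial. Every slice is zero-padded onto a square canvas (512 by default) by
centering, baseline and follow-up are stacked as channels (early fusion),
and the per-plane lists can be pooled into a single training set. Padding
bookkeeping is kept on each record so the operation inverts exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .errors import CanvasOverflowError, MissingLabelError
from .volio import LongitudinalCase

PLANES = ("sagittal", "coronal", "axial")
PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}
DEFAULT_CANVAS = 512


@dataclasses.dataclass(eq=False)
class SliceRecord:
    """One padded two-channel slice with exact-inversion bookkeeping.

    ``image`` is (canvas, canvas, 2): channel 0 baseline, channel 1
    follow-up. ``label`` (optional) is the matching padded binary slice of
    the new-lesion ground truth.
    """

    image: np.ndarray
    label: np.ndarray | None
    plane: str
    index: int
    orig_shape: tuple[int, int]
    pad_offsets: tuple[int, int]
    patient_id: str = ""


def pad_to_canvas(slice2d: np.ndarray,
                  canvas: int = DEFAULT_CANVAS) -> tuple[np.ndarray, tuple[int, int]]:
    """Center a 2D slice on a square zero canvas.

    Odd remainders put the smaller margin on the low-index side. Returns the
    padded array and the (row, col) low-side offsets needed for inversion.
    """
    h, w = slice2d.shape
    if h > canvas or w > canvas:
        raise CanvasOverflowError(
            f"slice {slice2d.shape} exceeds canvas {canvas}")
    r0 = (canvas - h) // 2
    c0 = (canvas - w) // 2
    out = np.zeros((canvas, canvas), dtype=slice2d.dtype)
    out[r0:r0 + h, c0:c0 + w] = slice2d
    return out, (r0, c0)


def unpad(padded: np.ndarray, pad_offsets: tuple[int, int],
          orig_shape: tuple[int, int]) -> np.ndarray:
    """Exact inverse of :func:`pad_to_canvas`."""
    r0, c0 = pad_offsets
    h, w = orig_shape
    return padded[r0:r0 + h, c0:c0 + w]


def _take_slice(data: np.ndarray, plane: str, index: int) -> np.ndarray:
    axis = PLANE_AXIS[plane]
    return np.take(data, index, axis=axis)


def extract_plane_slices(case: LongitudinalCase, plane: str,
                         canvas: int = DEFAULT_CANVAS) -> list[SliceRecord]:
    """All slices of a case along one plane, padded and channel-fused.

    Records are ordered by increasing slice index. When the case carries a
    new-lesion ground truth, each record gets the matching padded label.
    """
    if plane not in PLANE_AXIS:
        raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")
    axis = PLANE_AXIS[plane]
    n_slices = case.baseline.shape[axis]
    records = []
    for index in range(n_slices):
        b2d = _take_slice(case.baseline.data, plane, index)
        f2d = _take_slice(case.followup.data, plane, index)
        b_pad, offsets = pad_to_canvas(b2d, canvas)
        f_pad, _ = pad_to_canvas(f2d, canvas)
        image = np.stack([b_pad, f_pad], axis=-1).astype(np.float32)
        label = None
        if case.gt_new_lesions is not None:
            g2d = _take_slice(case.gt_new_lesions.data, plane, index)
            label, _ = pad_to_canvas(g2d, canvas)
        records.append(SliceRecord(image=image, label=label, plane=plane,
                                   index=index, orig_shape=b2d.shape,
                                   pad_offsets=offsets,
                                   patient_id=case.patient_id))
    return records


def extract_all_planes(case: LongitudinalCase,
                       canvas: int = DEFAULT_CANVAS) -> dict[str, list[SliceRecord]]:
    return {plane: extract_plane_slices(case, plane, canvas)
            for plane in PLANES}


def select_lesion_positive(records: list[SliceRecord]) -> list[SliceRecord]:
    """Keep exactly the slices whose label contains at least one lesion pixel."""
    for rec in records:
        if rec.label is None:
            raise MissingLabelError(
                f"record {rec.plane}/{rec.index} has no label")
    return [rec for rec in records if rec.label.sum() >= 1]


def aggregate_planes(axial: list[SliceRecord], sagittal: list[SliceRecord],
                     coronal: list[SliceRecord]) -> list[SliceRecord]:
    """Pool the three per-plane lists into a single training input."""
    return list(axial) + list(sagittal) + list(coronal)


# ------------------------------------------------------------- serialization

def save_pool(records: list[SliceRecord], out_dir) -> Path:
    """Serialize a slice pool as compressed arrays plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    arrays = {}
    for i, rec in enumerate(records):
        arrays[f"image_{i}"] = rec.image
        if rec.label is not None:
            arrays[f"label_{i}"] = rec.label
        manifest.append({
            "plane": rec.plane, "index": rec.index,
            "orig_shape": list(rec.orig_shape),
            "pad_offsets": list(rec.pad_offsets),
            "patient_id": rec.patient_id,
            "has_label": rec.label is not None,
        })
    np.savez_compressed(out_dir / "pool.npz", **arrays)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir


def load_pool(pool_dir) -> list[SliceRecord]:
    pool_dir = Path(pool_dir)
    manifest = json.loads((pool_dir / "manifest.json").read_text())
    arrays = np.load(pool_dir / "pool.npz")
    records = []
    for i, meta in enumerate(manifest):
        label = arrays[f"label_{i}"] if meta["has_label"] else None
        records.append(SliceRecord(
            image=arrays[f"image_{i}"], label=label, plane=meta["plane"],
            index=meta["index"], orig_shape=tuple(meta["orig_shape"]),
            pad_offsets=tuple(meta["pad_offsets"]),
            patient_id=meta["patient_id"]))
    return records
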