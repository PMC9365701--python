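"""3D reconstruction from 2D predictions and three-view majority voting.

Each plane's predicted slices are unpadded, binarized (threshold 0.5, ties
mapped to foreground) and stacked along the plane axis to give one 3D mask
per view; a voxelwise majority vote over the three views produces the final
segmentation.
"""

from __future__ import annotations

import numpy as np

from .errors import CompletenessError, GridMismatchError
from .slicer import PLANE_AXIS, SliceRecord, unpad
from .volio import BinaryMask, Volume

DEFAULT_THRESHOLD = 0.5


def reassemble_view(predictions: list[tuple[SliceRecord, np.ndarray]],
                    plane: str, reference: Volume,
                    threshold: float = DEFAULT_THRESHOLD) -> BinaryMask:
    """Stack per-slice probability maps back into a 3D binary mask.

    ``predictions`` pairs each source SliceRecord with its predicted
    probability map on the padded canvas. Every slice index along the plane
    axis must be present exactly once. Binarization uses ``>= threshold``.
    """
    axis = PLANE_AXIS[plane]
    n_slices = reference.shape[axis]
    out = np.zeros(reference.shape, dtype=np.uint8)
    seen: set[int] = set()
    for rec, prob in predictions:
        if rec.plane != plane:
            raise CompletenessError(
                f"record from plane {rec.plane!r} passed to {plane!r} view")
        plane_slice = unpad(np.asarray(prob), rec.pad_offsets, rec.orig_shape)
        binary = (plane_slice >= threshold).astype(np.uint8)
        indexer = [slice(None)] * 3
        indexer[axis] = rec.index
        out[tuple(indexer)] = binary
        seen.add(rec.index)
    missing = set(range(n_slices)) - seen
    if missing:
        raise CompletenessError(
            f"missing {plane} slice indices: {sorted(missing)[:10]}")
    return BinaryMask(out, reference.spacing, reference.affine)


def majority_vote(m_axial: BinaryMask, m_sagittal: BinaryMask,
                  m_coronal: BinaryMask) -> BinaryMask:
    """Voxel is foreground iff at least 2 of the 3 views mark it."""
    masks = (m_axial, m_sagittal, m_coronal)
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise GridMismatchError(f"vote inputs differ in shape: {shapes}")
    votes = sum(m.data.astype(np.uint8) for m in masks)
    return BinaryMask((votes >= 2).astype(np.uint8), m_axial.spacing,
                      m_axial.affine)
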