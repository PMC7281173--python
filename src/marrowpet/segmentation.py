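"""Metabolic tumor volume (MTV) segmentation by relative-SUVmax threshold.

The MTV is every search-region voxel with SUV >= fraction * SUVmax, the
maximum taken over the whole search region (single global SUVmax).  Ties at
exactly the threshold are included, so the hottest voxel is always a member.
No connected-component filtering is applied: disconnected marrow uptake is
biologically expected and the whole pelvic MTV is kept.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BinaryMask, SUVVolume

DEFAULT_FRACTION = 0.41


@dataclass
class MTVResult:
    mtv_mask: BinaryMask
    suv_max: float
    threshold_suv: float
    mtv_ml: float


def segment_mtv(
    volume: SUVVolume, search: BinaryMask, fraction: float = DEFAULT_FRACTION
) -> MTVResult:
    """Threshold the search region at ``fraction`` of its SUVmax."""
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction={fraction} must be in (0, 1)")
    if volume.values.shape != search.values.shape:
        raise ValueError(
            f"shape mismatch: volume {volume.values.shape} vs mask {search.values.shape}"
        )
    region = search.values.astype(bool)
    if not region.any():
        raise ValueError("empty search mask")
    suv_max = float(volume.values[region].max())
    if suv_max <= 0:
        raise ValueError("degenerate region: SUVmax is zero")
    threshold = fraction * suv_max
    mtv = region & (volume.values >= threshold)
    n = int(mtv.sum())
    return MTVResult(
        mtv_mask=BinaryMask(mtv.astype(np.uint8), volume.spacing_mm),
        suv_max=suv_max,
        threshold_suv=threshold,
        mtv_ml=n * volume.voxel_volume_ml,
    )
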