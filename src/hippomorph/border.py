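"""Relative medial-lateral position of the SUB-CA1 border in the body.

The measurement anchors at the most medial voxel of CA3 or DG (whichever
reaches further medially), drops a vertical line to the SUB/CA1 cortex
below (the *medial anchor*), and expresses the distance from the anchor to
the SUB-CA1 border line as a percentage of a reference width: either the
full hippocampal width (anchor to the lateral CA1 edge) or the DG width
(anchor to the lateral DG edge). Negative percentages mean the border lies
medial to the anchor, which real specimens do show.

Widths use a voxel-edge convention (lateral edge at max-x + 0.5 voxel),
applied uniformly so the ratios are convention-insensitive to first order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_volume import CoverageMask, LabelVolume, Landmarks, slice_mask
from .errors import AnchorError, DegenerateSliceError
from .subicular import select_body_slices  # noqa: F401  (shared increments convention)

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class BorderMeasurement:
    z: int
    offset_mm: float | None
    anchor: tuple[int, int]
    border_line_x: float
    full_width_mm: float
    dg_width_mm: float
    pct_of_full_width: float
    pct_of_dg_width: float


def medial_anchor(masks: dict[str, np.ndarray]) -> tuple[int, int]:
    """Most medial CA3/DG column, dropped vertically onto SUB or CA1.

    From the most inferior CA3/DG voxel in that column the march runs
    inferiorly until it hits SUB or CA1; if nothing is found a superior
    march is attempted with a warning (folded geometry). Raises
    :class:`AnchorError` when neither march lands.
    """
    medial = masks["CA3"] | masks["DG"]
    target = masks["SUB"] | masks["CA1"]
    if not medial.any() or not target.any():
        raise AnchorError("anchor needs CA3/DG and SUB/CA1 on the slice")
    x_star = int(np.nonzero(medial.any(axis=1))[0][0])
    ys = np.nonzero(medial[x_star])[0]
    y0 = int(ys[0])  # most inferior CA3/DG voxel in the column
    col = target[x_star]
    below = np.nonzero(col[:y0])[0]
    if below.size:
        return x_star, int(below[-1])  # first hit marching -y
    above = np.nonzero(col[y0 + 1:])[0]
    if above.size:
        warnings.warn("anchor found on superior march (folded geometry)", stacklevel=2)
        return x_star, int(above[0] + y0 + 1)
    raise AnchorError(f"no SUB/CA1 voxel on the vertical march at x={x_star}")


def border_position(
    masks: dict[str, np.ndarray],
    anchor: tuple[int, int],
    spacing,
    z: int | None = None,
    offset_mm: float | None = None,
) -> BorderMeasurement:
    """Quantify the SUB-CA1 border relative to both reference widths.

    The border line is the mean x of the CA1 voxels 8-adjacent to SUB (the
    'midpoint, if at an angle'). Raises :class:`DegenerateSliceError` when
    CA1 and SUB are nowhere adjacent on the slice.
    """
    dx = float(spacing[0])
    ca1, dg, sub = masks["CA1"], masks["DG"], masks["SUB"]
    if not ca1.any() or not dg.any():
        raise DegenerateSliceError("border measurement needs CA1 and DG")
    interface = ca1 & ndimage.binary_dilation(sub, structure=_STRUCT8)
    if not interface.any():
        raise DegenerateSliceError("no SUB-CA1 adjacency on slice")
    border_x = float(np.argwhere(interface)[:, 0].mean())
    ax = float(anchor[0])
    lat_ca1 = float(np.nonzero(ca1.any(axis=1))[0][-1]) + 0.5
    lat_dg = float(np.nonzero(dg.any(axis=1))[0][-1]) + 0.5
    full_w = (lat_ca1 - ax) * dx
    dg_w = (lat_dg - ax) * dx
    if full_w <= 0 or dg_w <= 0:
        raise DegenerateSliceError("non-positive reference width")
    offset = (border_x - ax) * dx
    return BorderMeasurement(
        z=z if z is not None else -1,
        offset_mm=offset_mm,
        anchor=(int(anchor[0]), int(anchor[1])),
        border_line_x=border_x,
        full_width_mm=full_w,
        dg_width_mm=dg_w,
        pct_of_full_width=offset / full_w * 100.0,
        pct_of_dg_width=offset / dg_w * 100.0,
    )


def _measure_slice(volume: LabelVolume, z: int, offset_mm: float | None) -> BorderMeasurement:
    masks = {n: slice_mask(volume, z, n) for n in ("CA1", "CA3", "DG", "SUB")}
    anchor = medial_anchor(masks)
    return border_position(masks, anchor, volume.spacing, z=z, offset_mm=offset_mm)


def measure_at_offsets(
    volume: LabelVolume,
    landmarks: Landmarks,
    offsets_mm=(0.0, 20.0),
    tolerance_mm: float = 3.0,
    coverage: CoverageMask | None = None,
) -> dict[float, BorderMeasurement | None]:
    """Border position at fixed distances posterior to the uncal apex.

    The 0 mm position is one slice posterior to the apex; others are
    ``apex + round(offset/dz)``. Unusable target slices are replaced by the
    nearest usable slice within ``tolerance_mm`` (searched alternating
    +1, -1, +2, ...); None when no usable slice exists in the window.
    """
    dz = volume.dz
    out: dict[float, BorderMeasurement | None] = {}
    max_delta = round(tolerance_mm / dz)
    for off in offsets_mm:
        target = landmarks.uncal_apex_z + (1 if off == 0 else round(off / dz))
        deltas = [0] + [s * d for d in range(1, max_delta + 1) for s in (1, -1)]
        result = None
        for d in deltas:
            z = target + d
            if not (0 <= z < volume.n_slices):
                continue
            if coverage is not None and not coverage.is_covered(z):
                continue
            try:
                result = _measure_slice(volume, z, off)
                break
            except (AnchorError, DegenerateSliceError):
                continue
        out[off] = result
    return out
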