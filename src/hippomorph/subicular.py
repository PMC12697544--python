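"""Medial-lateral composition of the subicular complex on body slices.

On selected coronal slices of the hippocampal body, the subicular cortex
(SUB -> PrS -> PaS, running lateral to medial) is traced along a
mid-cortical centerline from the SUB-CA1 interface to the most medial
extent of the most medial region present, and each region's share of the
centerline length is reported as a percentage. The centerline is the
medial-axis skeleton path of the union mask, anchored at both ends to the
anatomical extremes; this is a deterministic, curvature-adaptive stand-in
for manually drawn cortex-bisecting lines and coincides with them in the
straight-strip limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._path import centerline_path, extend_to_mask_edge, smoothed_cumlength
from .core_volume import LabelVolume, Landmarks, slice_mask
from .errors import DegenerateSliceError, LandmarkError, TopologyError

_STRUCT8 = np.ones((3, 3), dtype=bool)
_REGIONS = ("SUB", "PrS", "PaS")


@dataclass
class RibbonPath:
    """Ordered mid-cortical centerline with per-point region labels."""

    points: np.ndarray  # (N, 2) float, (x, y)
    labels: list[str]
    cum_mm: np.ndarray  # (N,) cumulative arclength in mm
    total_mm: float

    def region_lengths_mm(self) -> dict[str, float]:
        """Arclength per region; segments crossing an interface are split
        half-half between the two regions."""
        out: dict[str, float] = {}
        seg = np.diff(self.cum_mm)
        for i, length in enumerate(seg):
            out[self.labels[i]] = out.get(self.labels[i], 0.0) + length / 2.0
            out[self.labels[i + 1]] = out.get(self.labels[i + 1], 0.0) + length / 2.0
        return out


@dataclass
class ProportionRecord:
    z: int | None
    position_pct: float | None  # position along long axis, % posterior to apex
    pct: dict[str, float]  # per present region, sums to 100
    boundaries_pct: dict[str, float] = field(default_factory=dict)  # from lateral end
    total_length_mm: float = 0.0


def select_body_slices(
    landmarks: Landmarks, spacing, increments_pct=(10, 20, 30, 40, 50)
) -> list[int]:
    """Slices at percent-of-total-length increments posterior to the apex."""
    if landmarks.posterior_tip_z is None:
        raise LandmarkError("posterior tip required to select body slices")
    total = landmarks.posterior_tip_z - landmarks.anterior_tip_z
    out = []
    for k in increments_pct:
        z = landmarks.uncal_apex_z + round(k / 100.0 * total)
        if z > landmarks.posterior_tip_z:
            raise LandmarkError(f"{k}% increment lies posterior to the posterior tip")
        out.append(z)
    return out


def _interface_point(sub: np.ndarray, ca1: np.ndarray) -> tuple[float, float]:
    """SUB voxel nearest the centroid of the SUB-CA1 interface; falls back
    to the most lateral SUB voxel when no CA1 is adjacent."""
    touching = sub & ndimage.binary_dilation(ca1, structure=_STRUCT8)
    if touching.any():
        coords = np.argwhere(touching)
        centroid = coords.mean(axis=0)
        i = int(np.argmin(np.hypot(*(coords - centroid).T)))
        return tuple(coords[i].astype(float))
    coords = np.argwhere(sub)
    x_max = coords[:, 0].max()
    ys = coords[coords[:, 0] == x_max, 1]
    return float(x_max), float(np.median(ys))


def _medial_extreme(mask: np.ndarray) -> tuple[float, float]:
    coords = np.argwhere(mask)
    x_min = coords[:, 0].min()
    ys = coords[coords[:, 0] == x_min, 1]
    return float(x_min), float(np.median(ys))


def trace_ribbon(masks: dict[str, np.ndarray], spacing) -> RibbonPath:
    """Centerline of the subicular complex from the SUB-CA1 interface to the
    medial extreme of the most medial present region.

    ``masks`` holds 2D boolean masks for SUB, PrS, PaS (PaS and CA1 may be
    absent or all-false). Raises :class:`TopologyError` when the union is
    not a single connected component.
    """
    dx = float(spacing[0])
    sub = masks["SUB"]
    prs = masks.get("PrS")
    pas = masks.get("PaS")
    ca1 = masks.get("CA1")
    if not sub.any():
        raise DegenerateSliceError("no SUB on slice")
    if prs is None or not prs.any():
        warnings.warn("no PrS on slice; ribbon covers SUB only", stacklevel=2)
    union = sub.copy()
    for m in (prs, pas):
        if m is not None:
            union |= m
    _, n_comp = ndimage.label(union, structure=_STRUCT8)
    if n_comp != 1:
        raise TopologyError(f"subicular union has {n_comp} connected components")

    start = _interface_point(sub, ca1 if ca1 is not None else np.zeros_like(sub))
    medial_region = next(
        m for m in (pas, prs, sub) if m is not None and m.any()
    )
    end = _medial_extreme(medial_region)
    core = centerline_path(union, start, end)
    points = extend_to_mask_edge(core, union)

    region_masks = {"SUB": sub}
    if prs is not None:
        region_masks["PrS"] = prs
    if pas is not None:
        region_masks["PaS"] = pas
    labels = []
    for x, y in np.rint(points).astype(int):
        name = next((n for n, m in region_masks.items() if m[x, y]), None)
        labels.append(name if name is not None else labels[-1] if labels else "SUB")
    cum = smoothed_cumlength(points) * dx
    return RibbonPath(points=points, labels=labels, cum_mm=cum, total_mm=float(cum[-1]))


def subicular_proportions(
    path: RibbonPath, z: int | None = None, position_pct: float | None = None
) -> ProportionRecord:
    """Percentage of the centerline length occupied by each present region,
    plus boundary positions as % from the lateral (SUB-CA1) end."""
    if path.total_mm <= 0:
        raise DegenerateSliceError("zero-length subicular path")
    lengths = path.region_lengths_mm()
    pct = {k: v / path.total_mm * 100.0 for k, v in lengths.items()}
    boundaries: dict[str, float] = {}
    for i in range(len(path.labels) - 1):
        a, b = path.labels[i], path.labels[i + 1]
        if a != b:
            mid = (path.cum_mm[i] + path.cum_mm[i + 1]) / 2.0
            boundaries.setdefault(f"{a}-{b}", mid / path.total_mm * 100.0)
    return ProportionRecord(
        z=z, position_pct=position_pct, pct=pct,
        boundaries_pct=boundaries, total_length_mm=path.total_mm,
    )


def subicular_profile(
    volume: LabelVolume,
    landmarks: Landmarks,
    increments_pct=(10, 20, 30, 40, 50),
) -> list[ProportionRecord]:
    """Subicular composition at body slices; unusable slices are skipped."""
    records = []
    for k, z in zip(increments_pct, select_body_slices(landmarks, volume.spacing, increments_pct)):
        masks = {name: slice_mask(volume, z, name) for name in (*_REGIONS, "CA1")}
        try:
            path = trace_ribbon(masks, volume.spacing)
        except (DegenerateSliceError, TopologyError):
            continue
        records.append(subicular_proportions(path, z=z, position_pct=float(k)))
    return records
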