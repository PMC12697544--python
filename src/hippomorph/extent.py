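"""Longitudinal extent of subfields: appearance, disappearance, lengths.

All rules operate per coronal slice with 8-connectivity in plane (voxels
touching by edges *or* corners count as contiguous); 3D connectivity is
never used. A subfield *appears* on the first slice carrying a connected
cluster of at least four voxels; when the slice immediately anterior to a
candidate is uncovered (a histology gap), a single voxel suffices. A
subfield *disappears* on the last slice carrying any voxel of it - no
cluster rule is applied posteriorly.

Lengths are inter-slice distances: ``(z2 - z1) * dz`` mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_volume import CoverageMask, LabelVolume, Landmarks
from .errors import LandmarkError

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class LengthRecord:
    """Head and total hippocampal length, and their ratio in percent.

    ``total_length_mm`` and the ratio are ``None`` when the posterior tip
    was flagged undeterminable (the head length is still reported).
    """

    head_length_mm: float
    total_length_mm: float | None
    head_to_total_ratio_pct: float | None


@dataclass(frozen=True)
class ExtentRecord:
    label: str
    first_slice: int | None
    last_slice: int | None
    start_from_tip_mm: float | None
    start_pct_of_head: float | None
    length_mm: float | None
    length_pct_of_total: float | None


@dataclass(frozen=True)
class AppearanceEvent:
    label: str
    z: int
    gap_mm: float
    gap_pct_of_head: float
    tied_with_previous: bool


def _slice_has_cluster(mask2d: np.ndarray, min_cluster: int) -> bool:
    if min_cluster <= 1:
        return bool(mask2d.any())
    labeled, n = ndimage.label(mask2d, structure=_STRUCT8)
    if n == 0:
        return False
    counts = np.bincount(labeled.ravel())[1:]
    return bool((counts >= min_cluster).any())


def detect_appearance(
    volume: LabelVolume,
    label: str,
    coverage: CoverageMask | None = None,
    min_cluster: int = 4,
) -> int | None:
    """First slice where ``label`` satisfies the cluster rule, or None.

    The threshold drops to one voxel on slices whose immediately anterior
    neighbour is uncovered. Absence is a value, not an error.
    """
    mask = volume.mask(label)
    nonempty = np.nonzero(mask.any(axis=(0, 1)))[0]
    for z in nonempty:
        thr = min_cluster
        if coverage is not None and z > 0 and not coverage.is_covered(z - 1):
            thr = 1
        if _slice_has_cluster(mask[:, :, z], thr):
            return int(z)
    return None


def detect_disappearance(volume: LabelVolume, label: str) -> int | None:
    """Last slice carrying at least one voxel of ``label``, or None."""
    zs = np.nonzero(volume.mask(label).any(axis=(0, 1)))[0]
    return int(zs[-1]) if zs.size else None


def dg_enclosure_appearance(volume: LabelVolume) -> int | None:
    """First slice where a DG component is fully ringed by DG or SRLM.

    The DG is identified on MRI by grey matter fully surrounded by the dark
    band; on a label map this reads: some DG connected component whose
    entire 8-neighbourhood boundary carries only DG or SRLM labels.
    """
    dg = volume.mask("DG")
    srlm = volume.mask("SRLM")
    zs = np.nonzero(dg.any(axis=(0, 1)) & srlm.any(axis=(0, 1)))[0]
    for z in zs:
        dg2 = dg[:, :, z]
        ok2 = dg2 | srlm[:, :, z]
        # whole-mask shortcut: if the union boundary of all DG components is
        # clean, every component is enclosed
        ring = ndimage.binary_dilation(dg2, structure=_STRUCT8) & ~dg2
        if not (ring & ~ok2).any():
            return int(z)
        labeled, n = ndimage.label(dg2, structure=_STRUCT8)
        for i in range(1, n + 1):
            comp = labeled == i
            ring = ndimage.binary_dilation(comp, structure=_STRUCT8) & ~comp
            if not (ring & ~ok2).any():
                return int(z)
    return None


def head_length(landmarks: Landmarks, spacing) -> float:
    """Anterior tip to uncal apex, in mm."""
    dz = float(spacing[2])
    length = (landmarks.uncal_apex_z - landmarks.anterior_tip_z) * dz
    if length == 0.0:
        warnings.warn("degenerate head: anterior tip equals uncal apex", stacklevel=2)
    return length


def total_length_and_ratio(landmarks: Landmarks, spacing) -> LengthRecord:
    head = head_length(landmarks, spacing)
    if landmarks.posterior_tip_undeterminable or landmarks.posterior_tip_z is None:
        return LengthRecord(head, None, None)
    dz = float(spacing[2])
    total = (landmarks.posterior_tip_z - landmarks.anterior_tip_z) * dz
    if total <= 0:
        raise LandmarkError("total length must be positive")
    return LengthRecord(head, total, head / total * 100.0)


def appearance_slice(
    volume: LabelVolume,
    label: str,
    landmarks: Landmarks,
    coverage: CoverageMask | None = None,
    min_cluster: int = 4,
) -> int | None:
    """Appearance slice with the label-specific conventions applied.

    SUB appears by definition on the anterior-tip slice (it is the most
    anterior subfield, identified on the image independent of
    segmentation); the DG appears when first enclosed by the dark band;
    every other subfield follows the cluster rule.
    """
    if label == "SUB":
        if not volume.mask("SUB")[:, :, landmarks.anterior_tip_z].any():
            warnings.warn(
                "anterior tip slice carries no SUB label (QC)", stacklevel=2
            )
        return landmarks.anterior_tip_z
    if label == "DG":
        return dg_enclosure_appearance(volume)
    return detect_appearance(volume, label, coverage, min_cluster)


def appearance_order(
    volume: LabelVolume,
    labels,
    landmarks: Landmarks,
    coverage: CoverageMask | None = None,
) -> tuple[list[AppearanceEvent], list[str]]:
    """Order of appearance with inter-subfield gaps in mm and % head length.

    Returns (ordered events, labels that never appear). Ties are reported
    as simultaneous with a zero gap.
    """
    head_mm = head_length(landmarks, volume.spacing)
    found = []
    absent = []
    for label in labels:
        z = appearance_slice(volume, label, landmarks, coverage)
        (found if z is not None else absent).append((label, z) if z is not None else label)
    found.sort(key=lambda t: (t[1], list(labels).index(t[0])))
    events: list[AppearanceEvent] = []
    prev_z = None
    dz = volume.dz
    for label, z in found:
        gap_mm = 0.0 if prev_z is None else (z - prev_z) * dz
        pct = gap_mm / head_mm * 100.0 if head_mm > 0 else 0.0
        events.append(AppearanceEvent(label, z, gap_mm, pct, prev_z == z))
        prev_z = z
    return events, absent


def extent_record(
    volume: LabelVolume,
    label: str,
    landmarks: Landmarks,
    coverage: CoverageMask | None = None,
) -> ExtentRecord:
    first = appearance_slice(volume, label, landmarks, coverage)
    last = detect_disappearance(volume, label)
    dz = volume.dz
    head_mm = head_length(landmarks, volume.spacing)
    rec = total_length_and_ratio(landmarks, volume.spacing)
    start_mm = None if first is None else (first - landmarks.anterior_tip_z) * dz
    start_pct = None if (start_mm is None or head_mm == 0) else start_mm / head_mm * 100.0
    length_mm = None if (first is None or last is None) else (last - first) * dz
    length_pct = (
        None
        if (length_mm is None or rec.total_length_mm in (None, 0.0))
        else length_mm / rec.total_length_mm * 100.0
    )
    return ExtentRecord(label, first, last, start_mm, start_pct, length_mm, length_pct)


def tail_presence(
    volume: LabelVolume,
    labels,
    landmarks: Landmarks,
    coverage: CoverageMask | None = None,
    offsets_mm=(2.0, 1.0),
) -> dict[float, dict[str, bool | None]]:
    """Which subfields persist 2 mm / 1 mm anterior to the posterior tip.

    Offsets that are not slice multiples round to the nearest slice, ties
    toward anterior. On an uncovered target slice presence is undetermined
    (``None``) and should be excluded from cohort denominators.
    """
    if landmarks.posterior_tip_z is None:
        raise LandmarkError("posterior tip required for tail presence")
    dz = volume.dz
    out: dict[float, dict[str, bool | None]] = {}
    for off in offsets_mm:
        n_back = int(np.floor(off / dz + 0.5))  # ties toward anterior
        z = landmarks.posterior_tip_z - n_back
        if z < 0 or z >= volume.n_slices or (coverage is not None and not coverage.is_covered(z)):
            out[off] = {label: None for label in labels}
            continue
        sl = volume.voxels[:, :, z]
        out[off] = {label: bool((sl == volume.schema.code(label)).any()) for label in labels}
    return out
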