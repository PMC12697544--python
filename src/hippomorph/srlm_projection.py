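"""Projection of CA subfields onto the SRLM band ("flashlight" relabeling).

Only the portion of the SRLM lateral to the most medial DG point is
considered, since that is the part reliably visible in vivo. Each lateral
SRLM voxel is assigned the CA subfield of its nearest CA voxel (in-plane
Euclidean distance), and per-subfield proportions are the assigned counts
over the total lateral SRLM count.

Special case: when the SUB-CA1 interface lies lateral to the medial DG
point, the CA1 projection starts at the interface *midpoint*; lateral SRLM
voxels whose position along the band is medial to the midpoint's projection
stay unassigned, so the proportions then sum to less than one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._path import full_band_path, positions_along_path, smoothed_cumlength
from .core_volume import LabelVolume, Landmarks, slice_mask
from .errors import ProjectionError
from .subicular import select_body_slices

_STRUCT8 = np.ones((3, 3), dtype=bool)
_CA = ("CA1", "CA2", "CA3")


@dataclass
class ProjectionResult:
    z: int | None
    position_pct: float | None
    medial_dg_x: int
    n_srlm_total: int
    n_assigned: dict[str, int]
    prop: dict[str, float]
    sub_border_lateral_case: bool
    relabeled: np.ndarray  # 2D int mask of assigned subfield indices (QC)


def medial_dg_point(dg_mask: np.ndarray) -> int | None:
    """Column index of the most medial DG voxel (minimum x), or None."""
    cols = np.nonzero(dg_mask.any(axis=1))[0]
    return int(cols[0]) if cols.size else None


def curved_length_occupancy(border_start_pct: float, border_end_pct: float) -> float:
    """Share of the curved SRLM length occupied by a subfield, given the
    positions (in % of curved length from the medial DG point, lateral
    direction) of its medial and lateral borders.

    With the SUB-CA1 border at 33% and the CA1-CA2 border at 80% of the
    curved length, CA1 occupies 80 - 33 = 47% of the band.
    """
    return border_end_pct - border_start_pct


def _band_positions(lateral: np.ndarray, sub: np.ndarray | None):
    """Arclength position of every lateral-SRLM voxel along the band's
    skeleton path, measured from the band's medial end (the end nearest the
    subiculum when present, otherwise the more medial endpoint)."""
    coords = np.argwhere(lateral)
    if sub is not None and sub.any():
        hint = np.argwhere(sub).mean(axis=0)
    else:
        hint = coords[np.argmin(coords[:, 0])].astype(float)
    path = full_band_path(lateral, hint)
    cum = smoothed_cumlength(path)
    pos = positions_along_path(path, cum, coords)
    return coords, pos, path, cum


def project_onto_srlm(
    masks: dict[str, np.ndarray],
    medial_dg_x: int,
    z: int | None = None,
    position_pct: float | None = None,
) -> ProjectionResult | None:
    """Assign lateral SRLM voxels to CA subfields and compute proportions.

    ``masks`` holds 2D masks for SRLM, CA1, CA2, CA3 and (optionally) SUB.
    Returns None when no SRLM exists lateral to the medial DG point (the
    slice is skipped); raises :class:`ProjectionError` when all three CA
    masks are empty.
    """
    srlm = masks["SRLM"]
    nx_, ny_ = srlm.shape
    xg = np.arange(nx_)[:, None]
    lateral = srlm & (xg >= medial_dg_x)
    n_total = int(lateral.sum())
    if n_total == 0:
        return None
    ca_masks = {n: masks.get(n) for n in _CA}
    if not any(m is not None and m.any() for m in ca_masks.values()):
        raise ProjectionError("no CA voxels to project onto the SRLM")

    # nearest-CA assignment; ties across subfields resolved CA3 > CA2 > CA1
    # (affects only one-voxel border shells)
    dists = []
    order = ("CA3", "CA2", "CA1")
    for name in order:
        m = ca_masks[name]
        if m is None or not m.any():
            dists.append(np.full(srlm.shape, np.inf))
        else:
            dists.append(ndimage.distance_transform_edt(~m))
    dists = np.stack(dists)
    choice = np.argmin(dists, axis=0)  # first (highest-priority) minimum wins

    assigned = np.zeros(srlm.shape, dtype=np.int8)  # 0 none, 1..3 = CA1..CA3
    idx_of = {name: i + 1 for i, name in enumerate(_CA)}
    for k, name in enumerate(order):
        assigned[lateral & (choice == k)] = idx_of[name]

    # SUB-CA1 interface midpoint special case
    sub = masks.get("SUB")
    sub_lateral_case = False
    if sub is not None and sub.any() and ca_masks["CA1"] is not None and ca_masks["CA1"].any():
        interface = ca_masks["CA1"] & ndimage.binary_dilation(sub, structure=_STRUCT8)
        if interface.any():
            midpoint = np.argwhere(interface).mean(axis=0)
            if midpoint[0] >= medial_dg_x:
                sub_lateral_case = True
                coords, pos, path, cum = _band_positions(lateral, sub)
                d2 = np.hypot(coords[:, 0] - midpoint[0], coords[:, 1] - midpoint[1])
                pos_mid = pos[int(np.argmin(d2))]
                medial_of_mid = pos < pos_mid
                assigned[tuple(coords[medial_of_mid].T)] = 0

    counts = {name: int((assigned == idx_of[name]).sum()) for name in _CA}
    props = {name: counts[name] / n_total for name in _CA}
    return ProjectionResult(
        z=z,
        position_pct=position_pct,
        medial_dg_x=int(medial_dg_x),
        n_srlm_total=n_total,
        n_assigned=counts,
        prop=props,
        sub_border_lateral_case=sub_lateral_case,
        relabeled=assigned,
    )


def srlm_profile(
    volume: LabelVolume,
    landmarks: Landmarks,
    increments_pct=(10, 20, 30, 40, 50),
) -> list[ProjectionResult]:
    """Per-increment SRLM proportions along the body; slices missing the DG
    or the lateral SRLM are skipped."""
    results = []
    for k, z in zip(increments_pct, select_body_slices(landmarks, volume.spacing, increments_pct)):
        dg = slice_mask(volume, z, "DG")
        mx = medial_dg_point(dg)
        if mx is None:
            continue
        masks = {name: slice_mask(volume, z, name) for name in ("SRLM", *_CA, "SUB")}
        res = project_onto_srlm(masks, mx, z=z, position_pct=float(k))
        if res is not None:
            results.append(res)
    return results
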