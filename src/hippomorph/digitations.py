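"""Hippocampal-head digitations and the location of anterior CA3.

Digitations are bump-like undulations of the superior surface of the
hippocampal head. They are counted on the superior-surface height profile
y_top(x) of the whole hippocampal footprint: local maxima with a minimum
prominence (after light smoothing) are digitation peaks. The anterior CA3
slice is the first coronal slice where CA3 reaches the superior strip of
the CA ribbon, i.e. rises above the DG/SRLM at the same columns, and CA3 is
then classified by where its bulk sits relative to the peaks (on-top /
in-between / both) and to the medial-lateral thirds of the footprint.

The visual judgment is operationalized with explicit, tunable constants;
the defaults below are declared in :class:`DigitationConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core_volume import CoverageMask, LabelVolume
from .errors import DegenerateSliceError

_SUBFIELDS = ("SUB", "PrS", "PaS", "CA1", "CA2", "CA3", "DG", "SRLM")


@dataclass(frozen=True)
class DigitationConfig:
    """Thresholds that turn the visual classification into a rule."""

    prominence_voxels: float = 2.0
    smoothing_columns: int = 3
    peak_window_fraction: float = 0.25  # +- w/4 around a peak counts as on-top
    on_top_min_fraction: float = 0.70
    in_between_max_fraction: float = 0.30


DEFAULT_CONFIG = DigitationConfig()


def _window_max(values: np.ndarray) -> np.ndarray:
    """Column-wise max over a +-1 column window, no wrap-around."""
    left = np.concatenate([[-np.inf], values[:-1]])
    right = np.concatenate([values[1:], [-np.inf]])
    return np.maximum(np.maximum(values, left), right)


@dataclass
class DigitationProfile:
    z: int | None
    columns: np.ndarray  # x of footprint columns, ascending
    y_top: np.ndarray  # raw superior-surface height per column
    smoothed: np.ndarray
    peak_xs: np.ndarray
    trough_xs: np.ndarray
    n_digitations: int


@dataclass(frozen=True)
class CA3LocationRecord:
    relation: str  # on_top | in_between | both
    position: str  # lateral | medial | midpoint
    on_peak_fraction: float
    centroid_x: float


def footprint_mask(volume: LabelVolume, z: int) -> np.ndarray:
    """Union of all subfield labels on a slice (the hippocampal footprint)."""
    sl = volume.voxels[:, :, z]
    codes = [volume.schema.code(n) for n in _SUBFIELDS]
    return np.isin(sl, codes)


def digitation_profile(
    footprint: np.ndarray,
    z: int | None = None,
    config: DigitationConfig = DEFAULT_CONFIG,
) -> DigitationProfile:
    """Count digitation peaks on the superior-surface height profile.

    A featureless (flat-top) footprint counts as a single digitation.
    Raises :class:`DegenerateSliceError` for footprints narrower than five
    columns.
    """
    cols = np.nonzero(footprint.any(axis=1))[0]
    if cols.size < 5:
        raise DegenerateSliceError("footprint too narrow to profile")
    y_top = np.array([np.nonzero(footprint[c])[0][-1] for c in cols], dtype=float)
    w = config.smoothing_columns
    if w > 1 and y_top.size > w:
        kernel = np.ones(w) / w
        pad = w // 2
        padded = np.concatenate([y_top[pad:0:-1], y_top, y_top[-2:-2 - pad:-1]])
        sm = np.convolve(padded, kernel, mode="valid")
    else:
        sm = y_top.copy()
    peaks, _ = find_peaks(sm, prominence=config.prominence_voxels)
    troughs, _ = find_peaks(-sm, prominence=config.prominence_voxels)
    return DigitationProfile(
        z=z,
        columns=cols,
        y_top=y_top,
        smoothed=sm,
        peak_xs=cols[peaks],
        trough_xs=cols[troughs],
        n_digitations=max(1, len(peaks)),
    )


def anterior_ca3_slice(
    volume: LabelVolume, coverage: CoverageMask | None = None
) -> int | None:
    """First slice where CA3 enters the superior strip of the CA ribbon.

    A CA3 voxel qualifies when its y exceeds the maximum DG/SRLM y within
    one column of its own; on slices without DG or SRLM the fallback
    compares against the footprint's median height (warned).
    """
    ca3 = volume.mask("CA3")
    zs = np.nonzero(ca3.any(axis=(0, 1)))[0]
    dg_srlm = volume.mask("DG") | volume.mask("SRLM")
    for z in zs:
        if coverage is not None and not coverage.is_covered(z):
            continue
        ca3_sl = ca3[:, :, z]
        ref = dg_srlm[:, :, z]
        coords = np.argwhere(ca3_sl)
        if ref.any():
            nx_ = ca3_sl.shape[0]
            top = np.full(nx_, -np.inf)
            ref_cols = np.nonzero(ref.any(axis=1))[0]
            for c in ref_cols:
                top[c] = np.nonzero(ref[c])[0][-1]
            wtop = _window_max(top)
            valid = np.isfinite(wtop)
            qual = [
                y > wtop[x] for x, y in coords if valid[x]
            ]
            if any(qual):
                return int(z)
        else:
            fp = footprint_mask(volume, int(z))
            med_y = float(np.median(np.argwhere(fp)[:, 1]))
            warnings.warn(
                "no DG/SRLM on candidate slice; using footprint median height",
                stacklevel=2,
            )
            if (coords[:, 1] > med_y).any():
                return int(z)
    return None


def ca3_superior_strip(volume: LabelVolume, z: int) -> np.ndarray:
    """CA3 voxels on the slice lying above the DG/SRLM at their column."""
    ca3 = volume.voxels[:, :, z] == volume.schema.code("CA3")
    ref = (volume.voxels[:, :, z] == volume.schema.code("DG")) | (
        volume.voxels[:, :, z] == volume.schema.code("SRLM")
    )
    if not ref.any():
        return ca3
    nx_ = ca3.shape[0]
    top = np.full(nx_, -np.inf)
    for c in np.nonzero(ref.any(axis=1))[0]:
        top[c] = np.nonzero(ref[c])[0][-1]
    wtop = _window_max(top)
    yg = np.arange(ca3.shape[1])[None, :]
    return ca3 & np.where(np.isfinite(wtop)[:, None], yg > wtop[:, None], True)


def classify_ca3(
    profile: DigitationProfile,
    ca3_strip: np.ndarray,
    config: DigitationConfig = DEFAULT_CONFIG,
) -> CA3LocationRecord:
    """Relate the bulk of superior CA3 to the digitation peaks and to the
    medial-lateral thirds of the footprint."""
    if not ca3_strip.any():
        raise DegenerateSliceError("empty CA3 superior strip")
    ca3_cols = np.nonzero(ca3_strip.any(axis=1))[0]
    peaks = profile.peak_xs
    if peaks.size == 0:
        peaks = np.array([profile.columns[int(np.argmax(profile.smoothed))]])
    if peaks.size >= 2:
        w = float(np.median(np.diff(np.sort(peaks))))
    else:
        w = (profile.columns[-1] - profile.columns[0]) / 2.0
    window = config.peak_window_fraction * w
    on_peak = np.zeros(ca3_cols.shape, dtype=bool)
    for p in peaks:
        on_peak |= np.abs(ca3_cols - p) <= window
    frac = float(on_peak.mean())
    if frac >= config.on_top_min_fraction:
        relation = "on_top"
    elif frac <= config.in_between_max_fraction:
        relation = "in_between"
    else:
        relation = "both"

    centroid_x = float(np.argwhere(ca3_strip)[:, 0].mean())  # area-weighted bulk
    x0, x1 = profile.columns[0], profile.columns[-1]
    width = x1 - x0
    if centroid_x < x0 + width / 3.0:
        position = "medial"
    elif centroid_x > x0 + 2.0 * width / 3.0:
        position = "lateral"
    else:
        position = "midpoint"
    return CA3LocationRecord(relation, position, frac, centroid_x)
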