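"""Synthetic hippocampus-like label phantoms with exhaustively known truth.

The phantom emulates, slice by slice, the topology the measurements expect:

* a dentate-gyrus (DG) disc,
* an SRLM band around it (full ring, or an arc coextensive with the CA
  ribbon),
* a C-shaped CA ribbon partitioned by angle into CA1 -> CA2 -> CA3, opening
  at the inferior-medial side,
* a subicular cortex strip attached medially at the CA1 end, split
  lateral -> medial into SUB / PrS / PaS,
* optional digitations (sinusoidal bumps of the superior surface) in head
  slices, and
* per-subfield longitudinal extents along the anterior-posterior axis.

Every quantity a measurement module reports is known from the construction
and recorded in :class:`GroundTruth`. Noise (slice dropout, boundary
jitter) is applied *after* ground truth is computed, so recovery under
noise quantifies robustness rather than redefining truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .core_volume import (
    DEFAULT_SCHEMA_CODES,
    CoverageMask,
    LabelVolume,
    Landmarks,
    SubfieldSchema,
    mirror,  # re-exported: hemisphere-invariance testing lives next to the phantom
    save_label_volume,
)
from .errors import PhantomSpecError

__all__ = ["PhantomSpec", "GroundTruth", "generate", "mirror", "random_spec"]

_SUBFIELDS = ("SUB", "PrS", "PaS", "CA1", "CA2", "CA3", "DG", "SRLM")


def _default_extents() -> dict[str, tuple[int, int]]:
    # Anterior-to-posterior layout patterned on a typical specimen:
    # appearance order SUB-CA1-PrS-DG-CA3-PaS-CA2, subicular regions
    # disappearing 'last in, first out'.
    return {
        "SUB": (10, 230),
        "CA1": (20, 230),
        "PrS": (23, 192),
        "DG": (38, 224),
        "SRLM": (38, 224),
        "CA3": (46, 226),
        "PaS": (60, 149),
        "CA2": (61, 225),
    }


@dataclass
class PhantomSpec:
    """Parameters of the synthetic hippocampus.

    Geometry lengths are in voxels; angles in degrees. ``extents`` maps each
    subfield to its inclusive ``(z_start, z_end)`` slice range. The SUB-CA1
    border sits at ``center_x + border_offset`` voxels; the offset ramps
    linearly from its anterior to posterior value between the uncal apex and
    the posterior tip, which emulates the medial shift of the border along
    the long axis.
    """

    shape: tuple[int, int, int] = (120, 120, 250)
    spacing: tuple[float, float, float] = (0.2, 0.2, 0.2)
    hemisphere: str = "right"
    # landmarks
    anterior_tip_z: int = 10
    uncal_apex_z: int = 94
    posterior_tip_z: int = 230
    extents: dict[str, tuple[int, int]] = field(default_factory=_default_extents)
    # cross-section geometry
    center: tuple[int, int] = (64, 58)
    dg_radius: float = 20.0
    srlm_thickness: float = 3.0
    ca_thickness: float = 6.0
    ribbon_start_deg: float = -90.0
    ca_spans_deg: tuple[float, float, float] = (150.0, 18.0, 12.0)
    ca_spans_deg_posterior: tuple[float, float, float] | None = None
    srlm_arc: str = "ring"  # "ring" (DG fully enclosed) or "ribbon" (arc under CA only)
    strip_length: int = 60
    strip_fractions: tuple[float, float, float] = (0.46, 0.38, 0.16)  # SUB, PrS, PaS
    border_offset_anterior: float = 0.0
    border_offset_posterior: float = 0.0
    # digitations (head slices)
    digitation_count: int = 3
    digitation_amplitude: float = 6.0
    # noise
    dropout_prob: float = 0.0
    dropout_range: tuple[int, int] | None = None
    jitter_prob: float = 0.0
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        nx, ny, nz = self.shape
        for name in _SUBFIELDS:
            if name not in self.extents:
                raise PhantomSpecError(f"missing extent for {name}")
            z0, z1 = self.extents[name]
            if not (0 <= z0 <= z1 < nz):
                raise PhantomSpecError(f"extent of {name} outside volume: {(z0, z1)}")
        if not (0 <= self.anterior_tip_z <= self.uncal_apex_z <= self.posterior_tip_z < nz):
            raise PhantomSpecError("landmarks must be ordered within the volume")
        if abs(sum(self.strip_fractions) - 1.0) > 1e-9 or min(self.strip_fractions) <= 0:
            raise PhantomSpecError("strip fractions must be positive and sum to 1")
        for spans in filter(None, [self.ca_spans_deg, self.ca_spans_deg_posterior]):
            if sum(spans) > 360 or min(spans) <= 0:
                raise PhantomSpecError("CA angular spans must be positive and sum to <= 360")
        if self.srlm_arc not in ("ring", "ribbon"):
            raise PhantomSpecError("srlm_arc must be 'ring' or 'ribbon'")
        dg0, dg1 = self.extents["DG"]
        s0, s1 = self.extents["SRLM"]
        if self.srlm_arc == "ring" and not (s0 <= dg0 and dg1 <= s1):
            raise PhantomSpecError(
                "DG extent must lie within the SRLM extent when enclosure is requested"
            )
        # the strip construction nests the subicular regions ('last in,
        # first out'): PaS within PrS within SUB
        for inner, outer in (("PaS", "PrS"), ("PrS", "SUB")):
            i0, i1 = self.extents[inner]
            o0, o1 = self.extents[outer]
            if not (o0 <= i0 and i1 <= o1):
                raise PhantomSpecError(
                    f"{inner} extent must nest within {outer} extent"
                )
        cx, cy = self.center
        r_out = self.dg_radius + self.srlm_thickness + self.ca_thickness
        top = cy + r_out + (self.digitation_amplitude if self.digitation_count else 0)
        if not (cx - self.strip_length >= 0 and cx + r_out < nx and cy - r_out >= 0 and top < ny):
            raise PhantomSpecError("cross-section geometry does not fit inside the volume")
        w_pas = round(self.strip_fractions[2] * self.strip_length)
        w_sub = self.strip_length - w_pas - round(self.strip_fractions[1] * self.strip_length)
        if min(w_pas, w_sub) < 2:
            raise PhantomSpecError("strip regions must be at least 2 voxels wide")
        offs = (self.border_offset_anterior, self.border_offset_posterior)
        if min(offs) < 0 or max(offs) > self.dg_radius - 2:
            raise PhantomSpecError(
                "border offsets must lie in [0, dg_radius - 2] so the SUB-CA1 interface "
                "stays a single vertical crossing of the inferior CA arc"
            )

    # ------------------------------------------------------------------
    def spans_at(self, z: int) -> tuple[float, float, float]:
        if self.ca_spans_deg_posterior is None:
            return self.ca_spans_deg
        t = self._axial_t(z)
        return tuple(
            a + t * (b - a)
            for a, b in zip(self.ca_spans_deg, self.ca_spans_deg_posterior)
        )

    def border_x(self, z: int) -> float:
        t = self._axial_t(z)
        off = self.border_offset_anterior + t * (
            self.border_offset_posterior - self.border_offset_anterior
        )
        return self.center[0] + off

    def _axial_t(self, z: int) -> float:
        z0, z1 = self.uncal_apex_z, self.posterior_tip_z
        if z1 <= z0:
            return 0.0
        return float(np.clip((z - z0) / (z1 - z0), 0.0, 1.0))

    def landmarks(self) -> Landmarks:
        return Landmarks(self.anterior_tip_z, self.uncal_apex_z, self.posterior_tip_z)

    def body_increment_slices(self, increments_pct=(10, 20, 30, 40, 50)) -> list[int]:
        total = self.posterior_tip_z - self.anterior_tip_z
        return [self.uncal_apex_z + round(k / 100.0 * total) for k in increments_pct]

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "extents" in raw:
            raw["extents"] = {k: tuple(v) for k, v in raw["extents"].items()}
        for key in ("shape", "spacing", "center", "ca_spans_deg", "ca_spans_deg_posterior",
                    "strip_fractions", "dropout_range"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["extents"] = {k: list(v) for k, v in d["extents"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Exact values each measurement must recover on a zero-noise phantom.

    Slice-indexed quantities are exact integers; ribbon/arc quantities carry
    the discretization of the drawn geometry. ``subicular_fractions`` and
    ``srlm_fractions`` are recorded at the body increment slices;
    ``border`` at the 0 mm and 20 mm offset slices (where they exist).
    ``anterior_ca3_z`` assumes the CA3 sector reaches the superior arc, as
    it does under the default angular spans.
    """

    appearance: dict[str, int | None]
    disappearance: dict[str, int | None]
    dg_enclosure_z: int | None
    head_length_mm: float
    total_length_mm: float
    head_to_total_ratio_pct: float
    subicular_fractions: dict[int, dict[str, float]]
    srlm_fractions: dict[int, dict[str, float]]
    border: dict[int, dict[str, float]]
    digitation_count: int
    anterior_ca3_z: int | None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# drawing
# ---------------------------------------------------------------------------

def _grids(spec: PhantomSpec):
    nx, ny, _ = spec.shape
    cx, cy = spec.center
    xg, yg = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    rho = np.hypot(xg - cx, yg - cy)
    phi = np.degrees(np.arctan2(yg - cy, xg - cx))
    phi_rel = (phi - spec.ribbon_start_deg) % 360.0
    return xg, yg, rho, phi_rel


def _strip_segments(spec: PhantomSpec, present: dict[str, bool]) -> dict[str, tuple[int, int]]:
    """Column ranges [lo, hi) of each present strip region, lateral end at cx.

    Absent medial regions are absorbed by the nearest present lateral
    neighbour (the PrS takes over the PaS share when the PaS has
    disappeared, and so on).
    """
    cx = spec.center[0]
    L = spec.strip_length
    f_sub, f_prs, f_pas = spec.strip_fractions
    w_pas = round(f_pas * L)
    w_prs = round(f_prs * L)
    x0 = cx - L
    bounds = {"PaS": (x0, x0 + w_pas), "PrS": (x0 + w_pas, x0 + w_pas + w_prs),
              "SUB": (x0 + w_pas + w_prs, cx)}
    if not present.get("SUB"):
        return {}
    segs: dict[str, tuple[int, int]] = {"SUB": bounds["SUB"]}
    if present.get("PrS"):
        segs["PrS"] = bounds["PrS"]
        if present.get("PaS"):
            segs["PaS"] = bounds["PaS"]
        else:
            segs["PrS"] = (x0, bounds["PrS"][1])
    else:
        segs["SUB"] = (x0, cx)
    return segs


def _draw_slice(spec: PhantomSpec, z: int, grids, codes) -> np.ndarray:
    xg, yg, rho, phi_rel = grids
    nx, ny, _ = spec.shape
    cx, cy = spec.center
    r_dg = spec.dg_radius
    r_s = r_dg + spec.srlm_thickness
    r_c = r_s + spec.ca_thickness
    sl = np.zeros((nx, ny), dtype=np.int16)

    def present(name: str) -> bool:
        z0, z1 = spec.extents[name]
        return z0 <= z <= z1

    spans = spec.spans_at(z)
    total = sum(spans)

    if present("DG"):
        sl[rho <= r_dg] = codes["DG"]
    if present("SRLM"):
        ring = (rho > r_dg) & (rho <= r_s)
        if spec.srlm_arc == "ribbon":
            ring &= phi_rel < total
        sl[ring] = codes["SRLM"]
    band = (rho > r_s) & (rho <= r_c)
    lo = 0.0
    for name, span in zip(("CA1", "CA2", "CA3"), spans):
        hi = lo + span
        if present(name):
            sl[band & (phi_rel >= lo) & (phi_rel < hi)] = codes[name]
        lo = hi

    # subicular strip, same radial band as the CA annulus, attached at the
    # CA1 end of the opening
    segs = _strip_segments(spec, {n: present(n) for n in ("SUB", "PrS", "PaS")})
    row_top = cy - int(np.floor(r_s)) - 1
    row_bot = cy - int(np.floor(r_c))
    for name, (x_lo, x_hi) in segs.items():
        sl[x_lo:x_hi, row_bot:row_top + 1] = codes[name]

    # SUB-CA1 border: relabel the inferior CA1 arc medial to the border line
    bx = spec.border_x(z)
    if present("SUB") and present("CA1") and bx > cx:
        sel = (sl == codes["CA1"]) & (xg < bx) & (yg < cy)
        sl[sel] = codes["SUB"]

    # digitations: sinusoidal bumps of the superior ring surface in head
    # slices (never of the flat medial cortex strip)
    if spec.digitation_count > 0 and z <= spec.uncal_apex_z and present("DG"):
        all_cols = np.nonzero(sl.any(axis=1))[0]
        tops = {c: np.nonzero(sl[c])[0][-1] for c in all_cols}
        cols = np.array([c for c in all_cols if tops[c] > cy], dtype=int)
        if cols.size >= 2:
            x_min, x_max = cols[0], cols[-1]
            t = (cols - x_min) / (x_max - x_min)
            h = np.rint(
                spec.digitation_amplitude
                * 0.5
                * (1 - np.cos(2 * np.pi * spec.digitation_count * t))
            ).astype(int)
            for col, hh in zip(cols, h):
                if hh <= 0:
                    continue
                y_top = tops[col]
                sl[col, y_top + 1: min(ny, y_top + 1 + hh)] = sl[col, y_top]
    return sl


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _srlm_truth(spec: PhantomSpec, sl: np.ndarray, codes, grids) -> dict[str, float] | None:
    """Angle-rule fractions of the lateral SRLM band (the construction's own
    partition, independent of the distance-transform measurement)."""
    xg, _, _, phi_rel = grids
    dg = sl == codes["DG"]
    srlm = sl == codes["SRLM"]
    if not dg.any() or not srlm.any():
        return None
    medial_x = int(np.nonzero(dg.any(axis=1))[0][0])
    lateral = srlm & (xg >= medial_x)
    n = int(lateral.sum())
    if n == 0:
        return None
    spans = spec.spans_at(0)  # truth recorded only where spans are constant in z
    s1, s2, s3 = spans
    total = s1 + s2 + s3
    phi = phi_rel[lateral]
    phi_signed = np.where(phi > 180 + total / 2, phi - 360, phi)  # medial-of-start wedge
    unassigned = phi_signed < 0
    ca1 = (~unassigned) & (phi_signed < s1)
    ca2 = (~unassigned) & (phi_signed >= s1) & (phi_signed < s1 + s2)
    ca3 = (~unassigned) & (phi_signed >= s1 + s2)
    return {
        "CA1": ca1.sum() / n,
        "CA2": ca2.sum() / n,
        "CA3": ca3.sum() / n,
        "unassigned": unassigned.sum() / n,
        "n": float(n),
    }


def _border_truth_at(spec: PhantomSpec, z: int, sl: np.ndarray, codes) -> dict[str, float] | None:
    cx = spec.center[0]
    dg = sl == codes["DG"]
    ca3 = sl == codes["CA3"]
    ca1 = sl == codes["CA1"]
    if not (dg.any() and ca1.any()):
        return None
    anchor_x = int(np.nonzero((dg | ca3).any(axis=1))[0][0])
    bx = spec.border_x(z)
    border_col = int(np.ceil(bx)) if bx > cx else cx
    lat_ca1 = int(np.nonzero(ca1.any(axis=1))[0][-1])
    lat_dg = int(np.nonzero(dg.any(axis=1))[0][-1])
    full_w = lat_ca1 + 0.5 - anchor_x
    dg_w = lat_dg + 0.5 - anchor_x
    return {
        "anchor_x": float(anchor_x),
        "border_line_x": float(border_col),
        "rel_full_pct": (border_col - anchor_x) / full_w * 100.0,
        "rel_dg_pct": (border_col - anchor_x) / dg_w * 100.0,
    }


def _compute_truth(spec: PhantomSpec, voxels: np.ndarray, codes, grids) -> GroundTruth:
    dz = spec.spacing[2]
    head_mm = (spec.uncal_apex_z - spec.anterior_tip_z) * dz
    total_mm = (spec.posterior_tip_z - spec.anterior_tip_z) * dz
    appearance = {name: spec.extents[name][0] for name in _SUBFIELDS}
    appearance["SUB"] = spec.anterior_tip_z  # SUB appearance := anterior tip slice
    disappearance = {name: spec.extents[name][1] for name in _SUBFIELDS}
    dg_enc = (
        max(spec.extents["DG"][0], spec.extents["SRLM"][0])
        if spec.srlm_arc == "ring"
        else None
    )

    sub_fracs: dict[int, dict[str, float]] = {}
    srlm_fracs: dict[int, dict[str, float]] = {}
    increments = [
        z for z in spec.body_increment_slices()
        if z <= spec.posterior_tip_z and z < spec.shape[2]
    ]
    for z in increments:
        present = {n: spec.extents[n][0] <= z <= spec.extents[n][1]
                   for n in ("SUB", "PrS", "PaS")}
        segs = _strip_segments(spec, present)
        if segs:
            L = float(spec.strip_length)
            sub_fracs[z] = {n: (hi - lo) / L * 100.0 for n, (lo, hi) in segs.items()}
        if spec.ca_spans_deg_posterior is None:
            f = _srlm_truth(spec, voxels[:, :, z], codes, grids)
            if f is not None:
                srlm_fracs[z] = f

    border: dict[int, dict[str, float]] = {}
    for z in (spec.uncal_apex_z + 1, spec.uncal_apex_z + round(20.0 / dz)):
        if z <= spec.posterior_tip_z and z < spec.shape[2]:
            t = _border_truth_at(spec, z, voxels[:, :, z], codes)
            if t is not None:
                border[z] = t

    ca3_start = spec.extents["CA3"][0]
    return GroundTruth(
        appearance=appearance,
        disappearance=disappearance,
        dg_enclosure_z=dg_enc,
        head_length_mm=head_mm,
        total_length_mm=total_mm,
        head_to_total_ratio_pct=head_mm / total_mm * 100.0,
        subicular_fractions=sub_fracs,
        srlm_fractions=srlm_fracs,
        border=border,
        digitation_count=spec.digitation_count,
        anterior_ca3_z=ca3_start,
    )


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def _apply_jitter(voxels: np.ndarray, prob: float, rng: np.random.Generator) -> None:
    """Swap boundary voxels with a 4-neighbour's label, in place, per slice."""
    nx, ny, nz = voxels.shape
    for z in range(nz):
        sl = voxels[:, :, z]
        if not sl.any():
            continue
        shifts = [np.roll(sl, 1, 0), np.roll(sl, -1, 0), np.roll(sl, 1, 1), np.roll(sl, -1, 1)]
        boundary = np.zeros(sl.shape, bool)
        for sh in shifts:
            boundary |= sh != sl
        sel = boundary & (rng.random(sl.shape) < prob)
        if not sel.any():
            continue
        pick = rng.integers(0, 4, size=sl.shape)
        new = sl.copy()
        for k, sh in enumerate(shifts):
            m = sel & (pick == k)
            new[m] = sh[m]
        voxels[:, :, z] = new


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate(
    spec: PhantomSpec, schema: SubfieldSchema | None = None
) -> tuple[LabelVolume, Landmarks, CoverageMask, GroundTruth]:
    """Draw the phantom. Identical spec (and seed) gives bit-identical output."""
    spec.validate()
    schema = schema or SubfieldSchema()
    codes = {n: schema.code(n) for n in _SUBFIELDS}
    nx, ny, nz = spec.shape
    grids = _grids(spec)
    voxels = np.zeros((nx, ny, nz), dtype=np.int16)
    z_any = min(e[0] for e in spec.extents.values())
    z_end = max(e[1] for e in spec.extents.values())
    for z in range(z_any, z_end + 1):
        voxels[:, :, z] = _draw_slice(spec, z, grids, codes)

    truth = _compute_truth(spec, voxels, codes, grids)

    rng = np.random.default_rng(spec.seed)
    covered = np.ones(nz, dtype=bool)
    if spec.dropout_prob > 0:
        z_lo, z_hi = spec.dropout_range or (z_any, z_end)
        for z in range(z_lo, z_hi + 1):
            if rng.random() < spec.dropout_prob:
                voxels[:, :, z] = 0
                covered[z] = False
    if spec.jitter_prob > 0:
        _apply_jitter(voxels, spec.jitter_prob, rng)

    volume = LabelVolume(
        voxels=voxels,
        spacing=tuple(spec.spacing),
        hemisphere=spec.hemisphere,
        schema=schema,
    )
    return volume, spec.landmarks(), CoverageMask(covered), truth


def random_spec(rng: np.random.Generator, mode: str = "extent") -> PhantomSpec:
    """A randomized, internally consistent phantom spec for recovery studies.

    ``mode`` selects which ground-truth family the randomization exercises:
    ``"extent"`` varies longitudinal extents, ``"subicular"`` varies strip
    splits, ``"srlm"`` varies angular sector spans (SRLM drawn as an arc),
    ``"border"`` varies the border ramp.
    """
    if mode == "border":
        # room for the 20 mm offset slice (100 slices at dz 0.2) past the apex
        nz = 200
        tip = int(rng.integers(4, 10))
        apex = int(rng.integers(tip + 45, tip + 66))
        post = int(rng.integers(apex + 106, min(apex + 126, nz - 4)))
    else:
        nz = 160
        tip = int(rng.integers(4, 14))
        apex = int(rng.integers(tip + 50, tip + 70))
        # keep the 50% body increment anterior to the posterior tip
        post_lo = max(apex + 70, 2 * (apex - tip) + tip + 2)
        post = int(rng.integers(post_lo, nz - 5))

    def seg(lo_off, hi_off, end_lo, end_hi):
        z0 = int(rng.integers(tip + lo_off, tip + hi_off))
        z1 = int(rng.integers(post - end_hi, post - end_lo + 1))
        return z0, max(z0 + 10, z1)

    dg = seg(20, 34, 2, 10)
    prs = seg(10, 20, 30, 44)
    pas_end = int(rng.integers(apex + 16, min(apex + 40, prs[1] - 3)))
    extents = {
        "SUB": (tip, post),
        "CA1": seg(6, 16, 0, 2),
        "PrS": prs,
        "DG": dg,
        "SRLM": (dg[0] - int(rng.integers(0, 3)), min(nz - 1, dg[1] + int(rng.integers(0, 3)))),
        "CA3": seg(30, 44, 1, 8),
        "PaS": (int(rng.integers(max(tip + 44, prs[0] + 4), tip + 56)), pas_end),
        "CA2": seg(44, 56, 2, 12),
    }

    spans = (float(rng.uniform(100, 170)), float(rng.uniform(12, 40)), float(rng.uniform(8, 30)))
    f_prs = float(rng.uniform(0.25, 0.45))
    f_pas = float(rng.uniform(0.08, 0.25))
    fractions = (1.0 - f_prs - f_pas, f_prs, f_pas)

    kwargs = dict(
        shape=(100, 100, nz),
        center=(52, 48),
        anterior_tip_z=tip,
        uncal_apex_z=apex,
        posterior_tip_z=post,
        extents=extents,
        dg_radius=float(rng.uniform(14, 19)),
        srlm_thickness=float(rng.uniform(2.5, 4.0)),
        ca_thickness=float(rng.uniform(5.0, 7.0)),
        strip_length=int(rng.integers(42, 50)),
        strip_fractions=fractions,
        ca_spans_deg=spans,
        digitation_count=int(rng.integers(1, 5)),
        digitation_amplitude=float(rng.uniform(5, 8)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    if mode == "srlm":
        kwargs["srlm_arc"] = "ribbon"
        kwargs["digitation_count"] = 0
    elif mode == "border":
        # DG stays the most medial structure and the anchor march lands on SUB
        kwargs["ca_spans_deg"] = (
            float(rng.uniform(100, 150)), float(rng.uniform(12, 30)), float(rng.uniform(8, 20)))
        f_prs = float(rng.uniform(0.2, 0.3))
        f_pas = float(rng.uniform(0.08, 0.15))
        kwargs["strip_fractions"] = (1.0 - f_prs - f_pas, f_prs, f_pas)
        hi = kwargs["dg_radius"] - 2
        a = float(rng.uniform(hi * 0.5, hi))
        kwargs["border_offset_anterior"] = a
        kwargs["border_offset_posterior"] = float(rng.uniform(0, a * 0.5))
        # every structure the anchor construction needs covers both offsets
        for name in ("SUB", "CA1"):
            z0, _ = extents[name]
            extents[name] = (z0, post)
        for name in ("DG", "SRLM", "CA3", "CA2"):
            z0, z1 = extents[name]
            extents[name] = (z0, max(z1, min(nz - 2, apex + 102)))
    elif mode == "subicular":
        kwargs["border_offset_anterior"] = kwargs["border_offset_posterior"] = 0.0
    return PhantomSpec(**kwargs)


def write_outputs(spec: PhantomSpec, out_dir, schema: SubfieldSchema | None = None) -> dict:
    """Generate and write NIfTI + landmarks JSON + coverage TSV + truth JSON."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    volume, landmarks, coverage, truth = generate(spec, schema=schema)
    paths = {
        "volume": os.path.join(out_dir, "phantom.nii.gz"),
        "landmarks": os.path.join(out_dir, "landmarks.json"),
        "coverage": os.path.join(out_dir, "coverage.tsv"),
        "truth": os.path.join(out_dir, "ground_truth.json"),
        "schema": os.path.join(out_dir, "schema.json"),
    }
    save_label_volume(volume, paths["volume"])
    landmarks.to_json(paths["landmarks"], hemisphere=volume.hemisphere)
    coverage.to_tsv(paths["coverage"])
    truth.to_json(paths["truth"])
    volume.schema.to_json(paths["schema"])
    return paths
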