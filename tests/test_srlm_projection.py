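import numpy as np
import pytest

import hippomorph as hm
from hippomorph.errors import ProjectionError


def ring_slice(spans=(150, 20, 10), arc_start=-90.0, shape=(120, 120), center=(60, 60),
               r_dg=20, t_srlm=3, t_ca=6, with_sub=False, border_x=None):
    """Concentric DG disc / SRLM arc / CA sector annulus, arcs starting at
    ``arc_start`` degrees and spanning ``sum(spans)`` counterclockwise."""
    cx, cy = center
    x, y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    rho = np.hypot(x - cx, y - cy)
    phi = (np.degrees(np.arctan2(y - cy, x - cx)) - arc_start) % 360
    total = sum(spans)
    masks = {
        "DG": rho <= r_dg,
        "SRLM": (rho > r_dg) & (rho <= r_dg + t_srlm) & (phi < total),
    }
    band = (rho > r_dg + t_srlm) & (rho <= r_dg + t_srlm + t_ca)
    lo = 0.0
    for name, span in zip(("CA1", "CA2", "CA3"), spans):
        masks[name] = band & (phi >= lo) & (phi < lo + span)
        lo += span
    masks["SUB"] = np.zeros(shape, bool)
    if with_sub:
        bx = cx if border_x is None else border_x
        strip = ((y >= cy - (r_dg + t_srlm + t_ca)) & (y <= cy - (r_dg + t_srlm) - 1)
                 & (x >= cx - 40) & (x < bx))
        from_ca1 = masks["CA1"] & (x < bx) & (y < cy)  # inferior arc medial of border
        masks["SUB"] = strip | from_ca1
        masks["CA1"] = masks["CA1"] & ~from_ca1
    return masks


class TestMedialDgPoint:
    def test_min_column(self):
        masks = ring_slice()
        assert hm.medial_dg_point(masks["DG"]) == 40

    def test_single_voxel(self):
        dg = np.zeros((20, 20), bool)
        dg[7, 3] = True
        assert hm.medial_dg_point(dg) == 7

    def test_empty_is_none(self):
        assert hm.medial_dg_point(np.zeros((5, 5), bool)) is None


class TestProjection:
    def test_angular_fraction_oracle_180_degree_arc(self):
        spans = (150, 20, 10)
        masks = ring_slice(spans)
        res = hm.project_onto_srlm(masks, hm.medial_dg_point(masks["DG"]))
        total = sum(spans)
        for name, span in zip(("CA1", "CA2", "CA3"), spans):
            assert res.prop[name] == pytest.approx(span / total, abs=0.03)

    def test_only_ca1_takes_whole_band(self):
        masks = ring_slice((180, 1e-9, 1e-9))
        masks["CA2"][:, :] = False
        masks["CA3"][:, :] = False
        res = hm.project_onto_srlm(masks, hm.medial_dg_point(masks["DG"]))
        assert res.prop["CA1"] == pytest.approx(1.0)
        assert res.prop["CA2"] == 0.0 and res.prop["CA3"] == 0.0
        assert not res.sub_border_lateral_case

    def test_all_ca_empty_raises(self):
        masks = ring_slice()
        for n in ("CA1", "CA2", "CA3"):
            masks[n] = np.zeros_like(masks[n])
        with pytest.raises(ProjectionError):
            hm.project_onto_srlm(masks, hm.medial_dg_point(masks["DG"]))

    def test_no_lateral_srlm_skips_slice(self):
        masks = ring_slice()
        res = hm.project_onto_srlm(masks, medial_dg_x=200)
        assert res is None

    def test_sub_border_lateral_case_sums_below_one(self):
        # the SUB-CA1 interface sits a quarter of the way along the band:
        # everything medial of the projected midpoint stays unassigned
        spans = (170, 5, 5)
        cx, cy, r = 60, 60, 23
        bx = int(round(cx + (r + 3) * np.sin(np.radians(45))))
        masks = ring_slice(spans, with_sub=True, border_x=bx)
        res = hm.project_onto_srlm(masks, hm.medial_dg_point(masks["DG"]))
        assert res.sub_border_lateral_case
        total = sum(res.prop.values())
        assert total == pytest.approx(0.75, abs=0.05)
        assert total < 1.0

    def test_partition_every_lateral_voxel_assigned_once(self):
        masks = ring_slice()
        mx = hm.medial_dg_point(masks["DG"])
        res = hm.project_onto_srlm(masks, mx)
        lateral = masks["SRLM"] & (np.arange(masks["SRLM"].shape[0])[:, None] >= mx)
        assert res.n_srlm_total == int(lateral.sum())
        assert sum(res.n_assigned.values()) == res.n_srlm_total  # no SUB case here
        assert (res.relabeled[lateral] > 0).all()

    def test_medial_mask_monotonicity(self):
        masks = ring_slice()
        mx = hm.medial_dg_point(masks["DG"])
        n = [hm.project_onto_srlm(masks, m).n_srlm_total for m in (mx + 10, mx, mx - 5)]
        assert n[0] <= n[1] <= n[2]

    def test_resolution_consistency(self):
        masks = ring_slice()
        res1 = hm.project_onto_srlm(masks, hm.medial_dg_point(masks["DG"]))
        fine = {k: np.kron(v, np.ones((2, 2), bool)) for k, v in masks.items()}
        res2 = hm.project_onto_srlm(fine, hm.medial_dg_point(fine["DG"]))
        for name in ("CA1", "CA2", "CA3"):
            assert res2.prop[name] == pytest.approx(res1.prop[name], abs=0.02)


class TestProfile:
    def test_constant_spans_give_flat_profile(self):
        spec = hm.PhantomSpec(srlm_arc="ribbon", digitation_count=0)
        vol, lm, _, _ = hm.generate(spec)
        results = hm.srlm_profile(vol, lm)
        assert len(results) == 5
        for name in ("CA1", "CA2", "CA3"):
            vals = [r.prop[name] for r in results]
            assert max(vals) - min(vals) < 0.02

    def test_ramping_ca1_span_gives_monotone_profile(self):
        spec = hm.PhantomSpec(
            srlm_arc="ribbon", digitation_count=0,
            ca_spans_deg=(120.0, 25.0, 15.0),
            ca_spans_deg_posterior=(170.0, 25.0, 15.0),
        )
        vol, lm, _, _ = hm.generate(spec)
        vals = [r.prop["CA1"] for r in hm.srlm_profile(vol, lm)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_single_increment_request(self):
        spec = hm.PhantomSpec(srlm_arc="ribbon", digitation_count=0)
        vol, lm, _, _ = hm.generate(spec)
        results = hm.srlm_profile(vol, lm, increments_pct=(20,))
        assert len(results) == 1 and results[0].position_pct == 20.0


def test_curved_length_occupancy_worked_example():
    # border positions at 33% and 80% of the curved SRLM length imply a CA1
    # occupancy of 47% of the band
    assert hm.curved_length_occupancy(33.0, 80.0) == 47.0
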