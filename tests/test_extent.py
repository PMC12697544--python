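import numpy as np
import pytest

import hippomorph as hm
from hippomorph.errors import LandmarkError


class TestAppearanceRule:
    def test_first_two_by_two_block(self, volume_factory):
        arr = np.zeros((20, 20, 20), dtype=np.int16)
        arr[5:7, 5:7, 7] = 4
        assert hm.detect_appearance(volume_factory(arr), "CA1") == 7

    def test_corner_connected_chain_counts(self, volume_factory):
        arr = np.zeros((20, 20, 20), dtype=np.int16)
        arr[5:8, 5, 5] = 4  # only three in a row: below threshold
        for i in range(4):  # diagonal chain of four, corner-connected
            arr[5 + i, 5 + i, 6] = 4
        assert hm.detect_appearance(volume_factory(arr), "CA1") == 6

    def test_gap_fallback_single_voxel(self, volume_factory):
        arr = np.zeros((20, 20, 20), dtype=np.int16)
        arr[5, 5, 4] = 4
        covered = np.ones(20, bool)
        covered[3] = False
        vol = volume_factory(arr)
        assert hm.detect_appearance(vol, "CA1", hm.CoverageMask(covered)) == 4
        # without the gap the single voxel does not trigger appearance
        assert hm.detect_appearance(vol, "CA1") is None

    def test_raising_min_cluster_never_earlier(self, volume_factory):
        rng = np.random.default_rng(3)
        arr = (rng.random((16, 16, 12)) < 0.08).astype(np.int16) * 4
        vol = volume_factory(arr)
        previous = -1
        for k in (1, 2, 4, 8):
            z = hm.detect_appearance(vol, "CA1", min_cluster=k)
            if z is None:
                break
            assert z >= previous
            previous = z


class TestDisappearance:
    def test_last_voxel_slice(self, volume_factory):
        arr = np.zeros((20, 20, 150), dtype=np.int16)
        arr[3, 3, 100:141] = 3  # PaS
        assert hm.detect_disappearance(volume_factory(arr), "PaS") == 140

    def test_absent_label_returns_none(self, volume_factory):
        arr = np.zeros((20, 20, 20), dtype=np.int16)
        assert hm.detect_disappearance(volume_factory(arr), "CA2") is None

    def test_matches_ground_truth_on_phantom(self, default_phantom):
        _, vol, _, _, truth = default_phantom
        for label in ("PrS", "PaS", "CA2"):
            assert hm.detect_disappearance(vol, label) == truth.disappearance[label]


class TestDgEnclosure:
    def test_ring_closes_at_expected_slice(self, volume_factory):
        arr = np.zeros((20, 20, 40), dtype=np.int16)
        for z in (29, 30):
            arr[8:11, 8:11, z] = 8  # SRLM block
            arr[9, 9, z] = 7  # DG core
        arr[9, 8, 29] = 0  # break the ring anteriorly
        assert hm.dg_enclosure_appearance(volume_factory(arr)) == 30

    def test_no_srlm_anywhere_gives_absent(self, volume_factory):
        arr = np.zeros((20, 20, 20), dtype=np.int16)
        arr[5:8, 5:8, 5] = 7
        assert hm.dg_enclosure_appearance(volume_factory(arr)) is None

    def test_phantom_round_trip(self, default_phantom):
        _, vol, _, _, truth = default_phantom
        assert hm.dg_enclosure_appearance(vol) == truth.dg_enclosure_z


class TestLengths:
    def test_head_length_is_slice_gap_times_dz(self):
        lm = hm.Landmarks(10, 110, 200)
        assert hm.head_length(lm, (0.2, 0.2, 0.2)) == pytest.approx(20.0)
        lm5 = hm.Landmarks(0, 5, 10)
        assert hm.head_length(lm5, (0.2, 0.2, 0.2)) == pytest.approx(1.0)

    def test_degenerate_head_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            hm.head_length(hm.Landmarks(5, 5, 10), (0.2, 0.2, 0.2))

    def test_ratio(self):
        rec = hm.total_length_and_ratio(hm.Landmarks(0, 100, 200), (0.2, 0.2, 0.2))
        assert rec.head_to_total_ratio_pct == pytest.approx(50.0)

    def test_undeterminable_posterior_tip_keeps_head(self):
        lm = hm.Landmarks(0, 100, 200, posterior_tip_undeterminable=True)
        rec = hm.total_length_and_ratio(lm, (0.2, 0.2, 0.2))
        assert rec.head_length_mm == pytest.approx(20.0)
        assert rec.total_length_mm is None and rec.head_to_total_ratio_pct is None

    def test_phantom_recovery(self, default_phantom):
        _, vol, lm, _, truth = default_phantom
        rec = hm.total_length_and_ratio(lm, vol.spacing)
        assert rec.head_length_mm == pytest.approx(truth.head_length_mm)
        assert rec.total_length_mm == pytest.approx(truth.total_length_mm)
        assert rec.head_to_total_ratio_pct == pytest.approx(truth.head_to_total_ratio_pct)


class TestAppearanceOrder:
    def test_canonical_order_with_gap_distances(self, default_phantom):
        # phantom starts: SUB tip+0, CA1 +10, DG +28, CA3 +36, CA2 +51 slices
        _, vol, lm, cov, _ = default_phantom
        events, absent = hm.appearance_order(vol, ("SUB", "CA1", "DG", "CA3", "CA2"), lm, cov)
        assert absent == []
        assert [e.label for e in events] == ["SUB", "CA1", "DG", "CA3", "CA2"]
        gaps = [round(e.gap_mm, 3) for e in events]
        assert gaps == [0.0, 2.0, 3.6, 1.6, 3.0]
        head_mm = hm.head_length(lm, vol.spacing)
        for e in events:
            assert e.gap_pct_of_head == pytest.approx(e.gap_mm / head_mm * 100.0)

    def test_simultaneous_appearance_reported_as_tie(self, volume_factory):
        arr = np.zeros((20, 20, 30), dtype=np.int16)
        arr[2:4, 2:4, 6] = 5  # CA2
        arr[8:10, 8:10, 6] = 6  # CA3
        events, _ = hm.appearance_order(
            volume_factory(arr), ("CA2", "CA3"), hm.Landmarks(0, 20, 25)
        )
        assert events[1].tied_with_previous and events[1].gap_mm == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(11)
        spec = hm.random_spec(rng, mode="extent")
        vol, lm, cov, _ = hm.generate(spec)
        k = 7
        shifted = np.zeros_like(vol.voxels)
        shifted[:, :, k:] = vol.voxels[:, :, :-k]
        vol2 = hm.LabelVolume.from_array(shifted, spacing=vol.spacing)
        lm2 = lm.shifted(k)
        e1, _ = hm.appearance_order(vol, ("SUB", "CA1", "CA3"), lm)
        e2, _ = hm.appearance_order(vol2, ("SUB", "CA1", "CA3"), lm2)
        assert [(e.label, e.gap_mm, e.gap_pct_of_head) for e in e1] == [
            (e.label, e.gap_mm, e.gap_pct_of_head) for e in e2
        ]


class TestSubicularOrdering:
    def test_last_in_first_out_on_phantom(self, default_phantom):
        _, vol, lm, cov, _ = default_phantom
        appear = {l: hm.appearance_slice(vol, l, lm, cov) for l in ("SUB", "PrS", "PaS")}
        disappear = {l: hm.detect_disappearance(vol, l) for l in ("SUB", "PrS", "PaS")}
        order_in = sorted(appear, key=appear.get)
        order_out = sorted(disappear, key=disappear.get)
        assert order_in == ["SUB", "PrS", "PaS"]
        assert order_out == list(reversed(order_in))


class TestTailPresence:
    def test_presence_at_offsets(self, volume_factory):
        arr = np.zeros((10, 10, 60), dtype=np.int16)
        arr[4, 4, 40] = 4  # CA1 exactly 2 mm (10 slices) anterior to tip z=50
        vol = volume_factory(arr)
        lm = hm.Landmarks(0, 20, 50)
        table = hm.tail_presence(vol, ("CA1", "DG"), lm)
        assert table[2.0]["CA1"] is True and table[2.0]["DG"] is False
        assert table[1.0]["CA1"] is False

    def test_uncovered_target_is_undetermined(self, volume_factory):
        arr = np.zeros((10, 10, 60), dtype=np.int16)
        vol = volume_factory(arr)
        covered = np.ones(60, bool)
        covered[40] = False
        table = hm.tail_presence(vol, ("CA1",), hm.Landmarks(0, 20, 50),
                                 hm.CoverageMask(covered))
        assert table[2.0]["CA1"] is None
        assert table[1.0]["CA1"] is False

    def test_cohort_counting(self, volume_factory):
        # ten tiny cases, six with DG on the 2 mm slice -> DG present in 60%
        present = 0
        for i in range(10):
            arr = np.zeros((10, 10, 60), dtype=np.int16)
            if i < 6:
                arr[4, 4, 40] = 7
            table = hm.tail_presence(volume_factory(arr), ("DG",), hm.Landmarks(0, 20, 50))
            present += table[2.0]["DG"]
        assert present / 10 == pytest.approx(0.6)

    def test_missing_posterior_tip_raises(self, volume_factory):
        arr = np.zeros((10, 10, 20), dtype=np.int16)
        with pytest.raises(LandmarkError):
            hm.tail_presence(volume_factory(arr), ("CA1",), hm.Landmarks(0, 5, None))
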