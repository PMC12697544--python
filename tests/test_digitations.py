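import numpy as np
import pytest

import hippomorph as hm
from hippomorph.errors import DegenerateSliceError


def surface_footprint(heights, base=5, width=None):
    """Footprint mask whose superior surface follows ``heights`` per column."""
    heights = np.asarray(heights, dtype=int)
    n = len(heights)
    mask = np.zeros((n + 4, base + heights.max() + 6), bool)
    for i, h in enumerate(heights):
        mask[i + 2, : base + h + 1] = True
    return mask


def sinusoid_heights(n_cols=80, n_peaks=3, amplitude=8):
    t = np.linspace(0, 1, n_cols)
    return np.rint(amplitude * 0.5 * (1 - np.cos(2 * np.pi * n_peaks * t))).astype(int)


class TestProfile:
    def test_flat_top_is_single_digitation(self):
        profile = hm.digitation_profile(surface_footprint(np.zeros(30, int)))
        assert profile.n_digitations == 1
        assert profile.peak_xs.size == 0

    def test_three_sinusoid_peaks(self):
        profile = hm.digitation_profile(surface_footprint(sinusoid_heights(n_peaks=3)))
        assert profile.n_digitations == 3

    def test_amplitude_below_prominence_is_one(self):
        profile = hm.digitation_profile(
            surface_footprint(sinusoid_heights(n_peaks=3, amplitude=1)))
        assert profile.n_digitations == 1

    def test_narrow_footprint_errors(self):
        assert pytest.raises(
            DegenerateSliceError, hm.digitation_profile, surface_footprint(np.zeros(1, int))
        )

    @pytest.mark.parametrize("n_peaks", [1, 2, 3, 4])
    def test_peak_count_recovery(self, n_peaks):
        profile = hm.digitation_profile(
            surface_footprint(sinusoid_heights(n_cols=100, n_peaks=n_peaks)))
        assert profile.n_digitations == n_peaks

    def test_phantom_count_recovery(self, default_phantom):
        _, vol, _, _, truth = default_phantom
        z = hm.anterior_ca3_slice(vol)
        profile = hm.digitation_profile(hm.footprint_mask(vol, z), z=z)
        assert profile.n_digitations == truth.digitation_count


class TestAnteriorCa3Slice:
    def test_superior_strip_onset(self, volume_factory):
        arr = np.zeros((30, 30, 80), dtype=np.int16)
        arr[10:20, 10:14, 40:70] = 7  # DG slab
        arr[10:20, 14:16, 40:70] = 8  # SRLM above it
        arr[12:16, 5:8, 40:70] = 6  # CA3 inferior to DG until z=60
        arr[12:16, 20:23, 60:70] = 6  # CA3 enters the superior strip at z=60
        assert hm.anterior_ca3_slice(volume_factory(arr)) == 60

    def test_fallback_without_dg_srlm_warns(self, volume_factory):
        arr = np.zeros((30, 30, 20), dtype=np.int16)
        arr[5:20, 3:10, 10] = 4  # CA1 bulk defines the footprint
        arr[8:12, 15:18, 10] = 6  # CA3 above the footprint median height
        with pytest.warns(UserWarning, match="median"):
            assert hm.anterior_ca3_slice(volume_factory(arr)) == 10

    def test_phantom_round_trip(self, default_phantom):
        _, vol, _, _, truth = default_phantom
        assert hm.anterior_ca3_slice(vol) == truth.anterior_ca3_z


class TestClassification:
    @staticmethod
    def _strip_at(columns, shape=(110, 40), y=30):
        m = np.zeros(shape, bool)
        for c in columns:
            m[c, y] = True
        return m

    def test_on_top_medial(self):
        heights = sinusoid_heights(n_cols=90, n_peaks=3, amplitude=9)
        fp = surface_footprint(heights)
        profile = hm.digitation_profile(fp)
        peak = profile.peak_xs[0]  # most medial peak; footprint spans ~90 columns
        rec = hm.classify_ca3(profile, self._strip_at(range(peak - 1, peak + 2)))
        assert rec.relation == "on_top"
        assert rec.position == "medial"

    def test_in_between_midpoint(self):
        heights = sinusoid_heights(n_cols=90, n_peaks=2, amplitude=9)
        fp = surface_footprint(heights)
        profile = hm.digitation_profile(fp)
        trough = int(np.mean(profile.peak_xs))  # between the two peaks: center
        rec = hm.classify_ca3(profile, self._strip_at(range(trough - 1, trough + 2)))
        assert rec.relation == "in_between"
        assert rec.position == "midpoint"

    def test_straddling_is_both(self):
        heights = sinusoid_heights(n_cols=90, n_peaks=2, amplitude=9)
        profile = hm.digitation_profile(surface_footprint(heights))
        p0, p1 = profile.peak_xs
        trough = (p0 + p1) // 2
        cols = list(range(p0 - 1, p0 + 2)) + list(range(trough - 1, trough + 2))
        rec = hm.classify_ca3(profile, self._strip_at(cols))
        assert rec.relation == "both"

    def test_determinism(self):
        heights = sinusoid_heights(n_cols=90, n_peaks=3, amplitude=9)
        profile = hm.digitation_profile(surface_footprint(heights))
        strip = self._strip_at(range(40, 46))
        assert hm.classify_ca3(profile, strip) == hm.classify_ca3(profile, strip)

    def test_random_peak_trough_placement_always_correct(self):
        # amplitude three times the prominence threshold; CA3 placed exactly
        # at a peak or a trough must classify accordingly
        rng = np.random.default_rng(17)
        correct = 0
        trials = 30
        for _ in range(trials):
            n_peaks = int(rng.integers(2, 5))
            heights = sinusoid_heights(n_cols=96, n_peaks=n_peaks, amplitude=9)
            profile = hm.digitation_profile(surface_footprint(heights))
            at_peak = bool(rng.integers(0, 2))
            if at_peak:
                c = int(rng.choice(profile.peak_xs))
            else:
                peaks = np.sort(profile.peak_xs)
                i = int(rng.integers(0, len(peaks) - 1))
                c = int((peaks[i] + peaks[i + 1]) // 2)
            rec = hm.classify_ca3(profile, self._strip_at(range(c - 1, c + 2)))
            correct += rec.relation == ("on_top" if at_peak else "in_between")
        assert correct == trials

    def test_mirror_keeps_medial_position(self, default_phantom):
        _, vol, _, _, _ = default_phantom
        z = hm.anterior_ca3_slice(vol)
        rec = hm.classify_ca3(
            hm.digitation_profile(hm.footprint_mask(vol, z)),
            hm.ca3_superior_strip(vol, z),
        )
        m = hm.mirror(vol)
        rec_m = hm.classify_ca3(
            hm.digitation_profile(hm.footprint_mask(m, z)),
            hm.ca3_superior_strip(m, z),
        )
        assert rec_m.position == rec.position and rec_m.relation == rec.relation
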