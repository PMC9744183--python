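"""Mean-waveform processing and the 8 single-channel waveform features."""

import numpy as np
import pytest
from scipy.signal import resample

from deltaspike import (
    MeanWaveform,
    UnitRecording,
    extract_waveform_features,
    mean_and_upsample,
    scale_align,
    select_main_channel,
)
from deltaspike.core_data import DT_US, UPSAMPLED_LENGTH
from deltaspike.waveform import _ACCEL_WINDOW, _BREAK_WINDOW, _SMILE_WINDOW


def _unit_from_snippets(snippets):
    n = snippets.shape[0]
    return UnitRecording("u", np.arange(n) * 0.1 + 0.1, snippets)


def _scaled_vector(v):
    """Scale an arbitrary 256-sample vector per the scale_align contract."""
    v = np.asarray(v, float)
    if abs(v.min()) < abs(v.max()):
        v = -v
    return v / abs(v.min())


class TestMeanAndUpsample:
    def test_identical_snippets_mean_equals_upsampled_single(self, rng):
        snip = rng.normal(size=(1, 8, 32))
        snippets = np.repeat(snip, 20, axis=0)
        w = mean_and_upsample(_unit_from_snippets(snippets))
        assert w.values.shape == (8, 256)
        np.testing.assert_allclose(
            w.values, resample(snip[0], 256, axis=1), atol=1e-12
        )

    def test_averaging_and_interpolation_commute(self, rng):
        snippets = rng.normal(size=(15, 8, 32))
        w = mean_and_upsample(_unit_from_snippets(snippets))
        mean_of_up = resample(snippets, 256, axis=2).mean(axis=0)
        np.testing.assert_allclose(w.values, mean_of_up, rtol=1e-9, atol=1e-12)

    def test_empty_subset_rejected(self, rng):
        unit = _unit_from_snippets(rng.normal(size=(5, 8, 32)))
        with pytest.raises(ValueError, match="empty"):
            mean_and_upsample(unit, np.array([], dtype=int))


class TestMainChannel:
    def test_single_channel(self):
        w = MeanWaveform(values=np.sin(np.linspace(0, 3, 256))[None, :])
        assert select_main_channel(w) == 0

    def test_matches_exhaustive_ttp_argmax(self, rng):
        for _ in range(20):
            values = rng.normal(size=(8, 256))
            w = MeanWaveform(values=values)
            ttp = [values[c].max() - values[c].min() for c in range(8)]
            assert select_main_channel(w) == int(np.argmax(ttp))

    def test_tie_breaks_to_lowest_index(self):
        base = np.zeros((4, 256))
        base[1, 10], base[1, 20] = -1.0, 1.0
        base[3, 10], base[3, 20] = -1.0, 1.0  # exact tie with channel 1
        assert select_main_channel(MeanWaveform(values=base)) == 1


class TestScaleAlign:
    def test_minimum_exactly_minus_one(self, rng):
        w = MeanWaveform(values=rng.normal(size=(8, 256)) - 0.2)
        s = scale_align(w)
        main = s.values[s.main_channel]
        assert main.min() == -1.0
        assert main.max() <= 1.0

    def test_positive_dominant_spike_inverted(self):
        values = np.zeros((2, 256))
        values[0, 100] = 5.0  # peak dominates trough
        values[0, 50] = -1.0
        values[1, 100] = 1.0
        s = scale_align(MeanWaveform(values=values))
        assert s.polarity_inverted
        assert s.values[0, 100] == -1.0

    def test_idempotent(self, rng):
        w = MeanWaveform(values=rng.normal(size=(8, 256)) - 0.5)
        once = scale_align(w)
        twice = scale_align(once)
        np.testing.assert_allclose(once.values, twice.values)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            scale_align(MeanWaveform(values=np.zeros((2, 256))))


def _triangle_trough(center=128, half_width_samples=16):
    """Symmetric triangular trough of depth -1."""
    v = np.zeros(UPSAMPLED_LENGTH)
    for k in range(-2 * half_width_samples, 2 * half_width_samples + 1):
        idx = center + k
        v[idx] = -max(0.0, 1.0 - abs(k) / (2 * half_width_samples))
    return v


class TestWaveformFeatures:
    def test_triangular_trough_fwhm(self):
        # half-width 0.1 ms per side -> FWHM 0.2 ms
        v = _triangle_trough(center=128, half_width_samples=16)
        v[200] = 0.3  # ensuing positive peak
        feats = extract_waveform_features(v)
        assert feats["FWHM"] == pytest.approx(0.2)

    def test_ttp_duration_from_construction(self):
        v = np.zeros(UPSAMPLED_LENGTH)
        v[80] = -1.0
        v[80 + 123] = 0.4  # ensuing maximal positivity
        feats = extract_waveform_features(v)
        assert feats["TTP-duration"] == pytest.approx(123 * DT_US / 1000.0)
        assert feats["TTP-magnitude"] == pytest.approx(1.4)

    def test_no_positive_sample_after_trough_still_defined(self):
        v = -np.linspace(0.1, 1.0, UPSAMPLED_LENGTH)
        v = _scaled_vector(v)
        feats = extract_waveform_features(v)
        # the post-trough global maximum is used even though it is <= 0
        assert np.isfinite(feats["TTP-duration"])
        assert feats["TTP-duration"] == 0.0  # trough at the last sample

    def test_window_sums_by_hand_on_sparse_vector(self):
        """Break measure and smile-cry equal hand-computed window sums."""
        v = np.zeros(UPSAMPLED_LENGTH)
        trough = 128
        v[trough] = -1.0
        v[trough - 30] = 0.2  # inside the break window
        v[trough + 60] = 0.1  # inside the smile-cry window
        v[200] = 0.5
        feats = extract_waveform_features(v)
        d2 = np.diff(v, n=2)
        brk = d2[trough + _BREAK_WINDOW[0] : trough + _BREAK_WINDOW[1] + 1].sum()
        smc = d2[trough + _SMILE_WINDOW[0] : trough + _SMILE_WINDOW[1] + 1].sum()
        acc = (d2[trough + _ACCEL_WINDOW[0] : trough + _ACCEL_WINDOW[1] + 1] ** 2).sum()
        assert feats["Break-measure"] == pytest.approx(brk * 10)
        assert feats["Smile-cry"] == pytest.approx(smc * 100)
        assert feats["Acceleration"] == pytest.approx(acc * 1e6)

    def test_dual_implementation_oracle(self, rng):
        """Each feature equals a direct-formula reimplementation."""
        done = 0
        while done < 10:
            raw = np.cumsum(rng.normal(size=UPSAMPLED_LENGTH))
            raw -= raw.mean()
            v = _scaled_vector(raw)
            trough = int(np.argmin(v))
            if trough >= 250:  # degenerate: trough at the window edge
                continue
            done += 1
            feats = extract_waveform_features(v)
            ms = DT_US / 1000.0
            peak = trough + 1 + int(np.argmax(v[trough + 1 :])) if trough < 255 else trough
            assert feats["TTP-duration"] == pytest.approx((peak - trough) * ms)
            assert feats["TTP-magnitude"] == pytest.approx(v[peak] - v[trough])

            below = np.flatnonzero(v <= -0.5)
            lo = trough
            while lo - 1 in below:
                lo -= 1
            hi = trough
            while hi + 1 in below:
                hi += 1
            assert feats["FWHM"] == pytest.approx((hi - lo) * ms)

            ts = np.arange(trough, 256)
            line = np.interp(ts, [trough, 255], [v[trough], v[255]])
            assert feats["Rise-coefficient"] == pytest.approx(
                (np.argmax(np.abs(v[trough:] - line))) * ms
            )

            d1 = np.diff(v)[trough:]
            dmax = d1.max()
            ok = np.abs(d1 - dmax) <= 0.05 * abs(dmax)
            best = cur = 0
            for f in ok:
                cur = cur + 1 if f else 0
                best = max(best, cur)
            assert feats["Maximum-speed"] == pytest.approx(best * ms)

    def test_scale_and_inversion_invariance(self, rng):
        raw = np.cumsum(rng.normal(size=(8, 32)), axis=1)
        raw -= raw.mean(axis=1, keepdims=True)
        unit = _unit_from_snippets(np.repeat(raw[None], 3, axis=0))
        ref = scale_align(mean_and_upsample(unit))
        base = extract_waveform_features(ref.values[ref.main_channel])
        for c in (3.7, -1.0, 0.01):
            unit_c = _unit_from_snippets(np.repeat(c * raw[None], 3, axis=0))
            s = scale_align(mean_and_upsample(unit_c))
            got = extract_waveform_features(s.values[s.main_channel])
            for name, val in base.items():
                assert got[name] == pytest.approx(val, rel=1e-9), name

    def test_population_ttp_ordering(self, nochunk_table):
        """Wide PYR spikes vs narrow PV spikes: median TTP duration ordering."""
        med = nochunk_table.groupby("label")["TTP-duration"].median()
        assert med["PYR"] > med["PV"]
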