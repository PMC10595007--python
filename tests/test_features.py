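"""Band decomposition, PSD estimation and the valence/arousal metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import eegaffect as ea
from eegaffect.errors import BandError, ConfigurationError

from conftest import make_epoch

FS = 128.0
ALPHA = ea.BandDefinition("alpha", 8.0, 14.0)


class TestBandDecompose:
    def test_full_montage_yields_70_signals(self, tone_epoch):
        decomposed = ea.band_decompose(tone_epoch)
        assert len(decomposed) == 70
        assert all(v.shape == (128,) for v in decomposed.values())

    def test_two_channels_yield_10_signals(self):
        ep = make_epoch(np.zeros((2, 128)), channels=("F7", "F8"))
        assert len(ea.band_decompose(ep)) == 10

    def test_alpha_tone_lands_in_alpha_band(self):
        # alpha-centered tone on a 4 s epoch: an order-4 response cannot
        # deliver 20 dB for content sitting right at a neighboring edge
        t = np.arange(512) / FS
        x = np.vstack([np.sin(2 * np.pi * 11 * t)] * 14)
        decomposed = ea.band_decompose(make_epoch(x))
        rms = {b: np.sqrt(np.mean(decomposed[("F7", b)] ** 2)) for b in ea.BAND_NAMES}
        for band in ("delta", "theta", "beta", "gamma"):
            assert rms["alpha"] >= 10 * rms[band]

    def test_band_edge_at_nyquist_rejected(self, tone_epoch):
        bad = (ea.BandDefinition("wide", 30.0, 64.0),)
        with pytest.raises(ConfigurationError):
            ea.band_decompose(tone_epoch, bands=bad)


class TestPeriodogram:
    def test_bin_aligned_tone_peaks_at_its_bin(self):
        t = np.arange(128) / FS
        psd = ea.periodogram_psd(np.sin(2 * np.pi * 16 * t), FS)
        assert psd.frequencies[np.argmax(psd.density)] == pytest.approx(16.0)

    def test_zero_signal_zero_density(self):
        psd = ea.periodogram_psd(np.zeros(128), FS)
        np.testing.assert_array_equal(psd.density, 0.0)

    @given(
        x=hnp.arrays(
            np.float64,
            st.integers(16, 256),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_parseval_consistency(self, x):
        psd = ea.periodogram_psd(x, FS)
        total = psd.density.sum() * psd.resolution_hz
        ms = np.mean(x**2)
        assert total == pytest.approx(ms, rel=1e-6, abs=1e-12)


class TestPsdStatsAndBandPower:
    @pytest.mark.parametrize(
        "density, expected",
        [([1, 1, 1, 1], (1.0, 0.0)), ([0, 2], (1.0, 1.0)), ([0, 0, 0], (0.0, 0.0))],
    )
    def test_psd_stats(self, density, expected):
        psd = ea.PSDEstimate(np.arange(len(density), dtype=float), density, 1.0)
        assert ea.psd_stats(psd) == pytest.approx(expected)

    def test_tone_band_power_dominates_total(self):
        t = np.arange(128) / FS
        psd = ea.periodogram_psd(np.sin(2 * np.pi * 10 * t), FS)
        total = psd.density.sum() * psd.resolution_hz
        assert ea.band_power(psd, ALPHA) >= 0.99 * total

    def test_zero_signal_floors_at_epsilon(self):
        psd = ea.periodogram_psd(np.zeros(128), FS)
        assert ea.band_power(psd, ALPHA) == ea.EPSILON_POWER

    def test_uniform_density_integrates_band_width(self):
        psd = ea.PSDEstimate(np.arange(0.0, 65.0), np.ones(65), 1.0)
        assert ea.band_power(psd, ALPHA) == pytest.approx(6.0)

    def test_empty_band_raises(self):
        psd = ea.PSDEstimate(np.arange(0.0, 65.0, 16.0), np.ones(5), 16.0)
        with pytest.raises(BandError, match="alpha"):
            ea.band_power(psd, ALPHA)


class TestValenceArousal:
    def test_symmetric_input_zeroes_all_valences(self):
        out = ea.valence_arousal(ea.BandPowerQuad(2.0, 2.0, 1.0, 1.0))
        for key in ("v1", "v2", "v3", "v4"):
            assert out[key] == pytest.approx(0.0)
        assert out["a1"] == pytest.approx(2.0)
        assert out["a2"] == pytest.approx(-2 * np.log(2))
        assert out["a3"] == pytest.approx(-1.0)
        assert out["a4"] == pytest.approx(0.5)

    def test_log_identity_for_v2(self):
        out = ea.valence_arousal(ea.BandPowerQuad(1.0, np.e, 3.0, 3.0))
        assert out["v2"] == pytest.approx(-1.0)

    def test_worked_asymmetric_quad(self):
        out = ea.valence_arousal(ea.BandPowerQuad(1.0, 4.0, 2.0, 2.0))
        assert out["v1"] == pytest.approx(1.5)
        assert out["v4"] == pytest.approx(3.0)
        assert out["a4"] == pytest.approx(0.8)
        assert out["a3"] == pytest.approx(np.log2(0.8))

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ConfigurationError):
            ea.BandPowerQuad(0.0, 1.0, 1.0, 1.0)


class TestExtractFeatures:
    def test_vector_has_exactly_148_features(self, tone_epoch):
        fv = ea.extract_features(tone_epoch)
        assert len(fv.values) == 148
        assert list(fv.values.index) == ea.feature_names()

    def test_zero_epoch_gives_zero_valences(self):
        fv = ea.extract_features(make_epoch(np.zeros((14, 128))))
        spectral = fv.values[: 140]
        np.testing.assert_allclose(spectral.to_numpy(), 0.0)
        for key in ("v1", "v2", "v3", "v4"):
            assert fv.values[key] == pytest.approx(0.0)

    def test_planted_right_alpha_forces_metric_signs(self):
        rng = np.random.default_rng(2)
        t = np.arange(128) / FS
        x = 0.01 * rng.standard_normal((14, 128))
        x[ea.DEFAULT_MONTAGE.index("F8")] += 5 * np.sin(2 * np.pi * 10 * t)
        fv = ea.extract_features(make_epoch(x))
        assert fv.values["v4"] > 0
        assert fv.values["v2"] < 0

    def test_label_and_group_copied(self, tone_epoch):
        fv = ea.extract_features(tone_epoch)
        assert fv.label == tone_epoch.condition_label
        assert fv.group == tone_epoch.subject_id

    def test_scaling_by_c_scales_powers_by_c_squared(self, rng):
        x = rng.normal(size=(14, 128))
        c = 3.0
        a = ea.extract_features(make_epoch(x)).values
        b = ea.extract_features(make_epoch(c * x)).values
        mean_cols = [n for n in ea.feature_names() if n.endswith("psd_mean")]
        np.testing.assert_allclose(b[mean_cols], c**2 * a[mean_cols], rtol=1e-9)
        assert b["v2"] == pytest.approx(a["v2"], rel=1e-9)
        assert b["a3"] == pytest.approx(a["a3"], rel=1e-9)
        assert b["v4"] == pytest.approx(c**2 * a["v4"], rel=1e-9)

    def test_swapping_frontal_pair_negates_valences(self, rng):
        x = rng.normal(size=(14, 128))
        i7 = ea.DEFAULT_MONTAGE.index("F7")
        i8 = ea.DEFAULT_MONTAGE.index("F8")
        swapped = x.copy()
        swapped[[i7, i8]] = swapped[[i8, i7]]
        a = ea.extract_features(make_epoch(x)).values
        b = ea.extract_features(make_epoch(swapped)).values
        for key in ("v1", "v2", "v3", "v4"):
            assert b[key] == pytest.approx(-a[key], rel=1e-9)
        for key in ("a1", "a2", "a3", "a4"):
            assert b[key] == pytest.approx(a[key], rel=1e-9)

    def test_batch_matches_single_epoch_extraction(self, rng):
        epochs = [make_epoch(rng.normal(size=(14, 128)), label=k % 2, subject=f"S{k}")
                  for k in range(4)]
        frame = ea.extract_feature_matrix(epochs)
        assert frame.shape == (4, 150)
        for k, ep in enumerate(epochs):
            single = ea.extract_features(ep).values
            np.testing.assert_allclose(
                frame.iloc[k][ea.feature_names()].to_numpy(dtype=float),
                single.to_numpy(),
                rtol=1e-12,
            )

    def test_empty_batch_gives_empty_matrix(self):
        frame = ea.extract_feature_matrix([])
        assert len(frame) == 0
        assert list(frame.columns) == ea.feature_names() + ["label", "group"]
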