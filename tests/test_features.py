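"""Window segmentation, the feature catalog, and its brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from actimet.features import (
    DEFAULT_BAND_HZ,
    extract_features,
    extract_window_features,
    feature_catalog,
    orientation_angles,
    segment_windows,
    synchronize,
    vector_magnitude,
    window_count,
)
from actimet.records import RawTriaxialRecording

from _oracles import (
    oracle_axis_features,
    oracle_cross_and_orientation,
    random_windows,
)


def _recording(samples, rate=100.0, site="hip"):
    return RawTriaxialRecording(
        site=site, sampling_rate=rate,
        start_time=pd.Timestamp("2019-06-01T09:00:00"), samples=samples,
    )


class TestVectorMagnitude:
    def test_unit_and_pythagoras(self):
        assert vector_magnitude([0.0], [0.0], [1.0])[0] == 1.0
        assert vector_magnitude([0.3], [0.4], [0.0])[0] == pytest.approx(0.5)

    def test_matches_elementwise_oracle(self, rng):
        x, y, z = rng.normal(size=(3, 500))
        expected = np.array([np.sqrt(a*a + b*b + c*c) for a, b, c in zip(x, y, z)])
        assert np.allclose(vector_magnitude(x, y, z), expected, atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            vector_magnitude([1.0, 2.0], [1.0], [1.0])


class TestSegmentation:
    @pytest.mark.parametrize(
        "n,expected",
        [(1_578_000, 1578), (974_000, 974), (999, 0), (2500, 2)],
    )
    def test_window_counts(self, n, expected):
        assert window_count(n) == expected

    def test_segment_shape_and_trailing_drop(self):
        rec = _recording(np.zeros((2500, 3)))
        wins = segment_windows(rec)
        assert wins.shape == (2, 1000, 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            segment_windows(_recording(np.empty((0, 3))))


class TestFeatureOracle:
    def test_catalog_size_and_order_stable(self):
        cat = feature_catalog()
        assert len(cat) == 118
        assert len(set(cat)) == 118
        assert cat[-3:] == ["tilt", "roll", "pitch"]

    def test_constant_window_sentinels(self):
        f = extract_window_features(np.tile([0.0, 0.0, 1.0], (1000, 1)))
        for axis in ("x", "y", "z", "vm"):
            assert f[f"sd_{axis}"] == 0.0
            assert f[f"p2p_{axis}"] == 0.0
            assert f[f"zero_crossings_{axis}"] == 0.0
            assert f[f"lag1_autocorr_{axis}"] == 0.0
            assert f[f"skewness_{axis}"] == 0.0
        assert f["corr_xy"] == 0.0
        assert f["tilt"] == pytest.approx(0.0)

    def test_sinusoid_zero_crossings(self):
        t = np.arange(1000) / 100.0
        w = np.zeros((1000, 3))
        # phase keeps all 40 crossings inside the sampled span (oracle-checked)
        w[:, 0] = np.sin(2 * np.pi * 2.0 * t + 0.2)
        f = extract_window_features(w)
        assert f["zero_crossings_x"] == 40.0
        assert f["dominant_frequency_x"] == pytest.approx(2.0)

    def test_band_excludes_out_of_band_peak(self):
        t = np.arange(1000) / 100.0
        w = np.zeros((1000, 3))
        w[:, 2] = 2.0 * np.sin(2 * np.pi * 7.0 * t) + 0.2 * np.sin(2 * np.pi * 1.0 * t)
        f = extract_window_features(w)
        assert f["dominant_frequency_z"] == pytest.approx(1.0)

    def test_two_burst_activation(self):
        t = np.arange(1000) / 100.0
        w = np.zeros((1000, 3))
        burst = ((t >= 2) & (t < 3)) | ((t >= 6) & (t < 7))
        w[:, 1] = np.where(burst, 0.5 * np.sin(2 * np.pi * 3 * t), 0.0)
        f = extract_window_features(w, activation_threshold_g=0.05)
        assert f["n_activations_y"] == 2.0
        assert f["mean_activation_interval_y"] == pytest.approx(1.0, abs=0.15)
        assert f["activation_interval_variability_y"] == pytest.approx(0.0, abs=0.05)

    def test_threshold_above_signal(self):
        w = random_windows(1, seed=3)[0] * 0.001
        f = extract_window_features(w, activation_threshold_g=5.0)
        for axis in ("x", "y", "z", "vm"):
            assert f[f"n_activations_{axis}"] == 0.0
            assert f[f"active_samples_{axis}"] == 0.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_brute_force_oracle_agreement(self, seed):
        """Every catalog feature matches the naive oracle on random windows."""
        wins = random_windows(100, seed=seed)
        rec = _recording(wins.reshape(-1, 3))
        table = extract_features(rec)
        assert len(table) == 100
        axes = {"x": 0, "y": 1, "z": 2}
        for i in range(100):
            row = table.iloc[i]
            w3 = wins[i]
            signals = {name: w3[:, j] for name, j in axes.items()}
            signals["vm"] = np.sqrt((w3**2).sum(axis=1))
            for axis, sig in signals.items():
                expected = oracle_axis_features(sig)
                for stat, val in expected.items():
                    got = row[f"{stat}_{axis}"]
                    assert got == pytest.approx(val, rel=1e-9, abs=1e-9), (
                        f"window {i}, {stat}_{axis}"
                    )
            for stat, val in oracle_cross_and_orientation(w3).items():
                assert row[stat] == pytest.approx(val, rel=1e-9, abs=1e-9), (
                    f"window {i}, {stat}"
                )


class TestEquivariance:
    def _features(self, w3):
        return extract_window_features(w3)

    def test_translation(self, rng):
        w = random_windows(3, seed=9)[2]  # index 2: oscillatory window
        shifted = w + np.array([0.3, -0.2, 0.5])
        f0, f1 = self._features(w), self._features(shifted)
        for axis, c in zip(("x", "y", "z"), (0.3, -0.2, 0.5)):
            assert f1[f"mean_{axis}"] == pytest.approx(f0[f"mean_{axis}"] + c, rel=1e-9)
            assert f1[f"p50_{axis}"] == pytest.approx(f0[f"p50_{axis}"] + c, rel=1e-9)
            assert f1[f"max_{axis}"] == pytest.approx(f0[f"max_{axis}"] + c, rel=1e-9)
            for stat in ("sd", "iqr", "p2p", "lag1_autocorr", "mad", "variance",
                         "zero_crossings"):
                assert f1[f"{stat}_{axis}"] == pytest.approx(
                    f0[f"{stat}_{axis}"], rel=1e-9, abs=1e-9
                )

    def test_positive_scaling(self):
        # oscillatory window with nonzero per-axis means
        w = random_windows(3, seed=10)[2] + np.array([0.5, 0.5, 1.0])
        c = 2.5
        f0, f1 = self._features(w), self._features(w * c)
        for axis in ("x", "y", "z", "vm"):
            assert f1[f"sd_{axis}"] == pytest.approx(c * f0[f"sd_{axis}"], rel=1e-9)
            assert f1[f"mad_{axis}"] == pytest.approx(c * f0[f"mad_{axis}"], rel=1e-9)
            assert f1[f"p2p_{axis}"] == pytest.approx(c * f0[f"p2p_{axis}"], rel=1e-9)
            assert f1[f"power_{axis}"] == pytest.approx(c**2 * f0[f"power_{axis}"], rel=1e-9)
            assert f1[f"cv_{axis}"] == pytest.approx(f0[f"cv_{axis}"], rel=1e-9)
            assert f1[f"dominant_frequency_{axis}"] == pytest.approx(
                f0[f"dominant_frequency_{axis}"]
            )
        for stat in ("corr_xy", "corr_xz", "corr_yz", "tilt", "roll", "pitch"):
            assert f1[stat] == pytest.approx(f0[stat], rel=1e-9, abs=1e-9)


class TestOrientation:
    def test_convention_anchors(self):
        tilt, roll, pitch = orientation_angles(0.0, 0.0, 1.0)
        assert (tilt, roll, pitch) == (0.0, 0.0, 0.0)
        tilt, roll, _ = orientation_angles(0.0, 1.0, 0.0)
        assert tilt == pytest.approx(90.0)
        assert roll == pytest.approx(90.0)

    def test_known_rotation(self):
        # rotate (0,0,1) by 30 degrees about the y axis
        ang = np.radians(30.0)
        mx, my, mz = np.sin(ang), 0.0, np.cos(ang)
        tilt, roll, pitch = orientation_angles(mx, my, mz)
        assert tilt == pytest.approx(30.0)
        assert pitch == pytest.approx(-30.0)


class TestSynchronize:
    def _tables(self, n=10, shift=0.0):
        f = pd.DataFrame({"window_start_s": np.arange(n) * 10.0, "feat": np.arange(n)})
        e = pd.DataFrame(
            {"bin_start_s": np.arange(n) * 10.0 + shift, "ee_kcal_min": np.ones(n)}
        )
        return f, e

    def test_identical_grids_full_match(self):
        f, e = self._tables()
        merged, dropped = synchronize(f, e)
        assert len(merged) == 10 and dropped == 0

    def test_missing_bins_drop_windows(self):
        f, e = self._tables()
        merged, dropped = synchronize(f, e.iloc[:-3])
        assert len(merged) == 7 and dropped == 3

    def test_shifted_grid_exact_vs_tolerant(self):
        f, e = self._tables(shift=5.0)
        merged, dropped = synchronize(f, e)
        assert len(merged) == 0 and dropped == 10
        merged, dropped = synchronize(f, e, tolerance_s=5.0)
        assert len(merged) == 10 and dropped == 0

    def test_zero_overlap_rejected(self):
        f, e = self._tables()
        e["bin_start_s"] += 1000.0
        with pytest.raises(ValueError):
            synchronize(f, e)
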