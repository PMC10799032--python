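"""Oculometrics: smoothing, I-VT classification, the 12 features,
subject-wise standardization."""
import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import make_gaze
from surgskill.gaze_features import (FIXATION, GAZE_FEATURE_NAMES, INVALID,
                                     SACCADE, angular_velocity, classify_ivt,
                                     direction_change_rate,
                                     extract_gaze_features, pupil_features,
                                     rate_features, shannon_entropy, smooth,
                                     subjectwise_standardize,
                                     trajectory_length)
from surgskill.simulate import SimulationConfig, generate_gaze


def vec_from_angles(h_deg, v_deg=None):
    h = np.radians(np.asarray(h_deg, float))
    v = np.radians(np.zeros_like(h) if v_deg is None
                   else np.asarray(v_deg, float))
    return np.column_stack([np.cos(v) * np.sin(h), np.sin(v),
                            np.cos(v) * np.cos(h)])


class TestSmooth:
    def test_constant_series_unchanged(self):
        rec = make_gaze(50)
        out = smooth(rec)
        pd.testing.assert_frame_equal(out.samples, rec.samples)

    def test_three_point_average(self):
        rec = make_gaze(3, diam_fn=lambda n: np.array([2.0, 5.0, 2.0]))
        out = smooth(rec)
        assert out.pupil_diameters("L")[1] == pytest.approx(3.0)

    def test_invalid_sample_stays_invalid_and_is_skipped(self):
        rec = make_gaze(3, diam_fn=lambda n: np.array([2.0, 9.0, 4.0]),
                        invalid=[1])
        out = smooth(rec)
        d = out.pupil_diameters("L")
        assert np.isnan(d[1])
        assert d[0] == pytest.approx(2.0)     # mean of the 2 valid points
        assert d[2] == pytest.approx(4.0)     # at the edges only itself
        assert not out.valid_mask("L")[1]

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth(make_gaze(10), window=2)


class TestAngularVelocity:
    def test_static_gaze_has_zero_velocity(self):
        rec = make_gaze(10)
        v = angular_velocity(rec, "L")
        assert np.allclose(v[1:], 0.0) and np.isnan(v[0])

    def test_one_degree_step_at_50hz_is_50_deg_s(self):
        rec = make_gaze(3, gaze_fn=lambda n: vec_from_angles([0, 1, 2]))
        v = angular_velocity(rec, "L")
        assert v[1] == pytest.approx(50.0, rel=1e-6)

    def test_small_step_lands_below_threshold(self):
        rec = make_gaze(2, gaze_fn=lambda n: vec_from_angles([0, 0.4]))
        v = angular_velocity(rec, "L")
        assert v[1] == pytest.approx(20.0, rel=1e-6)
        assert classify_ivt(v)[1] == FIXATION

    def test_undefined_across_invalid_gap(self):
        rec = make_gaze(5, invalid=[2])
        v = angular_velocity(rec, "L")
        assert np.isnan(v[2]) and np.isnan(v[3])


class TestClassifyIvt:
    def test_slow_motion_is_fixation(self):
        assert (classify_ivt(np.full(5, 10.0)) == FIXATION).all()

    def test_boundary_velocity_is_saccade(self):
        labels = classify_ivt(np.array([29.999, 30.0, 30.001]))
        assert labels.tolist() == [FIXATION, SACCADE, SACCADE]

    def test_undefined_velocity_is_invalid(self):
        assert classify_ivt(np.array([np.nan]))[0] == INVALID

    def test_agreement_with_generator_labels(self):
        cfg = SimulationConfig(seed=21, eeg_duration_s=40.0,
                               blink_rate_hz=0.0)
        rec = generate_gaze(cfg, 1, 1)
        truth = rec.ground_truth_labels
        labels = classify_ivt(angular_velocity(rec, rec.eye_for_role(
            "dominant")))
        away = np.ones(len(truth), dtype=bool)
        for c in np.flatnonzero(np.diff(truth) != 0):
            away[max(0, c - 1):c + 2] = False
        away &= (truth != INVALID) & (labels != INVALID)
        assert (labels[away] == truth[away]).mean() >= 0.97


class TestRates:
    def test_counts_over_total_samples(self):
        labels = np.array([FIXATION] * 80 + [SACCADE] * 20)
        assert rate_features(labels) == (0.8, 0.2)

    def test_rates_sum_to_one_without_invalid(self, rng):
        labels = rng.choice([FIXATION, SACCADE], size=200)
        f, s = rate_features(labels)
        assert f + s == pytest.approx(1.0)

    def test_invalid_samples_deflate_default_rates(self):
        labels = np.array([FIXATION] * 50 + [INVALID] * 50)
        assert rate_features(labels) == (0.5, 0.0)
        assert rate_features(labels, valid_only=True) == (1.0, 0.0)

    def test_all_invalid_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="no valid"):
            assert rate_features(np.full(10, INVALID),
                                 valid_only=True) == (0.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rate_features(np.array([]))

    def test_generator_saccade_fraction_recovered(self):
        cfg = SimulationConfig(seed=8, eeg_duration_s=120.0,
                               blink_rate_hz=0.0)
        rec = generate_gaze(cfg, 1, 1)
        truth_rate = (rec.ground_truth_labels == SACCADE).mean()
        labels = classify_ivt(angular_velocity(
            rec, rec.eye_for_role("dominant")))
        _, sac_rate = rate_features(labels)
        assert abs(sac_rate - truth_rate) <= 0.03


class TestPupilFeatures:
    def test_constant_series_has_zero_entropy(self):
        assert shannon_entropy(np.full(100, 3.3)) == 0.0

    def test_uniform_16_bin_occupation_is_four_bits(self):
        vals = np.repeat(np.arange(16) + 0.5, 10) / 16
        assert shannon_entropy(vals, bins=16) == pytest.approx(4.0)

    def test_entropy_matches_histogram_oracle(self, rng):
        x = rng.normal(3.5, 0.2, 500)
        counts, _ = np.histogram(x, bins=16, range=(x.min(), x.max()))
        p = counts[counts > 0] / len(x)
        oracle = float(-(p * np.log2(p)).sum())
        assert abs(shannon_entropy(x, 16) - oracle) < 1e-12

    def test_mean_uses_valid_samples_only(self):
        rec = make_gaze(4, diam_fn=lambda n: np.array([2.0, 4.0, 6.0, 99.0]),
                        invalid=[3])
        mean, ent = pupil_features(rec, "L")
        assert mean == pytest.approx(4.0)

    def test_no_valid_samples_flagged_missing(self):
        rec = make_gaze(5, invalid=range(5))
        with pytest.warns(UserWarning, match="no valid"):
            mean, ent = pupil_features(rec, "L")
        assert np.isnan(mean) and np.isnan(ent)


class TestDirectionChangeRate:
    def test_monotone_sweep_has_no_changes(self):
        rec = make_gaze(20, gaze_fn=lambda n: vec_from_angles(
            np.linspace(0, 10, n)))
        h, v = direction_change_rate(rec, "L")
        assert h == 0.0 and v == 0.0

    def test_strict_zigzag_counts_n_minus_2(self):
        n = 20
        angles = np.where(np.arange(n) % 2 == 0, 0.0, 1.0)
        rec = make_gaze(n, gaze_fn=lambda m: vec_from_angles(angles))
        h, _ = direction_change_rate(rec, "L")
        assert h == pytest.approx((n - 2) / n)

    def test_matches_recount_oracle_on_random_walk(self, rng):
        n = 300
        angles = np.cumsum(rng.normal(0, 0.3, n))
        rec = make_gaze(n, gaze_fn=lambda m: vec_from_angles(angles))
        h, _ = direction_change_rate(rec, "L")
        x = rec.gaze_vectors("L")[:, 0]
        d = np.diff(x)
        d = d[d != 0]
        oracle = int((np.sign(d[1:]) != np.sign(d[:-1])).sum()) / n
        assert h == pytest.approx(oracle)


class TestTrajectoryLength:
    def test_three_four_five(self):
        pos = np.array([[0, 0, 0], [3, 4, 0]], dtype=float)
        rec = make_gaze(2, pos_fn=lambda n: pos)
        assert trajectory_length(rec, "L") == pytest.approx(5.0)

    def test_stationary_pupil_has_zero_length(self):
        assert trajectory_length(make_gaze(10), "L") == 0.0

    def test_closed_unit_square(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                        [0, 0, 0]], dtype=float)
        rec = make_gaze(5, pos_fn=lambda n: pos)
        assert trajectory_length(rec, "L") == pytest.approx(4.0)

    def test_gap_bridged_with_warning(self):
        pos = np.array([[0, 0, 0], [9, 9, 9], [3, 4, 0]], dtype=float)
        rec = make_gaze(3, pos_fn=lambda n: pos, invalid=[1])
        with pytest.warns(UserWarning, match="bridged"):
            assert trajectory_length(rec, "L") == pytest.approx(5.0)


class TestExtractGazeFeatures:
    def test_twelve_named_features(self):
        cfg = SimulationConfig(seed=4, eeg_duration_s=10.0)
        feats = extract_gaze_features(generate_gaze(cfg, 1, 1))
        assert list(feats.index) == list(GAZE_FEATURE_NAMES)
        assert feats.notna().all()
        assert 0 <= feats["rate_of_fixation"] <= 1
        assert feats["rate_of_fixation"] + feats["rate_of_saccade"] <= 1

    def test_dominance_relabeling(self):
        rec = make_gaze(50, dominant_eye="left",
                        diam_fn=lambda n: np.full(n, 3.0))
        df = rec.samples.copy()
        df["pupil_diam_R"] = 5.0
        rec = rec.__class__(df, rec.fs_hz, "left")
        feats = extract_gaze_features(rec)
        assert feats["avg_pupil_diameter_dominant"] == pytest.approx(3.0)
        assert feats["avg_pupil_diameter_nondominant"] == pytest.approx(5.0)

    def test_appending_invalid_samples_only_moves_the_rates(self):
        # every feature whose Table-style definition divides by the total
        # number of recorded time points deflates when blank samples are
        # appended; all others are untouched
        cfg = SimulationConfig(seed=4, eeg_duration_s=10.0,
                               blink_rate_hz=0.0)
        rec = generate_gaze(cfg, 1, 1)
        base = extract_gaze_features(rec)
        df = rec.samples.copy()
        pad = df.tail(20).copy()
        pad["time_s"] = df["time_s"].iloc[-1] + np.arange(1, 21) / rec.fs_hz
        for e in ("L", "R"):
            sig_cols = [c for c in pad.columns
                        if f"_{e}_" in c or c == f"pupil_diam_{e}"]
            pad[sig_cols] = np.nan
            pad[f"valid_{e}"] = 0
        padded = rec.__class__(pd.concat([df, pad], ignore_index=True),
                               rec.fs_hz, rec.dominant_eye)
        feats = extract_gaze_features(padded)
        moved = {n for n in GAZE_FEATURE_NAMES
                 if "rate" in n}            # fixation/saccade + 4 direction
        for name in GAZE_FEATURE_NAMES:
            if name in moved:
                assert feats[name] < base[name]
            else:
                assert feats[name] == pytest.approx(base[name], rel=1e-9)


class TestSubjectwiseStandardize:
    def make_table(self):
        return pd.DataFrame({
            "subject": [1, 1, 1, 2, 2, 2],
            "task": ["Tubes"] * 6,
            "f": [2.0, 4.0, 6.0, 10.0, 20.0, 30.0],
        })

    def test_population_sd_example(self):
        out, ledger = subjectwise_standardize(self.make_table(), ["f"])
        expect = np.array([-1, 0, 1]) * np.sqrt(1.5)
        assert np.allclose(out.loc[:2, "f"], expect)
        assert set(ledger.columns) >= {"subject", "task", "column", "mean",
                                       "sd", "n"}

    def test_group_mean_zero_sd_one(self, rng):
        t = self.make_table()
        t["f"] = rng.normal(5, 3, len(t))
        out, _ = subjectwise_standardize(t, ["f"])
        for _, sub in out.groupby("subject"):
            assert abs(sub["f"].mean()) < 1e-9
            assert abs(sub["f"].std(ddof=0) - 1) < 1e-9

    def test_idempotent(self):
        out1, _ = subjectwise_standardize(self.make_table(), ["f"])
        out2, _ = subjectwise_standardize(out1, ["f"])
        assert np.allclose(out1["f"], out2["f"], atol=1e-12)

    def test_constant_column_flagged_missing(self):
        t = self.make_table()
        t["f"] = 7.0
        with pytest.warns(UserWarning, match="no variance"):
            out, _ = subjectwise_standardize(t, ["f"])
        assert out["f"].isna().all()

    def test_singleton_group_flagged_missing(self):
        t = pd.DataFrame({"subject": [1, 2, 2], "task": ["Tubes"] * 3,
                          "f": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning):
            out, _ = subjectwise_standardize(t, ["f"])
        assert np.isnan(out.loc[0, "f"])
        assert out.loc[1:, "f"].notna().all()
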