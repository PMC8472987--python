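import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecgluco import features
from ecgluco.delineation import FiducialSet
from ecgluco.features import (
    FEATURE_NAMES,
    apply_standardizer,
    correct_qt,
    distance,
    extract_features,
    fit_outlier_bounds,
    fit_standardizer,
    invert_standardizer,
    label_glucose,
    remove_outliers,
    slope,
)

finite = st.floats(min_value=-5, max_value=5, allow_nan=False, width=32)
point = st.tuples(finite, finite)


def make_fiducials(points: dict) -> FiducialSet:
    return FiducialSet(points=dict(points))


def make_matrix(columns: dict) -> pd.DataFrame:
    n = len(next(iter(columns.values())))
    df = pd.DataFrame(
        {"beat_id": range(n), "subject_id": 0, "label": 0}
    )
    for name in FEATURE_NAMES:
        df[name] = columns.get(name, np.linspace(1.0, 2.0, n))
    return df


class TestDistanceSlope:
    def test_three_four_five(self):
        assert distance((0, 0), (0.3, 0.4)) == pytest.approx(0.5)

    def test_identity(self):
        assert distance((0.2, -0.1), (0.2, -0.1)) == 0.0

    def test_hand_value(self):
        assert distance((0.10, 0.15), (0.24, -0.12)) == pytest.approx(
            math.sqrt(0.14**2 + 0.27**2)
        )
        assert distance((0.10, 0.15), (0.24, -0.12)) == pytest.approx(0.30414, abs=1e-5)

    def test_slope_values(self):
        assert slope((0, 0), (0.3, 0.4)) == pytest.approx(4 / 3)
        assert slope((0.1, 0.5), (0.4, 0.5)) == 0.0
        assert slope((0.10, 0.15), (0.24, -0.12)) == pytest.approx(-1.92857, abs=1e-5)

    def test_degenerate_slope(self):
        with pytest.raises(features.DegenerateBeatError):
            slope((0.1, 0.0), (0.1, 1.0))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(a=point, b=point, c=point)
    def test_metric_properties(self, a, b, c):
        assert distance(a, b) == pytest.approx(distance(b, a))
        assert distance(a, b) >= 0
        assert distance(a, c) <= distance(a, b) + distance(b, c) + 1e-9

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=point, b=point, dx=finite, dy=finite)
    def test_translation_invariance(self, a, b, dx, dy):
        a2 = (a[0] + dx, a[1] + dy)
        b2 = (b[0] + dx, b[1] + dy)
        assert distance(a, b) == pytest.approx(distance(a2, b2), abs=1e-5)
        if abs(b[0] - a[0]) > 1e-3:
            assert slope(a, b) == pytest.approx(slope(a2, b2), abs=1e-3, rel=1e-3)


class TestQtCorrection:
    def test_fixed_point_at_hr_60(self):
        assert correct_qt(0.40, 60.0) == pytest.approx(0.40)

    @pytest.mark.parametrize("hr,expected", [(120.0, 0.477), (40.0, 0.323)])
    def test_hand_values(self, hr, expected):
        assert correct_qt(0.40, hr) == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_heart_rate(self):
        hrs = np.linspace(40, 180, 50)
        vals = [correct_qt(0.40, h) for h in hrs]
        assert np.all(np.diff(vals) > 0)

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            correct_qt(0.4, 0.0)


class TestLabeling:
    @pytest.mark.parametrize("glucose,expected", [(100.0, 0), (100.1, 1), (85.0, 0), (180.0, 1)])
    def test_threshold_rule(self, glucose, expected):
        assert label_glucose(glucose) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            label_glucose(-1.0)


class TestExtractFeatures:
    PTS = {
        "P": (-0.17, 0.15),
        "Q": (-0.03, -0.12),
        "R": (0.0, 1.0),
        "S": (0.03, -0.20),
        "T": (0.25, 0.30),
    }

    def test_exactly_18_features(self):
        out = extract_features(make_fiducials(self.PTS), heart_rate=60.0)
        assert out is not None
        assert set(out) == set(FEATURE_NAMES)
        assert len(out) == 18

    def test_collinear_points_share_slope(self):
        m = 2.5
        pts = {w: (x, m * x) for w, x in
               [("P", -0.2), ("Q", -0.05), ("R", 0.0), ("S", 0.05), ("T", 0.3)]}
        out = extract_features(make_fiducials(pts), heart_rate=60.0)
        for pair in features.FEATURE_PAIRS:
            if pair != "QT":  # QT's time axis is replaced by QTc
                assert out[f"{pair.lower()}_slope"] == pytest.approx(m)

    def test_values_match_hand_computation_at_hr_60(self):
        # at HR 60 the Framingham correction vanishes, so every feature
        # is the plain Eq-style distance/slope of the raw coordinates
        out = extract_features(make_fiducials(self.PTS), heart_rate=60.0)
        for pair in features.FEATURE_PAIRS:
            a, b = self.PTS[pair[0]], self.PTS[pair[1]]
            assert out[f"{pair.lower()}_len"] == pytest.approx(distance(a, b), rel=1e-9)
            assert out[f"{pair.lower()}_slope"] == pytest.approx(slope(a, b), rel=1e-9)

    def test_qtc_replaces_qt_time_axis(self):
        hr = 120.0
        out = extract_features(make_fiducials(self.PTS), heart_rate=hr)
        q, t = self.PTS["Q"], self.PTS["T"]
        dt_c = correct_qt(t[0] - q[0], hr)
        assert out["qt_len"] == pytest.approx(math.hypot(dt_c, t[1] - q[1]))
        assert out["qt_slope"] == pytest.approx((t[1] - q[1]) / dt_c)
        # other features untouched by the correction
        assert out["pr_len"] == pytest.approx(distance(self.PTS["P"], self.PTS["R"]))

    def test_missing_wave_drops_beat(self):
        pts = dict(self.PTS)
        pts["P"] = None
        assert extract_features(make_fiducials(pts), heart_rate=60.0) is None

    def test_qtc_reduces_heart_rate_dependence(self):
        # corrected QT on beats whose template QT is constant but HR varies
        # has a strictly smaller coefficient of variation than raw QT
        from ecgluco.delineation import delineate_recording
        from conftest import clean_config
        from ecgluco.synthetic import generate_recording
        from ecgluco.preprocess import preprocess

        raw, cor = [], []
        for hr in (50, 70, 90, 110):
            rec = generate_recording(clean_config(duration=30, mean_hr=hr, seed=hr))
            clean = preprocess(rec, trim_seconds=5.0)
            _, fids = delineate_recording(clean)
            valid = [f for f in fids if f.valid]
            r_times = np.array([f.r_time_global for f in valid])
            rr = np.diff(r_times)
            for i, f in enumerate(valid):
                rr_i = rr[0] if i == 0 else rr[i - 1]
                qt = f["T"][0] - f["Q"][0]
                raw.append(qt)
                cor.append(correct_qt(qt, 60.0 / rr_i))
        cv = lambda x: np.std(x) / np.mean(x)
        assert cv(cor) < cv(raw)


class TestOutlierRemoval:
    def test_hand_quantiles(self):
        col = list(range(1, 10)) + [100]
        mat = make_matrix({"pq_len": col})
        bounds = fit_outlier_bounds(mat)
        assert bounds.q1["pq_len"] == pytest.approx(3.25)
        assert bounds.q3["pq_len"] == pytest.approx(7.75)
        assert bounds.upper["pq_len"] == pytest.approx(14.5)
        kept, mask = remove_outliers(mat, bounds)
        assert mask.sum() == 1 and len(kept) == 9

    def test_constant_column_flags_nothing(self):
        mat = make_matrix({"pq_len": [5.0] * 8})
        bounds = fit_outlier_bounds(mat)
        assert bounds.iqr["pq_len"] == 0.0
        _, mask = remove_outliers(mat, bounds)
        assert mask.sum() == 0

    def test_symmetric_column_symmetric_bounds(self):
        mat = make_matrix({"pq_len": [-3, -1, 0, 1, 3]})
        bounds = fit_outlier_bounds(mat)
        assert bounds.lower["pq_len"] == pytest.approx(-bounds.upper["pq_len"])

    def test_any_feature_rule(self):
        base = np.ones(12)
        cols = {}
        # rows 0,1,2 each exceed a distinct feature's upper bound
        for j, name in enumerate(["pq_len", "pr_len", "ps_len"]):
            col = base.copy() + np.linspace(0, 0.5, 12)
            col[j] = 100.0
            cols[name] = col
        mat = make_matrix(cols)
        bounds = fit_outlier_bounds(mat)
        kept, mask = remove_outliers(mat, bounds)
        assert mask.sum() == 3 and len(kept) == 9

    def test_idempotent_with_fixed_bounds(self, effect_matrix):
        bounds = fit_outlier_bounds(effect_matrix)
        once, _ = remove_outliers(effect_matrix, bounds)
        twice, mask = remove_outliers(once, bounds)
        assert mask.sum() == 0
        pd.testing.assert_frame_equal(once, twice)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            fit_outlier_bounds(make_matrix({"pq_len": [1, 2, 3]}))


class TestStandardizer:
    def test_hand_values(self):
        mat = make_matrix({"pq_len": [2.0, 4.0, 6.0]})
        params = fit_standardizer(mat)
        assert params.mean["pq_len"] == pytest.approx(4.0)
        assert params.sd["pq_len"] == pytest.approx(1.63299, abs=1e-5)
        z = apply_standardizer(params, mat)["pq_len"].to_numpy()
        assert z == pytest.approx([-1.22474, 0.0, 1.22474], abs=1e-5)

    def test_idempotent_on_fitted_data(self, effect_matrix):
        params = fit_standardizer(effect_matrix)
        z = apply_standardizer(params, effect_matrix)
        p2 = fit_standardizer(z)
        z2 = apply_standardizer(p2, z)
        for name in FEATURE_NAMES:
            assert np.allclose(z[name], z2[name], atol=1e-9)

    def test_roundtrip_inverse(self, effect_matrix):
        params = fit_standardizer(effect_matrix)
        z = apply_standardizer(params, effect_matrix)
        back = invert_standardizer(params, z)
        for name in FEATURE_NAMES:
            assert np.allclose(back[name], effect_matrix[name], atol=1e-9)

    def test_constant_column_rejected_by_name(self):
        mat = make_matrix({"rt_slope": [3.0] * 6})
        with pytest.raises(ValueError, match="rt_slope"):
            fit_standardizer(mat)


class TestBuildMatrix:
    def test_matrix_schema_and_labels(self, effect_matrix):
        assert list(effect_matrix.columns[:3]) == ["beat_id", "subject_id", "label"]
        assert list(effect_matrix.columns[3:]) == list(FEATURE_NAMES)
        assert set(effect_matrix["label"]) == {0, 1}
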