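"""Trend-change extraction and the f1-f5 variability features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vitalvar as vv
from vitalvar.features import intensity_diffs

from conftest import naive_extrema, random_windows

# values quantised to 1e-3 so that adding a constant cannot merge distinct
# samples through floating-point absorption (which would change the plateau
# structure rather than falsify the mathematical property)
finite_windows = st.lists(
    st.floats(min_value=-1000, max_value=1000, allow_nan=False).map(lambda v: round(v, 3)),
    min_size=2,
    max_size=60,
).map(np.asarray)


@pytest.mark.parametrize(
    "series, interior, augmented",
    [
        ([1, 2, 3, 4], [], [1, 4]),  # monotone: no interior extrema
        ([2, 5, 3, 6, 1], [5, 3, 6], [2, 5, 3, 6, 1]),
        ([7, 7, 7, 7], [], [7, 7]),  # constant series
        ([1, 3, 3, 2], [3], [1, 3, 2]),  # plateau summit counts once
        ([1, 2, 2, 3], [], [1, 3]),  # plateau on a rise is not an extremum
        ([5, 1, 1, 4, 4, 0], [1, 4], [5, 1, 4, 0]),
    ],
)
def test_extract_extrema_examples(series, interior, augmented):
    e = vv.extract_extrema(series)
    assert e.interior.tolist() == interior
    assert e.augmented.tolist() == augmented


def test_intensity_diffs_over_augmented_sequence():
    e = vv.extract_extrema([2, 5, 3, 6, 1])
    assert intensity_diffs(e).tolist() == [3, 2, 3, 5]
    assert intensity_diffs(vv.extract_extrema([4, 4, 4])).tolist() == [0]


def test_variability_features_worked_example():
    f = vv.compute_features([2, 5, 3, 6, 1])
    assert f.f1 == 3
    assert f.f2 == pytest.approx(3.25)
    assert f.f3 == pytest.approx(3.0)  # even count: midpoint average
    assert f.f4 == pytest.approx(2.0)
    assert f.f5 == pytest.approx(5.0)


def test_triangular_excursion_matches_single_trend_change_pattern():
    """A symmetric 60->95->60 excursion gives f1=1 and four equal swings of 35."""
    tri = np.concatenate([np.linspace(60, 95, 8), np.linspace(95, 60, 8)[1:]])
    f = vv.compute_features(tri)
    assert f.f1 == 1
    assert (f.f2, f.f3, f.f4, f.f5) == pytest.approx((35, 35, 35, 35))


def test_constant_window_scores_zero_instability():
    f = vv.compute_features(np.full(48, 37.0))
    assert (f.f1, f.f2, f.f3, f.f4, f.f5) == (0, 0, 0, 0, 0)


def test_baseline_descriptive_features():
    b = vv.compute_baseline([2, 5, 3, 6, 1])
    assert (b.min, b.max, b.mean, b.median) == (1, 6, pytest.approx(3.4), 3)
    assert b.sd == pytest.approx(np.std([2, 5, 3, 6, 1], ddof=1))
    flat = vv.compute_baseline([7.0] * 10)
    assert flat.sd == 0 and flat.min == flat.max == 7


def test_extrema_rejects_too_short_input():
    with pytest.raises(ValueError):
        vv.extract_extrema([1.0])


def test_extrema_oracle_equivalence():
    rng = np.random.default_rng(2024)
    for w in random_windows(rng, 400):
        got = vv.extract_extrema(w).interior.tolist()
        assert got == naive_extrema(w), f"disagreement on {w!r}"


@given(finite_windows, st.integers(min_value=-4000, max_value=4000).map(lambda k: k / 4))
def test_translation_invariance(x, c):
    base, shifted = vv.compute_features(x), vv.compute_features(x + c)
    assert base.f1 == shifted.f1
    for name in ("f2", "f3", "f4", "f5"):
        assert getattr(shifted, name) == pytest.approx(getattr(base, name), rel=1e-6, abs=1e-6)


@given(finite_windows, st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
def test_scale_covariance(x, a):
    base, scaled = vv.compute_features(x), vv.compute_features(a * x)
    assert base.f1 == scaled.f1
    for name in ("f2", "f3", "f4", "f5"):
        assert getattr(scaled, name) == pytest.approx(a * getattr(base, name), rel=1e-6, abs=1e-9)


@given(finite_windows)
def test_intensity_ordering(x):
    f = vv.compute_features(x)
    assert f.f4 <= f.f2 <= f.f5 and f.f4 <= f.f3 <= f.f5


@given(finite_windows)
def test_signed_swings_telescope(x):
    aug = vv.extract_extrema(x).augmented
    assert np.diff(aug).sum() == pytest.approx(x[-1] - x[0], rel=1e-9, abs=1e-9)


@given(finite_windows)
def test_reflection_symmetry(x):
    fwd, rev = vv.extract_extrema(x), vv.extract_extrema(x[::-1])
    assert fwd.interior.size == rev.interior.size
    assert sorted(intensity_diffs(fwd)) == pytest.approx(sorted(intensity_diffs(rev)))


# ---------------------------------------------------------------------------
# Window slicing


def _series(t0_min=720.0, step=10.0):
    times = np.arange(0.0, t0_min, step)
    values = 70 + np.sin(times / 60.0)
    return times, values


def test_slice_window_reference_layout():
    times, values = _series()
    w = vv.slice_window(times, values, 720.0, 8, 4, sign="MAP")
    assert w.n_samples == 48
    assert w.start_min == 0.0
    # half-open: the sample at the prediction moment (480 min) is excluded
    assert np.allclose(w.values, values[:48])


def test_slice_window_one_hour():
    times, values = _series()
    w = vv.slice_window(times, values, 720.0, 1, 4, sign="RR")
    assert w.n_samples == 6


def test_slice_window_rejects_gaps():
    times, values = _series()
    keep = times != 200.0
    with pytest.raises(vv.WindowCoverageError, match="t=200"):
        vv.slice_window(times[keep], values[keep], 720.0, 8, 4, sign="HR", patient_id="P1")


# ---------------------------------------------------------------------------
# Patient records


def _windows(values_by_sign):
    return {
        sign: vv.VitalSignWindow(patient_id="P1", sign=sign, values=np.asarray(vals, float))
        for sign, vals in values_by_sign.items()
    }


def test_featurize_patient_twenty_named_features():
    windows = _windows({s: [1, 2, 1, 3, 1, 2] for s in vv.SIGNS})
    rec = vv.featurize_patient(windows, "variability", label=1)
    assert len(rec.features) == 20
    assert set(rec.features) == set(vv.feature_names("variability"))
    base = vv.featurize_patient(windows, "baseline")
    assert len(base.features) == 20
    assert "MAP_sd" in base.features


def test_featurize_patient_constant_windows_zero_intensity():
    windows = _windows({s: [5.0] * 6 for s in vv.SIGNS})
    rec = vv.featurize_patient(windows, "variability")
    assert all(v == 0 for v in rec.features.values())


def test_featurize_patient_missing_sign_rejected():
    windows = _windows({s: [1, 2, 3] for s in ("MAP", "HR", "RR")})
    with pytest.raises(ValueError, match="TEMP"):
        vv.featurize_patient(windows)


def test_featurize_cohort_shape_and_labels(feature_table):
    assert feature_table.shape == (120, 21)
    assert feature_table["label"].sum() == 60
    assert list(feature_table.columns[1:]) == vv.feature_names("variability")
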