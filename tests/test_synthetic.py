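"""Synthetic cohort generator: structure, determinism, calibration."""

from dataclasses import replace

import numpy as np
import pytest

import vitalvar as vv
from vitalvar.synthetic import REFERENCE_GROUP_STATS, _simulated_moments, initial_params


def _flat_params(group="control"):
    params = initial_params(group)
    for sign in vv.SIGNS:
        params.signs[sign] = replace(
            params.signs[sign],
            extrema_count_mean=0.0,
            noise_sd=0.0,
            baseline_jitter_sd=0.0,
            extrema_dispersion=None,
            swing_frailty_sigma=0.0,
        )
    return replace(params, ramp_gain=0.0)


def test_zero_rate_zero_noise_gives_constant_window_at_baseline():
    params = _flat_params()
    w = vv.simulate_window(params, "MAP", 48, rng_seed=7)
    assert w.n_samples == 48
    assert np.all(w.values == params.signs["MAP"].baseline_level)


def test_window_length_matches_eight_hour_interval():
    w = vv.simulate_window(vv.default_params("septic"), "HR", 48, rng_seed=0)
    assert w.n_samples == 48  # 6 samples/hour for 8 hours
    assert w.T_hours == 8.0


def test_invalid_sign_and_sample_count_rejected():
    params = vv.default_params("control")
    with pytest.raises(ValueError, match="vital sign"):
        vv.simulate_window(params, "SpO2", 48, rng_seed=0)
    with pytest.raises(ValueError, match="n_samples"):
        vv.simulate_window(params, "MAP", 1, rng_seed=0)


def test_window_determinism_same_seed():
    params = vv.default_params("septic")
    a = vv.simulate_window(params, "RR", 48, rng_seed=123)
    b = vv.simulate_window(params, "RR", 48, rng_seed=123)
    assert np.array_equal(a.values, b.values)


def test_values_respect_physiologic_bounds():
    params = vv.default_params("control")
    tight = replace(params.signs["MAP"], physiologic_bounds=(70.0, 80.0), baseline_level=75.0)
    params.signs["MAP"] = tight
    for seed in range(20):
        w = vv.simulate_window(params, "MAP", 48, rng_seed=seed)
        assert w.values.min() >= 70.0 and w.values.max() <= 80.0


def test_mean_trend_changes_increase_with_extrema_rate():
    """Monte-Carlo: a 20/window rate yields strictly more extracted extrema than 5."""
    base = initial_params("control")
    means = {}
    for rate in (5.0, 20.0):
        params = replace(base, signs={s: replace(base.signs[s], extrema_count_mean=rate) for s in vv.SIGNS})
        seeds = np.random.SeedSequence(99).spawn(1000)
        f1 = [
            vv.compute_features(vv.simulate_window(params, "MAP", 48, np.random.default_rng(s))).f1
            for s in seeds
        ]
        means[rate] = np.mean(f1)
    assert means[20.0] > means[5.0]


def test_simulate_patient_structure_and_determinism():
    spec = vv.CohortSpec(1, 1, seed=0)
    params = vv.default_params("septic")
    rec = vv.simulate_patient(spec, "septic", params, rng_seed=5)
    assert rec.label == 1
    assert set(rec.windows) == set(vv.SIGNS)
    lengths = {w.n_samples for w in rec.windows.values()}
    assert lengths == {72}  # (8 + 4) hours at 6 samples/hour
    again = vv.simulate_patient(spec, "septic", params, rng_seed=5)
    for sign in vv.SIGNS:
        assert np.array_equal(rec.windows[sign].values, again.windows[sign].values)


def test_control_patient_flat_params_gives_flat_windows_label_zero():
    spec = vv.CohortSpec(1, 1, seed=0)
    rec = vv.simulate_patient(spec, "control", _flat_params(), rng_seed=1)
    assert rec.label == 0
    for w in rec.windows.values():
        assert np.ptp(w.values) == 0.0


def test_cohort_counts_and_labels(small_cohort):
    labels = small_cohort.labels
    assert len(labels) == 120 and labels.sum() == 60
    per_patient = small_cohort.series.groupby("patient_id").size()
    assert (per_patient == 4 * 72).all()


def test_all_control_cohort_has_no_positive_labels(control_params):
    cohort = vv.simulate_cohort(vv.CohortSpec(0, 5, seed=2), vv.default_params("septic"), control_params)
    assert cohort.labels.sum() == 0


def test_cohort_csv_byte_identical_under_fixed_seed(tmp_path, septic_params, control_params):
    spec = vv.CohortSpec(4, 4, seed=31)
    paths = []
    for name in ("a.csv", "b.csv"):
        cohort = vv.simulate_cohort(spec, septic_params, control_params)
        p = tmp_path / name
        cohort.to_csv(p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_cohort_spec_validation():
    with pytest.raises(ValueError):
        vv.CohortSpec(10, 10, T_hours=14, horizon_hours=4)  # stay too long
    with pytest.raises(ValueError):
        vv.CohortSpec(-1, 10)
    spec = vv.CohortSpec(10, 10, T_hours=8, horizon_hours=5)  # 13 h stay is allowed
    assert spec.n_samples == 48


# ---------------------------------------------------------------------------
# Calibration


def test_calibration_fixed_point():
    """Targets equal to the initial parameters' own moments leave them unchanged."""
    params = vv.default_params("septic")
    seeds = np.random.SeedSequence([1, 0]).spawn(400)
    emp = _simulated_moments(params, "MAP", 48, seeds)
    targets = {"MAP": {k: (emp[k], REFERENCE_GROUP_STATS["septic"]["MAP"][k][1]) for k in ("f1", "f3", "f4")}}
    result = vv.calibrate(params, targets, n_sim=400, seed=1, signs=("MAP",))
    assert result.diagnostics["MAP"].n_iter == 1
    sp0, sp1 = params.signs["MAP"], result.params.signs["MAP"]
    assert sp1.extrema_count_mean == pytest.approx(sp0.extrema_count_mean)
    assert sp1.swing_magnitude_mean == pytest.approx(sp0.swing_magnitude_mean)


def test_calibration_monotone_in_count_target():
    """Doubling the trend-change target drives the turning rate strictly up."""
    start = initial_params("control")
    base_t = REFERENCE_GROUP_STATS["control"]["RR"]
    lo = {"RR": {"f1": (8.0, base_t["f1"][1]), "f3": base_t["f3"]}}
    hi = {"RR": {"f1": (16.0, base_t["f1"][1]), "f3": base_t["f3"]}}
    rate = {}
    for name, targets in (("lo", lo), ("hi", hi)):
        res = vv.calibrate(start, targets, n_sim=200, seed=3, max_iter=15, signs=("RR",))
        rate[name] = res.params.signs["RR"].extrema_count_mean
    assert rate["hi"] > rate["lo"]


def test_calibration_requires_f1_and_an_intensity_target():
    params = vv.default_params("septic")
    with pytest.raises(ValueError, match="f1"):
        vv.calibrate(params, {"MAP": {"f3": (10.0, 9.0)}}, n_sim=50, signs=("MAP",))
    with pytest.raises(ValueError, match="intensity"):
        vv.calibrate(params, {"MAP": {"f1": (20.0, 8.0)}}, n_sim=50, signs=("MAP",))


def test_calibration_closure_on_selected_features(septic_params, control_params):
    """The shipped calibrated parameters reproduce the published group means.

    Re-simulates 300 patients per group with an independent seed and checks
    the four model-input features (MAP and RR trend-change counts, RR minimal
    swing, HR median swing) per group against the published means with a
    two-sample z at 2 sigma (both means carry n=300 sampling error).
    """
    spec = vv.CohortSpec(300, 300, seed=777)
    cohort = vv.simulate_cohort(spec, septic_params, control_params)
    feats = vv.featurize_cohort(cohort.series, 8, 4)
    checks = [
        (1, "MAP_f1"), (0, "MAP_f1"),
        (1, "RR_f1"), (0, "RR_f1"),
        (1, "RR_f4"), (0, "RR_f4"),
        (1, "HR_f3"), (0, "HR_f3"),
    ]
    for label, col in checks:
        group = "septic" if label else "control"
        sign, feat = col.split("_")
        target_mean, target_sd = REFERENCE_GROUP_STATS[group][sign][feat]
        sample = feats.loc[feats.label == label, col]
        se = np.sqrt(target_sd**2 / 300 + sample.var(ddof=1) / len(sample))
        z = (sample.mean() - target_mean) / se
        assert abs(z) < 2.0, f"{group} {col}: mean {sample.mean():.2f} vs {target_mean} (z={z:.2f})"
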