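"""Calibration metrics and the different-targets-and-different-flight CV."""

import itertools

import numpy as np
import pandas as pd
import pytest

from uavheight.calibrate import (
    CVSet,
    LinearCalibration,
    bias,
    condition_table,
    enumerate_cv_sets,
    evaluate,
    fit_linear,
    pearson_r,
    run_condition,
)
from uavheight.errors import (
    DegenerateRegressionError,
    IncompleteDesignError,
    UndefinedCorrelationError,
)


def samples_df(ph_measured, ph_sfm, repetition=1, group=1):
    n = len(ph_measured)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "ph_measured": ph_measured,
            "ph_sfm": ph_sfm,
            "repetition": repetition,
            "group": group,
        }
    )


def design_df(rng, n_reps=3, n_groups=3, per_cell=4, sfm_of=None):
    """A full (repetition x group) design with optional PH_SfM transform."""
    rows = []
    sid = 0
    truth = {}
    for g in range(1, n_groups + 1):
        for k in range(per_cell):
            truth[(g, k)] = rng.uniform(0.6, 1.2)
    for rep in range(1, n_reps + 1):
        for g in range(1, n_groups + 1):
            for k in range(per_cell):
                y = truth[(g, k)]
                x = y if sfm_of is None else sfm_of(y, rep)
                rows.append(
                    {"sample_id": f"g{g}k{k}", "ph_measured": y, "ph_sfm": x,
                     "repetition": rep, "group": g}
                )
                sid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# elementary statistics


def test_pearson_perfect_lines():
    x = np.linspace(0, 1, 10)
    assert pearson_r(x, x) == pytest.approx(1.0)
    assert pearson_r(x, -x) == pytest.approx(-1.0)


def test_pearson_matches_covariance_oracle():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=20), rng.normal(size=20)
    expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)


def test_pearson_zero_variance_raises():
    with pytest.raises(UndefinedCorrelationError):
        pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_bias_examples():
    df = samples_df([1.0, 2.0], [1.0, 2.0])
    assert bias(df) == 0.0
    df = samples_df([1.0, 2.0], [0.92, 1.92])
    assert bias(df) == pytest.approx(-0.08)


def test_fit_linear_examples_and_oracle():
    assert fit_linear(samples_df([0.0, 1.0], [0.0, 1.0])) == LinearCalibration(1.0, 0.0)
    cal = fit_linear(samples_df([0.6, 1.1, 0.9], [0.5, 1.0, 0.8]))
    assert (cal.a, cal.b) == (pytest.approx(1.0), pytest.approx(0.1))
    rng = np.random.default_rng(2)
    x = rng.uniform(0.5, 1.5, 50)
    y = 0.9 * x + 0.1 + rng.normal(0, 0.05, 50)
    cal = fit_linear(samples_df(y, x))
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    assert cal.a == pytest.approx(slope, abs=1e-10)
    assert cal.b == pytest.approx(intercept, abs=1e-10)


def test_fit_linear_constant_predictor_raises():
    with pytest.raises(DegenerateRegressionError):
        fit_linear(samples_df([1.0, 2.0, 3.0], [0.7, 0.7, 0.7]))


def test_ols_beats_any_other_line_on_training_data():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 1, 30)
    y = 1.2 * x + rng.normal(0, 0.1, 30)
    cal = fit_linear(samples_df(y, x))
    best_sse = np.sum((y - cal.predict(x)) ** 2)
    for a in np.linspace(0.5, 2.0, 16):
        for b in np.linspace(-0.5, 0.5, 16):
            assert best_sse <= np.sum((y - (a * x + b)) ** 2) + 1e-12


def test_evaluate_perfect_and_mean_prediction():
    df = samples_df([1.0, 1.2, 0.8], [1.0, 1.2, 0.8])
    m = evaluate(LinearCalibration(1.0, 0.0), df)
    assert (m.r2_val, m.mae, m.rmse, m.mape) == (1.0, 0.0, 0.0, 0.0)
    # predicting the validation mean scores R2 = 0 by definition
    mean_model = LinearCalibration(0.0, float(df["ph_measured"].mean()))
    assert evaluate(mean_model, df).r2_val == pytest.approx(0.0, abs=1e-12)


def test_evaluate_constant_error_oracle():
    y = np.array([0.9, 1.0, 1.1, 1.2])
    df = samples_df(y, y - 0.1)
    m = evaluate(LinearCalibration(1.0, 0.0), df)  # predicts y - 0.1
    assert m.mae == pytest.approx(0.1) and m.rmse == pytest.approx(0.1)
    assert m.mape == pytest.approx(np.mean(0.1 / y) * 100.0)
    assert m.r2_val == pytest.approx(1 - 4 * 0.01 / np.sum((y - y.mean()) ** 2))


def test_mae_never_exceeds_rmse():
    rng = np.random.default_rng(4)
    for _ in range(20):
        y = rng.uniform(0.5, 3.0, 25)
        x = y + rng.normal(0, 0.2, 25)
        m = evaluate(LinearCalibration(1.0, 0.0), samples_df(y, x))
        assert m.mae <= m.rmse + 1e-12


# ---------------------------------------------------------------------------
# CV-set enumeration


@pytest.mark.parametrize(
    "n_reps, n_groups, expected", [(3, 3, 18), (1, 3, 0), (2, 2, 4)]
)
def test_cv_set_counts(n_reps, n_groups, expected):
    assert len(enumerate_cv_sets(n_reps, n_groups)) == expected


@pytest.mark.parametrize("n_reps", [1, 2, 3, 4, 5])
@pytest.mark.parametrize("n_groups", [1, 2, 3])
def test_cv_set_count_matches_brute_force(n_reps, n_groups):
    brute = [
        (tr, vr, g)
        for tr in range(1, n_reps + 1)
        for vr in range(1, n_reps + 1)
        for g in range(1, n_groups + 1)
        if tr != vr
    ]
    sets = enumerate_cv_sets(n_reps, n_groups)
    assert len(sets) == len(brute) == n_reps * (n_reps - 1) * n_groups
    assert {(s.train_repetition, s.validation_repetition, s.validation_group)
            for s in sets} == set(brute)


def test_cv_sets_never_share_flight():
    with pytest.raises(ValueError):
        CVSet(2, 2, 1)
    for s in enumerate_cv_sets(4, 3):
        assert s.train_repetition != s.validation_repetition


def test_no_target_leakage_between_partitions():
    """No sample id may appear in both partitions of any CV set, and the
    flights always differ — the scheme's defining property."""
    rng = np.random.default_rng(5)
    df = design_df(rng, n_reps=3, n_groups=3, per_cell=4)
    for cv in enumerate_cv_sets(3, 3):
        train = df[(df.repetition == cv.train_repetition) & (df.group != cv.validation_group)]
        val = df[(df.repetition == cv.validation_repetition) & (df.group == cv.validation_group)]
        assert not set(train.sample_id) & set(val.sample_id)
        assert set(train.repetition) != set(val.repetition)


# ---------------------------------------------------------------------------
# condition-level reports


def test_run_condition_perfect_predictions():
    rng = np.random.default_rng(6)
    df = design_df(rng, sfm_of=None)  # PH_SfM == PH_measured
    report = run_condition(df, enumerate_cv_sets(3, 3))
    assert report.n_sets == 18
    assert report.r2_val == pytest.approx(1.0)
    assert report.mae == pytest.approx(0.0, abs=1e-12)
    assert report.bias == pytest.approx(0.0, abs=1e-12)


def test_run_condition_partition_sizes(field2_layout):
    """The full design trains on 112 and validates on 56 samples per set."""
    rows = field2_layout.measured_rows()
    rng = np.random.default_rng(7)
    frames = []
    for rep in (1, 2, 3):
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": [r.row_id for r in rows],
                    "ph_measured": rng.uniform(0.6, 1.2, len(rows)),
                    "ph_sfm": rng.uniform(0.6, 1.2, len(rows)),
                    "repetition": rep,
                    "group": [r.group for r in rows],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    for cv in enumerate_cv_sets(3, 3):
        train = df[(df.repetition == cv.train_repetition) & (df.group != cv.validation_group)]
        val = df[(df.repetition == cv.validation_repetition) & (df.group == cv.validation_group)]
        assert (len(train), len(val)) == (112, 56)


def test_run_condition_flags_missing_partition():
    rng = np.random.default_rng(8)
    df = design_df(rng)
    df = df[~((df.repetition == 2) & (df.group == 3))]
    with pytest.raises(IncompleteDesignError):
        run_condition(df, enumerate_cv_sets(3, 3))


def test_per_flight_datum_offsets_break_validation_only():
    """Flight-specific datum offsets (the M1-without-GCP mechanism) leave
    within-flight fits excellent but push validation R2 strongly negative."""
    rng = np.random.default_rng(9)
    offsets = {1: 0.0, 2: 0.9, 3: -0.7}
    df = design_df(rng, per_cell=8, sfm_of=lambda y, rep: y - 0.08 + offsets[rep])
    report = run_condition(df, enumerate_cv_sets(3, 3))
    assert report.r2_train > 0.99
    assert report.r2_val < -10.0
    assert report.mae > 0.3


def test_single_repetition_reports_r_and_bias_only():
    rng = np.random.default_rng(10)
    df = design_df(rng, n_reps=1, sfm_of=lambda y, rep: y - 0.05)
    report = run_condition(df, [])
    assert report.n_sets == 0
    assert report.bias == pytest.approx(-0.05)
    assert np.isnan(report.r2_val)


def test_condition_table_ranked_and_labeled():
    good = run_condition(
        design_df(np.random.default_rng(11), sfm_of=lambda y, rep: y - 0.08),
        enumerate_cv_sets(3, 3),
    )
    bad = run_condition(
        design_df(
            np.random.default_rng(12),
            sfm_of=lambda y, rep: y - 0.08 + {1: 0.0, 2: 0.9, 3: -0.7}[rep],
        ),
        enumerate_cv_sets(3, 3),
    )
    table = condition_table({(-60, False, False, "M3"): good, (-60, True, True, "M1"): bad})
    assert list(table["case"]) == ["LC", "HC"]
    assert table.iloc[0]["r2_val"] >= table.iloc[1]["r2_val"]
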