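"""Linear calibration of SfM heights and cross-flight validation.

SfM-derived heights systematically underestimate ruler measurements (the
reconstruction shaves thin plant tops), so a simple linear model

    PH_measured = a * PH_SfM + b

is fitted by ordinary least squares and evaluated with a
"different-targets-and-different-flight" scheme: the model is trained on two
of the three spatial groups from one flight repetition and validated on the
held-out group *from a different repetition*. All ordered pairs of distinct
repetitions crossed with the three hold-out groups are enumerated — 18
validation sets for 3 repetitions — so a model is never scored on targets or
a reconstruction it has seen.

Validation R² uses the validation partition's own mean in the total sum of
squares and is not clipped below zero: a model carrying a foreign datum
offset can score arbitrarily negative, which is exactly the failure this
scheme exists to expose.

Sample tables are plain :class:`pandas.DataFrame` with columns ``sample_id``,
``ph_measured``, ``ph_sfm``, ``repetition`` and ``group``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    mean_absolute_error,
    mean_absolute_percentage_error,
    mean_squared_error,
    r2_score,
)

from .errors import (
    DegenerateRegressionError,
    IncompleteDesignError,
    UndefinedCorrelationError,
)

__all__ = [
    "LinearCalibration",
    "CVSet",
    "CVReport",
    "EvalMetrics",
    "pearson_r",
    "bias",
    "fit_linear",
    "evaluate",
    "enumerate_cv_sets",
    "run_condition",
    "condition_table",
]

SAMPLE_COLUMNS = ("sample_id", "ph_measured", "ph_sfm", "repetition", "group")


@dataclass(frozen=True)
class LinearCalibration:
    a: float  # slope (dimensionless)
    b: float  # intercept (m)

    def predict(self, ph_sfm) -> np.ndarray:
        return self.a * np.asarray(ph_sfm, dtype=float) + self.b


@dataclass(frozen=True)
class CVSet:
    train_repetition: int
    validation_repetition: int
    validation_group: int

    def __post_init__(self) -> None:
        if self.train_repetition == self.validation_repetition:
            raise ValueError("training and validation flights must differ")


@dataclass(frozen=True)
class EvalMetrics:
    r2_val: float
    mae: float  # m
    rmse: float  # m
    mape: float  # percent


@dataclass(frozen=True)
class CVReport:
    """Per-condition summary: r and bias averaged over repetitions, CV
    metrics averaged over all validation sets."""

    r: float
    bias: float
    r2_train: float
    r2_val: float
    mae: float
    rmse: float
    mape: float
    n_sets: int


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("pearson_r needs at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance data")
    return float(stats.pearsonr(x, y).statistic)


def bias(samples: pd.DataFrame) -> float:
    """Mean of PH_SfM − PH_measured, in meters."""
    if len(samples) == 0:
        raise ValueError("bias of an empty sample table")
    return float((samples["ph_sfm"] - samples["ph_measured"]).mean())


def fit_linear(train: pd.DataFrame) -> LinearCalibration:
    """OLS of PH_measured on PH_SfM."""
    x = train["ph_sfm"].to_numpy(dtype=float)
    y = train["ph_measured"].to_numpy(dtype=float)
    if len(x) < 2 or np.ptp(x) == 0:
        raise DegenerateRegressionError("need >= 2 distinct PH_SfM values to calibrate")
    fit = stats.linregress(x, y)
    return LinearCalibration(a=float(fit.slope), b=float(fit.intercept))


def evaluate(model: LinearCalibration, validation: pd.DataFrame) -> EvalMetrics:
    """Validation R² (about the validation mean, unclipped), MAE, RMSE and
    MAPE (percent) of the calibrated predictions."""
    if len(validation) == 0:
        raise ValueError("empty validation partition")
    y = validation["ph_measured"].to_numpy(dtype=float)
    if np.any(y == 0):
        raise ValueError("MAPE undefined: validation contains zero measured height")
    pred = model.predict(validation["ph_sfm"])
    return EvalMetrics(
        r2_val=float(r2_score(y, pred)),
        mae=float(mean_absolute_error(y, pred)),
        rmse=float(np.sqrt(mean_squared_error(y, pred))),
        mape=float(mean_absolute_percentage_error(y, pred) * 100.0),
    )


def enumerate_cv_sets(n_repetitions: int, n_groups: int) -> list[CVSet]:
    """All ordered (train, validation) repetition pairs with distinct flights,
    crossed with every choice of hold-out group: n_reps·(n_reps−1)·n_groups
    sets (18 for three repetitions and three groups)."""
    if n_repetitions < 1 or n_groups < 1:
        raise ValueError("counts must be >= 1")
    return [
        CVSet(tr, vr, g)
        for tr, vr in itertools.permutations(range(1, n_repetitions + 1), 2)
        for g in range(1, n_groups + 1)
    ]


def _check_design(samples: pd.DataFrame, cv_sets: Sequence[CVSet]) -> None:
    present = set(zip(samples["repetition"], samples["group"]))
    groups = sorted(samples["group"].unique())
    for cv in cv_sets:
        needed = [(cv.validation_repetition, cv.validation_group)] + [
            (cv.train_repetition, g) for g in groups if g != cv.validation_group
        ]
        for key in needed:
            if key not in present:
                raise IncompleteDesignError(f"no samples for (repetition, group) = {key}")


def run_condition(samples: pd.DataFrame, cv_sets: Sequence[CVSet]) -> CVReport:
    """Evaluate one analysis condition.

    ``r`` and ``bias`` are computed per repetition on the full flight and
    averaged over repetitions. Each CV set trains on the two non-held-out
    groups of the training flight and validates on the held-out group of the
    validation flight; reported CV metrics are means over all sets. With an
    empty ``cv_sets`` (single repetition), only r and bias are reported.
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table lacks columns {missing}")
    _check_design(samples, cv_sets)

    per_rep = samples.groupby("repetition")
    r_mean = float(np.mean([pearson_r(g["ph_sfm"], g["ph_measured"]) for _, g in per_rep]))
    bias_mean = float(np.mean([bias(g) for _, g in per_rep]))

    if not cv_sets:
        return CVReport(
            r=r_mean, bias=bias_mean, r2_train=np.nan, r2_val=np.nan,
            mae=np.nan, rmse=np.nan, mape=np.nan, n_sets=0,
        )

    r2_train, metrics = [], []
    for cv in cv_sets:
        train = samples[
            (samples["repetition"] == cv.train_repetition)
            & (samples["group"] != cv.validation_group)
        ]
        val = samples[
            (samples["repetition"] == cv.validation_repetition)
            & (samples["group"] == cv.validation_group)
        ]
        model = fit_linear(train)
        r2_train.append(r2_score(train["ph_measured"], model.predict(train["ph_sfm"])))
        metrics.append(evaluate(model, val))
    return CVReport(
        r=r_mean,
        bias=bias_mean,
        r2_train=float(np.mean(r2_train)),
        r2_val=float(np.mean([m.r2_val for m in metrics])),
        mae=float(np.mean([m.mae for m in metrics])),
        rmse=float(np.mean([m.rmse for m in metrics])),
        mape=float(np.mean([m.mape for m in metrics])),
        n_sets=len(cv_sets),
    )


#: the named cost extremes among analysis conditions: low-cost (diagonal
#: camera, no RTK, no GCP, polynomial-DTM method) and highest-cost (diagonal
#: camera, RTK, GCP, off-season differencing)
LC_CONDITION = (-60, False, False, "M3")
HC_CONDITION = (-60, True, True, "M1")


def condition_table(reports: dict[tuple, CVReport]) -> pd.DataFrame:
    """Ranked comparison across conditions, sorted by validation R²
    (descending). Condition keys are (camera_angle, rtk, gcp, method)."""
    if not reports:
        raise ValueError("no condition reports to tabulate")
    rows = []
    for cond, rep in reports.items():
        angle, rtk, gcp, method = cond
        label = "LC" if cond == LC_CONDITION else ("HC" if cond == HC_CONDITION else "")
        rows.append(
            {
                "camera_angle": angle,
                "rtk": "+" if rtk else "-",
                "gcp": "+" if gcp else "-",
                "method": method,
                "case": label,
                "r": rep.r,
                "bias": rep.bias,
                "r2_train": rep.r2_train,
                "r2_val": rep.r2_val,
                "mae": rep.mae,
                "rmse": rep.rmse,
                "mape": rep.mape,
                "n_sets": rep.n_sets,
            }
        )
    table = pd.DataFrame(rows).sort_values("r2_val", ascending=False, na_position="last")
    return table.reset_index(drop=True)
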