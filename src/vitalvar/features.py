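"""Vital-sign variability features from bedside-monitor time series.

The central idea: a patient's instability in the hours before sepsis onset
shows up as frequent reversals (trend changes) in routinely monitored vital
signs.  For a sampled series ``X`` (one vital sign, one patient, one
collection window) we locate its local extrema, in order of appearance, and
summarise them with five features per sign:

* ``f1`` — number of interior local extrema (trend changes),
* ``f2``–``f5`` — mean / median / min / max of the absolute swings between
  consecutive points of the *augmented* extrema sequence (the interior
  extrema with the window's first and last samples prepended/appended).

Four signs (mean arterial pressure, heart rate, respiratory rate, core
temperature) x five features give a 20-dimensional patient record.  A set of
descriptive statistics (mean, median, min, max, sd of the raw samples) is
provided as the prior-work comparator feature set.

Conventions (degenerate cases the extrema definition does not pin down):

* runs of equal consecutive values (plateaus) are collapsed to a single
  representative point before extremum testing, so a flat summit or valley
  counts as one trend change;
* intensity features use the augmented sequence: a single symmetric
  excursion (e.g. 60 -> 95 -> 60) yields f1=1 and two equal swings of 35;
* a constant window scores f1=0 and f2..f5=0;
* the median of an even-length swing sequence is the midpoint average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SIGNS = ("MAP", "HR", "RR", "TEMP")
#: Units per sign, for documentation and error messages.
SIGN_UNITS = {"MAP": "mmHg", "HR": "bpm", "RR": "breaths/min", "TEMP": "degC"}

VARIABILITY_NAMES = ("f1", "f2", "f3", "f4", "f5")
BASELINE_NAMES = ("mean", "median", "min", "max", "sd")

SAMPLE_INTERVAL_MIN = 10  # bedside systems record one value every 10 minutes
SAMPLES_PER_HOUR = 60 // SAMPLE_INTERVAL_MIN


class WindowCoverageError(ValueError):
    """The requested collection window is not completely covered by data."""


@dataclass(frozen=True)
class VitalSignWindow:
    """One patient's sampled series for one vital sign.

    ``values`` holds ``N = sampling_per_hour * T_hours`` measurements taken on
    a regular grid.  ``start_min`` is the offset (minutes since admission) of
    the first sample; ``t0_min``, when known, is the reference moment (sepsis
    detection for septic patients, an arbitrary moment for controls).
    """

    patient_id: str
    sign: str
    values: np.ndarray
    sampling_per_hour: int = SAMPLES_PER_HOUR
    start_min: float = 0.0
    t0_min: float | None = None

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise ValueError(f"unknown vital sign {self.sign!r}; expected one of {SIGNS}")
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("a vital-sign window needs at least 2 samples")
        if not np.all(np.isfinite(arr)):
            raise ValueError("vital-sign window contains non-finite values")
        object.__setattr__(self, "values", arr)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def T_hours(self) -> float:
        return self.n_samples / self.sampling_per_hour


@dataclass(frozen=True)
class ExtremaSequence:
    """Ordered local extrema of a window (interior) and with endpoints added."""

    interior: np.ndarray
    augmented: np.ndarray


@dataclass(frozen=True)
class VariabilityFeatures:
    f1: int
    f2: float
    f3: float
    f4: float
    f5: float

    def as_dict(self, sign: str | None = None) -> dict[str, float]:
        prefix = f"{sign}_" if sign else ""
        return {
            f"{prefix}f1": float(self.f1),
            f"{prefix}f2": self.f2,
            f"{prefix}f3": self.f3,
            f"{prefix}f4": self.f4,
            f"{prefix}f5": self.f5,
        }


@dataclass(frozen=True)
class BaselineFeatures:
    mean: float
    median: float
    min: float
    max: float
    sd: float

    def as_dict(self, sign: str | None = None) -> dict[str, float]:
        prefix = f"{sign}_" if sign else ""
        return {
            f"{prefix}mean": self.mean,
            f"{prefix}median": self.median,
            f"{prefix}min": self.min,
            f"{prefix}max": self.max,
            f"{prefix}sd": self.sd,
        }


@dataclass
class PatientFeatureRecord:
    patient_id: str
    label: int
    feature_set: str  # "variability" | "baseline"
    features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_set not in ("variability", "baseline"):
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if len(self.features) != 20:
            raise ValueError(f"expected 20 features, got {len(self.features)}")


def slice_window(
    times_min: Sequence[float],
    values: Sequence[float],
    t0_min: float,
    T_hours: float,
    horizon_hours: float,
    *,
    patient_id: str = "",
    sign: str = "MAP",
    sampling_per_hour: int = SAMPLES_PER_HOUR,
) -> VitalSignWindow:
    """Cut the collection window out of a full per-patient series.

    The stay before the reference moment t0 is split into the collection
    interval of ``T_hours`` and the prediction horizon of ``horizon_hours``
    immediately before t0.  The window is half-open: it covers
    ``[t0 - (T+horizon), t0 - horizon)`` and excludes the sample at the
    prediction moment itself.  Any missing grid sample rejects the patient
    (mirrors the complete-records inclusion criterion).
    """
    times = np.asarray(times_min, dtype=float)
    vals = np.asarray(values, dtype=float)
    if times.shape != vals.shape:
        raise ValueError("times and values must have equal length")
    step = 60.0 / sampling_per_hour
    start = t0_min - (T_hours + horizon_hours) * 60.0
    end = t0_min - horizon_hours * 60.0
    expected = start + step * np.arange(round((end - start) / step))
    if expected.size < 2:
        raise ValueError("collection window must contain at least 2 samples")
    lookup = {round(float(t), 6): float(v) for t, v in zip(times, vals)}
    out = np.empty(expected.size)
    for i, t in enumerate(expected):
        key = round(float(t), 6)
        if key not in lookup:
            raise WindowCoverageError(
                f"patient {patient_id or '?'} sign {sign}: no sample at "
                f"t={t:g} min; window [{start:g}, {end:g}) not fully covered"
            )
        out[i] = lookup[key]
    return VitalSignWindow(
        patient_id=patient_id,
        sign=sign,
        values=out,
        sampling_per_hour=sampling_per_hour,
        start_min=start,
        t0_min=t0_min,
    )


def extract_extrema(window: VitalSignWindow | Sequence[float]) -> ExtremaSequence:
    """Locate the ordered local extrema of a window.

    Plateaus are collapsed to one representative value first, so strict
    neighbour comparisons suffice afterwards; interior point ``c[j]`` of the
    collapsed series is an extremum iff the slope changes sign across it.
    The augmented sequence prepends/appends the window's raw first and last
    samples.
    """
    x = window.values if isinstance(window, VitalSignWindow) else np.asarray(window, float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 samples to extract extrema")
    keep = np.concatenate(([True], np.diff(x) != 0.0))
    c = x[keep]
    if c.size < 3:
        interior = np.empty(0)
    else:
        d = np.diff(c)
        turning = d[:-1] * d[1:] < 0.0
        interior = c[1:-1][turning]
    augmented = np.concatenate(([x[0]], interior, [x[-1]]))
    return ExtremaSequence(interior=interior, augmented=augmented)


def compute_f1(extrema: ExtremaSequence) -> int:
    """Number of trend changes: the count of interior local extrema."""
    return int(extrema.interior.size)


def intensity_diffs(extrema: ExtremaSequence) -> np.ndarray:
    """Absolute swings between consecutive points of the augmented sequence."""
    return np.abs(np.diff(extrema.augmented))


def compute_features(window: VitalSignWindow | Sequence[float]) -> VariabilityFeatures:
    e = extract_extrema(window)
    diffs = intensity_diffs(e)
    return VariabilityFeatures(
        f1=compute_f1(e),
        f2=float(np.mean(diffs)),
        f3=float(np.median(diffs)),
        f4=float(np.min(diffs)),
        f5=float(np.max(diffs)),
    )


def compute_baseline(window: VitalSignWindow | Sequence[float]) -> BaselineFeatures:
    x = window.values if isinstance(window, VitalSignWindow) else np.asarray(window, float)
    return BaselineFeatures(
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        min=float(np.min(x)),
        max=float(np.max(x)),
        sd=float(np.std(x, ddof=1)),
    )


def feature_names(feature_set: str = "variability") -> list[str]:
    """Canonical column order: signs in SIGNS order, features within sign."""
    names = VARIABILITY_NAMES if feature_set == "variability" else BASELINE_NAMES
    return [f"{sign}_{name}" for sign in SIGNS for name in names]


def featurize_patient(
    windows: Mapping[str, VitalSignWindow],
    feature_set: str = "variability",
    *,
    label: int = 0,
) -> PatientFeatureRecord:
    """Turn one patient's four windows into a 20-feature record."""
    if set(windows) != set(SIGNS):
        missing = set(SIGNS) - set(windows)
        extra = set(windows) - set(SIGNS)
        raise ValueError(f"need exactly one window per sign; missing={sorted(missing)} extra={sorted(extra)}")
    pid = next(iter(windows.values())).patient_id
    feats: dict[str, float] = {}
    for sign in SIGNS:
        w = windows[sign]
        if w.sign != sign:
            raise ValueError(f"window filed under {sign} is for sign {w.sign}")
        if feature_set == "variability":
            feats.update(compute_features(w).as_dict(sign))
        else:
            feats.update(compute_baseline(w).as_dict(sign))
    return PatientFeatureRecord(patient_id=pid, label=int(label), feature_set=feature_set, features=feats)


def featurize_cohort(
    series: pd.DataFrame,
    T_hours: float,
    horizon_hours: float,
    feature_set: str = "variability",
    *,
    sampling_per_hour: int = SAMPLES_PER_HOUR,
    t0_by_patient: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Feature table (one row per patient) from a long-format cohort.

    ``series`` columns: patient_id, group, vital_sign, time_offset_min, value.
    Unless given explicitly, each patient's t0 is taken as one sampling step
    after their last recorded sample (the series is assumed to run from
    admission up to, but excluding, t0).
    """
    required = {"patient_id", "group", "vital_sign", "time_offset_min", "value"}
    if not required.issubset(series.columns):
        raise ValueError(f"series table must have columns {sorted(required)}")
    step = 60.0 / sampling_per_hour
    rows: list[dict[str, float]] = []
    index: list[str] = []
    labels: list[int] = []
    for pid, chunk in series.groupby("patient_id", sort=True):
        group = chunk["group"].iloc[0]
        t0 = (
            float(t0_by_patient[pid])
            if t0_by_patient is not None
            else float(chunk["time_offset_min"].max()) + step
        )
        windows = {}
        for sign in SIGNS:
            sub = chunk[chunk["vital_sign"] == sign]
            windows[sign] = slice_window(
                sub["time_offset_min"].to_numpy(),
                sub["value"].to_numpy(),
                t0,
                T_hours,
                horizon_hours,
                patient_id=str(pid),
                sign=sign,
                sampling_per_hour=sampling_per_hour,
            )
        record = featurize_patient(windows, feature_set, label=int(group == "septic"))
        index.append(str(pid))
        labels.append(record.label)
        rows.append(record.features)
    if not rows:
        raise ValueError("empty cohort: no patients in series table")
    table = pd.DataFrame(rows, index=pd.Index(index, name="patient_id"))
    table = table[feature_names(feature_set)]
    table.insert(0, "label", labels)
    return table
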