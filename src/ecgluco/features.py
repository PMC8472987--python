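"""Per-beat fiducial features: 9 inter-wave distances and 9 slopes,
with Framingham QT correction, IQR outlier removal and standardization.

Coordinate convention (important): each fiducial point is a pair
``(time in seconds relative to R, amplitude in mV)``.  The Euclidean
"length" features therefore mix units -- seconds on one axis, millivolts
on the other -- exactly as a pixel/sample-space measurement would.  The
per-feature standardization applied before modelling absorbs the
resulting scale arbitrariness.

The QT features are special-cased: before computing QT length and
slope, the Q->T time separation is replaced by its Framingham-corrected
value ``QTc = QT + 0.154 (1 - RR)`` with ``RR = 60 / heart rate``; the
amplitude separation is untouched.  The per-beat heart rate is taken
from the beat's preceding R-R interval (first beat: the following one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .delineation import FiducialSet
from .synthetic import WAVE_LABELS

#: Framingham linear correction coefficient (seconds per second of RR)
FRAMINGHAM_COEFF = 0.154

#: the nine fiducial pairs, in table order
FEATURE_PAIRS = ("PQ", "PR", "PS", "PT", "QR", "QS", "QT", "RS", "RT")

#: the 18 feature column names, in table order (length then slope per pair)
FEATURE_NAMES = tuple(
    f"{pair.lower()}_{kind}" for pair in FEATURE_PAIRS for kind in ("len", "slope")
)

META_COLUMNS = ("beat_id", "subject_id", "label")


class DegenerateBeatError(ValueError):
    pass


def distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Euclidean separation of two fiducial points (seconds, mV mixed)."""
    return math.hypot(b[0] - a[0], b[1] - a[1])


def slope(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Amplitude change per unit time between two fiducial points (mV/s)."""
    dx = b[0] - a[0]
    if dx == 0.0:
        raise DegenerateBeatError("coincident fiducial times")
    return (b[1] - a[1]) / dx


def correct_qt(qt: float, heart_rate: float) -> float:
    """Framingham heart-rate correction of a QT interval (seconds)."""
    if heart_rate <= 0:
        raise ValueError("heart rate must be positive")
    rr = 60.0 / heart_rate
    return qt + FRAMINGHAM_COEFF * (1.0 - rr)


def label_glucose(concentration: float, threshold: float = 100.0) -> int:
    """Binary hyperglycemia label: 1 iff strictly above the threshold."""
    if concentration < 0:
        raise ValueError("glucose concentration cannot be negative")
    return int(concentration > threshold)


def extract_features(
    fiducials: FiducialSet,
    heart_rate: float,
    apply_qtc: bool = True,
) -> dict[str, float] | None:
    """The 18 length/slope features of one delineated beat.

    Returns None when any of the five waves is missing or a pair is
    time-degenerate (the beat is dropped, not imputed).
    """
    if not fiducials.valid:
        return None
    pts = {w: fiducials[w] for w in WAVE_LABELS}
    out: dict[str, float] = {}
    try:
        for pair in FEATURE_PAIRS:
            a, b = pts[pair[0]], pts[pair[1]]
            if pair == "QT" and apply_qtc:
                dt = correct_qt(b[0] - a[0], heart_rate)
                b = (a[0] + dt, b[1])
            out[f"{pair.lower()}_len"] = distance(a, b)
            out[f"{pair.lower()}_slope"] = slope(a, b)
    except DegenerateBeatError:
        return None
    return out


def build_feature_matrix(
    per_recording: list[tuple[list[FiducialSet], float | None, int, int]],
    apply_qtc: bool = True,
) -> pd.DataFrame:
    """Assemble a beats x features table from delineated recordings.

    ``per_recording`` holds ``(fiducial_sets, glucose_mg_dl_or_None,
    label, subject_id)`` tuples; glucose, when given, overrides the
    label via the 100 mg/dL rule.  Per-beat heart rate comes from the
    R-R interval preceding each beat.
    """
    rows = []
    beat_id = 0
    for fids, glucose, label, subject in per_recording:
        if glucose is not None:
            label = label_glucose(glucose)
        r_times = np.array([f.r_time_global for f in fids])
        if len(r_times) < 2:
            continue
        rr = np.diff(r_times)
        for i, fid in enumerate(fids):
            rr_i = rr[0] if i == 0 else rr[i - 1]
            if rr_i <= 0:
                continue
            feats = extract_features(fid, heart_rate=60.0 / rr_i, apply_qtc=apply_qtc)
            if feats is None:
                continue
            rows.append({"beat_id": beat_id, "subject_id": subject, "label": label, **feats})
            beat_id += 1
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_NAMES))


# ---------------------------------------------------------------------------
# outlier removal (IQR rule)


@dataclass(frozen=True)
class OutlierBounds:
    """Per-feature quartiles and Tukey fences (Q1 - 1.5 IQR, Q3 + 1.5 IQR)."""

    q1: pd.Series
    q3: pd.Series

    @property
    def iqr(self) -> pd.Series:
        return self.q3 - self.q1

    @property
    def lower(self) -> pd.Series:
        return self.q1 - 1.5 * self.iqr

    @property
    def upper(self) -> pd.Series:
        return self.q3 + 1.5 * self.iqr

    def to_dict(self) -> dict:
        return {
            name: {
                "q1": float(self.q1[name]),
                "q3": float(self.q3[name]),
                "iqr": float(self.iqr[name]),
                "lower": float(self.lower[name]),
                "upper": float(self.upper[name]),
            }
            for name in self.q1.index
        }


def _feature_block(matrix: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in matrix.columns if c in FEATURE_NAMES]
    return matrix[cols]


def fit_outlier_bounds(matrix: pd.DataFrame) -> OutlierBounds:
    """Quartiles by linear interpolation between order statistics."""
    X = _feature_block(matrix)
    if len(X) < 4:
        raise ValueError("need at least 4 rows to fit quartiles")
    return OutlierBounds(
        q1=X.quantile(0.25, interpolation="linear"),
        q3=X.quantile(0.75, interpolation="linear"),
    )


def remove_outliers(
    matrix: pd.DataFrame, bounds: OutlierBounds
) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop every row with any feature strictly outside its fences.

    Returns ``(kept rows, removal mask)`` where the mask is True for
    removed rows.  Comparisons are strict, so a zero-IQR feature whose
    values all equal the fence flags nothing.
    """
    X = _feature_block(matrix)
    below = X.lt(bounds.lower, axis=1)
    above = X.gt(bounds.upper, axis=1)
    mask = (below | above).any(axis=1).to_numpy()
    return matrix.loc[~mask].reset_index(drop=True), mask


# ---------------------------------------------------------------------------
# standardization (z-scores, population sd)


@dataclass(frozen=True)
class StandardizerParams:
    mean: pd.Series
    sd: pd.Series

    def to_dict(self) -> dict:
        return {
            name: {"mean": float(self.mean[name]), "sd": float(self.sd[name])}
            for name in self.mean.index
        }


def fit_standardizer(train: pd.DataFrame) -> StandardizerParams:
    """Per-feature mean and population standard deviation."""
    X = _feature_block(train)
    mean = X.mean()
    sd = X.std(ddof=0)
    zero = sd[sd <= 0]
    if len(zero):
        raise ValueError(f"zero-variance feature(s): {', '.join(zero.index)}")
    return StandardizerParams(mean=mean, sd=sd)


def apply_standardizer(params: StandardizerParams, matrix: pd.DataFrame) -> pd.DataFrame:
    out = matrix.copy()
    cols = list(params.mean.index)
    out[cols] = (out[cols] - params.mean) / params.sd
    return out


def invert_standardizer(params: StandardizerParams, matrix: pd.DataFrame) -> pd.DataFrame:
    out = matrix.copy()
    cols = list(params.mean.index)
    out[cols] = out[cols] * params.sd + params.mean
    return out


def feature_array(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """``(X, y)`` arrays for modelling: the 18 features and the labels."""
    X = _feature_block(matrix).to_numpy(dtype=np.float64)
    y = matrix["label"].to_numpy(dtype=int)
    return X, y
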