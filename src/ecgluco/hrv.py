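"""Recording-level HRV and interval features, and the 16-feature
3-layer ANN comparison model.

This module reproduces, in kind, the older literature approach the
beat-level pipeline is compared against: sixteen per-recording features
(interval means HR, PR, QTc, RTc, TpTec; time-domain mean RR, SDNN,
RMSSD, pNN50, HRVi, TINN; frequency-domain VLF, LF, HF, total power,
LF/HF) fed to a single-hidden-layer network with nine tanh units
trained by SGD.

Caveats inherent to 40-s usable recordings: the VLF band (0.0033-0.04
Hz) contains less than one full cycle and its power is reported with a
low-confidence flag; TpTec requires a T-end the peak delineator does not
produce and is computed with a fixed 0.08-s T-peak-to-T-end proxy,
flagged approximate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import interp1d

from .delineation import FiducialSet, RPeakList
from .features import correct_qt
from .nn import MLP, TrainSchedule
from . import evaluation

RR_MIN_S = 0.2
RR_MAX_S = 3.0
HIST_BIN_S = 1.0 / 128.0
VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
TPTE_PROXY_S = 0.08
RESAMPLE_HZ = 4.0

HRV_FEATURE_NAMES = (
    "hr", "pr", "qtc", "rtc", "tptec",
    "mean_rr", "sdnn", "rmssd", "pnn50", "hrvi", "tinn",
    "vlf", "lf", "hf", "total_pw", "lf_hf",
)


class InsufficientDataError(ValueError):
    pass


@dataclass
class RrSeries:
    """Successive R-R intervals (seconds) after physiologic gating."""

    intervals: np.ndarray
    beat_times: np.ndarray  # time of the interval's closing R peak

    def __len__(self) -> int:
        return len(self.intervals)


def rr_from_peaks(peaks: RPeakList) -> RrSeries:
    """Successive differences of R times, gated to (0.2 s, 3 s)."""
    if len(peaks) < 3:
        raise InsufficientDataError("need at least 3 R peaks")
    times = peaks.times
    rr = np.diff(times)
    keep = (rr > RR_MIN_S) & (rr < RR_MAX_S)
    if keep.sum() < 2:
        raise InsufficientDataError("fewer than 2 intervals after gating")
    return RrSeries(intervals=rr[keep], beat_times=times[1:][keep])


def time_domain_features(rr: RrSeries) -> dict[str, float]:
    """SDNN, RMSSD, pNN50, triangular index, TINN and mean RR."""
    x = rr.intervals
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 intervals")
    diffs = np.diff(x)
    sdnn = float(np.std(x, ddof=1))
    rmssd = float(np.sqrt(np.mean(diffs**2))) if len(diffs) else 0.0
    pnn50 = float(100.0 * np.mean(np.abs(diffs) > 0.050)) if len(diffs) else 0.0
    hrvi, tinn = _triangular_features(x)
    return {
        "mean_rr": float(np.mean(x)),
        "sdnn": sdnn,
        "rmssd": rmssd,
        "pnn50": pnn50,
        "hrvi": hrvi,
        "tinn": tinn,
    }


def _triangular_features(x: np.ndarray) -> tuple[float, float]:
    """HRV triangular index (count / modal bin) and TINN (base width of
    the least-squares triangular fit), on a 1/128-s histogram."""
    lo = np.floor(x.min() / HIST_BIN_S) * HIST_BIN_S
    hi = np.ceil(x.max() / HIST_BIN_S) * HIST_BIN_S + HIST_BIN_S
    edges = np.arange(lo, hi + HIST_BIN_S / 2, HIST_BIN_S)
    counts, edges = np.histogram(x, bins=edges)
    if counts.max() == 0:
        return 0.0, 0.0
    hrvi = float(len(x) / counts.max())
    centers = (edges[:-1] + edges[1:]) / 2
    peak = int(np.argmax(counts))
    if len(centers) == 1:
        return hrvi, 0.0
    # grid-search the triangle's feet (N left of the mode, M right of it)
    best = (np.inf, centers[0], centers[-1])
    left_candidates = range(0, peak + 1)
    right_candidates = range(peak, len(centers))
    y_peak = counts[peak]
    for li in left_candidates:
        for ri in right_candidates:
            if ri == li:
                continue
            n_ft, m_ft = centers[li] - HIST_BIN_S / 2, centers[ri] + HIST_BIN_S / 2
            tri = np.zeros_like(counts, dtype=float)
            up = (centers >= n_ft) & (centers <= centers[peak])
            dn = (centers > centers[peak]) & (centers <= m_ft)
            if centers[peak] > n_ft:
                tri[up] = y_peak * (centers[up] - n_ft) / (centers[peak] - n_ft)
            if m_ft > centers[peak]:
                tri[dn] = y_peak * (m_ft - centers[dn]) / (m_ft - centers[peak])
            err = float(np.sum((counts - tri) ** 2))
            if err < best[0]:
                best = (err, n_ft, m_ft)
    return hrvi, float(best[2] - best[1])


def frequency_domain_features(rr: RrSeries) -> dict[str, float]:
    """Band powers (ms^2) of the evenly resampled RR tachogram.

    The tachogram is cubic-interpolated onto a 4-Hz grid, mean-removed,
    and its periodogram integrated over the VLF/LF/HF bands.  For
    recordings shorter than one LF cycle a ``low_confidence`` flag is
    set instead of raising.
    """
    if len(rr) < 16:
        raise InsufficientDataError("need at least 16 intervals for spectra")
    t = rr.beat_times
    x_ms = rr.intervals * 1000.0
    if np.ptp(x_ms) == 0.0:
        flat = {"vlf": 0.0, "lf": 0.0, "hf": 0.0, "total_pw": 0.0, "lf_hf": 0.0}
        flat["low_confidence"] = float(t[-1] - t[0] < 1.0 / LF_BAND[0])
        return flat
    interp = interp1d(t, x_ms, kind="cubic", fill_value="extrapolate")
    grid = np.arange(t[0], t[-1], 1.0 / RESAMPLE_HZ)
    series = interp(grid)
    series = series - np.mean(series)
    freqs, power = sps.periodogram(series, fs=RESAMPLE_HZ, scaling="density")

    def band(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs < hi)
        return float(np.trapezoid(power[m], freqs[m])) if m.sum() > 1 else 0.0

    vlf = band(*VLF_BAND)
    lf = band(*LF_BAND)
    hf = band(*HF_BAND)
    total = band(VLF_BAND[0], HF_BAND[1])
    out = {
        "vlf": vlf,
        "lf": lf,
        "hf": hf,
        "total_pw": total,
        "lf_hf": lf / hf if hf > 0 else np.inf,
    }
    out["low_confidence"] = float(t[-1] - t[0] < 1.0 / VLF_BAND[1])
    return out


def interval_features(fiducial_sets: list[FiducialSet]) -> dict[str, float]:
    """Recording means of HR, PR, QTc, RTc and the TpTec proxy.

    QT, RT and the TpTe proxy are Framingham-corrected with the beat's
    own heart rate (preceding R-R interval).
    """
    valid = [f for f in fiducial_sets if f.valid]
    if not valid:
        raise InsufficientDataError("no valid beats")
    r_times = np.array([f.r_time_global for f in valid])
    if len(r_times) < 2:
        raise InsufficientDataError("need at least 2 valid beats")
    rr = np.diff(r_times)
    rows = []
    for i, fid in enumerate(valid):
        rr_i = rr[0] if i == 0 else rr[i - 1]
        if not (RR_MIN_S < rr_i < RR_MAX_S):
            continue
        hr = 60.0 / rr_i
        p, q, t_ = fid["P"], fid["Q"], fid["T"]
        rows.append(
            {
                "hr": hr,
                "pr": -p[0],
                "qtc": correct_qt(t_[0] - q[0], hr),
                "rtc": correct_qt(t_[0], hr),
                # T-end proxied as T-peak + 0.08 s (approximate; see module docs)
                "tptec": correct_qt(TPTE_PROXY_S, hr),
            }
        )
    if not rows:
        raise InsufficientDataError("no beats with physiologic RR")
    return {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}


def hrv_feature_vector(
    peaks: RPeakList, fiducial_sets: list[FiducialSet]
) -> dict[str, float]:
    """All 16 recording-level features as one dict (plus flags)."""
    rr = rr_from_peaks(peaks)
    out: dict[str, float] = {}
    out.update(interval_features(fiducial_sets))
    out.update(time_domain_features(rr))
    out.update(frequency_domain_features(rr))
    return out


def hrv_matrix(rows: list[dict[str, float]], labels: list[int]) -> pd.DataFrame:
    df = pd.DataFrame(rows)[list(HRV_FEATURE_NAMES)]
    df.insert(0, "label", labels)
    return df


def baseline_model(
    train: pd.DataFrame,
    test: pd.DataFrame,
    seed: int = 0,
    max_epochs: int = 1000,
    learning_rate: float = 0.01,
    batch_size: int = 8,
) -> evaluation.EvaluationReport:
    """Train the 3-layer reference network (9 tanh hidden units, SGD) on
    standardized 16-feature recording vectors and evaluate on ``test``.

    Expects ``train``/``test`` frames with a ``label`` column and the 16
    HRV feature columns, already standardized.
    """
    feats = [c for c in HRV_FEATURE_NAMES if c in train.columns]
    if len(feats) != 16:
        raise ValueError("expected the 16 HRV feature columns")
    X = train[feats].to_numpy(float)
    y = train["label"].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training set")
    rng = np.random.default_rng(seed)
    n_val = max(2, int(0.15 * len(X)))
    order = rng.permutation(len(X))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    net = MLP(n_inputs=16, hidden_sizes=(9,), hidden_activation="tanh", seed=seed)
    net.fit(
        X[tr_idx], y[tr_idx], X[val_idx], y[val_idx],
        schedule=TrainSchedule(
            learning_rate=learning_rate, max_epochs=max_epochs,
            batch_size=batch_size, seed=seed,
        ),
    )
    scores = net.predict_proba(test[feats].to_numpy(float))
    return evaluation.evaluate_scores(
        scores, test["label"].to_numpy(int),
        model_name="baseline-ann",
        config={"hidden": 9, "activation": "tanh", "features": 16},
    )
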