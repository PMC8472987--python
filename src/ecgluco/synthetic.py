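"""Synthetic single-lead ECG generator with exact fiducial ground truth.

Each heartbeat is a sum of five Gaussian kernels (P, Q, R, S, T), a
simplification of the ECGSYN family of dynamical models that keeps the
P-QRS-T morphology a delineator needs while making every wave peak's
true time and amplitude available analytically.  Recordings concatenate
beats at jittered RR intervals and add sinusoidal baseline wander plus
white measurement noise.

Two physiology knobs separate the classes: ``qt_scale`` stretches the
Q->T timing (hyperglycemia prolongs the corrected QT interval) and
``pr_scale`` stretches the P->R timing (the PR interval lengthens under
acute hyperglycemia).  On top of the class effect, the generator applies
a rate-adaptation rule to the T-wave offset -- the measured QT interval
shortens as heart rate rises, with the heart-rate-corrected QT being the
rate-invariant quantity -- so that downstream QT correction has a real
signal to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

WAVE_LABELS = ("P", "Q", "R", "S", "T")

#: Framingham linear QT/RR coefficient, reused for the generator's
#: inverse rate-adaptation rule (seconds of QT per second of RR).
QT_RR_COEFF = 0.154


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class WaveKernel:
    """One Gaussian wave component of a beat template.

    Parameters
    ----------
    label : str
        One of ``P, Q, R, S, T``.
    amplitude : float
        Peak amplitude in mV (signed; Q and S are negative deflections).
    center_offset : float
        Peak time in seconds relative to the R peak (negative = before R).
    width : float
        Gaussian standard deviation in seconds.
    """

    label: str
    amplitude: float
    center_offset: float
    width: float

    def __post_init__(self) -> None:
        if self.label not in WAVE_LABELS:
            raise InvalidConfigError(f"unknown wave label {self.label!r}")
        if self.width <= 0:
            raise InvalidConfigError("kernel width must be positive")


def _default_kernels() -> tuple[WaveKernel, ...]:
    return (
        WaveKernel("P", 0.15, -0.17, 0.02),
        WaveKernel("Q", -0.12, -0.03, 0.008),
        WaveKernel("R", 1.00, 0.0, 0.01),
        WaveKernel("S", -0.20, 0.03, 0.008),
        WaveKernel("T", 0.30, 0.25, 0.04),
    )


@dataclass(frozen=True)
class BeatTemplate:
    """A five-kernel beat with class-dependent timing multipliers.

    ``qt_scale`` multiplies the S and T center offsets (the Q->T limb),
    ``pr_scale`` multiplies the P center offset (the P->R limb).  Both
    default to 1 (no effect).
    """

    kernels: tuple[WaveKernel, ...] = field(default_factory=_default_kernels)
    qt_scale: float = 1.0
    pr_scale: float = 1.0

    def __post_init__(self) -> None:
        labels = [k.label for k in self.kernels]
        if sorted(labels) != sorted(WAVE_LABELS):
            raise InvalidConfigError("template must contain exactly P,Q,R,S,T")
        if self.qt_scale <= 0 or self.pr_scale <= 0:
            raise InvalidConfigError("qt_scale and pr_scale must be positive")
        offs = {k.label: k.center_offset for k in self.kernels}
        order = [offs[w] for w in WAVE_LABELS]
        if not all(a < b for a, b in zip(order, order[1:])):
            raise InvalidConfigError("kernel centers must be ordered P<Q<R<S<T")

    def kernel(self, label: str) -> WaveKernel:
        for k in self.kernels:
            if k.label == label:
                return k
        raise KeyError(label)

    def effective_offsets(self, rr: float | None = None) -> dict[str, float]:
        """Wave peak offsets (s, relative to R) after scaling.

        When ``rr`` (the beat's RR interval, seconds) is given, the T
        offset is additionally shifted by ``0.154 * (rr - 1)`` -- the
        inverse of the Framingham correction -- so that QTc, not QT, is
        the rate-invariant quantity.
        """
        out: dict[str, float] = {}
        for k in self.kernels:
            off = k.center_offset
            if k.label == "P":
                off = off * self.pr_scale
            elif k.label in ("S", "T"):
                if k.label == "T" and rr is not None:
                    off = off + QT_RR_COEFF * (rr - 1.0)
                off = off * self.qt_scale
            out[k.label] = off
        return out


@dataclass(frozen=True)
class RecordingConfig:
    """Parameters of one synthetic recording.

    Defaults mirror the acquisition protocol being emulated: 60 s of
    single-lead ECG sampled at 1000 Hz.
    """

    duration: float = 60.0
    sampling_rate: float = 1000.0
    mean_hr: float = 70.0
    hr_jitter_sd: float = 0.02
    baseline_wander_amp: float = 0.05
    baseline_wander_freq: float = 0.25
    white_noise_sd: float = 0.01
    beat_center_jitter_sd: float = 0.002
    beat_amplitude_jitter: float = 0.02
    rate_adaptation: bool = True
    class_label: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidConfigError("duration must be positive")
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling rate must be positive")
        if not (20.0 < self.mean_hr < 240.0):
            raise InvalidConfigError("mean_hr must be in (20, 240) bpm")
        if self.class_label not in (0, 1):
            raise InvalidConfigError("class_label must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class GroundTruth:
    """Exact per-beat fiducial annotations of a synthetic recording."""

    fiducials: pd.DataFrame  # columns: beat_index, wave, time_s, amplitude_mv
    label: int

    @property
    def r_times(self) -> np.ndarray:
        rows = self.fiducials[self.fiducials["wave"] == "R"]
        return rows.sort_values("beat_index")["time_s"].to_numpy()

    def wave_times(self, wave: str) -> np.ndarray:
        rows = self.fiducials[self.fiducials["wave"] == wave]
        return rows.sort_values("beat_index")["time_s"].to_numpy()

    def shifted(self, dt: float, t_min: float, t_max: float) -> "GroundTruth":
        """Translate annotations by -dt and drop beats outside [t_min, t_max)."""
        df = self.fiducials.copy()
        df["time_s"] = df["time_s"] - dt
        keep_beats = (
            df.groupby("beat_index")["time_s"]
            .agg(lambda s: (s.min() >= t_min) and (s.max() < t_max))
        )
        df = df[df["beat_index"].map(keep_beats)].reset_index(drop=True)
        return GroundTruth(fiducials=df, label=self.label)

    def to_csv(self, path: str | Path) -> None:
        self.fiducials.to_csv(path, index=False)


@dataclass
class EcgRecording:
    """A sampled single-lead ECG with optional label and ground truth."""

    signal: np.ndarray  # mV
    sampling_rate: float  # Hz
    glucose_mg_dl: float | None = None
    label: int | None = None
    ground_truth: GroundTruth | None = None
    subject_id: int | None = None
    seed: int | None = None

    @property
    def duration(self) -> float:
        return len(self.signal) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.signal)) / self.sampling_rate

    def write(self, csv_path: str | Path) -> None:
        """Write voltages as single-column CSV plus a JSON sidecar."""
        csv_path = Path(csv_path)
        pd.DataFrame({"voltage_mv": self.signal}).to_csv(csv_path, index=False)
        sidecar = {
            "sampling_rate_hz": self.sampling_rate,
            "duration_s": self.duration,
            "glucose_mg_dl": self.glucose_mg_dl,
            "label": self.label,
            "seed": self.seed,
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read(cls, csv_path: str | Path) -> "EcgRecording":
        csv_path = Path(csv_path)
        sig = pd.read_csv(csv_path)["voltage_mv"].to_numpy(float)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        return cls(
            signal=sig,
            sampling_rate=float(meta["sampling_rate_hz"]),
            glucose_mg_dl=meta.get("glucose_mg_dl"),
            label=meta.get("label"),
            seed=meta.get("seed"),
        )


def generate_beat(
    template: BeatTemplate,
    sampling_rate: float,
    window: tuple[float, float] = (-0.35, 0.45),
) -> tuple[np.ndarray, np.ndarray, dict[str, tuple[float, float]]]:
    """Sample one beat on a uniform grid around its R peak.

    Returns ``(times, waveform, truth)`` where times are seconds relative
    to R and ``truth`` maps each wave label to its (peak time, peak
    amplitude).  The waveform is the plain sum of the five Gaussian
    kernels with the template's qt/pr scaling applied; no rate
    adaptation or noise.
    """
    if sampling_rate <= 0:
        raise InvalidConfigError("sampling rate must be positive")
    t = np.arange(
        round(window[0] * sampling_rate), round(window[1] * sampling_rate) + 1
    ) / sampling_rate
    offsets = template.effective_offsets()
    wave = np.zeros_like(t)
    truth: dict[str, tuple[float, float]] = {}
    for k in template.kernels:
        c = offsets[k.label]
        wave += k.amplitude * np.exp(-0.5 * ((t - c) / k.width) ** 2)
        truth[k.label] = (c, k.amplitude)
    return t, wave, truth


def _place_r_times(config: RecordingConfig, rng: np.random.Generator) -> np.ndarray:
    mean_rr = 60.0 / config.mean_hr
    if config.duration < mean_rr:
        raise InvalidConfigError("recording too short for a single beat")
    r_times = []
    t = 0.5 * mean_rr
    while t < config.duration:
        r_times.append(t)
        rr = mean_rr + (rng.normal(0.0, config.hr_jitter_sd) if config.hr_jitter_sd > 0 else 0.0)
        rr = max(rr, 0.3)
        t += rr
    return np.asarray(r_times)


def generate_recording(
    config: RecordingConfig,
    templates: BeatTemplate | tuple[BeatTemplate, BeatTemplate] = BeatTemplate(),
    glucose_mg_dl: float | None = None,
) -> EcgRecording:
    """Generate one annotated recording.

    ``templates`` is either a single template or a ``(negative-class,
    positive-class)`` pair selected by ``config.class_label``.  The output
    has exactly ``round(duration * sampling_rate)`` samples and is fully
    reproducible from ``config.seed``.
    """
    if isinstance(templates, BeatTemplate):
        template = templates
    else:
        template = templates[config.class_label]

    rng = np.random.default_rng(config.seed)
    r_times = _place_r_times(config, rng)
    n = config.n_samples
    t_grid = np.arange(n) / config.sampling_rate
    signal = np.zeros(n)

    rr_intervals = np.diff(r_times)
    rows = []
    for i, r_t in enumerate(r_times):
        # per-beat RR context: preceding interval; first beat uses the following
        if len(rr_intervals) == 0:
            rr = 60.0 / config.mean_hr
        elif i == 0:
            rr = rr_intervals[0]
        else:
            rr = rr_intervals[i - 1]
        offsets = template.effective_offsets(rr=rr if config.rate_adaptation else None)
        beat_ok = True
        beat_rows = []
        for k in template.kernels:
            c = offsets[k.label]
            amp = k.amplitude
            if config.beat_center_jitter_sd > 0 and k.label != "R":
                c = c + rng.normal(0.0, config.beat_center_jitter_sd)
            if config.beat_amplitude_jitter > 0:
                amp = amp * (1.0 + rng.normal(0.0, config.beat_amplitude_jitter))
            peak_t = r_t + c
            lo = max(0, int((peak_t - 5 * k.width) * config.sampling_rate))
            hi = min(n, int((peak_t + 5 * k.width) * config.sampling_rate) + 1)
            if hi > lo:
                seg = t_grid[lo:hi]
                signal[lo:hi] += amp * np.exp(-0.5 * ((seg - peak_t) / k.width) ** 2)
            if peak_t < 0 or peak_t >= config.duration:
                beat_ok = False
            beat_rows.append((i, k.label, peak_t, amp))
        if beat_ok:
            rows.extend(beat_rows)

    if config.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += config.baseline_wander_amp * np.sin(
            2 * np.pi * config.baseline_wander_freq * t_grid + phase
        )
    if config.white_noise_sd > 0:
        signal += rng.normal(0.0, config.white_noise_sd, size=n)

    truth = GroundTruth(
        fiducials=pd.DataFrame(
            rows, columns=["beat_index", "wave", "time_s", "amplitude_mv"]
        ),
        label=config.class_label,
    )
    return EcgRecording(
        signal=signal,
        sampling_rate=config.sampling_rate,
        glucose_mg_dl=glucose_mg_dl,
        label=config.class_label,
        ground_truth=truth,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# dataset generation

#: default class effect: multiplicative prolongation of QT and PR timing
#: in the hyperglycemia class.  Directions follow the acute-hyperglycemia
#: literature (QTc and PR both lengthen); magnitudes are free generator
#: parameters, not physiologic estimates.
DEFAULT_QT_EFFECT = 1.08
DEFAULT_PR_EFFECT = 1.05

#: inter-subject variability (lognormal sd of amplitudes/widths, sd of
#: center offsets in seconds, sd of the subject's baseline qt/pr scale,
#: sd of resting heart rate in bpm)
SUBJECT_AMP_SD = 0.10
SUBJECT_OFFSET_SD = 0.008
SUBJECT_WIDTH_SD = 0.08
SUBJECT_SCALE_SD = 0.02
SUBJECT_HR_SD = 8.0


def _subject_template(rng: np.random.Generator) -> BeatTemplate:
    kernels = []
    for k in _default_kernels():
        amp = k.amplitude * float(np.exp(rng.normal(0.0, SUBJECT_AMP_SD)))
        off = k.center_offset + (
            float(rng.normal(0.0, SUBJECT_OFFSET_SD)) if k.label != "R" else 0.0
        )
        width = k.width * float(np.exp(rng.normal(0.0, SUBJECT_WIDTH_SD)))
        kernels.append(WaveKernel(k.label, amp, off, width))
    # reject pathological orderings by falling back to default offsets
    try:
        return BeatTemplate(
            kernels=tuple(kernels),
            qt_scale=float(np.exp(rng.normal(0.0, SUBJECT_SCALE_SD))),
            pr_scale=float(np.exp(rng.normal(0.0, SUBJECT_SCALE_SD))),
        )
    except InvalidConfigError:
        return BeatTemplate(
            qt_scale=float(np.exp(rng.normal(0.0, SUBJECT_SCALE_SD))),
            pr_scale=float(np.exp(rng.normal(0.0, SUBJECT_SCALE_SD))),
        )


def make_dataset(
    n_subjects: int,
    class_balance: float = 0.5,
    qt_effect: float = DEFAULT_QT_EFFECT,
    pr_effect: float = DEFAULT_PR_EFFECT,
    seed: int = 0,
    config: RecordingConfig | None = None,
) -> list[EcgRecording]:
    """Generate a labelled cohort of synthetic recordings.

    Each subject receives a template drawn with inter-subject
    variability; positive-class subjects get ``qt_effect`` / ``pr_effect``
    multiplied on top of their baseline scales.  Labels are assigned
    deterministically at the requested balance, and every recording's
    stream is seeded from ``(seed, subject index)``.
    """
    if n_subjects < 2:
        raise InvalidConfigError("need at least 2 subjects")
    if not (0.0 < class_balance < 1.0):
        raise InvalidConfigError("class_balance must be in (0, 1)")
    base = config or RecordingConfig()

    n_pos = int(round(n_subjects * class_balance))
    labels = np.zeros(n_subjects, dtype=int)
    labels[:n_pos] = 1
    labels = labels[np.random.default_rng(seed).permutation(n_subjects)]

    recordings: list[EcgRecording] = []
    for i in range(n_subjects):
        child_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(child_seed)
        template = _subject_template(rng)
        label = int(labels[i])
        if label == 1:
            template = replace(
                template,
                qt_scale=template.qt_scale * qt_effect,
                pr_scale=template.pr_scale * pr_effect,
            )
            glucose = float(rng.uniform(105.0, 180.0))
        else:
            glucose = float(rng.uniform(70.0, 100.0))
        hr = float(np.clip(base.mean_hr + rng.normal(0.0, SUBJECT_HR_SD), 45.0, 120.0))
        cfg = replace(
            base,
            mean_hr=hr,
            class_label=label,
            seed=int(rng.integers(0, 2**31)),
        )
        rec = generate_recording(cfg, template, glucose_mg_dl=glucose)
        rec.subject_id = i
        recordings.append(rec)
    return recordings


def write_dataset(recordings: Sequence[EcgRecording], out_dir: str | Path) -> None:
    """Write a cohort as per-subject CSV/JSON pairs plus truth CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        stem = f"subject_{rec.subject_id:04d}"
        rec.write(out_dir / f"{stem}.csv")
        if rec.ground_truth is not None:
            rec.ground_truth.to_csv(out_dir / f"{stem}_truth.csv")
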