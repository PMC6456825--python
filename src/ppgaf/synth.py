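"""Synthetic cardiac rhythm and waveform generation.

Every downstream stage of the screening pipeline (beat detection, quality
filtering, rhythm classification, diagnostic accuracy) is exercised against
cohorts produced here, so each generator carries its ground truth with it:
an :class:`RRSeries` records the exact beat times and rhythm label used to
render a waveform.

Rhythm models
-------------
sinus
    Mean RR plus Gaussian beat-to-beat noise plus a sinusoidal respiratory
    modulation (respiratory sinus arrhythmia).
af
    Atrial fibrillation: intervals drawn i.i.d. as a ventricular refractory
    period plus an exponential conduction delay — serially uncorrelated and
    heavy-tailed, the "irregularly irregular" signature that RR-variability
    detectors key on.
flutter
    Atrial flutter with fixed N:1 atrioventricular conduction: a fast but
    perfectly *regular* ventricular response.  Variability-based detectors
    call this sinus rhythm — the canonical false negative of PPG screening.

Ectopic (premature) beats are injected into an existing series by splitting
a normal interval into a premature interval and a pause; frequent ectopy is
the canonical false-positive mechanism.

All intervals are in milliseconds, beat times in seconds, and every
stochastic operation is reproducible from an integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "RR_MIN_MS",
    "RR_MAX_MS",
    "RRSeries",
    "Waveform",
    "CohortConfig",
    "Measurement",
    "Subject",
    "Cohort",
    "simulate_rr_sinus",
    "simulate_rr_af",
    "simulate_rr_flutter",
    "inject_ectopy",
    "render_ecg",
    "render_ppg",
    "corrupt",
    "simulate_cohort",
    "save_cohort",
    "load_cohort",
    "read_waveform_csv",
    "write_waveform_csv",
]

#: Physiological bounds on a single RR interval (ms): 20–300 bpm.
RR_MIN_MS = 200.0
RR_MAX_MS = 3000.0

RhythmLabel = Literal["sinus", "af", "flutter"]
Modality = Literal["PPG", "ECG"]


class ParameterError(ValueError):
    """A generator was called with a physiologically impossible parameter."""


@dataclass(frozen=True)
class RRSeries:
    """A sequence of inter-beat (RR) intervals with its beat-time realisation.

    ``beat_times`` has one more element than ``intervals``; the first beat is
    at t = 0 and ``beat_times[k+1] - beat_times[k] == intervals[k] / 1000``.
    ``ectopic_flags`` marks premature beats (aligned with ``beat_times``).
    """

    intervals: np.ndarray
    beat_times: np.ndarray
    rhythm_truth: RhythmLabel | None
    ectopic_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        intervals = np.asarray(self.intervals, dtype=float)
        beat_times = np.asarray(self.beat_times, dtype=float)
        if self.ectopic_flags is None:
            flags = np.zeros(beat_times.size, dtype=bool)
        else:
            flags = np.asarray(self.ectopic_flags, dtype=bool)
        object.__setattr__(self, "intervals", intervals)
        object.__setattr__(self, "beat_times", beat_times)
        object.__setattr__(self, "ectopic_flags", flags)
        if beat_times.size != intervals.size + 1:
            raise ValueError("beat_times must have len(intervals) + 1 entries")
        if flags.size != beat_times.size:
            raise ValueError("ectopic_flags must align with beat_times")
        # physiological bounds [RR_MIN_MS, RR_MAX_MS] are guaranteed by the
        # generators; series derived from detected beats may fall outside
        # them (e.g. a missed beat doubles an interval), so the type itself
        # only requires positivity
        if intervals.size and intervals.min() <= 0:
            raise ValueError("intervals must be positive")
        if np.any(np.diff(beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if not np.allclose(np.diff(beat_times), intervals / 1000.0, rtol=0, atol=1e-9):
            raise ValueError("beat_times inconsistent with intervals")

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    @property
    def duration_s(self) -> float:
        return float(self.intervals.sum() / 1000.0)

    @property
    def mean_rr_ms(self) -> float:
        return float(self.intervals.mean())


def _series_from_intervals(
    intervals: Sequence[float],
    rhythm: RhythmLabel | None,
    ectopic_flags: np.ndarray | None = None,
) -> RRSeries:
    intervals = np.asarray(intervals, dtype=float)
    beat_times = np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
    return RRSeries(intervals, beat_times, rhythm, ectopic_flags)


def _draw_until(duration_s: float, draw, clip: bool = True) -> np.ndarray:
    """Draw intervals one beat at a time until the next beat would fall at or
    beyond ``duration_s``.  ``draw(k, t)`` returns interval k (ms) for a beat
    at time t (s)."""
    t = 0.0
    out: list[float] = []
    while True:
        rr = float(draw(len(out), t))
        if clip:
            rr = min(max(rr, RR_MIN_MS), RR_MAX_MS)
        if t + rr / 1000.0 >= duration_s - 1e-9:
            break
        out.append(rr)
        t += rr / 1000.0
    return np.asarray(out)


def simulate_rr_sinus(
    duration_s: float = 60.0,
    mean_rr_ms: float = 800.0,
    sdnn_ms: float = 30.0,
    resp_freq_hz: float = 0.25,
    resp_depth_ms: float = 20.0,
    seed: int | None = None,
) -> RRSeries:
    """Simulate sinus rhythm: Gaussian RR noise + respiratory modulation.

    interval(t) = mean_rr_ms + N(0, sdnn_ms) + resp_depth_ms * sin(2π f t),
    clipped to physiological bounds.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    if not (300.0 <= mean_rr_ms <= 1500.0):
        raise ParameterError("mean_rr_ms must lie in [300, 1500] ms")
    if sdnn_ms < 0:
        raise ParameterError("sdnn_ms must be non-negative")
    rng = np.random.default_rng(seed)

    def draw(k: int, t: float) -> float:
        noise = rng.normal(0.0, sdnn_ms) if sdnn_ms > 0 else 0.0
        resp = resp_depth_ms * np.sin(2.0 * np.pi * resp_freq_hz * t)
        return mean_rr_ms + noise + resp

    return _series_from_intervals(_draw_until(duration_s, draw), "sinus")


def simulate_rr_af(
    duration_s: float = 60.0,
    mean_rr_ms: float = 750.0,
    refractory_ms: float = 350.0,
    seed: int | None = None,
) -> RRSeries:
    """Simulate atrial fibrillation RR intervals.

    Intervals are i.i.d. refractory_ms + Exponential(mean_rr_ms − refractory_ms),
    truncated to physiological bounds: high variability with no serial
    correlation.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    if refractory_ms < RR_MIN_MS:
        raise ParameterError(f"refractory_ms must be ≥ {RR_MIN_MS} ms")
    if mean_rr_ms <= refractory_ms:
        raise ParameterError("mean_rr_ms must exceed refractory_ms")
    rng = np.random.default_rng(seed)
    scale = mean_rr_ms - refractory_ms

    def draw(k: int, t: float) -> float:
        return refractory_ms + rng.exponential(scale)

    return _series_from_intervals(_draw_until(duration_s, draw), "af")


def simulate_rr_flutter(
    duration_s: float = 60.0,
    atrial_cycle_ms: float = 250.0,
    conduction_ratio: int = 3,
) -> RRSeries:
    """Simulate atrial flutter with fixed N:1 conduction.

    The ventricular response is perfectly regular at
    atrial_cycle_ms × conduction_ratio, which is why RR-variability
    classifiers mistake flutter for sinus rhythm.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    if not (180.0 <= atrial_cycle_ms <= 300.0):
        raise ParameterError("atrial_cycle_ms must lie in [180, 300] ms")
    if int(conduction_ratio) != conduction_ratio or conduction_ratio < 2:
        raise ParameterError("conduction_ratio must be an integer ≥ 2")
    rr = atrial_cycle_ms * conduction_ratio
    if rr < RR_MIN_MS:
        raise ParameterError("resulting RR below physiological minimum")
    n = int(np.ceil(duration_s * 1000.0 / rr))
    intervals = np.full(max(n - 1, 1), rr)
    # trim so beats stay inside the record
    while intervals.sum() / 1000.0 >= duration_s:
        intervals = intervals[:-1]
    return _series_from_intervals(intervals, "flutter")


def inject_ectopy(
    rr: RRSeries,
    kind: Literal["atrial", "ventricular"] = "atrial",
    n_ectopics: int = 1,
    prematurity: float = 0.6,
    compensatory: bool | None = None,
    seed: int | None = None,
) -> RRSeries:
    """Insert premature (ectopic) beats into a series.

    A chosen normal interval RR1 followed by RR2 becomes
    ``(prematurity·RR1, pause)``.  A ventricular ectopic leaves the next sinus
    beat on schedule (fully compensatory pause: the pair sums to RR1+RR2);
    an atrial ectopic resets the sinus node (non-compensatory: pause = RR2,
    the pair sums to less than RR1+RR2).  The rhythm label is unchanged —
    ectopy is a perturbation, not a rhythm.
    """
    if kind not in ("atrial", "ventricular"):
        raise ParameterError("kind must be 'atrial' or 'ventricular'")
    if not (0.0 < prematurity < 1.0):
        raise ParameterError("prematurity must lie in (0, 1)")
    if n_ectopics == 0:
        return rr
    n_iv = rr.intervals.size
    if n_ectopics < 0 or n_ectopics > rr.n_beats // 3:
        raise ParameterError("n_ectopics must lie in [0, n_beats/3]")
    if n_iv < 2:
        raise ParameterError("series too short for ectopy injection")
    if compensatory is None:
        compensatory = kind == "ventricular"

    rng = np.random.default_rng(seed)
    # pick non-adjacent interval indices i so pairs (i, i+1) never overlap
    candidates = np.arange(n_iv - 1)
    for _ in range(1000):
        picked = np.sort(rng.choice(candidates, size=n_ectopics, replace=False))
        if np.all(np.diff(picked) >= 2):
            break
    else:
        raise ParameterError("could not place ectopics without overlap")

    intervals = rr.intervals.copy()
    flags = rr.ectopic_flags.copy()
    for i in picked:
        rr1, rr2 = intervals[i], intervals[i + 1]
        premature = max(prematurity * rr1, RR_MIN_MS)
        if compensatory:
            pause = (rr1 - premature) + rr2
        else:
            pause = rr2
        intervals[i] = premature
        intervals[i + 1] = min(pause, RR_MAX_MS)
        flags[i + 1] = True
    return _series_from_intervals(intervals, rr.rhythm_truth, flags)


# ---------------------------------------------------------------------------
# Waveform rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled single-channel signal.

    ``truth`` optionally carries the RR series the waveform was rendered
    from, so detectors can be scored against exact beat times.
    """

    samples: np.ndarray
    fs: float
    modality: Modality
    duration_s: float
    truth: RRSeries | None = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if samples.size != round(self.fs * self.duration_s):
            raise ValueError("len(samples) must equal round(fs * duration_s)")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


# ECG template: Gaussian bumps (amplitude, centre offset s, width s) relative
# to the R peak.  QRS spans ~90 ms; amplitudes relative to the R wave.
_ECG_COMPONENTS = (
    (0.12, -0.200, 0.030),  # P
    (-0.12, -0.035, 0.010),  # Q
    (1.00, 0.000, 0.012),  # R
    (-0.18, 0.035, 0.012),  # S
    (0.30, 0.240, 0.050),  # T
)


def render_ecg(
    rr: RRSeries,
    fs: float = 250.0,
    qrs_amplitude: float = 1.0,
    noise_sd: float = 0.02,
    seed: int | None = None,
) -> Waveform:
    """Render a single-lead ECG as a sum of per-beat P-QRS-T templates.

    The template is a Gaussian mixture — morphologically schematic, but the
    R peak falls exactly on each true beat time, which is all the RR-based
    pipeline needs.
    """
    if fs < 125.0:
        raise ParameterError("fs must be ≥ 125 Hz (QRS undersampled below)")
    duration_s = _render_duration(rr)
    n = round(fs * duration_s)
    t = np.arange(n) / fs
    x = np.zeros(n)
    half = 0.55  # template support ± seconds
    for tb in rr.beat_times:
        lo = max(0, int((tb - half) * fs))
        hi = min(n, int((tb + half) * fs) + 1)
        tau = t[lo:hi] - tb
        for amp, mu, sig in _ECG_COMPONENTS:
            x[lo:hi] += qrs_amplitude * amp * np.exp(-0.5 * ((tau - mu) / sig) ** 2)
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return Waveform(x, fs, "ECG", duration_s, truth=rr)


def _ppg_pulse(tau: np.ndarray, width_s: float) -> np.ndarray:
    """Smooth asymmetric pulse (gamma-shaped): fast upstroke, slow decay,
    unit maximum exactly at tau = 0."""
    theta = width_s / 4.0
    rise = 2.0 * theta  # peak of a shape-3 gamma at 2θ
    z = (tau + rise) / theta
    out = np.zeros_like(tau)
    pos = z > 0
    out[pos] = (z[pos] / 2.0) ** 2 * np.exp(2.0 - z[pos])
    return out


def render_ppg(
    rr: RRSeries,
    fs: float = 30.0,
    pulse_width_frac: float = 0.5,
    noise_sd: float = 0.02,
    seed: int | None = None,
) -> Waveform:
    """Render a fingertip PPG: one smooth asymmetric pulse per beat, slow
    baseline wander, white noise.  The systolic peak of each pulse falls on
    the true beat time.
    """
    if fs < 25.0:
        raise ParameterError("fs must be ≥ 25 Hz (camera-grade sampling)")
    if not (0.2 <= pulse_width_frac <= 0.8):
        raise ParameterError("pulse_width_frac must lie in [0.2, 0.8]")
    duration_s = _render_duration(rr)
    n = round(fs * duration_s)
    t = np.arange(n) / fs
    x = np.zeros(n)
    # pulse width tracks the beat interval but saturates: systolic ejection
    # time is roughly rate-independent in slow rhythms
    width_s = pulse_width_frac * rr.mean_rr_ms / 1000.0 if rr.intervals.size else 0.4
    width_s = min(width_s, 0.42)
    half = max(1.5 * width_s, 0.5)
    for tb in rr.beat_times:
        lo = max(0, int((tb - half) * fs))
        hi = min(n, int((tb + 3 * half) * fs) + 1)
        x[lo:hi] += _ppg_pulse(t[lo:hi] - tb, width_s)
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    x += 0.10 * np.sin(2 * np.pi * 0.15 * t + phase)  # baseline wander
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n)
    return Waveform(x, fs, "PPG", duration_s, truth=rr)


def _render_duration(rr: RRSeries) -> float:
    # round the record up to the next whole second past the last beat
    return float(np.ceil(rr.beat_times[-1] + 0.8)) if rr.n_beats else 60.0


def corrupt(
    w: Waveform,
    mode: Literal["motion_burst", "flatline", "saturation"],
    start_s: float,
    dur_s: float,
    seed: int | None = None,
) -> Waveform:
    """Overwrite a window of a waveform with an artifact.

    motion_burst: high-amplitude broadband noise; flatline: constant;
    saturation: hard clipping at rails inside the signal range.
    """
    if dur_s < 0 or start_s < 0 or start_s + dur_s > w.duration_s + 1e-9:
        raise ParameterError("corruption window outside record")
    if dur_s == 0:
        return w
    lo = int(round(start_s * w.fs))
    hi = min(int(round((start_s + dur_s) * w.fs)), w.samples.size)
    x = w.samples.copy()
    seg = x[lo:hi]
    if mode == "motion_burst":
        amp = 5.0 * (np.ptp(w.samples) + 1e-12)
        x[lo:hi] = np.random.default_rng(seed).normal(0.0, amp, seg.size)
    elif mode == "flatline":
        x[lo:hi] = x[lo] if lo < x.size else 0.0
    elif mode == "saturation":
        lo_rail, hi_rail = np.percentile(w.samples, [35, 65])
        x[lo:hi] = np.clip(seg, lo_rail, hi_rail)
    else:
        raise ParameterError(f"unknown corruption mode {mode!r}")
    return Waveform(x, w.fs, w.modality, w.duration_s, truth=w.truth)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Study-cohort generator settings.

    Defaults emulate the screening-study design: repeated 60-second
    recordings, three per subject, AF prevalence 50% in the recruited
    sample.  Ectopy, flutter and artifact rates default to zero; studies of
    the error modes switch them on explicitly.
    """

    n_subjects: int = 160
    af_prevalence: float = 0.5
    measurements_per_subject: int = 3
    ectopy_rate: float = 0.0  # expected atrial ectopics per minute (sinus subjects)
    flutter_fraction: float = 0.0  # fraction of AF-positive subjects in flutter
    artifact_rate: float = 0.0  # fraction of recordings corrupted
    duration_s: float = 60.0
    ppg_fs: float = 30.0
    ecg_fs: float = 250.0
    seed: int = 0

    def __post_init__(self):
        for name in ("af_prevalence", "flutter_fraction", "artifact_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be ≥ 1")
        if self.measurements_per_subject < 1:
            raise ParameterError("measurements_per_subject must be ≥ 1")
        if self.ectopy_rate < 0:
            raise ParameterError("ectopy_rate must be ≥ 0")


@dataclass
class Measurement:
    index: int  # 1-based within subject
    rr: RRSeries
    ppg: Waveform | None = None
    ecg: Waveform | None = None
    corrupted: dict | None = None  # modality -> artifact mode, if corrupted


@dataclass
class Subject:
    subject_id: str
    gold: Literal["af", "no_af"]
    rhythm: RhythmLabel
    measurements: list[Measurement] = field(default_factory=list)


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[Subject]

    @property
    def n_measurements(self) -> int:
        return sum(len(s.measurements) for s in self.subjects)


def simulate_cohort(cfg: CohortConfig, render: bool = True) -> Cohort:
    """Simulate a ground-truthed screening cohort.

    Exactly ``round(n_subjects × af_prevalence)`` subjects carry the gold
    label ``af`` (a ``flutter_fraction`` of them in atrial flutter, the
    rest fibrillating); the remainder are in sinus rhythm with
    Poisson-distributed atrial ectopy at ``ectopy_rate`` per minute.  Each
    subject contributes ``measurements_per_subject`` synchronized PPG+ECG
    recordings of the same beat sequence; a fraction ``artifact_rate`` of
    recordings (independently per modality) is corrupted badly enough to be
    rejected by the quality filter.  Bit-identical for identical config.

    With ``render=False`` only the RR-level truth is produced (fast path
    for large classifier studies).
    """
    root = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n_af = round(cfg.n_subjects * cfg.af_prevalence)
    labels = np.array(["af"] * n_af + ["no_af"] * (cfg.n_subjects - n_af))
    root.shuffle(labels)

    subjects: list[Subject] = []
    subj_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    for i, (gold, ss) in enumerate(zip(labels, subj_seeds)):
        rng = np.random.default_rng(ss)
        if gold == "af":
            rhythm = "flutter" if rng.random() < cfg.flutter_fraction else "af"
        else:
            rhythm = "sinus"
        subject = Subject(subject_id=f"S{i:04d}", gold=str(gold), rhythm=rhythm)

        if rhythm == "sinus":
            hr = float(np.clip(rng.normal(72.0, 10.0), 50.0, 95.0))
            params = {"mean_rr_ms": 60000.0 / hr}
        elif rhythm == "af":
            hr = float(np.clip(rng.normal(85.0, 12.0), 60.0, 115.0))
            params = {"mean_rr_ms": 60000.0 / hr, "refractory_ms": 350.0}
        else:  # flutter
            params = {
                "atrial_cycle_ms": float(rng.uniform(200.0, 280.0)),
                "conduction_ratio": int(rng.choice([2, 3])),
            }

        for m in range(cfg.measurements_per_subject):
            mseed = int(rng.integers(0, 2**31 - 1))
            if rhythm == "sinus":
                rr = simulate_rr_sinus(cfg.duration_s, seed=mseed, **params)
                n_ect = min(int(rng.poisson(cfg.ectopy_rate * cfg.duration_s / 60.0)),
                            rr.n_beats // 3)
                if n_ect > 0:
                    rr = inject_ectopy(rr, "atrial", n_ect, seed=mseed + 1)
            elif rhythm == "af":
                rr = simulate_rr_af(cfg.duration_s, seed=mseed, **params)
            else:
                rr = simulate_rr_flutter(cfg.duration_s, **params)

            meas = Measurement(index=m + 1, rr=rr, corrupted={})
            if render:
                meas.ppg = render_ppg(rr, fs=cfg.ppg_fs, seed=mseed + 2)
                meas.ecg = render_ecg(rr, fs=cfg.ecg_fs, seed=mseed + 3)
                for mod in ("ppg", "ecg"):
                    if rng.random() < cfg.artifact_rate:
                        w = getattr(meas, mod)
                        mode = str(rng.choice(["motion_burst", "flatline"]))
                        dur = float(rng.uniform(0.6, 0.95)) * w.duration_s
                        start = float(rng.uniform(0.0, w.duration_s - dur))
                        setattr(meas, mod, corrupt(w, mode, start, dur,
                                                   seed=mseed + 4))
                        meas.corrupted[mod.upper()] = mode
            subject.measurements.append(meas)
        subjects.append(subject)
    return Cohort(config=cfg, subjects=subjects)


# ---------------------------------------------------------------------------
# Serialization: cohort directory with cohort.json + one CSV per waveform
# ---------------------------------------------------------------------------


def write_waveform_csv(w: Waveform, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_s,value\n")
        for i, v in enumerate(w.samples):
            fh.write(f"{i / w.fs:.17g},{v:.17g}\n")


def read_waveform_csv(
    path: str | Path, fs: float | None = None, modality: Modality = "PPG"
) -> Waveform:
    """Read a ``time_s,value`` CSV.  If ``fs`` is omitted it is inferred
    from the median sample spacing."""
    data = np.genfromtxt(path, delimiter=",", names=True)
    t = np.atleast_1d(data["time_s"])
    v = np.atleast_1d(data["value"])
    if fs is None:
        if t.size < 2:
            raise ValueError("cannot infer fs from fewer than 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
        fs = round(fs, 6)
    return Waveform(v, fs, modality, duration_s=v.size / fs)


def _rr_to_dict(rr: RRSeries) -> dict:
    return {
        "intervals_ms": [float(x) for x in rr.intervals],
        "rhythm_truth": rr.rhythm_truth,
        "ectopic_flags": [bool(b) for b in rr.ectopic_flags],
    }


def _rr_from_dict(d: dict) -> RRSeries:
    return _series_from_intervals(
        d["intervals_ms"], d["rhythm_truth"], np.asarray(d["ectopic_flags"], bool)
    )


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config": vars(cohort.config) | {}, "subjects": []}
    for s in cohort.subjects:
        srec = {"subject_id": s.subject_id, "gold": s.gold, "rhythm": s.rhythm,
                "measurements": []}
        for m in s.measurements:
            mrec = {"index": m.index, "rr": _rr_to_dict(m.rr),
                    "corrupted": m.corrupted or {}}
            for mod in ("ppg", "ecg"):
                w = getattr(m, mod)
                if w is not None:
                    name = f"{s.subject_id}_m{m.index}_{mod}.csv"
                    write_waveform_csv(w, out_dir / name)
                    mrec[mod] = {"file": name, "fs": w.fs,
                                 "duration_s": w.duration_s}
            srec["measurements"].append(mrec)
        meta["subjects"].append(srec)
    with (out_dir / "cohort.json").open("w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out_dir


def load_cohort(in_dir: str | Path) -> Cohort:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "cohort.json").read_text(encoding="utf-8"))
    cfg = CohortConfig(**meta["config"])
    subjects = []
    for srec in meta["subjects"]:
        s = Subject(srec["subject_id"], srec["gold"], srec["rhythm"])
        for mrec in srec["measurements"]:
            m = Measurement(index=mrec["index"], rr=_rr_from_dict(mrec["rr"]),
                            corrupted=mrec.get("corrupted") or {})
            for mod, tag in (("ppg", "PPG"), ("ecg", "ECG")):
                if mod in mrec:
                    w = read_waveform_csv(in_dir / mrec[mod]["file"],
                                          fs=mrec[mod]["fs"], modality=tag)
                    setattr(m, mod, replace(w, truth=m.rr))
            s.measurements.append(m)
        subjects.append(s)
    return Cohort(config=cfg, subjects=subjects)
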