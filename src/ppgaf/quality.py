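"""Signal-quality assessment.

The production system this emulates used a recurrent neural network to
reject unreliable recordings; its architecture and weights were never
published, so this module provides a transparent rule-based filter with the
same contract — a binary sufficient/insufficient label derived from quality
metrics.  A recording is sufficient only if every metric passes its
threshold:

beat_count
    Too few detected beats means either heartbeats were absent or detection
    failed — either way the rhythm cannot be judged.
beat_coverage
    Fraction of the record spanned by physiologically plausible inter-beat
    gaps.  Flatline or dropped segments leave gaps that do not count.
noise_ratio
    Out-of-band to in-band spectral power; broadband motion artifact drives
    this up even when spurious "beats" are still detected in the noise.
template_consistency
    Mean correlation of beat-centred waveform snippets with their average;
    genuine beats repeat a morphology, noise does not.

Thresholds are calibrated on the clean synthetic fixtures, not learned.
Degenerate input never raises — it is simply insufficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .beats import BeatSeries
from .synth import Waveform

__all__ = ["QualityThresholds", "QualityAssessment", "assess_quality"]

# spectral bands (Hz) per modality: (in_lo, in_hi, out_lo)
_BANDS = {"PPG": (0.5, 5.0, 8.0), "ECG": (1.0, 20.0, 40.0)}


@dataclass(frozen=True)
class QualityThresholds:
    min_beat_count: int = 30
    min_beat_coverage: float = 0.7
    max_noise_ratio: float = 0.5
    min_template_consistency: float = 0.4


@dataclass(frozen=True)
class QualityAssessment:
    label: str  # 'sufficient' | 'insufficient'
    beat_coverage: float
    noise_ratio: float
    beat_count: int
    template_consistency: float

    @property
    def sufficient(self) -> bool:
        return self.label == "sufficient"

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "beat_count": self.beat_count,
            "beat_coverage": self.beat_coverage,
            "noise_ratio": self.noise_ratio,
            "template_consistency": self.template_consistency,
        }


def _beat_coverage(b: BeatSeries, duration_s: float) -> float:
    if len(b) < 2 or duration_s <= 0:
        return 0.0
    gaps = np.diff(b.beat_times)
    plausible = gaps[(gaps >= 0.25) & (gaps <= 2.5)]
    return float(min(plausible.sum() / duration_s, 1.0))


def _noise_ratio(w: Waveform) -> float:
    in_lo, in_hi, out_lo = _BANDS.get(w.modality, _BANDS["PPG"])
    x = w.samples - np.mean(w.samples)
    if np.ptp(x) == 0.0:
        return float("inf")
    nper = min(x.size, int(8 * w.fs))
    f, pxx = sps.welch(x, fs=w.fs, nperseg=max(nper, 16))
    in_band = pxx[(f >= in_lo) & (f <= in_hi)].sum()
    out_band = pxx[f >= out_lo].sum()
    if in_band <= 0:
        return float("inf")
    return float(out_band / in_band)


def _template_consistency(w: Waveform, b: BeatSeries) -> float:
    if len(b) < 3:
        return 0.0
    med_rr = float(np.median(np.diff(b.beat_times)))
    half = max(int(0.25 * med_rr * w.fs), 2)
    snippets = []
    for t in b.beat_times:
        c = int(round(t * w.fs))
        lo, hi = c - half, c + half + 1
        if lo < 0 or hi > w.samples.size:
            continue
        snippets.append(w.samples[lo:hi])
    if len(snippets) < 3:
        return 0.0
    mat = np.asarray(snippets)
    template = mat.mean(axis=0)
    t_sd = template.std()
    if t_sd == 0:
        return 0.0
    corrs = []
    for row in mat:
        r_sd = row.std()
        if r_sd == 0:
            corrs.append(0.0)
        else:
            corrs.append(float(np.corrcoef(row, template)[0, 1]))
    return float(np.mean(corrs))


def assess_quality(
    w: Waveform, b: BeatSeries, thresholds: QualityThresholds | None = None
) -> QualityAssessment:
    """Judge whether a recording is reliable enough for rhythm analysis.

    Deterministic; never raises on degenerate input (an empty beat series or
    a flat record simply yields ``insufficient``).
    """
    thr = thresholds or QualityThresholds()
    coverage = _beat_coverage(b, w.duration_s)
    noise = _noise_ratio(w)
    consistency = _template_consistency(w, b)
    count = len(b)
    ok = (
        count >= thr.min_beat_count
        and coverage >= thr.min_beat_coverage
        and noise <= thr.max_noise_ratio
        and consistency >= thr.min_template_consistency
    )
    return QualityAssessment(
        label="sufficient" if ok else "insufficient",
        beat_coverage=coverage,
        noise_ratio=noise,
        beat_count=count,
        template_consistency=consistency,
    )
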