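"""RR-interval-variability rhythm classification.

A measurement's RR series is reduced to a small feature set — normalized
RMSSD, Shannon entropy of the RR histogram, turning-point ratio and mean
heart rate — and called *AF* when both the variability (RMSSD) and the
disorganisation (entropy) of the intervals are high.  This RMSSD + entropy
AND-rule is the standard family of RR-based AF detectors; the proprietary
algorithm it stands in for disclosed only that it analyses RR-interval
variability, so the decision boundary here is a documented functional
surrogate, not a reconstruction.

Two properties of the rule matter for its failure modes, and are preserved
deliberately:

* Atrial flutter with fixed conduction produces a *regular* RR series —
  zero RMSSD — and is therefore called sinus rhythm (a false negative).
* Premature ectopic beats inflate RMSSD and entropy and can push a sinus
  series over both thresholds (a false positive).  No ectopy filtering is
  applied before feature computation by default, so this failure mode is
  reproduced; an optional premature-beat filter can be enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quality import QualityAssessment
from .synth import RRSeries

__all__ = [
    "ClassifierConfig",
    "RhythmFeatures",
    "RhythmCall",
    "rr_features",
    "classify_rhythm",
    "classify_rr",
    "filter_premature_beats",
    "N_ENTROPY_BINS",
    "MIN_INTERVALS",
]

N_ENTROPY_BINS = 16
MIN_INTERVALS = 30  # one minute of beats at ≤ 2000 ms RR


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision thresholds for the AF call.

    ``theta_rmssd``: normalized-RMSSD threshold (dimensionless).
    ``theta_entropy_frac``: entropy threshold as a fraction of the maximum
    ln(n_bins); both must be exceeded for an AF call.
    """

    theta_rmssd: float = 0.10
    theta_entropy_frac: float = 0.55
    n_bins: int = N_ENTROPY_BINS
    ectopy_filter: bool = False

    @property
    def theta_entropy(self) -> float:
        return self.theta_entropy_frac * np.log(self.n_bins)


@dataclass(frozen=True)
class RhythmFeatures:
    rmssd_norm: float
    shannon_entropy: float
    turning_point_ratio: float
    mean_hr_bpm: float


@dataclass(frozen=True)
class RhythmCall:
    call: str  # 'af' | 'sinus' | 'insufficient'
    features: RhythmFeatures | None = None


def filter_premature_beats(rr: RRSeries) -> RRSeries:
    """Remove premature-beat interval couples.

    An interval shorter than 80% of the series median marks a premature
    beat; it and the following (pause) interval are dropped as a couple.
    Off by default in the classifier: the screening pipeline this emulates
    did not filter ectopy, which is precisely why ectopy causes false
    positives.
    """
    x = rr.intervals
    if x.size < 5:
        return rr
    med = float(np.median(x))
    keep = np.ones(x.size, dtype=bool)
    for i in range(x.size - 1):
        if x[i] < 0.8 * med:
            keep[i] = keep[i + 1] = False
    kept = x[keep]
    if kept.size < 2:
        return rr
    from .synth import _series_from_intervals

    return _series_from_intervals(kept, rr.rhythm_truth)


def rr_features(rr: RRSeries, n_bins: int = N_ENTROPY_BINS) -> RhythmFeatures:
    """Compute the variability feature set of an RR series.

    RMSSD = sqrt(mean of squared successive differences), normalized by the
    mean RR.  Shannon entropy (nats) uses ``n_bins`` equal-width bins over
    [min RR, max RR]; a constant series has zero entropy by convention.
    The turning-point ratio is the fraction of interior intervals that are
    strict local extrema.
    """
    x = np.asarray(rr.intervals, dtype=float)
    if x.size < MIN_INTERVALS:
        raise InsufficientDataError(
            f"need ≥ {MIN_INTERVALS} intervals, got {x.size}"
        )
    mean_rr = float(x.mean())
    diffs = np.diff(x)
    rmssd = float(np.sqrt(np.mean(diffs**2)))

    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
        p = counts / counts.sum()
        p = p[p > 0]
        entropy = float(-(p * np.log(p)).sum())
    else:
        entropy = 0.0

    interior = x[1:-1]
    if interior.size:
        is_max = (interior > x[:-2]) & (interior > x[2:])
        is_min = (interior < x[:-2]) & (interior < x[2:])
        tpr = float((is_max | is_min).mean())
    else:
        tpr = 0.0

    return RhythmFeatures(
        rmssd_norm=rmssd / mean_rr,
        shannon_entropy=entropy,
        turning_point_ratio=tpr,
        mean_hr_bpm=60000.0 / mean_rr,
    )


def classify_rhythm(
    features: RhythmFeatures | None,
    quality: QualityAssessment | None = None,
    config: ClassifierConfig | None = None,
) -> RhythmCall:
    """AF/sinus call from RR-variability features.

    An insufficient-quality measurement propagates as ``insufficient`` with
    no features.  Otherwise the call is AF iff normalized RMSSD *and*
    histogram entropy both exceed their thresholds.
    """
    cfg = config or ClassifierConfig()
    if quality is not None and not quality.sufficient:
        return RhythmCall(call="insufficient", features=None)
    if features is None:
        return RhythmCall(call="insufficient", features=None)
    is_af = (
        features.rmssd_norm > cfg.theta_rmssd
        and features.shannon_entropy > cfg.theta_entropy
    )
    return RhythmCall(call="af" if is_af else "sinus", features=features)


def classify_rr(
    rr: RRSeries,
    quality: QualityAssessment | None = None,
    config: ClassifierConfig | None = None,
) -> RhythmCall:
    """Convenience: features + classification in one step.

    Too few intervals yields an ``insufficient`` call rather than an error,
    mirroring the quality filter's contract.
    """
    cfg = config or ClassifierConfig()
    if quality is not None and not quality.sufficient:
        return RhythmCall(call="insufficient", features=None)
    if cfg.ectopy_filter:
        rr = filter_premature_beats(rr)
    try:
        feats = rr_features(rr, n_bins=cfg.n_bins)
    except InsufficientDataError:
        return RhythmCall(call="insufficient", features=None)
    return classify_rhythm(feats, None, cfg)
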