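"""End-to-end pipeline: waveforms → beats → quality → calls → accuracy.

`run_pipeline` reproduces, offline, what the mobile screening stack does in
production: every recording is beat-detected, quality-checked and rhythm-
classified; per-subject calls are aggregated by majority rule under each
insufficient-quality scenario; and the resulting calls are scored against
the gold-standard labels.  Everything is deterministic given the cohort and
configuration, so re-running writes byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .aggregate import SCENARIOS, aggregate_subject
from .beats import InsufficientBeatsError, detect_ppg_pulses, pan_tompkins, rr_from_beats
from .diagnostics import AccuracyReport, evaluate
from .quality import QualityThresholds, assess_quality
from .rhythm import ClassifierConfig, classify_rr
from .synth import Cohort, Waveform

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "classify_waveform", "save_config", "load_config"]

log = logging.getLogger("ppgaf")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the analysis pipeline, with study-like defaults."""

    ppg_fs: float = 30.0
    ecg_fs: float = 250.0
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    severity: tuple[str, ...] = ("af", "sinus")
    scenarios: tuple[str, ...] = SCENARIOS
    external_prevalence: float = 0.06
    seed: int = 0


def _flatten(cfg: PipelineConfig) -> dict[str, object]:
    flat: dict[str, object] = {}
    for k, v in asdict(cfg).items():
        if isinstance(v, dict):
            for kk, vv in v.items():
                flat[f"{k}.{kk}"] = vv
        elif isinstance(v, (tuple, list)):
            flat[k] = ",".join(str(x) for x in v)
        else:
            flat[k] = v
    return flat


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the config as flat ``key = value`` lines (lossless round-trip)."""
    lines = [f"{k} = {v}" for k, v in sorted(_flatten(cfg).items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_config(path: str | Path) -> PipelineConfig:
    raw: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, _, v = line.partition("=")
        raw[k.strip()] = v.strip()

    def take(prefix: str) -> dict[str, str]:
        return {k.split(".", 1)[1]: v for k, v in raw.items()
                if k.startswith(prefix + ".")}

    def conv(cls, d: dict[str, str]):
        kwargs = {}
        for f_ in cls.__dataclass_fields__.values():
            if f_.name not in d:
                continue
            v = d[f_.name]
            if f_.type in ("int", int):
                kwargs[f_.name] = int(v)
            elif f_.type in ("float", float):
                kwargs[f_.name] = float(v)
            elif f_.type in ("bool", bool):
                kwargs[f_.name] = v.lower() in ("true", "1", "yes")
            else:
                kwargs[f_.name] = v
        return cls(**kwargs)

    quality = conv(QualityThresholds, take("quality"))
    classifier = conv(ClassifierConfig, take("classifier"))
    return PipelineConfig(
        ppg_fs=float(raw.get("ppg_fs", 30.0)),
        ecg_fs=float(raw.get("ecg_fs", 250.0)),
        quality=quality,
        classifier=classifier,
        severity=tuple(raw.get("severity", "af,sinus").split(",")),
        scenarios=tuple(raw.get("scenarios", ",".join(SCENARIOS)).split(",")),
        external_prevalence=float(raw.get("external_prevalence", 0.06)),
        seed=int(raw.get("seed", 0)),
    )


def classify_waveform(w: Waveform, cfg: PipelineConfig | None = None) -> dict:
    """Single-recording pipeline: detect, quality-check, classify.

    Returns a dict with the beat series, quality assessment and rhythm call.
    Detection failures yield an insufficient call, never an exception.
    """
    cfg = cfg or PipelineConfig()
    detector = pan_tompkins if w.modality == "ECG" else detect_ppg_pulses
    beats = detector(w)
    quality = assess_quality(w, beats, cfg.quality)
    if not quality.sufficient:
        call = "insufficient"
        features = None
    else:
        try:
            rr = rr_from_beats(beats)
        except InsufficientBeatsError:
            call, features = "insufficient", None
        else:
            result = classify_rr(rr, None, cfg.classifier)
            call, features = result.call, result.features
    return {"beats": beats, "quality": quality, "call": call,
            "features": features}


@dataclass
class PipelineResult:
    calls: pd.DataFrame
    outcomes: pd.DataFrame
    reports: list[AccuracyReport]
    gold: pd.DataFrame


def run_pipeline(
    cohort: Cohort,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on a simulated (or loaded) cohort.

    Produces the per-measurement calls table, per-subject outcomes under
    every scenario, and the accuracy reports at both levels, optionally
    written to ``out_dir`` as calls.csv / outcomes.csv / report.json plus a
    run log of versions and parameters.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for s in cohort.subjects:
        for m in s.measurements:
            for mod, w in (("PPG", m.ppg), ("ECG", m.ecg)):
                if w is None:
                    continue
                res = classify_waveform(w, cfg)
                rows.append({
                    "subject_id": s.subject_id,
                    "measurement_index": m.index,
                    "modality": mod,
                    "call": res["call"],
                    "n_beats": len(res["beats"]),
                    "quality": res["quality"].label,
                })
    calls = pd.DataFrame(rows, columns=["subject_id", "measurement_index",
                                        "modality", "call", "n_beats",
                                        "quality"])
    gold = pd.DataFrame(
        [{"subject_id": s.subject_id, "gold": s.gold, "rhythm": s.rhythm}
         for s in cohort.subjects]
    )

    out_rows = []
    if not calls.empty:
        for mod, sub in calls.groupby("modality"):
            for sid, grp in sub.groupby("subject_id"):
                cl = list(grp.sort_values("measurement_index")["call"])
                for scenario in cfg.scenarios:
                    o = aggregate_subject(sid, cl, scenario, cfg.severity)
                    out_rows.append({"subject_id": sid, "modality": mod,
                                     "scenario": scenario, "call": o.call})
    outcomes = pd.DataFrame(out_rows, columns=["subject_id", "modality",
                                               "scenario", "call"])

    reports = []
    if not calls.empty:
        reports = evaluate(calls, gold, ("participant", "measurement"),
                           cfg.scenarios, cfg.external_prevalence,
                           cfg.severity)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        calls.to_csv(out_dir / "calls.csv", index=False, lineterminator="\n")
        outcomes.to_csv(out_dir / "outcomes.csv", index=False,
                        lineterminator="\n")
        with (out_dir / "report.json").open("w", encoding="utf-8") as fh:
            json.dump([r.to_dict() for r in reports], fh, indent=1,
                      sort_keys=True)
            fh.write("\n")
        run_log = {
            "ppgaf_version": __version__,
            "config": _flatten(cfg),
            "n_subjects": len(cohort.subjects),
            "n_measurements": cohort.n_measurements,
        }
        with (out_dir / "run.json").open("w", encoding="utf-8") as fh:
            json.dump(run_log, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return PipelineResult(calls=calls, outcomes=outcomes, reports=reports,
                          gold=gold)
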