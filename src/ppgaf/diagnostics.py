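"""Diagnostic-accuracy statistics for repeated-measurement screening.

Index-test calls are scored against a gold-standard rhythm label in 2×2
tables, at two levels (per participant after majority aggregation, and per
measurement) and under three handling scenarios for insufficient-quality
results.  Point estimates come with exact (Clopper-Pearson) binomial
confidence intervals, and predictive values are additionally re-expressed
at an external screening prevalence via Bayes' rule (the study sample is
enriched, so raw PPV/NPV do not transfer to the screening population).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .aggregate import SCENARIOS, aggregate_subject

__all__ = [
    "ConfusionTable",
    "Metric",
    "AccuracyReport",
    "confusion",
    "metrics",
    "clopper_pearson_ci",
    "adjusted_predictive_values",
    "adjusted_predictive_cis",
    "scenario_table",
    "evaluate",
    "paired_agreement",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2×2 table: positive = AF call, condition = gold-standard AF."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_condition_positive(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class Metric:
    """A proportion k/n with its exact binomial confidence interval.

    ``value`` is None when the denominator is zero (undefined metric)."""

    value: float | None
    k: int | None = None
    n: int | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def pct(self, digits: int = 1) -> float | None:
        return None if self.value is None else round(100.0 * self.value, digits)


def confusion(index_calls: Sequence[str], gold_labels: Sequence[str]) -> ConfusionTable:
    """Count a 2×2 table from aligned call/gold sequences.

    Calls must be fully resolved ('af'/'sinus'); gold is 'af'/'no_af'.
    """
    if len(index_calls) != len(gold_labels):
        raise ValueError("index_calls and gold_labels must be aligned")
    tp = fp = fn = tn = 0
    for c, g in zip(index_calls, gold_labels):
        if c not in ("af", "sinus"):
            raise ValueError(f"unresolved call {c!r} (apply a scenario first)")
        if g not in ("af", "no_af"):
            raise ValueError(f"unknown gold label {g!r}")
        if c == "af":
            if g == "af":
                tp += 1
            else:
                fp += 1
        else:
            if g == "af":
                fn += 1
            else:
                tn += 1
    return ConfusionTable(tp, fp, fn, tn)


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval (beta quantiles)."""
    if n < 1 or not (0 <= k <= n):
        raise ValueError("require 0 ≤ k ≤ n and n ≥ 1")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _proportion(k: int, n: int, level: float = 0.95) -> Metric:
    if n == 0:
        return Metric(value=None, k=k, n=n)
    lo, hi = clopper_pearson_ci(k, n, level)
    return Metric(value=k / n, k=k, n=n, ci_low=lo, ci_high=hi)


def metrics(t: ConfusionTable, level: float = 0.95) -> dict[str, Metric]:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact CIs.

    Zero denominators yield undefined metrics (``value is None``), never an
    exception — a cohort without AF subjects simply has no sensitivity.
    """
    return {
        "sensitivity": _proportion(t.tp, t.tp + t.fn, level),
        "specificity": _proportion(t.tn, t.tn + t.fp, level),
        "ppv": _proportion(t.tp, t.tp + t.fp, level),
        "npv": _proportion(t.tn, t.tn + t.fn, level),
        "accuracy": _proportion(t.tp + t.tn, t.n, level),
    }


def adjusted_predictive_values(
    sens: float, spec: float, prevalence: float
) -> tuple[float | None, float | None]:
    """Predictive values at an external prevalence, by Bayes' rule.

    ppv = se·p / (se·p + (1−sp)(1−p));
    npv = sp·(1−p) / (sp·(1−p) + (1−se)·p).
    Returns None for a degenerate denominator.
    """
    for name, v in (("sens", sens), ("spec", spec)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    p = prevalence
    ppv_den = sens * p + (1 - spec) * (1 - p)
    npv_den = spec * (1 - p) + (1 - sens) * p
    ppv = sens * p / ppv_den if ppv_den > 0 else None
    npv = spec * (1 - p) / npv_den if npv_den > 0 else None
    return ppv, npv


def adjusted_predictive_cis(
    t: ConfusionTable, prevalence: float, level: float = 0.95
) -> dict[str, Metric]:
    """Prevalence-adjusted PPV/NPV with logit-transform CIs.

    The interval propagates the binomial variance of sensitivity and
    specificity through the logit of the Bayes formula (delta method);
    approximate, and degenerate at perfect sensitivity or specificity,
    where only the point estimate is returned.
    """
    n1 = t.tp + t.fn
    n0 = t.tn + t.fp
    if n1 == 0 or n0 == 0:
        return {"adjusted_ppv": Metric(None), "adjusted_npv": Metric(None)}
    sens, spec = t.tp / n1, t.tn / n0
    ppv, npv = adjusted_predictive_values(sens, spec, prevalence)
    z = float(stats.norm.ppf(0.5 + level / 2))

    def logit_ci(point: float | None, var: float | None) -> Metric:
        if point is None:
            return Metric(None)
        if var is None or point in (0.0, 1.0):
            return Metric(value=point)
        lg = math.log(point / (1 - point))
        lo = 1 / (1 + math.exp(-(lg - z * math.sqrt(var))))
        hi = 1 / (1 + math.exp(-(lg + z * math.sqrt(var))))
        return Metric(value=point, ci_low=lo, ci_high=hi)

    var_ppv = var_npv = None
    if 0 < sens < 1 and 0 < spec < 1:
        var_ppv = (1 - sens) / (sens * n1) + spec / ((1 - spec) * n0)
        var_npv = (1 - spec) / (spec * n0) + sens / ((1 - sens) * n1)
    return {
        "adjusted_ppv": logit_ci(ppv, var_ppv),
        "adjusted_npv": logit_ci(npv, var_npv),
    }


def scenario_table(
    base: ConfusionTable, n_insufficient_af: int, n_insufficient_no_af: int,
    scenario: str,
) -> ConfusionTable:
    """Recode wholly-insufficient units into an exclusion-scenario table.

    Units (subjects or measurements) with no usable call are absent from the
    ``exclude`` table; recoding them as sinus adds them to the false/true
    negatives, recoding as AF adds them to the true/false positives.
    """
    if scenario == "exclude":
        return base
    if scenario == "as_sinus":
        return ConfusionTable(base.tp, base.fp,
                              base.fn + n_insufficient_af,
                              base.tn + n_insufficient_no_af)
    if scenario == "as_af":
        return ConfusionTable(base.tp + n_insufficient_af,
                              base.fp + n_insufficient_no_af,
                              base.fn, base.tn)
    raise ValueError(f"unknown scenario {scenario!r}")


@dataclass
class AccuracyReport:
    """One Table-style row set: a 2×2 table and all derived statistics."""

    level: str  # 'participant' | 'measurement'
    scenario: str
    modality: str
    table: ConfusionTable | None
    n: int
    prevalence_n: int
    external_prevalence: float
    metrics: dict[str, Metric] = field(default_factory=dict)
    adjusted: dict[str, Metric] = field(default_factory=dict)
    n_excluded: int = 0

    def to_dict(self) -> dict:
        def mdict(m: Metric) -> dict:
            return {"value": m.value, "k": m.k, "n": m.n,
                    "ci_low": m.ci_low, "ci_high": m.ci_high}

        return {
            "level": self.level,
            "scenario": self.scenario,
            "modality": self.modality,
            "table": None if self.table is None else vars(self.table),
            "n": self.n,
            "prevalence_n": self.prevalence_n,
            "n_excluded": self.n_excluded,
            "external_prevalence": self.external_prevalence,
            "metrics": {k: mdict(m) for k, m in self.metrics.items()},
            "adjusted": {k: mdict(m) for k, m in self.adjusted.items()},
        }


def _report_from_table(
    t: ConfusionTable | None, level: str, scenario: str, modality: str,
    external_prevalence: float, n_excluded: int = 0,
) -> AccuracyReport:
    if t is None:
        return AccuracyReport(level, scenario, modality, None, 0, 0,
                              external_prevalence, {}, {}, n_excluded)
    mets = metrics(t)
    adj: dict[str, Metric] = {}
    if mets["sensitivity"].defined and mets["specificity"].defined:
        adj = adjusted_predictive_cis(t, external_prevalence)
    return AccuracyReport(level, scenario, modality, t, t.n,
                          t.n_condition_positive, external_prevalence,
                          mets, adj, n_excluded)


def evaluate(
    calls: pd.DataFrame,
    gold: pd.DataFrame,
    levels: Iterable[str] = ("participant", "measurement"),
    scenarios: Iterable[str] = SCENARIOS,
    external_prevalence: float = 0.06,
    severity: Sequence[str] = ("af", "sinus"),
) -> list[AccuracyReport]:
    """Score a cohort's calls against gold labels at every level × scenario.

    ``calls`` needs columns subject_id, measurement_index, modality, call;
    ``gold`` needs subject_id, gold.  Participant-level results recode each
    subject's calls per scenario and then apply the majority rule; under
    the exclude scenario, subjects with no sufficient measurement are
    dropped (and counted in ``n_excluded``).  Measurement-level results
    score each recoded measurement directly.
    """
    required = {"subject_id", "measurement_index", "modality", "call"}
    if not required.issubset(calls.columns):
        raise ValueError(f"calls table needs columns {sorted(required)}")
    gold_map = dict(zip(gold["subject_id"], gold["gold"]))
    reports: list[AccuracyReport] = []

    for modality in sorted(calls["modality"].unique()):
        sub = calls[calls["modality"] == modality]
        per_subject = {
            sid: list(grp.sort_values("measurement_index")["call"])
            for sid, grp in sub.groupby("subject_id")
        }
        for scenario in scenarios:
            if "participant" in levels:
                idx_calls, gold_seq = [], []
                excluded = 0
                for sid, cl in per_subject.items():
                    outcome = aggregate_subject(sid, cl, scenario, severity).call
                    if outcome == "excluded":
                        excluded += 1
                        continue
                    idx_calls.append(outcome)
                    gold_seq.append(gold_map[sid])
                t = confusion(idx_calls, gold_seq) if idx_calls else None
                reports.append(_report_from_table(
                    t, "participant", scenario, modality,
                    external_prevalence, excluded))
            if "measurement" in levels:
                idx_calls, gold_seq = [], []
                excluded = 0
                for sid, cl in per_subject.items():
                    for c in cl:
                        if scenario == "exclude" and c == "insufficient":
                            excluded += 1
                            continue
                        if c == "insufficient":
                            c = "sinus" if scenario == "as_sinus" else "af"
                        idx_calls.append(c)
                        gold_seq.append(gold_map[sid])
                t = confusion(idx_calls, gold_seq) if idx_calls else None
                reports.append(_report_from_table(
                    t, "measurement", scenario, modality,
                    external_prevalence, excluded))
    return reports


def paired_agreement(
    calls_a: Sequence[str], calls_b: Sequence[str]
) -> dict[str, float | int]:
    """Agreement between two modalities' calls on the same units.

    Restricted to pairs where both calls are sufficient; returns the pair
    count, agreement count and percentage (None when no pair qualifies).
    """
    if len(calls_a) != len(calls_b):
        raise ValueError("call sequences must be aligned")
    both = [(a, b) for a, b in zip(calls_a, calls_b)
            if a != "insufficient" and b != "insufficient"]
    n = len(both)
    agree = sum(1 for a, b in both if a == b)
    return {
        "n_both_sufficient": n,
        "n_agree": agree,
        "percent": (100.0 * agree / n) if n else None,
    }
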