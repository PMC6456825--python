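"""Subject-level aggregation of repeated measurement calls.

Each subject performs several (by default three) consecutive measurements;
the subject-level result is a majority vote over the per-measurement calls.
Insufficient-quality calls are handled under three scenarios before the
vote: excluded, recoded as sinus rhythm, or recoded as possible AF.  When
the vote is tied (two discordant calls remaining after exclusion), the more
severe finding wins — in a screening context AF is the conservative call.
The severity ordering is configurable for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["SCENARIOS", "SubjectOutcome", "apply_scenario", "majority_rule",
           "aggregate_subject"]

SCENARIOS = ("exclude", "as_sinus", "as_af")


@dataclass(frozen=True)
class SubjectOutcome:
    subject_id: str
    scenario: str
    call: str  # 'af' | 'sinus' | 'excluded'


def apply_scenario(calls: Sequence[str], scenario: str) -> list[str]:
    """Recode insufficient-quality calls according to a scenario.

    exclude: drop them; as_sinus: treat as sinus rhythm; as_af: treat as
    possible AF.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    for c in calls:
        if c not in ("af", "sinus", "insufficient"):
            raise ValueError(f"unknown call {c!r}")
    if scenario == "exclude":
        return [c for c in calls if c != "insufficient"]
    sub = "sinus" if scenario == "as_sinus" else "af"
    return [sub if c == "insufficient" else c for c in calls]


def majority_rule(
    recoded: Sequence[str],
    scenario: str,
    severity: Sequence[str] = ("af", "sinus"),
) -> str:
    """Vote over recoded calls.

    Three calls decide by strict majority; two agreeing calls decide; two
    discordant calls fall to the most severe; a single call decides; no
    calls at all (possible only under the exclude scenario) yields
    ``excluded``.
    """
    if any(c == "insufficient" for c in recoded):
        raise ValueError("recoded calls must not contain 'insufficient'")
    n = len(recoded)
    if n == 0:
        if scenario != "exclude":
            raise ValueError("empty call list outside the exclude scenario")
        return "excluded"
    counts = {c: recoded.count(c) if isinstance(recoded, list)
              else list(recoded).count(c) for c in set(recoded)}
    top = max(counts.values())
    leaders = sorted(c for c, k in counts.items() if k == top)
    if len(leaders) == 1:
        return leaders[0]
    # tie: decide by severity
    for c in severity:
        if c in leaders:
            return c
    return leaders[0]


def aggregate_subject(
    subject_id: str,
    calls: Sequence[str],
    scenario: str,
    severity: Sequence[str] = ("af", "sinus"),
) -> SubjectOutcome:
    recoded = apply_scenario(calls, scenario)
    return SubjectOutcome(subject_id, scenario, majority_rule(recoded, scenario, severity))
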