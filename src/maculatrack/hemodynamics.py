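"""Mean arterial pressure and anchored cohort summaries.

MAP is computed with the standard one-third pulse-pressure formula,
MAP = DBP + (SBP - DBP) / 3, reported internally to 0.1 mmHg with integer
rounding only at presentation (112/70 -> 84, 150/100 -> 117).

Cohort summaries anchor each participant's MAP at a clinically meaningful
encounter -- enrollment (first pregnancy visit), the visit at which loss of
macular thinning (LOT) was first detected, or delivery -- and report the mean
with a Student-t 95% confidence interval.  Participants whose LOT is first
seen at the delivery encounter are excluded from the LOT anchor because the
pressure at the true moment of loss cannot be reliably estimated for them.
Rises between anchors are paired within participant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .trajectory import Encounter, ParticipantTrajectory

__all__ = [
    "ANCHORS",
    "BloodPressure",
    "MapSummary",
    "mean_arterial_pressure",
    "present_mmhg",
    "map_at_anchor",
    "map_rise",
]

ANCHORS: tuple[str, ...] = ("enrollment", "lot", "delivery")


@dataclass(frozen=True)
class BloodPressure:
    """One office blood pressure reading, mmHg."""

    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sbp) and math.isfinite(self.dbp)):
            raise ValueError("blood pressures must be finite")
        if not (40 <= self.dbp < self.sbp <= 300):
            raise ValueError(f"implausible blood pressure {self.sbp:.0f}/{self.dbp:.0f} mmHg")


def mean_arterial_pressure(bp: BloodPressure) -> float:
    """MAP = DBP + pulse pressure / 3, to 0.1 mmHg."""
    return round(bp.dbp + (bp.sbp - bp.dbp) / 3.0, 1)


def present_mmhg(map_mmhg: float) -> int:
    """Presentation rounding to the nearest integer mmHg."""
    return int(math.floor(map_mmhg + 0.5))


@dataclass
class MapSummary:
    """Mean MAP (or within-participant MAP difference) at an anchor, with 95% CI."""

    anchor: str
    n: int
    mean: float
    ci_lo: float
    ci_hi: float
    degenerate: bool = False  # single participant: CI undefined

    def row(self) -> dict:
        return {
            "anchor": self.anchor,
            "n": self.n,
            "mean": self.mean,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
        }


def _t_summary(anchor: str, values: Sequence[float]) -> MapSummary:
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError(f"no participants resolvable at anchor {anchor!r}")
    mean = float(x.mean())
    if n == 1:
        return MapSummary(anchor, 1, mean, math.nan, math.nan, degenerate=True)
    half = float(stats.t.ppf(0.975, n - 1) * x.std(ddof=1) / math.sqrt(n))
    return MapSummary(anchor, n, mean, mean - half, mean + half)


def _anchor_map(
    trajectory: "ParticipantTrajectory",
    pregnancy: list["Encounter"],
    anchor: str,
) -> float | None:
    """Resolve one participant's MAP at an anchor; None if not resolvable."""
    if anchor == "enrollment":
        return pregnancy[0].map_mmhg
    if anchor == "delivery":
        deliveries = [e for e in pregnancy if e.epoch == "delivery"]
        return deliveries[0].map_mmhg if deliveries else None
    if anchor == "lot":
        if trajectory.lot_ga is None or trajectory.lot_at_delivery:
            return None
        at = [e for e in pregnancy if e.gestational_age == trajectory.lot_ga]
        return at[0].map_mmhg if at else None
    raise ValueError(f"unknown anchor {anchor!r}; expected one of {ANCHORS}")


def _per_participant(
    encounters: Iterable["Encounter"],
    trajectories: Iterable["ParticipantTrajectory"],
    participants: Iterable[str] | None,
) -> list[tuple["ParticipantTrajectory", list["Encounter"]]]:
    keep = None if participants is None else set(participants)
    by_pid: dict[str, list] = {}
    for e in encounters:
        if e.epoch != "nonpregnant_baseline":
            by_pid.setdefault(e.participant_id, []).append(e)
    out = []
    for tr in trajectories:
        if keep is not None and tr.participant_id not in keep:
            continue
        encs = sorted(by_pid.get(tr.participant_id, []), key=lambda e: e.gestational_age)
        if encs:
            out.append((tr, encs))
    return out


def map_at_anchor(
    encounters: Iterable["Encounter"],
    trajectories: Iterable["ParticipantTrajectory"],
    anchor: str,
    participants: Iterable[str] | None = None,
) -> MapSummary:
    """Mean and t-based 95% CI of per-participant MAP at the anchor encounter."""
    values = []
    for tr, encs in _per_participant(encounters, trajectories, participants):
        v = _anchor_map(tr, encs, anchor)
        if v is not None:
            values.append(v)
    return _t_summary(anchor, values)


def map_rise(
    encounters: Iterable["Encounter"],
    trajectories: Iterable["ParticipantTrajectory"],
    from_anchor: str,
    to_anchor: str,
    participants: Iterable[str] | None = None,
) -> MapSummary:
    """Mean within-participant MAP difference to_anchor - from_anchor, with CI.

    Paired within participant; participants lacking either anchor are
    excluded.  On balanced complete data this equals the difference of the two
    anchor means, but the paired version is authoritative.
    """
    diffs = []
    for tr, encs in _per_participant(encounters, trajectories, participants):
        a = _anchor_map(tr, encs, from_anchor)
        b = _anchor_map(tr, encs, to_anchor)
        if a is not None and b is not None:
            diffs.append(b - a)
    return _t_summary(f"{from_anchor}->{to_anchor}", diffs)
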