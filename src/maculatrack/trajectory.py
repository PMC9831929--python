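"""Longitudinal classification of eyes and participants.

Each eye contributes an ordered sequence of selected scans: one non-pregnant
baseline (acquired postpartum, used purely as the reference state) and at
least three pregnancy encounters (<20 weeks, 20 weeks-delivery, delivery).
The contiguity rule drives four calls per eye:

* **early thinning** -- the rule fires in the thinning direction for
  (baseline -> pregnancy scan); the gestational age of the first firing is
  recorded (most eyes fire at the first, <20 week, scan).
* **loss of thinning (LOT)** -- the rule fires in the thickening direction on
  some *sequential* within-pregnancy pair (previous pregnancy scan ->
  current); a baseline image is deliberately not needed for this call.
* **sudden thinning events** -- sequential pairs firing in the thinning
  direction after thinning (or a LOT) is already established; candidate
  hypoperfusion injuries when they coincide with a systemic pressure drop.
* **overt thickening** -- a pregnancy scan thicker than the non-pregnant
  baseline by the rule (frank edema above baseline, rare).

Participants are labelled from their two eyes.  The eyes are treated as
independent measurements, but both eyes must be normal for a participant to
count as free of microvascular injury.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .change_rule import RuleParams, apply_rule, interval_change
from .grid import AdjacencyGraph
from .hemodynamics import BloodPressure, mean_arterial_pressure

if TYPE_CHECKING:  # pragma: no cover
    from .io import ScanRecord

__all__ = [
    "EPOCHS",
    "PREGNANCY_EPOCHS",
    "Encounter",
    "EyeTrajectory",
    "ParticipantTrajectory",
    "classify_eye",
    "detect_hypoperfusion",
    "classify_participant",
]

logger = logging.getLogger(__name__)

#: Pregnancy epochs in temporal order, then the non-pregnant reference state.
PREGNANCY_EPOCHS: tuple[str, ...] = ("early", "mid", "delivery")
EPOCHS: tuple[str, ...] = PREGNANCY_EPOCHS + ("nonpregnant_baseline",)

DEFAULT_MAP_DROP_MMHG = 15.0


@dataclass(frozen=True)
class Encounter:
    """One clinical visit: epoch, gestational age and office blood pressure."""

    participant_id: str
    encounter_id: str
    epoch: str
    gestational_age: float | None  # weeks; None for the non-pregnant baseline
    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if self.epoch not in EPOCHS:
            raise ValueError(f"unknown epoch {self.epoch!r}")
        if self.epoch == "nonpregnant_baseline":
            if self.gestational_age is not None:
                raise ValueError("baseline encounters carry no gestational age")
        else:
            if self.gestational_age is None:
                raise ValueError("pregnancy encounters require a gestational age")
            if self.epoch == "early" and not self.gestational_age < 20:
                raise ValueError("early encounters must be before 20 weeks gestation")
        BloodPressure(self.sbp, self.dbp)  # validates the pressure invariants

    @property
    def map_mmhg(self) -> float:
        return mean_arterial_pressure(BloodPressure(self.sbp, self.dbp))


@dataclass
class EyeTrajectory:
    """Rule-based longitudinal calls for a single eye."""

    participant_id: str
    eye: str
    early_thinning: bool
    early_thinning_ga: float | None
    lot: bool
    lot_ga: float | None
    lot_at_delivery: bool
    sudden_thinning_events: list[tuple[float, float]]  # (ga weeks, mean um in component)
    overt_thickening: bool


@dataclass
class ParticipantTrajectory:
    """Participant-level labels aggregated over both eyes."""

    participant_id: str
    label: str  # maintained_thinning | loss_of_thinning | no_early_thinning
    single_eye_lot: bool
    hypoperfusion: bool
    no_injury: bool
    lot_ga: float | None
    lot_at_delivery: bool
    early_thinning_ga: float | None


def _pregnancy_scans(
    scans: Sequence["ScanRecord"], encounters: Mapping[str, Encounter]
) -> tuple["ScanRecord", list[tuple[float, "ScanRecord"]]]:
    """Split one eye's scans into (baseline scan, time-ordered pregnancy scans)."""
    baseline = None
    pregnancy: list[tuple[float, "ScanRecord"]] = []
    for scan in scans:
        enc = encounters.get(scan.encounter_id)
        if enc is None:
            raise ValueError(f"scan references unknown encounter {scan.encounter_id!r}")
        if enc.participant_id != scan.participant_id:
            raise ValueError(f"encounter {scan.encounter_id!r} belongs to another participant")
        if enc.epoch == "nonpregnant_baseline":
            if baseline is not None:
                raise ValueError(f"multiple baseline scans for {scan.participant_id}/{scan.eye}")
            baseline = scan
        else:
            pregnancy.append((float(enc.gestational_age), scan))
    if baseline is None:
        raise ValueError(f"missing non-pregnant baseline scan for {scans[0].participant_id}/{scans[0].eye}")
    if not pregnancy:
        raise ValueError("at least one pregnancy scan is required")
    gas = [ga for ga, _ in pregnancy]
    if gas != sorted(gas):
        raise ValueError("pregnancy scans must be supplied in gestational-age order")
    return baseline, pregnancy


def _component_mean(diffs: Mapping[str, float], direction: str, params: RuleParams, graph: AdjacencyGraph) -> float:
    """Mean signed difference over sectors past the threshold in ``direction``."""
    if direction == "-":
        vals = [d for d in diffs.values() if d <= -params.tau]
    else:
        vals = [d for d in diffs.values() if d >= params.tau]
    return sum(vals) / len(vals) if vals else 0.0


def classify_eye(
    scans: Sequence["ScanRecord"],
    encounters: Mapping[str, Encounter],
    params: RuleParams = RuleParams(),
    graph: AdjacencyGraph | None = None,
) -> EyeTrajectory:
    """Classify one eye's scan sequence (baseline + ordered pregnancy scans)."""
    graph = graph if graph is not None else AdjacencyGraph()
    baseline, pregnancy = _pregnancy_scans(scans, encounters)

    early_thinning = False
    early_ga: float | None = None
    overt_thickening = False
    for ga, scan in pregnancy:
        res = apply_rule(interval_change(baseline.sectors, scan.sectors), params, graph)
        if res.fires_thinning and not early_thinning:
            early_thinning = True
            early_ga = ga
        if res.fires_thickening:
            overt_thickening = True

    lot = False
    lot_ga: float | None = None
    sudden: list[tuple[float, float]] = []
    for (ga_prev, prev), (ga_cur, cur) in zip(pregnancy, pregnancy[1:]):
        diffs = interval_change(prev.sectors, cur.sectors)
        res = apply_rule(diffs, params, graph)
        if res.fires_thickening and not lot:
            lot = True
            lot_ga = ga_cur
        if res.fires_thinning:
            thinning_established = early_thinning and early_ga is not None and early_ga < ga_cur
            lot_established = lot and lot_ga is not None and lot_ga < ga_cur
            if thinning_established or lot_established:
                sudden.append((ga_cur, _component_mean(diffs, "-", params, graph)))

    lot_at_delivery = False
    if lot:
        delivery_gas = {
            float(e.gestational_age)
            for e in encounters.values()
            if e.participant_id == baseline.participant_id and e.epoch == "delivery"
        }
        lot_at_delivery = lot_ga in delivery_gas

    return EyeTrajectory(
        participant_id=baseline.participant_id,
        eye=baseline.eye,
        early_thinning=early_thinning,
        early_thinning_ga=early_ga,
        lot=lot,
        lot_ga=lot_ga,
        lot_at_delivery=lot_at_delivery,
        sudden_thinning_events=sudden,
        overt_thickening=overt_thickening,
    )


def detect_hypoperfusion(
    eye: EyeTrajectory,
    encounters: Iterable[Encounter],
    drop_threshold: float = DEFAULT_MAP_DROP_MMHG,
) -> bool:
    """True iff a sudden thinning event coincides with a MAP drop >= threshold.

    The drop is measured against the immediately preceding pregnancy
    encounter.  Events whose blood pressures cannot be resolved are skipped
    with a warning.
    """
    pregnancy = sorted(
        (e for e in encounters if e.participant_id == eye.participant_id and e.epoch != "nonpregnant_baseline"),
        key=lambda e: e.gestational_age,
    )
    for ga, _magnitude in eye.sudden_thinning_events:
        idx = next((i for i, e in enumerate(pregnancy) if e.gestational_age == ga), None)
        if idx is None or idx == 0:
            logger.warning(
                "sudden thinning event at %.1f wks for %s/%s has no resolvable preceding encounter; skipped",
                ga, eye.participant_id, eye.eye,
            )
            continue
        drop = pregnancy[idx - 1].map_mmhg - pregnancy[idx].map_mmhg
        if drop >= drop_threshold:
            return True
    return False


def classify_participant(
    od: EyeTrajectory,
    os_eye: EyeTrajectory,
    encounters: Iterable[Encounter],
    drop_threshold: float = DEFAULT_MAP_DROP_MMHG,
) -> ParticipantTrajectory:
    """Aggregate the two eyes of one participant into a response label.

    Any eye with LOT makes the participant ``loss_of_thinning``; otherwise
    ``no_early_thinning`` if neither eye ever showed early thinning, else
    ``maintained_thinning``.  ``no_injury`` requires both eyes free of every
    adverse rule firing (LOT, sudden thinning, hypoperfusion, overt
    thickening); early thinning itself is the normal response, not an injury.
    """
    if od.participant_id != os_eye.participant_id:
        raise ValueError(f"participant mismatch: {od.participant_id!r} vs {os_eye.participant_id!r}")
    encounters = list(encounters)
    eyes = (od, os_eye)

    lot_eyes = [e for e in eyes if e.lot]
    if lot_eyes:
        label = "loss_of_thinning"
    elif not any(e.early_thinning for e in eyes):
        label = "no_early_thinning"
    else:
        label = "maintained_thinning"

    hypo = any(detect_hypoperfusion(e, encounters, drop_threshold) for e in eyes)
    no_injury = not any(
        e.lot or e.overt_thickening or e.sudden_thinning_events for e in eyes
    ) and not hypo

    lot_ga = min((e.lot_ga for e in lot_eyes), default=None)
    lot_at_delivery = bool(lot_eyes) and all(e.lot_at_delivery for e in lot_eyes if e.lot_ga == lot_ga)
    early_ga = min((e.early_thinning_ga for e in eyes if e.early_thinning_ga is not None), default=None)

    return ParticipantTrajectory(
        participant_id=od.participant_id,
        label=label,
        single_eye_lot=len(lot_eyes) == 1,
        hypoperfusion=hypo,
        no_injury=no_injury,
        lot_ga=lot_ga,
        lot_at_delivery=lot_at_delivery,
        early_thinning_ga=early_ga,
    )
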