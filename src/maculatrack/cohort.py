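"""Seeded synthetic cohorts with the study's statistical structure.

The generator emulates a prospective repeated-measures pregnancy cohort:
per participant one non-pregnant baseline plus pregnancy encounters at
<20 weeks, 20 weeks-delivery and delivery; per encounter and eye two
replicate SD-OCT scans whose test-retest noise is anchored to a 2 um
coefficient of repeatability (CoR = 1.96 * sqrt(2) * SD => SD = 0.7215 um);
and office blood pressures tracing group-specific mean-arterial-pressure
trajectories.

Four pregnancy groups are generated: non-hypertensive controls, de novo HDP
(hypertensive disorders of pregnancy arising without prior hypertension; all
lose their early macular thinning), HDP superimposed on chronic hypertension
with loss of thinning (chtn_lot), and chronic hypertension maintaining
thinning (chtn_nolot).  Group x epoch mean thickness changes are planted
exactly at the configured effects: every spatial deviation -- the patchy
contiguous loss-of-thinning (LOT) effacement and the sudden confluent
hypoperfusion thinning -- is mean-preserving within the eye (effaced sectors
are compensated by the remaining six), so at zero noise the sample group
means equal the configured truths to machine precision.

LOT is planted as a contiguous 3-sector effacement whose rebound between
consecutive scans equals ``lot.seq_jump`` (default 6 um, above the 4 um rule
threshold) at the onset visit and then grows slowly; affected eyes also get
extra early thinning on the effaced sectors so the effacement never lifts
the sectors meaningfully above baseline.  Hypoperfusion participants receive
one extra pre-delivery "crisis" encounter with surged blood pressure; their
delivery encounter pairs a sudden contiguous thinning with a >= 16 mmHg MAP
drop while still landing on the group's delivery MAP anchor.

``default_fixture`` is the deterministic acceptance cohort: same composition
(11 controls + 27 HDP = 12 de novo + 8 chtn_lot + 7 chtn_nolot; 20 LOT, 7
single-eye, 5 hypoperfusion, exactly one participant first thinning between
20 and 32 weeks) with all planted signals >= 6 um and no visit jitter, so
the classification counts are invariant to test-retest noise.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .grid import EYES, SECTORS, AdjacencyGraph, SectorMap
from .io import ScanRecord
from .trajectory import Encounter

__all__ = [
    "GroupEffects",
    "MapPlan",
    "LotSpec",
    "HypoSpec",
    "NoiseSpec",
    "Composition",
    "Schedule",
    "CohortConfig",
    "ParticipantTruth",
    "CohortData",
    "default_config",
    "fixture_config",
    "generate_cohort",
    "default_fixture",
    "load_config",
]

DEFAULT_SEED = 20210617

#: Default per-sector non-pregnant mean thickness, um (centre lowest).
DEFAULT_BASELINE_SECTORS: dict[str, float] = {
    "C": 250.0,
    "IS": 284.0, "IN": 286.0, "II": 283.0, "IT": 281.0,
    "OS": 269.0, "ON": 272.0, "OI": 266.0, "OT": 262.0,
}


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GroupEffects(_Model):
    """Mean thinning from non-pregnant baseline per epoch (um, positive = thinner)."""

    early: float = Field(gt=0)
    mid: float = Field(gt=0)
    delivery: float = Field(gt=0)

    def magnitude(self, epoch: str) -> float:
        return getattr(self, epoch)


class MapPlan(_Model):
    """Within-participant mean-arterial-pressure trajectory anchors, mmHg."""

    enroll_mean: float
    enroll_sd: float = Field(4.0, ge=0)
    mid_step_mean: float = 0.0
    delivery_step_mean: float = 0.0
    step_sd: float = Field(3.0, ge=0)
    baseline_mean: float = 85.0


class LotSpec(_Model):
    """Planted loss-of-thinning pattern."""

    n_sectors: int = Field(3, ge=1, le=8)
    early_extra: float = Field(3.0, ge=0)   # extra early thinning on effaced sectors, um
    seq_jump: float = Field(6.0, gt=0)      # sequential rebound at onset, um
    growth: float = Field(0.5, ge=0)        # further effacement per later epoch, um


class HypoSpec(_Model):
    """Planted sudden hypoperfusion thinning and its systemic pressure drop.

    With ``compensate`` the thinning is redistributed within the eye so group
    means stay exact; without it the injury is planted as a plain confluent
    loss (used by the fixture, where a large unambiguous signal matters more
    than mean exactness).
    """

    sudden_um: float = Field(6.0, gt=0)
    compensate: bool = True
    map_drop_mean: float = Field(21.0, gt=0)
    map_drop_sd: float = Field(2.0, ge=0)
    map_drop_min: float = Field(16.0, gt=0)


class NoiseSpec(_Model):
    """All noise scales, um (pressure jitter lives in MapPlan)."""

    replicate_sd: float = Field(0.7215, ge=0)   # CoR 2 um / (1.96 * sqrt 2)
    participant_sd: float = Field(0.6, ge=0)    # response heterogeneity
    eye_sd: float = Field(0.35, ge=0)
    sector_sd: float = Field(0.35, ge=0)
    visit_sd: float = Field(0.5, ge=0)          # biological visit-level fluctuation
    visit_corr_length: float = Field(20.0, gt=0)  # weeks; corr = exp(-dt / length)
    level_participant_sd: float = Field(12.0, ge=0)  # absolute-thickness offsets
    level_eye_sd: float = Field(2.5, ge=0)
    level_sector_sd: float = Field(1.5, ge=0)


class Composition(_Model):
    """Cohort composition; the defaults reproduce the study's published counts."""

    n_control: int = Field(11, ge=0)
    n_denovo: int = Field(12, ge=0)
    n_chtn_lot: int = Field(8, ge=0)
    n_chtn_nolot: int = Field(7, ge=0)
    single_eye_denovo: int = Field(4, ge=0)
    single_eye_chtn_lot: int = Field(3, ge=0)
    delivery_onset_chtn_lot: int = Field(3, ge=0)
    hypo_denovo: int = Field(2, ge=0)
    hypo_chtn_lot: int = Field(2, ge=0)
    hypo_chtn_nolot: int = Field(1, ge=0)
    n_late_early: int = Field(1, ge=0)  # chtn_nolot participants first thinning at the mid visit

    @model_validator(mode="after")
    def _feasible(self) -> "Composition":
        problems = []
        if self.single_eye_denovo + self.hypo_denovo > self.n_denovo:
            problems.append("de novo flags exceed group size")
        if self.single_eye_chtn_lot + self.delivery_onset_chtn_lot + self.hypo_chtn_lot > self.n_chtn_lot:
            problems.append("chtn_lot flags exceed group size")
        if self.hypo_chtn_nolot + self.n_late_early > self.n_chtn_nolot:
            problems.append("chtn_nolot flags exceed group size")
        if problems:
            raise ValueError("; ".join(problems))
        return self


class Schedule(_Model):
    """Visit schedule, weeks of gestation (baseline is postpartum)."""

    early_week: float = Field(12.0, gt=0, lt=20)
    mid_week: float = 30.0
    delivery_week: float = 38.0
    crisis_lead: float = Field(2.0, gt=0)  # crisis visit at delivery - lead
    visit_jitter: float = Field(2.0, ge=0)
    baseline_weeks_postpartum: float = Field(31.0, gt=0)


class CohortConfig(_Model):
    """Every generator parameter, including the seed."""

    effects: dict[str, GroupEffects] = Field(
        default_factory=lambda: {
            "control": GroupEffects(early=3.92, mid=3.08, delivery=5.16),
            "denovo_hdp": GroupEffects(early=4.35, mid=2.99, delivery=3.45),
            "chtn_lot": GroupEffects(early=3.39, mid=2.85, delivery=1.06),
            "chtn_nolot": GroupEffects(early=3.91, mid=3.80, delivery=4.46),
        }
    )
    map_plans: dict[str, MapPlan] = Field(
        default_factory=lambda: {
            "control": MapPlan(enroll_mean=84.0, mid_step_mean=2.0, delivery_step_mean=5.0, baseline_mean=84.0),
            "denovo_hdp": MapPlan(enroll_mean=84.0, mid_step_mean=-2.0, delivery_step_mean=19.0, baseline_mean=85.0),
            "chtn_lot": MapPlan(enroll_mean=87.0, mid_step_mean=11.0, delivery_step_mean=4.0, baseline_mean=92.0),
            "chtn_nolot": MapPlan(enroll_mean=92.0, mid_step_mean=5.0, delivery_step_mean=20.0, baseline_mean=93.0),
        }
    )
    baseline_sectors: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_BASELINE_SECTORS))
    late_early_change: float = Field(1.0, ge=0)  # early thinning of the late-onset participant, um
    lot: LotSpec = Field(default_factory=LotSpec)
    hypo: HypoSpec = Field(default_factory=HypoSpec)
    noise: NoiseSpec = Field(default_factory=NoiseSpec)
    composition: Composition = Field(default_factory=Composition)
    schedule: Schedule = Field(default_factory=Schedule)
    plant_spatial: bool = True  # False: labels only, no effacement/sudden patterns
    signal_strength_range: tuple[float, float] = (7.0, 10.0)
    pulse_pressure_mean: float = 42.0
    pulse_pressure_sd: float = 5.0
    seed: int = DEFAULT_SEED

    @model_validator(mode="after")
    def _validate(self) -> "CohortConfig":
        problems = []
        for name, d in (("effects", self.effects), ("map_plans", self.map_plans)):
            missing = {"control", "denovo_hdp", "chtn_lot", "chtn_nolot"} - set(d)
            if missing:
                problems.append(f"{name} missing groups {sorted(missing)}")
        if set(self.baseline_sectors) != set(SECTORS):
            problems.append("baseline_sectors must cover exactly the 9 ETDRS sectors")
        lo, hi = self.signal_strength_range
        if not (0 <= lo <= hi <= 10):
            problems.append("signal_strength_range must satisfy 0 <= lo <= hi <= 10")
        if problems:
            raise ValueError("; ".join(problems))
        return self


def default_config(seed: int = DEFAULT_SEED) -> CohortConfig:
    """Shipped default configuration: effect sizes at the published values."""
    return CohortConfig(seed=seed)


def fixture_config(seed: int = DEFAULT_SEED) -> CohortConfig:
    """Acceptance-fixture configuration: boosted (>= 6 um) planted signals, no
    visit jitter, so the classification counts are deterministic."""
    cfg = CohortConfig(seed=seed)
    return cfg.model_copy(
        update={
            "effects": {
                # Non-LOT trajectories are monotone (no early->mid rebound) so
                # the only sequential thickening anywhere near the threshold is
                # the planted effacement itself.
                "control": GroupEffects(early=7.0, mid=7.0, delivery=8.0),
                "denovo_hdp": GroupEffects(early=7.0, mid=6.0, delivery=5.0),
                "chtn_lot": GroupEffects(early=7.0, mid=6.0, delivery=5.0),
                "chtn_nolot": GroupEffects(early=7.0, mid=7.0, delivery=7.0),
            },
            "lot": LotSpec(n_sectors=3, early_extra=4.0, seq_jump=8.0, growth=0.5),
            "hypo": HypoSpec(sudden_um=10.0, compensate=False),
            "schedule": Schedule(visit_jitter=0.0),
        }
    )


@dataclass
class ParticipantTruth:
    """Planted ground truth for one participant."""

    participant_id: str
    group: str
    label: str
    lot: bool
    lot_onset_week: float | None
    lot_eyes: tuple[str, ...]
    single_eye_lot: bool
    lot_at_delivery: bool
    hypoperfusion: bool
    hypo_eye: str | None
    late_early: bool
    map_enroll: float
    map_lot: float | None
    map_delivery: float
    effaced_sectors: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class CohortData:
    """Generator output: scans, encounters and planted truth."""

    scans: list[ScanRecord]
    encounters: list[Encounter]
    truth: list[ParticipantTruth]
    config: CohortConfig

    def encounters_by_id(self) -> dict[str, Encounter]:
        return {e.encounter_id: e for e in self.encounters}

    def groups(self) -> dict[str, str]:
        return {t.participant_id: t.group for t in self.truth}

    def truth_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "participant_id": t.participant_id,
                    "group": t.group,
                    "label": t.label,
                    "lot": t.lot,
                    "lot_onset_week": t.lot_onset_week,
                    "single_eye_lot": t.single_eye_lot,
                    "lot_at_delivery": t.lot_at_delivery,
                    "hypoperfusion": t.hypoperfusion,
                    "late_early": t.late_early,
                    "map_enroll": t.map_enroll,
                    "map_lot": t.map_lot,
                    "map_delivery": t.map_delivery,
                }
                for t in self.truth
            ]
        )


# ---------------------------------------------------------------------------
# generation internals


def _contiguous_subset(rng: np.random.Generator, size: int, graph: AdjacencyGraph) -> tuple[str, ...]:
    """A random connected sector subset grown by seeded neighbour accretion."""
    start = SECTORS[rng.integers(9)]
    chosen = {start}
    while len(chosen) < size:
        frontier = sorted({nb for s in chosen for nb in graph.neighbors[s]} - chosen)
        chosen.add(frontier[rng.integers(len(frontier))])
    return tuple(s for s in SECTORS if s in chosen)


def _bp_from_map(rng: np.random.Generator, map_mmhg: float, pp_mean: float, pp_sd: float) -> tuple[float, float]:
    """Integer office SBP/DBP whose one-third-pulse-pressure MAP tracks the plan."""
    pp = float(np.clip(rng.normal(pp_mean, pp_sd), 28.0, 75.0))
    dbp = float(np.round(map_mmhg - pp / 3.0))
    sbp = float(dbp + np.round(pp))
    dbp = max(dbp, 41.0)
    if sbp <= dbp:
        sbp = dbp + 10.0
    return sbp, dbp


@dataclass
class _Plan:
    pid: str
    group: str
    lot_eyes: tuple[str, ...]
    onset_epoch: str | None  # "mid" or "delivery"
    hypo_eye: str | None
    late_early: bool


def _build_plans(comp: Composition, rng: np.random.Generator) -> list[_Plan]:
    plans: list[_Plan] = []
    counter = 0

    def next_pid() -> str:
        nonlocal counter
        counter += 1
        return f"P{counter:03d}"

    for _ in range(comp.n_control):
        plans.append(_Plan(next_pid(), "control", (), None, None, False))

    # de novo HDP: every participant loses thinning at the mid visit
    idx = list(rng.permutation(comp.n_denovo))
    single = set(idx[: comp.single_eye_denovo])
    hypo = set(idx[comp.single_eye_denovo : comp.single_eye_denovo + comp.hypo_denovo])
    for i in range(comp.n_denovo):
        eyes = (EYES[int(rng.integers(2))],) if i in single else EYES
        hypo_eye = eyes[int(rng.integers(len(eyes)))] if i in hypo else None
        plans.append(_Plan(next_pid(), "denovo_hdp", tuple(eyes), "mid", hypo_eye, False))

    # chronic hypertension with LOT: some single-eye, some first seen at delivery
    idx = list(rng.permutation(comp.n_chtn_lot))
    single = set(idx[: comp.single_eye_chtn_lot])
    late = set(idx[comp.single_eye_chtn_lot : comp.single_eye_chtn_lot + comp.delivery_onset_chtn_lot])
    hypo = set(
        idx[
            comp.single_eye_chtn_lot
            + comp.delivery_onset_chtn_lot : comp.single_eye_chtn_lot
            + comp.delivery_onset_chtn_lot
            + comp.hypo_chtn_lot
        ]
    )
    for i in range(comp.n_chtn_lot):
        eyes = (EYES[int(rng.integers(2))],) if i in single else EYES
        onset = "delivery" if i in late else "mid"
        hypo_eye = eyes[int(rng.integers(len(eyes)))] if i in hypo else None
        plans.append(_Plan(next_pid(), "chtn_lot", tuple(eyes), onset, hypo_eye, False))

    # chronic hypertension maintaining thinning
    idx = list(rng.permutation(comp.n_chtn_nolot))
    hypo = set(idx[: comp.hypo_chtn_nolot])
    late_early = set(idx[comp.hypo_chtn_nolot : comp.hypo_chtn_nolot + comp.n_late_early])
    for i in range(comp.n_chtn_nolot):
        hypo_eye = EYES[int(rng.integers(2))] if i in hypo else None
        plans.append(_Plan(next_pid(), "chtn_nolot", (), None, hypo_eye, i in late_early))
    return plans


def _spread_cents(total: float, n: int) -> np.ndarray:
    """Split ``total`` (um) into n parts on the 0.01 um grid with an exact sum.

    Planted deviations must both live on the storage grid (so zero-noise
    scans round losslessly) and sum to zero within the eye (so group means
    stay exact); largest-remainder distribution achieves both.
    """
    cents = int(round(total * 100))
    base, rem = divmod(cents, n)
    parts = np.full(n, base, dtype=float)
    parts[:rem] += 1
    return parts / 100.0


def _sector_deviation(
    cfg: CohortConfig,
    plan: _Plan,
    eye: str,
    effaced: Mapping[str, tuple[str, ...]],
    hypo_set: tuple[str, ...] | None,
) -> dict[str, np.ndarray]:
    """Mean-preserving per-sector deviation (um of *change*) per epoch key.

    Positive deviation = thicker than the group's epoch mean.  Each planted
    pattern sums to zero over the 9 sectors, so group x epoch means stay at
    the configured effects exactly.
    """
    mu = cfg.effects[plan.group]
    dev = {k: np.zeros(9) for k in ("early", "mid", "delivery")}
    if not cfg.plant_spatial:
        return dev

    def add(sectors: tuple[str, ...], epoch: str, amount: float, compensate: bool = True) -> None:
        sel = np.array([s in sectors for s in SECTORS])
        amt = round(float(amount), 2)
        dev[epoch][sel] += amt
        if compensate:
            dev[epoch][~sel] -= _spread_cents(amt * int(sel.sum()), int((~sel).sum()))

    if eye in plan.lot_eyes:
        F = effaced[eye]
        e0 = cfg.lot.early_extra
        add(F, "early", -e0)
        if plan.onset_epoch == "mid":
            d_mid = -e0 + cfg.lot.seq_jump - (mu.early - mu.mid)
            add(F, "mid", d_mid)
            add(F, "delivery", d_mid + cfg.lot.growth)
        else:  # first effacement at the delivery scan
            add(F, "mid", -e0)
            add(F, "delivery", -e0 + cfg.lot.seq_jump - (mu.mid - mu.delivery))

    if hypo_set is not None:
        add(hypo_set, "delivery", -cfg.hypo.sudden_um, compensate=cfg.hypo.compensate)
    return dev


def generate_cohort(config: CohortConfig | None = None) -> CohortData:
    """Generate scans, encounters and ground truth; bit-reproducible per seed."""
    cfg = config if config is not None else default_config()
    rng = np.random.default_rng(cfg.seed)
    graph = AdjacencyGraph()
    sched = cfg.schedule
    noise = cfg.noise
    base = np.array([cfg.baseline_sectors[s] for s in SECTORS])

    plans = _build_plans(cfg.composition, rng)

    # Group-level compensation keeping the early-epoch mean exact despite the
    # late-onset participant's reduced early thinning.
    late_comp: dict[str, float] = {}  # per-participant, on the 0.01 um grid
    for g in cfg.effects if cfg.plant_spatial else ():
        members = [p for p in plans if p.group == g]
        late = [p for p in members if p.late_early]
        others = [p for p in members if not p.late_early]
        if late and others:
            deficit = round(cfg.effects[g].early - cfg.late_early_change, 2) * len(late)
            shares = _spread_cents(deficit, len(others))
            for p, share in zip(others, shares):
                late_comp[p.pid] = -float(share)  # extra thinning for the others

    scans: list[ScanRecord] = []
    encounters: list[Encounter] = []
    truths: list[ParticipantTruth] = []

    for plan in plans:
        mu = cfg.effects[plan.group]
        mp = cfg.map_plans[plan.group]
        jit = sched.visit_jitter

        t_early = float(np.clip(sched.early_week + rng.uniform(-jit, jit), 6.0, 19.5))
        t_delivery = float(sched.delivery_week + rng.uniform(-jit, jit))
        t_mid = float(np.clip(sched.mid_week + rng.uniform(-jit, jit), 20.5, t_delivery - 3.0))
        visit_weeks: list[tuple[str, str, float]] = [("early", "early", t_early), ("mid", "mid", t_mid)]
        if plan.hypo_eye is not None:
            visit_weeks.append(("mid", "crisis", t_delivery - sched.crisis_lead))
        visit_weeks.append(("delivery", "delivery", t_delivery))
        t_baseline = t_delivery + sched.baseline_weeks_postpartum

        # ---- blood pressures -------------------------------------------------
        map_enroll = float(rng.normal(mp.enroll_mean, mp.enroll_sd))
        map_mid = map_enroll + float(rng.normal(mp.mid_step_mean, mp.step_sd))
        map_delivery = map_mid + float(rng.normal(mp.delivery_step_mean, mp.step_sd))
        map_crisis = None
        if plan.hypo_eye is not None:
            drop = max(float(rng.normal(cfg.hypo.map_drop_mean, cfg.hypo.map_drop_sd)), cfg.hypo.map_drop_min)
            map_crisis = map_delivery + drop
        map_baseline = float(rng.normal(mp.baseline_mean, mp.enroll_sd))
        visit_maps = {"early": map_enroll, "mid": map_mid, "crisis": map_crisis, "delivery": map_delivery}

        enc_ids: dict[str, str] = {}
        for i, (epoch, tag, week) in enumerate(visit_weeks, start=1):
            eid = f"{plan.pid}-E{i}"
            enc_ids[tag] = eid
            sbp, dbp = _bp_from_map(rng, visit_maps[tag], cfg.pulse_pressure_mean, cfg.pulse_pressure_sd)
            encounters.append(Encounter(plan.pid, eid, epoch, week, sbp, dbp))
        eid_base = f"{plan.pid}-E0"
        sbp, dbp = _bp_from_map(rng, map_baseline, cfg.pulse_pressure_mean, cfg.pulse_pressure_sd)
        encounters.append(Encounter(plan.pid, eid_base, "nonpregnant_baseline", None, sbp, dbp))

        # ---- planted spatial patterns ---------------------------------------
        effaced = {eye: _contiguous_subset(rng, cfg.lot.n_sectors, graph) for eye in plan.lot_eyes}
        hypo_sets: dict[str, tuple[str, ...] | None] = {eye: None for eye in EYES}
        if plan.hypo_eye is not None:
            hypo_sets[plan.hypo_eye] = (
                effaced[plan.hypo_eye]
                if plan.hypo_eye in effaced
                else _contiguous_subset(rng, cfg.lot.n_sectors, graph)
            )

        # ---- thickness truths and replicate scans ---------------------------
        level_p = rng.normal(0.0, noise.level_participant_sd)
        resp_p = rng.normal(0.0, noise.participant_sd)
        for eye in EYES:
            level_e = rng.normal(0.0, noise.level_eye_sd)
            resp_e = rng.normal(0.0, noise.eye_sd)
            level_s = rng.normal(0.0, noise.level_sector_sd, 9)
            resp_s = rng.normal(0.0, noise.sector_sd, 9)
            dev = _sector_deviation(cfg, plan, eye, effaced, hypo_sets[eye])

            # visit-level AR fluctuation over the eye's encounter times
            times = [w for (_, _, w) in visit_weeks] + [t_baseline]
            v = np.empty(len(times))
            v[0] = rng.normal(0.0, noise.visit_sd)
            for i in range(1, len(times)):
                phi = float(np.exp(-abs(times[i] - times[i - 1]) / noise.visit_corr_length))
                v[i] = phi * v[i - 1] + noise.visit_sd * np.sqrt(max(1.0 - phi * phi, 0.0)) * rng.standard_normal()

            nonpreg = base + level_p + level_e + level_s
            for i, (epoch, tag, _week) in enumerate(visit_weeks + [("nonpregnant_baseline", "baseline", t_baseline)]):
                if epoch == "nonpregnant_baseline":
                    truth_vals = nonpreg + v[i]
                    eid = eid_base
                else:
                    change = -mu.magnitude(epoch) + dev[epoch] + resp_p + resp_e + resp_s
                    if epoch == "early" and plan.late_early and cfg.plant_spatial:
                        change = change + round(mu.early - cfg.late_early_change, 2)
                    elif epoch == "early" and plan.pid in late_comp:
                        change = change + late_comp[plan.pid]
                    truth_vals = nonpreg + change + v[i]
                    eid = enc_ids[tag]
                for rep in (1, 2):
                    vals = truth_vals + rng.normal(0.0, noise.replicate_sd, 9)
                    ss = round(float(rng.uniform(*cfg.signal_strength_range)), 1)
                    scans.append(
                        ScanRecord(
                            participant_id=plan.pid,
                            eye=eye,
                            encounter_id=eid,
                            replicate=rep,
                            signal_strength=ss,
                            sectors=SectorMap(dict(zip(SECTORS, vals)), laterality=eye),
                        )
                    )

        lot = bool(plan.lot_eyes)
        onset_week = None
        if lot:
            onset_week = t_mid if plan.onset_epoch == "mid" else t_delivery
        truths.append(
            ParticipantTruth(
                participant_id=plan.pid,
                group=plan.group,
                label="loss_of_thinning" if lot else "maintained_thinning",
                lot=lot,
                lot_onset_week=onset_week,
                lot_eyes=plan.lot_eyes,
                single_eye_lot=len(plan.lot_eyes) == 1,
                lot_at_delivery=lot and plan.onset_epoch == "delivery",
                hypoperfusion=plan.hypo_eye is not None,
                hypo_eye=plan.hypo_eye,
                late_early=plan.late_early,
                map_enroll=map_enroll,
                map_lot=map_mid if (lot and plan.onset_epoch == "mid") else None,
                map_delivery=map_delivery,
                effaced_sectors=dict(effaced),
            )
        )

    return CohortData(scans=scans, encounters=encounters, truth=truths, config=cfg)


def default_fixture(seed: int = DEFAULT_SEED) -> CohortData:
    """The deterministic acceptance cohort (see module docstring)."""
    return generate_cohort(fixture_config(seed))


def load_config(path) -> CohortConfig:
    """Load a cohort configuration from YAML (validated)."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return CohortConfig.model_validate(payload or {})


def shipped_default_config_path():
    """Path to the full default configuration file shipped with the package."""
    return importlib.resources.files("maculatrack").joinpath("data/default_config.yaml")
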