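"""End-to-end pipeline: select scans, calibrate, classify, fit, summarise.

The pipeline can run in ``simulate`` mode (generate a synthetic cohort from a
:class:`~maculatrack.cohort.CohortConfig`) or on user-supplied scan and
encounter CSV files plus a participant->group table.  Every stage writes its
CSV output into the chosen output directory, and a short text report collects
the headline numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import io as mio
from .change_rule import DEFAULT_K_GRID, DEFAULT_TAU_GRID, RuleParams, calibrate_null
from .cohort import CohortConfig, generate_cohort
from .grid import AdjacencyGraph
from .hemodynamics import ANCHORS, map_at_anchor, map_rise
from .interval_model import GROUPS, build_long_table, fit_interval_model, pool_hdp
from .trajectory import DEFAULT_MAP_DROP_MMHG, classify_eye, classify_participant

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    simulate: bool = True
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    scans_path: str | None = None
    encounters_path: str | None = None
    groups_path: str | None = None  # CSV: participant_id, group
    rule: dict = Field(default_factory=lambda: {"tau": 4.0, "k": 3})
    map_drop_threshold: float = DEFAULT_MAP_DROP_MMHG
    out_dir: str = "maculatrack-out"


@dataclass
class PipelineReport:
    counts: dict[str, int] = field(default_factory=dict)
    p_at_rule: float | None = None
    n_pairs: int | None = None
    outputs: list[str] = field(default_factory=list)

    def text(self) -> str:
        lines = ["maculatrack pipeline report", "=" * 27, ""]
        lines.append("participant classification counts:")
        for k, v in sorted(self.counts.items()):
            lines.append(f"  {k}: {v}")
        if self.p_at_rule is not None:
            lines.append("")
            lines.append(f"empirical null exceedance at the configured rule: {self.p_at_rule:.4f} ({self.n_pairs} pairs)")
        lines.append("")
        lines.append("outputs:")
        lines.extend(f"  {p}" for p in self.outputs)
        return "\n".join(lines) + "\n"


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        cohort = generate_cohort(config.cohort)
        return cohort.scans, cohort.encounters, cohort.groups()
    for name in ("scans_path", "encounters_path", "groups_path"):
        if getattr(config, name) is None:
            raise PipelineError("io", f"{name} is required when simulate is false")
    scans = mio.read_scans(config.scans_path)
    encounters = mio.read_encounters(config.encounters_path)
    gdf = pd.read_csv(config.groups_path, dtype=str)
    if not {"participant_id", "group"} <= set(gdf.columns):
        raise PipelineError("io", "groups table needs participant_id and group columns")
    return scans, encounters, dict(zip(gdf["participant_id"], gdf["group"]))


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport()
    graph = AdjacencyGraph()
    params = RuleParams(**config.rule)

    scans, encounters, groups = _load_inputs(config)
    enc_by_id = {e.encounter_id: e for e in encounters}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        report.outputs.append(str(path))

    if config.simulate:
        emit("scans.csv", lambda p: mio.write_scans(scans, p))
        emit("encounters.csv", lambda p: mio.write_encounters(encounters, p))

    # ---- better-of-two selection + empirical null calibration ---------------
    try:
        selected = mio.select_better(scans)
        pairs = mio.replicate_pairs(scans)
        if not pairs:
            raise ValueError("no replicate pairs available for null calibration")
        calibration = calibrate_null(pairs, DEFAULT_TAU_GRID, DEFAULT_K_GRID, graph, params)
    except ValueError as err:
        raise PipelineError("change_rule", str(err)) from err
    report.p_at_rule = calibration.p_at_rule
    report.n_pairs = calibration.n_pairs
    emit("calibration.csv", calibration.to_csv)

    # ---- trajectory classification ------------------------------------------
    try:
        by_eye: dict[tuple[str, str], list] = {}
        for s in selected:
            by_eye.setdefault((s.participant_id, s.eye), []).append(s)
        eye_trajs = {}
        for (pid, eye), recs in sorted(by_eye.items()):
            recs.sort(key=lambda r: (
                enc_by_id[r.encounter_id].gestational_age is None,
                enc_by_id[r.encounter_id].gestational_age or 0.0,
            ))
            try:
                eye_trajs[(pid, eye)] = classify_eye(recs, enc_by_id, params, graph)
            except ValueError as err:
                logger.warning("dropping %s/%s from classification: %s", pid, eye, err)
        participants = sorted({pid for pid, _ in eye_trajs})
        trajectories = []
        for pid in participants:
            if ((pid, "OD") not in eye_trajs) or ((pid, "OS") not in eye_trajs):
                logger.warning("dropping %s from classification: missing an eye", pid)
                continue
            trajectories.append(
                classify_participant(
                    eye_trajs[(pid, "OD")], eye_trajs[(pid, "OS")], encounters, config.map_drop_threshold
                )
            )
    except (KeyError, ValueError) as err:
        raise PipelineError("trajectory", str(err)) from err

    tdf = pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "group": groups.get(t.participant_id, ""),
                "label": t.label,
                "single_eye_lot": t.single_eye_lot,
                "hypoperfusion": t.hypoperfusion,
                "lot_ga": t.lot_ga,
                "early_thinning_ga": t.early_thinning_ga,
            }
            for t in trajectories
        ]
    )
    emit("participants.csv", lambda p: tdf.to_csv(p, index=False))

    hdp = tdf[tdf["group"].isin(("denovo_hdp", "chtn_lot", "chtn_nolot"))]
    report.counts = {
        "participants": len(tdf),
        "hdp_participants": len(hdp),
        "hdp_loss_of_thinning": int((hdp["label"] == "loss_of_thinning").sum()),
        "hdp_single_eye_lot": int(((hdp["label"] == "loss_of_thinning") & hdp["single_eye_lot"]).sum()),
        "hdp_early_thinning_lt20w": int((hdp["early_thinning_ga"] < 20).sum()),
        "hdp_hypoperfusion": int(hdp["hypoperfusion"].sum()),
    }

    # ---- interval mixed model ------------------------------------------------
    try:
        table = build_long_table(selected, encounters, groups)
        fit_groups = fit_interval_model(table, by_group=True)
        fit_pooled = fit_interval_model(pool_hdp(table), by_group=True)
    except (ValueError, RuntimeError) as err:
        raise PipelineError("interval_model", str(err)) from err
    emit("interval_estimates_by_group.csv", fit_groups.to_csv)
    emit("interval_estimates_pooled.csv", fit_pooled.to_csv)

    # ---- MAP summaries --------------------------------------------------------
    rows = []
    for group in GROUPS:
        pids = [p for p, g in groups.items() if g == group]
        if not pids:
            continue
        for anchor in ANCHORS:
            try:
                s = map_at_anchor(encounters, trajectories, anchor, pids)
            except ValueError:
                continue  # anchor unresolvable for this group (e.g. no LOT)
            rows.append({"group": group, **s.row()})
        try:
            r = map_rise(encounters, trajectories, "lot", "delivery", pids)
            rows.append({"group": group, **r.row()})
        except ValueError:
            pass
    emit("map_summaries.csv", lambda p: pd.DataFrame(rows).to_csv(p, index=False))

    emit("report.txt", lambda p: Path(p).write_text(report.text(), encoding="utf-8"))
    logger.info("pipeline complete; outputs in %s", out)
    return report
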