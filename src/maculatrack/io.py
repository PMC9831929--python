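"""Tabular readers/writers and better-of-two scan selection.

All tables are UTF-8 comma-separated files with a header row and dot
decimals.  Scan tables carry one row per scan with the 9 sector thicknesses
in the fixed order C, IS, IN, II, IT, OS, ON, OI, OT; encounter tables carry
one row per clinical visit.  Round-trips are stable to the 0.01 um storage
resolution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .grid import EYES, SECTORS, SectorMap
from .trajectory import Encounter

__all__ = [
    "SCAN_COLUMNS",
    "ENCOUNTER_COLUMNS",
    "ScanRecord",
    "select_better_scan",
    "select_better",
    "replicate_pairs",
    "read_scans",
    "write_scans",
    "read_encounters",
    "write_encounters",
]

logger = logging.getLogger(__name__)

SCAN_COLUMNS = ["participant_id", "eye", "encounter_id", "replicate", "signal_strength", *SECTORS]
ENCOUNTER_COLUMNS = ["participant_id", "encounter_id", "epoch", "gestational_age", "sbp", "dbp"]


@dataclass(frozen=True)
class ScanRecord:
    """One SD-OCT scan: sector map plus acquisition metadata."""

    participant_id: str
    eye: str
    encounter_id: str
    replicate: int
    signal_strength: float
    sectors: SectorMap

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        if self.replicate not in (1, 2):
            raise ValueError("replicate index must be 1 or 2")
        if not 0 <= self.signal_strength <= 10:
            raise ValueError("signal_strength must be in [0, 10]")
        if self.sectors.laterality != self.eye:
            raise ValueError("sector map laterality must match the scan's eye")

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.participant_id, self.eye, self.encounter_id, self.replicate)


def select_better_scan(r1: ScanRecord, r2: ScanRecord) -> ScanRecord:
    """The replicate with higher signal strength; ties keep replicate 1."""
    if (r1.participant_id, r1.eye, r1.encounter_id) != (r2.participant_id, r2.eye, r2.encounter_id):
        raise ValueError("scan pair metadata mismatch")
    if {r1.replicate, r2.replicate} != {1, 2}:
        raise ValueError("expected replicates 1 and 2")
    if r1.signal_strength == r2.signal_strength:
        return r1 if r1.replicate == 1 else r2
    return r1 if r1.signal_strength > r2.signal_strength else r2


def _paired(records: Iterable[ScanRecord]) -> dict[tuple[str, str, str], dict[int, ScanRecord]]:
    pairs: dict[tuple[str, str, str], dict[int, ScanRecord]] = {}
    for r in records:
        slot = pairs.setdefault((r.participant_id, r.eye, r.encounter_id), {})
        if r.replicate in slot:
            raise ValueError(f"duplicate scan key {r.key}")
        slot[r.replicate] = r
    return pairs


def select_better(records: Iterable[ScanRecord]) -> list[ScanRecord]:
    """Better-of-two selection over a whole cohort; lone scans pass through."""
    out = []
    for key, slot in _paired(records).items():
        if len(slot) == 2:
            out.append(select_better_scan(slot[1], slot[2]))
        else:
            logger.warning("unpaired scan for %s; using the single replicate", key)
            out.append(next(iter(slot.values())))
    return out


def replicate_pairs(records: Iterable[ScanRecord]) -> list[tuple[SectorMap, SectorMap]]:
    """Same-eye same-encounter replicate pairs, for empirical-null calibration."""
    return [
        (slot[1].sectors, slot[2].sectors)
        for slot in _paired(records).values()
        if len(slot) == 2
    ]


def write_scans(records: Sequence[ScanRecord], path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "eye": r.eye,
            "encounter_id": r.encounter_id,
            "replicate": r.replicate,
            "signal_strength": r.signal_strength,
            **{s: f"{r.sectors[s]:.2f}" for s in SECTORS},
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SCAN_COLUMNS).to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_scans(path) -> list[ScanRecord]:
    df = pd.read_csv(path, dtype={"participant_id": str, "eye": str, "encounter_id": str},
                     float_precision="round_trip")
    _require_columns(df, SCAN_COLUMNS, path)
    records: list[ScanRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            values = {s: float(getattr(row, s)) for s in SECTORS}
            if any(not math.isfinite(v) for v in values.values()):
                raise ValueError("non-numeric sector thickness")
            rec = ScanRecord(
                participant_id=str(row.participant_id),
                eye=str(row.eye),
                encounter_id=str(row.encounter_id),
                replicate=int(row.replicate),
                signal_strength=float(row.signal_strength),
                sectors=SectorMap(values, laterality=str(row.eye)),
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: line {i}: {err}") from err
        if rec.key in seen:
            raise ValueError(f"{path}: line {i}: duplicate scan key {rec.key}")
        seen.add(rec.key)
        records.append(rec)
    return records


def write_encounters(encounters: Sequence[Encounter], path) -> None:
    rows = [
        {
            "participant_id": e.participant_id,
            "encounter_id": e.encounter_id,
            "epoch": e.epoch,
            "gestational_age": "" if e.gestational_age is None else repr(float(e.gestational_age)),
            "sbp": e.sbp,
            "dbp": e.dbp,
        }
        for e in encounters
    ]
    pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS).to_csv(path, index=False)


def read_encounters(path) -> list[Encounter]:
    df = pd.read_csv(path, dtype={"participant_id": str, "encounter_id": str, "epoch": str},
                     float_precision="round_trip")
    _require_columns(df, ENCOUNTER_COLUMNS, path)
    encounters: list[Encounter] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ga = row.gestational_age
            ga = None if (ga is None or (isinstance(ga, float) and math.isnan(ga))) else float(ga)
            enc = Encounter(
                participant_id=str(row.participant_id),
                encounter_id=str(row.encounter_id),
                epoch=str(row.epoch),
                gestational_age=ga,
                sbp=float(row.sbp),
                dbp=float(row.dbp),
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: line {i}: {err}") from err
        if enc.encounter_id in seen:
            raise ValueError(f"{path}: line {i}: duplicate encounter id {enc.encounter_id!r}")
        seen.add(enc.encounter_id)
        encounters.append(enc)
    return encounters
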