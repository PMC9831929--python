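"""Eye-level and participant-level longitudinal classification."""

from __future__ import annotations

import pytest

from maculatrack.change_rule import RuleParams
from maculatrack.cohort import default_config, fixture_config, generate_cohort
from maculatrack.grid import SECTORS, SectorMap
from maculatrack.io import ScanRecord
from maculatrack.trajectory import (
    Encounter,
    classify_eye,
    classify_participant,
    detect_hypoperfusion,
)

from conftest import classify_cohort, flat_map


def make_encounters(bps=None):
    """Baseline + pregnancy visits at 12/30/38 weeks for participant P1."""
    bps = bps or {}
    def bp(tag, default=(112, 70)):
        return bps.get(tag, default)
    return {
        "E1": Encounter("P1", "E1", "early", 12.0, *bp("early")),
        "E2": Encounter("P1", "E2", "mid", 30.0, *bp("mid")),
        "E3": Encounter("P1", "E3", "delivery", 38.0, *bp("delivery")),
        "E0": Encounter("P1", "E0", "nonpregnant_baseline", None, *bp("baseline")),
    }


def scan(eid, value, eye="OD", **overrides):
    return ScanRecord("P1", eye, eid, 1, 9.0, flat_map(value, laterality=eye, **overrides))


def eye_sequence(baseline=280.0, values=(276.0, 276.0, 276.0), eye="OD", overrides=None):
    overrides = overrides or {}
    recs = [scan("E0", baseline, eye)]
    for eid, v in zip(("E1", "E2", "E3"), values):
        recs.append(scan(eid, v, eye, **overrides.get(eid, {})))
    return recs


class TestClassifyEye:
    def test_control_pattern_thins_early_and_keeps_it(self):
        traj = classify_eye(eye_sequence(280.0, (276.0, 276.0, 276.0)), make_encounters())
        assert traj.early_thinning and traj.early_thinning_ga == 12.0
        assert not traj.lot and not traj.overt_thickening
        assert traj.sudden_thinning_events == []

    def test_loss_of_thinning_on_sequential_pair(self):
        # thinning at 12 wks, then +4 um rebound in the outer-ring chain at 30 wks
        rebound = {s: 280.0 for s in ("OS", "ON", "OI")}
        recs = [scan("E0", 280.0), scan("E1", 276.0),
                scan("E2", 276.0, **rebound), scan("E3", 276.0, **rebound)]
        traj = classify_eye(recs, make_encounters())
        assert traj.early_thinning and traj.lot and traj.lot_ga == 30.0
        assert not traj.lot_at_delivery

    def test_flat_series_never_fires(self):
        traj = classify_eye(eye_sequence(280.0, (280.0, 280.0, 280.0)), make_encounters())
        assert not traj.early_thinning and not traj.lot

    def test_late_first_thinning_recorded_at_first_firing(self):
        traj = classify_eye(eye_sequence(280.0, (279.0, 273.0, 273.0)), make_encounters())
        assert traj.early_thinning and traj.early_thinning_ga == 30.0

    def test_lot_first_seen_at_delivery_is_flagged(self):
        rebound = {s: 280.0 for s in ("OS", "ON", "OI")}
        recs = [scan("E0", 280.0), scan("E1", 276.0), scan("E2", 276.0),
                scan("E3", 276.0, **rebound)]
        traj = classify_eye(recs, make_encounters())
        assert traj.lot and traj.lot_ga == 38.0 and traj.lot_at_delivery

    def test_overt_thickening_versus_baseline(self):
        thick = {s: 285.0 for s in ("IS", "IN", "II")}
        recs = [scan("E0", 280.0), scan("E1", 276.0), scan("E2", 276.0),
                scan("E3", 276.0, **thick)]
        assert classify_eye(recs, make_encounters()).overt_thickening

    def test_sudden_thinning_after_established_thinning(self):
        drop = {s: 268.0 for s in ("IS", "IN", "II")}
        recs = [scan("E0", 280.0), scan("E1", 276.0), scan("E2", 276.0),
                scan("E3", 276.0, **drop)]
        traj = classify_eye(recs, make_encounters())
        assert [ga for ga, _ in traj.sudden_thinning_events] == [38.0]
        assert traj.sudden_thinning_events[0][1] == pytest.approx(-8.0)

    def test_missing_baseline_rejected(self):
        recs = eye_sequence()[1:]
        with pytest.raises(ValueError, match="baseline"):
            classify_eye(recs, make_encounters())

    def test_unordered_scans_rejected(self):
        recs = eye_sequence()
        recs[1], recs[2] = recs[2], recs[1]
        with pytest.raises(ValueError, match="order"):
            classify_eye(recs, make_encounters())


class TestDetectHypoperfusion:
    def _traj_with_event(self, bps):
        drop = {s: 268.0 for s in ("IS", "IN", "II")}
        recs = [scan("E0", 280.0), scan("E1", 276.0), scan("E2", 276.0),
                scan("E3", 276.0, **drop)]
        enc = make_encounters(bps)
        return classify_eye(recs, enc), enc

    def test_event_with_map_drop_flags(self):
        # MAP 101 (135/84) at mid -> 80 (106/67) at delivery: drop 21 >= 15
        traj, enc = self._traj_with_event({"mid": (135, 84), "delivery": (106, 67)})
        assert detect_hypoperfusion(traj, enc.values())

    def test_event_without_map_drop_does_not_flag(self):
        traj, enc = self._traj_with_event({})
        assert not detect_hypoperfusion(traj, enc.values())

    def test_map_drop_without_event_does_not_flag(self):
        recs = eye_sequence(280.0, (276.0, 276.0, 276.0))
        enc = make_encounters({"mid": (135, 84), "delivery": (106, 67)})
        traj = classify_eye(recs, enc)
        assert not detect_hypoperfusion(traj, enc.values())


class TestClassifyParticipant:
    def _od_os(self, od_values, os_values, od_over=None, os_over=None):
        enc = make_encounters()
        od = classify_eye(eye_sequence(280.0, od_values, "OD", od_over), enc)
        os_ = classify_eye(eye_sequence(280.0, os_values, "OS", os_over), enc)
        return od, os_, enc

    def test_single_eye_lot(self):
        rebound = {"E2": {s: 280.0 for s in ("OS", "ON", "OI")},
                   "E3": {s: 280.0 for s in ("OS", "ON", "OI")}}
        od, os_, enc = self._od_os((276.0,) * 3, (276.0,) * 3, od_over=rebound)
        p = classify_participant(od, os_, enc.values())
        assert p.label == "loss_of_thinning" and p.single_eye_lot
        assert not p.no_injury and p.lot_ga == 30.0

    def test_both_eyes_maintained(self):
        od, os_, enc = self._od_os((276.0,) * 3, (276.0,) * 3)
        p = classify_participant(od, os_, enc.values())
        assert p.label == "maintained_thinning" and p.no_injury and not p.single_eye_lot

    def test_no_early_thinning_label(self):
        od, os_, enc = self._od_os((280.0,) * 3, (280.0,) * 3)
        assert classify_participant(od, os_, enc.values()).label == "no_early_thinning"

    def test_bilateral_lot_is_not_single_eye(self):
        rebound = {"E2": {s: 280.0 for s in ("OS", "ON", "OI")}}
        od, os_, enc = self._od_os((276.0,) * 3, (276.0,) * 3, od_over=rebound, os_over=rebound)
        p = classify_participant(od, os_, enc.values())
        assert p.label == "loss_of_thinning" and not p.single_eye_lot

    def test_eye_order_is_irrelevant(self):
        rebound = {"E2": {s: 280.0 for s in ("OS", "ON", "OI")}}
        od, os_, enc = self._od_os((276.0,) * 3, (276.0,) * 3, od_over=rebound)
        a = classify_participant(od, os_, enc.values())
        b = classify_participant(os_, od, enc.values())
        assert (a.label, a.single_eye_lot, a.hypoperfusion, a.no_injury) == \
               (b.label, b.single_eye_lot, b.hypoperfusion, b.no_injury)

    def test_participant_mismatch_rejected(self):
        od, os_, enc = self._od_os((276.0,) * 3, (276.0,) * 3)
        os_.participant_id = "P2"
        with pytest.raises(ValueError, match="mismatch"):
            classify_participant(od, os_, enc.values())


class TestCohortRecovery:
    def test_labels_exhaustive_and_exclusive(self, fixture_trajectories):
        labels = {"maintained_thinning", "loss_of_thinning", "no_early_thinning"}
        for t in fixture_trajectories.values():
            assert t.label in labels

    def test_low_noise_cohort_recovers_every_planted_label(self):
        # planted signals >= 6 um dominate a 0.2 um replicate noise floor
        cfg = fixture_config(seed=424242)
        cfg = cfg.model_copy(update={"noise": cfg.noise.model_copy(update={
            "replicate_sd": 0.2, "participant_sd": 0.1, "eye_sd": 0.05,
            "sector_sd": 0.05, "visit_sd": 0.1})})
        cohort = generate_cohort(cfg)
        trajs = classify_cohort(cohort)
        for truth in cohort.truth:
            got = trajs[truth.participant_id]
            assert got.label == truth.label
            assert got.single_eye_lot == truth.single_eye_lot
            assert got.hypoperfusion == truth.hypoperfusion
            if truth.lot:
                assert got.lot_ga == pytest.approx(truth.lot_onset_week)
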