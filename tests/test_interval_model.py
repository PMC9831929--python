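"""Long-table construction and the hierarchical interval model."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from maculatrack import io as mio
from maculatrack.cohort import default_config, generate_cohort
from maculatrack.interval_model import (
    ConvergenceError,
    build_long_table,
    fit_interval_model,
    pool_hdp,
)
from maculatrack.io import ScanRecord
from maculatrack.trajectory import Encounter

from conftest import flat_map


def small_cohort_scans(values_by_encounter, participants=("P1",), eyes=("OD", "OS")):
    """Hand-built selected scans: same sector map per (encounter template)."""
    scans, encounters = [], []
    for pid in participants:
        for tag, (epoch, ga, value) in values_by_encounter.items():
            eid = f"{pid}-{tag}"
            encounters.append(Encounter(pid, eid, epoch, ga, 112, 70))
            for eye in eyes:
                scans.append(ScanRecord(pid, eye, eid, 1, 9.0, flat_map(value, laterality=eye)))
    return scans, encounters


BASE_SCHEDULE = {
    "E0": ("nonpregnant_baseline", None, 280.0),
    "E1": ("early", 12.0, 276.0),
    "E2": ("mid", 30.0, 276.0),
    "E3": ("delivery", 38.0, 276.0),
}


class TestBuildLongTable:
    def test_row_count_single_participant(self):
        scans, encounters = small_cohort_scans(BASE_SCHEDULE)
        table = build_long_table(scans, encounters, {"P1": "control"})
        assert len(table) == 2 * 9 * 3  # eyes x sectors x pregnancy encounters

    def test_change_zero_when_scan_equals_baseline(self):
        sched = dict(BASE_SCHEDULE)
        sched["E1"] = ("early", 12.0, 280.0)
        scans, encounters = small_cohort_scans(sched)
        table = build_long_table(scans, encounters, {"P1": "control"})
        assert (table.loc[table.epoch == "early", "change_um"] == 0.0).all()

    def test_full_cohort_row_count(self, default_cohort, default_long_table):
        # 38 participants x 2 eyes x 9 sectors x 3 encounters, plus one extra
        # pre-delivery encounter for each of the 5 hypoperfusion participants
        assert len(default_long_table) == 38 * 2 * 9 * 3 + 5 * 2 * 9

    def test_missing_baseline_drops_participant(self, caplog):
        sched = {k: v for k, v in BASE_SCHEDULE.items() if k != "E0"}
        scans, encounters = small_cohort_scans(sched)
        ok_scans, ok_encounters = small_cohort_scans(BASE_SCHEDULE, participants=("P2",))
        with caplog.at_level("WARNING"):
            table = build_long_table(scans + ok_scans, encounters + ok_encounters,
                                     {"P1": "control", "P2": "control"})
        assert set(table.participant_id) == {"P2"}
        assert "P1" in caplog.text


class TestFitIntervalModel:
    def test_zero_noise_uniform_change_recovered_exactly(self):
        sched = dict(BASE_SCHEDULE)
        sched.update(E1=("early", 12.0, 280.0 - 3.94), E2=("mid", 30.0, 277.0), E3=("delivery", 38.0, 275.0))
        scans, encounters = small_cohort_scans(sched, participants=("P1", "P2", "P3"))
        table = build_long_table(scans, encounters, {p: "control" for p in ("P1", "P2", "P3")})
        fit = fit_interval_model(table, by_group=False, fix_rho=0.0)
        assert fit.estimate(None, "early")["mean"] == pytest.approx(-3.94, abs=1e-6)

    def test_null_cohort_estimates_near_zero(self):
        cfg = default_config(seed=606)
        cfg = cfg.model_copy(update={
            "effects": {g: e.model_copy(update={"early": 1e-9, "mid": 1e-9, "delivery": 1e-9})
                        for g, e in cfg.effects.items()},
            "plant_spatial": False,
        })
        cohort = generate_cohort(cfg)
        table = build_long_table(mio.select_better(cohort.scans), cohort.encounters, cohort.groups())
        fit = fit_interval_model(pool_hdp(table), by_group=False)
        for r in fit.estimates.itertuples():
            assert abs(r.mean) < 2 * r.se

    def test_matches_closed_form_anova_oracle_on_balanced_design(self):
        # 3 participants x 2 eyes x 2 epochs, one sector, serial correlation off
        rng = np.random.default_rng(1)
        mu = {"early": -4.0, "mid": -2.0}
        rows, y = [], {}
        for p in range(3):
            a = rng.normal(0, 2.0)
            for e, eye in enumerate(("OD", "OS")):
                b = rng.normal(0, 1.0)
                for epoch, week in (("early", 12.0), ("mid", 30.0)):
                    val = mu[epoch] + a + b + rng.normal(0, 0.5)
                    y[(p, e, epoch)] = val
                    rows.append({"participant_id": f"P{p}", "eye": eye, "sector": "C",
                                 "epoch": epoch, "time_weeks": week, "change_um": val,
                                 "group": "all"})
        table = pd.DataFrame(rows)
        fit = fit_interval_model(table, by_group=False, fix_rho=0.0, require_all_epochs=False)

        arr = np.array([[[y[(p, e, ep)] for ep in ("early", "mid")] for e in range(2)] for p in range(3)])
        grand = arr.mean()
        m_pe = arr.mean(axis=2)
        m_p = m_pe.mean(axis=1)
        epoch_means = arr.mean(axis=(0, 1))
        ss_p = 4 * ((m_p - grand) ** 2).sum()
        ss_e = 2 * ((m_pe - m_p[:, None]) ** 2).sum()
        resid = arr - m_pe[:, :, None] - (epoch_means - grand)[None, None, :]
        ms_p, ms_e, ms_r = ss_p / 2, ss_e / 3, (resid ** 2).sum() / 5
        sp2, se2, sr2 = (ms_p - ms_e) / 4, (ms_e - ms_r) / 2, ms_r
        assert min(sp2, se2, sr2) > 0  # oracle valid only at an interior solution
        se_mean = np.sqrt((4 * sp2 + 2 * se2 + 2 * sr2) / 12)

        for i, epoch in enumerate(("early", "mid")):
            est = fit.estimate(None, epoch)
            assert est["mean"] == pytest.approx(epoch_means[i], abs=1e-6)
            assert est["se"] == pytest.approx(se_mean, rel=1e-3)
        comps = fit.variance_components
        assert comps["participant"] == pytest.approx(sp2, rel=1e-2)
        assert comps["eye"] + comps["sector"] == pytest.approx(se2, rel=1e-2)
        assert comps["residual"] == pytest.approx(sr2, rel=1e-2)

    def test_estimates_invariant_to_row_order_and_eye_relabel(self, default_long_table):
        base = fit_interval_model(default_long_table, by_group=True)
        shuffled = default_long_table.sample(frac=1.0, random_state=0)
        relabeled = shuffled.copy()
        relabeled["eye"] = relabeled["eye"].map({"OD": "OS", "OS": "OD"})
        alt = fit_interval_model(relabeled, by_group=True)
        assert list(base.estimates.group) == list(alt.estimates.group)
        assert list(base.estimates.epoch) == list(alt.estimates.epoch)
        for col in ("mean", "se", "ci_lo", "ci_hi"):
            np.testing.assert_allclose(base.estimates[col], alt.estimates[col], atol=1e-4)

    def test_serial_correlation_recovered_positive(self, default_fit_by_group):
        assert 0.0 <= default_fit_by_group.rho_week < 1.0
        assert all(v >= 0 for v in default_fit_by_group.variance_components.values())

    def test_missing_epoch_rejected(self):
        sched = {k: v for k, v in BASE_SCHEDULE.items() if k != "E3"}
        scans, encounters = small_cohort_scans(sched, participants=("P1", "P2"))
        table = build_long_table(scans, encounters, {"P1": "control", "P2": "control"})
        with pytest.raises(ValueError, match="interval"):
            fit_interval_model(table, by_group=False)

    def test_single_participant_group_rejected(self):
        scans, encounters = small_cohort_scans(BASE_SCHEDULE, participants=("P1",))
        table = build_long_table(scans, encounters, {"P1": "control"})
        with pytest.raises(ValueError, match="participants"):
            fit_interval_model(table, by_group=True)

    def test_table3_layout(self, default_fit_by_group):
        frame = default_fit_by_group.to_frame()
        assert list(frame.columns) == ["group", "epoch", "mean", "ci_lo", "ci_hi", "p_vs_early", "p_vs_mid"]
        delivery = frame[(frame.group == "control") & (frame.epoch == "delivery")].iloc[0]
        assert np.isfinite(delivery.p_vs_early) and np.isfinite(delivery.p_vs_mid)
        early = frame[(frame.group == "control") & (frame.epoch == "early")].iloc[0]
        assert pd.isna(early.p_vs_early)


class TestPoolHdp:
    def test_pooling_merges_only_hdp_groups(self, default_long_table):
        pooled = pool_hdp(default_long_table)
        assert set(pooled.group) == {"control", "hdp"}
        n_hdp = (default_long_table.group != "control").sum()
        assert (pooled.group == "hdp").sum() == n_hdp
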