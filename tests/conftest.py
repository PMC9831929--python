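"""Shared fixtures: cohorts and fits are expensive, so they are session-scoped."""

from __future__ import annotations

import warnings

import pytest

from maculatrack import io as mio
from maculatrack.change_rule import RuleParams
from maculatrack.cohort import default_config, default_fixture, generate_cohort
from maculatrack.grid import AdjacencyGraph, SECTORS, SectorMap
from maculatrack.interval_model import build_long_table, fit_interval_model, pool_hdp
from maculatrack.trajectory import classify_eye, classify_participant


@pytest.fixture(scope="session")
def graph() -> AdjacencyGraph:
    return AdjacencyGraph()


@pytest.fixture(scope="session")
def rule() -> RuleParams:
    return RuleParams()


def flat_map(value: float, laterality: str = "OD", **overrides) -> SectorMap:
    values = {s: value for s in SECTORS}
    values.update(overrides)
    return SectorMap(values, laterality=laterality)


@pytest.fixture(scope="session")
def fixture_cohort():
    return default_fixture()


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(default_config())


def classify_cohort(cohort, params: RuleParams = RuleParams(), drop_threshold: float = 15.0):
    """Select better-of-two scans and classify every participant."""
    enc = cohort.encounters_by_id()
    selected = mio.select_better(cohort.scans)
    by_eye: dict[tuple[str, str], list] = {}
    for s in selected:
        by_eye.setdefault((s.participant_id, s.eye), []).append(s)
    eye_trajs = {}
    for key, recs in by_eye.items():
        recs.sort(key=lambda r: (enc[r.encounter_id].gestational_age is None,
                                 enc[r.encounter_id].gestational_age or 0.0))
        eye_trajs[key] = classify_eye(recs, enc, params)
    return {
        pid: classify_participant(eye_trajs[(pid, "OD")], eye_trajs[(pid, "OS")],
                                  cohort.encounters, drop_threshold)
        for pid in sorted({p for p, _ in eye_trajs})
    }


@pytest.fixture(scope="session")
def fixture_trajectories(fixture_cohort):
    return classify_cohort(fixture_cohort)


@pytest.fixture(scope="session")
def default_trajectories(default_cohort):
    return classify_cohort(default_cohort)


@pytest.fixture(scope="session")
def default_long_table(default_cohort):
    selected = mio.select_better(default_cohort.scans)
    return build_long_table(selected, default_cohort.encounters, default_cohort.groups())


@pytest.fixture(scope="session")
def default_fit_by_group(default_long_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_interval_model(default_long_table, by_group=True)


@pytest.fixture(scope="session")
def default_fit_pooled(default_long_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_interval_model(pool_hdp(default_long_table), by_group=True)
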