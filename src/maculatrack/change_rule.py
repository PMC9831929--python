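"""Interval change between two scans and the contiguity decision rule.

The decision-support rule calls an interval change clinically meaningful when
a directionally identical difference of at least tau = 4 um (twice the 2 um
test-retest coefficient of repeatability of the instrument) appears in k = 3
or more contiguous ETDRS sectors of a single eye.  Thickening and thinning
are evaluated independently and may both fire on one pair of scans.

Because a parametric null is unavailable for spatially correlated sector
maps, the rule is calibrated empirically: given a collection of same-eye,
same-encounter replicate scan pairs (a null of pure test-retest difference),
:func:`calibrate_null` tabulates the firing frequency of every weaker rule
(tau', k') dominated by the chosen one and reports the frequency at the
configured rule as its empirical exceedance probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import SECTORS, AdjacencyGraph, SectorMap, _round01, largest_directional_component, max_component_sizes

__all__ = [
    "RuleParams",
    "RuleResult",
    "NullCalibration",
    "interval_change",
    "apply_rule",
    "calibrate_null",
]

DEFAULT_TAU_GRID: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
DEFAULT_K_GRID: tuple[int, ...] = tuple(range(1, 10))


@dataclass(frozen=True)
class RuleParams:
    """Decision rule: change threshold ``tau`` (um) and contiguity count ``k``."""

    tau: float = 4.0
    k: int = 3

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if not 1 <= self.k <= 9:
            raise ValueError("k must be in 1..9")


@dataclass(frozen=True)
class RuleResult:
    """Outcome of the rule on one pair of scans."""

    fires_thickening: bool
    fires_thinning: bool
    max_pos_component: int
    max_neg_component: int
    diffs: Mapping[str, float]


def interval_change(reference: SectorMap, followup: SectorMap) -> dict[str, float]:
    """Per-sector signed difference followup - reference (um); negative = thinning."""
    if reference.laterality != followup.laterality:
        raise ValueError(
            f"laterality mismatch: reference {reference.laterality}, followup {followup.laterality}"
        )
    return {s: _round01(followup[s] - reference[s]) for s in SECTORS}


def apply_rule(
    diffs: Mapping[str, float],
    params: RuleParams = RuleParams(),
    graph: AdjacencyGraph | None = None,
) -> RuleResult:
    """Evaluate the contiguity rule on per-sector differences, both directions."""
    graph = graph if graph is not None else AdjacencyGraph()
    pos = largest_directional_component(diffs, params.tau, "+", graph)
    neg = largest_directional_component(diffs, params.tau, "-", graph)
    return RuleResult(
        fires_thickening=pos >= params.k,
        fires_thinning=neg >= params.k,
        max_pos_component=pos,
        max_neg_component=neg,
        diffs={s: _round01(diffs[s]) for s in SECTORS},
    )


@dataclass
class NullCalibration:
    """Empirical firing frequencies of the rule family on null scan pairs."""

    n_pairs: int
    tau_grid: tuple[float, ...]
    k_grid: tuple[int, ...]
    freq_table: dict[tuple[float, int], float]
    params: RuleParams
    p_at_rule: float = field(init=False)

    def __post_init__(self) -> None:
        key = (float(self.params.tau), int(self.params.k))
        if key not in self.freq_table:
            raise ValueError(f"configured rule {key} is not on the calibration grid")
        self.p_at_rule = self.freq_table[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tau": t, "k": k, "n_pairs": self.n_pairs, "freq": self.freq_table[(t, k)]}
            for t in self.tau_grid
            for k in self.k_grid
        ]
        return pd.DataFrame(rows, columns=["tau", "k", "n_pairs", "freq"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def calibrate_null(
    null_pairs: Sequence[tuple[SectorMap, SectorMap]],
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    graph: AdjacencyGraph | None = None,
    params: RuleParams = RuleParams(),
) -> NullCalibration:
    """Firing frequency (either direction) of every (tau', k') rule on null pairs.

    Each pair should be two same-eye, same-encounter replicate scans so that
    their difference reflects test-retest noise only.  Frequencies are
    non-increasing in tau' and in k' by construction.
    """
    if len(null_pairs) == 0:
        raise ValueError("null calibration requires at least one scan pair")
    graph = graph if graph is not None else AdjacencyGraph()
    tau_grid = tuple(sorted(float(t) for t in tau_grid))
    k_grid = tuple(sorted(int(k) for k in k_grid))
    if any(t <= 0 for t in tau_grid):
        raise ValueError("all tau grid values must be > 0")

    diffs = np.empty((len(null_pairs), 9))
    for i, (a, b) in enumerate(null_pairs):
        if a.laterality != b.laterality:
            raise ValueError(f"pair {i}: laterality mismatch")
        diffs[i] = np.round(b.as_array() - a.as_array(), 2)

    freq: dict[tuple[float, int], float] = {}
    for tau in tau_grid:
        pos_sizes = max_component_sizes(diffs >= tau, graph)
        neg_sizes = max_component_sizes(diffs <= -tau, graph)
        best = np.maximum(pos_sizes, neg_sizes)
        for k in k_grid:
            freq[(tau, k)] = float(np.mean(best >= k))
    return NullCalibration(
        n_pairs=len(null_pairs),
        tau_grid=tau_grid,
        k_grid=k_grid,
        freq_table=freq,
        params=params,
    )
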