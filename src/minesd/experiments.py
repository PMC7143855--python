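"""Scenario experiment: six allocation cases, ranking, and OAT sensitivity.

The scenario table holds six investment allocations.  Cases 1–5 each boost
one subsystem to 0.4 while the other four stay at 0.15; case 6 splits the
budget evenly at 0.2.  Each case is simulated over the 24-month horizon and
scored against the shared zero-investment baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import SimConfig, Trajectory, simulate
from .mine import (
    SUBSYSTEM_STOCKS,
    SUBSYSTEMS,
    AllocationPolicy,
    MineModelConfig,
    QualitySeries,
    ZERO_POLICY,
    assemble_full_model,
    baseline_trajectory,
    build_subsystem,
    quality_assessment,
)

__all__ = [
    "ScenarioTable",
    "ScenarioResult",
    "RankingReport",
    "OATPoint",
    "default_scenarios",
    "run_scenarios",
    "rank_scenarios",
    "oat_sensitivity",
]


@dataclass(frozen=True)
class ScenarioTable:
    """An ordered list of (case_id, policy) scenarios with unique ids."""

    cases: tuple[tuple[int, AllocationPolicy], ...]

    def __post_init__(self):
        ids = [cid for cid, _ in self.cases]
        if len(set(ids)) != len(ids):
            raise ValueError("case ids must be unique")

    @property
    def case_ids(self) -> tuple[int, ...]:
        return tuple(cid for cid, _ in self.cases)

    def policy(self, case_id: int) -> AllocationPolicy:
        for cid, pol in self.cases:
            if cid == case_id:
                return pol
        raise KeyError(f"unknown case {case_id}; valid cases are {list(self.case_ids)}")


def default_scenarios() -> ScenarioTable:
    """The six tabulated allocation cases (each column sums to 1)."""
    boosted, rest = 0.4, 0.15
    cases = []
    for i, sub in enumerate(SUBSYSTEMS, start=1):
        props = {f"p_{tag}": rest for tag in ("air", "solid", "water", "green", "land")}
        props[_policy_field(sub)] = boosted
        cases.append((i, AllocationPolicy(**props)))
    cases.append((6, AllocationPolicy(p_air=0.2, p_solid=0.2, p_water=0.2, p_green=0.2, p_land=0.2)))
    return ScenarioTable(cases=tuple(cases))


def _policy_field(subsystem: str) -> str:
    from .mine import PROPORTION_FIELDS

    return PROPORTION_FIELDS[subsystem]


@dataclass
class ScenarioResult:
    """One simulated case with its quality series against the shared baseline."""

    case_id: int
    policy: AllocationPolicy
    trajectory: Trajectory
    quality: QualitySeries


def run_scenarios(
    config: MineModelConfig | None = None,
    table: ScenarioTable | None = None,
    sim: SimConfig | None = None,
) -> tuple[list[ScenarioResult], Trajectory]:
    """Simulate every case plus the shared zero-allocation baseline.

    Returns the per-case results (in table order) and the baseline trajectory.
    Fully deterministic.
    """
    config = config or MineModelConfig()
    table = table or default_scenarios()
    sim = sim or SimConfig()
    baseline = baseline_trajectory(config, sim)
    results = []
    for cid, policy in table.cases:
        traj = simulate(assemble_full_model(config, policy), sim)
        results.append(
            ScenarioResult(
                case_id=cid,
                policy=policy,
                trajectory=traj,
                quality=quality_assessment(traj, baseline),
            )
        )
    return results, baseline


@dataclass
class RankingReport:
    """Case ordering by overall quality, plus the per-subsystem winners.

    ``ordering`` sorts case ids by overall quality (descending, ties broken
    by lower case id) evaluated at ``at_time`` (``statistic="final"``) or
    averaged over the horizon (``statistic="mean"``).  ``case4_then_case6``
    records whether the vegetation-boosted case ranks first with the uniform
    split second — the headline ordering this experiment is usually read for —
    without asserting it.
    """

    at_time: float
    statistic: str
    ordering: tuple[int, ...]
    overall_quality: dict[int, float]
    per_subsystem_best: dict[str, int]
    case4_then_case6: bool = field(init=False)

    def __post_init__(self):
        self.case4_then_case6 = (
            len(self.ordering) >= 2 and self.ordering[0] == 4 and self.ordering[1] == 6
        )


def rank_scenarios(
    results: list[ScenarioResult],
    at_time: float | None = None,
    statistic: str = "final",
) -> RankingReport:
    """Rank cases by overall quality; pure function of its inputs.

    ``per_subsystem_best`` maps each subsystem to the case with the minimal
    final stock (ties to the lower case id).
    """
    if not results:
        raise ValueError("no scenario results to rank")
    if statistic not in ("final", "mean"):
        raise ValueError(f"statistic must be 'final' or 'mean', got {statistic!r}")
    times = results[0].trajectory.times
    if at_time is None:
        at_time = float(times[-1])
    idx = np.flatnonzero(np.isclose(times, at_time))
    if idx.size == 0:
        raise ValueError(f"time {at_time!r} is not on the simulation grid")
    k = int(idx[0])

    overall: dict[int, float] = {}
    for r in results:
        if statistic == "final":
            overall[r.case_id] = float(r.quality.overall[k])
        else:
            overall[r.case_id] = float(np.mean(r.quality.overall))
    ordering = tuple(sorted(overall, key=lambda cid: (-overall[cid], cid)))

    best: dict[str, int] = {}
    for sub, stock in SUBSYSTEM_STOCKS.items():
        finals = {r.case_id: float(r.trajectory.series[stock][-1]) for r in results}
        best[sub] = min(finals, key=lambda cid: (finals[cid], cid))
    return RankingReport(
        at_time=float(at_time),
        statistic=statistic,
        ordering=ordering,
        overall_quality=overall,
        per_subsystem_best=best,
    )


@dataclass
class OATPoint:
    """Final stock and final quality of one subsystem at one proportion."""

    proportion: float
    final_stock: float
    final_quality: float


def oat_sensitivity(
    config: MineModelConfig | None = None,
    subsystem: str = "air",
    proportion_grid: tuple[float, ...] = (0.15, 0.4),
    sim: SimConfig | None = None,
    reference: float = 0.15,
) -> dict[float, OATPoint]:
    """One-at-a-time sensitivity: vary one subsystem's proportion over a grid.

    The other four proportions are held at ``reference`` (capped at
    ``(1 - p) / 4`` so the allocation stays within budget; because the
    subsystems are independent, the reference value has no effect on the
    reported subsystem).  Returns, per grid value, the subsystem's final
    stock and final quality against the zero-allocation baseline.
    """
    config = config or MineModelConfig()
    sim = sim or SimConfig()
    if subsystem not in SUBSYSTEMS:
        raise ValueError(f"unknown subsystem {subsystem!r}; one of {SUBSYSTEMS}")
    if any(p < 0 or p > 1 for p in proportion_grid):
        raise ValueError("grid proportions must lie in [0, 1]")
    stock = SUBSYSTEM_STOCKS[subsystem]
    baseline = simulate(build_subsystem(subsystem, config, ZERO_POLICY), sim)
    b_final = float(baseline.series[stock][-1])
    out: dict[float, OATPoint] = {}
    for p in proportion_grid:
        others = min(reference, (1.0 - p) / 4.0)
        props = {f"p_{tag}": others for tag in ("air", "solid", "water", "green", "land")}
        props[_policy_field(subsystem)] = p
        policy = AllocationPolicy(**props)
        traj = simulate(build_subsystem(subsystem, config, policy), sim)
        s_final = float(traj.series[stock][-1])
        out[float(p)] = OATPoint(
            proportion=float(p),
            final_stock=s_final,
            final_quality=(b_final - s_final) / b_final,
        )
    return out
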