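"""The two experiment designs: transmission-rate sensitivity and the
scenario x alternative intervention sweep, with ranking by final childhood
overweight+obesity prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .interventions import (
    Alternative,
    Scenario,
    alternative_catalog,
    intervention_schedule,
    scenario_catalog,
    total_impacts,
    DEFAULT_DISCOUNT,
    DEFAULT_MAGNITUDE,
)
from .model import (
    BehaviorParams,
    Group,
    PopulationState,
    SimulationConfig,
    Trajectory,
    integrate,
    prevalence,
)

#: Sensitivity axis bounds and increment for both transmission rates.
SENSITIVITY_LO = 0.0011
SENSITIVITY_HI = 0.0019
SENSITIVITY_STEP = 0.0002

BASELINE_LABEL = "BASELINE"


@dataclass(frozen=True)
class SensitivityGrid:
    """Two-way grid of final childhood prevalence over (beta_ac, beta_cc).

    ``final_child_prevalence[i, j]`` is the end-of-horizon percentage for
    ``beta_ac_values[i]`` and ``beta_cc_values[j]``.
    """

    beta_ac_values: np.ndarray
    beta_cc_values: np.ndarray
    final_child_prevalence: np.ndarray

    def __post_init__(self) -> None:
        ac = np.asarray(self.beta_ac_values, dtype=float)
        cc = np.asarray(self.beta_cc_values, dtype=float)
        if np.any(np.diff(ac) <= 0) or np.any(np.diff(cc) <= 0):
            raise ValueError("sensitivity axes must be strictly increasing")
        if np.asarray(self.final_child_prevalence).shape != (ac.size, cc.size):
            raise ValueError("prevalence matrix shape must match the axes")
        object.__setattr__(self, "beta_ac_values", ac)
        object.__setattr__(self, "beta_cc_values", cc)
        object.__setattr__(
            self, "final_child_prevalence",
            np.asarray(self.final_child_prevalence, dtype=float),
        )

    @property
    def n_cells(self) -> int:
        return self.final_child_prevalence.size

    def ratio_extremes(self) -> Tuple[float, float]:
        """(min, max) of beta_ac / beta_cc over all grid cells."""
        ratios = self.beta_ac_values[:, None] / self.beta_cc_values[None, :]
        return float(ratios.min()), float(ratios.max())

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: beta_ac, beta_cc, final_prevalence_pct."""
        rows = [
            (ac, cc, self.final_child_prevalence[i, j])
            for i, ac in enumerate(self.beta_ac_values)
            for j, cc in enumerate(self.beta_cc_values)
        ]
        return pd.DataFrame(rows, columns=["beta_ac", "beta_cc", "final_prevalence_pct"])


def _axis(lo: float, hi: float, step: float) -> np.ndarray:
    if not lo < hi:
        raise ValueError(f"need lo < hi, got {lo} >= {hi}")
    n = (hi - lo) / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"step {step} does not divide the range [{lo}, {hi}]")
    return lo + step * np.arange(round(n) + 1)


def run_sensitivity(
    base: BehaviorParams,
    initial: PopulationState,
    lo: float = SENSITIVITY_LO,
    hi: float = SENSITIVITY_HI,
    step: float = SENSITIVITY_STEP,
    config: SimulationConfig = SimulationConfig(),
) -> SensitivityGrid:
    """Two-way sensitivity of final childhood prevalence to the
    adult-to-child and child-to-child transmission rates.

    Simulates every (beta_ac, beta_cc) combination on the axis
    lo..hi in the given increments (default: 5 x 5 = 25 runs over
    0.0011..0.0019 by 0.0002), with baseline parameters otherwise and no
    interventions, and records the childhood overweight+obesity prevalence
    at the horizon.
    """
    values = _axis(lo, hi, step)
    grid = np.empty((values.size, values.size))
    for i, beta_ac in enumerate(values):
        for j, beta_cc in enumerate(values):
            params = replace(base, beta_ac=float(beta_ac), beta_cc=float(beta_cc))
            try:
                traj = integrate(initial, params, config)
            except ValueError as exc:
                raise ValueError(
                    f"sensitivity cell (beta_ac={beta_ac}, beta_cc={beta_cc}): {exc}"
                ) from exc
            grid[i, j] = prevalence(traj.final_state, Group.CHILD)
    return SensitivityGrid(values.copy(), values.copy(), grid)


@dataclass(frozen=True)
class SweepResult:
    """Final childhood prevalence of one (scenario, alternative) run."""

    scenario: str
    alternative: str
    final_child_prevalence_pct: float
    trajectory: Trajectory


def run_sweep(
    base: BehaviorParams,
    initial: PopulationState,
    scenarios: Optional[Sequence[Scenario]] = None,
    alternatives: Optional[Sequence[Alternative]] = None,
    magnitude: float = DEFAULT_MAGNITUDE,
    discount: float = DEFAULT_DISCOUNT,
    config: SimulationConfig = SimulationConfig(),
) -> List[SweepResult]:
    """Simulate every scenario x alternative combination plus a baseline.

    With the default catalogs this is 6 x 15 = 90 intervention runs plus one
    shared no-intervention baseline, reported once per scenario under the
    alternative label "BASELINE". Intervention effects ramp linearly over the
    full horizon.
    """
    scenarios = list(scenario_catalog() if scenarios is None else scenarios)
    alternatives = list(alternative_catalog() if alternatives is None else alternatives)
    if not scenarios or not alternatives:
        raise ValueError("scenario and alternative catalogs must be non-empty")
    baseline_traj = integrate(initial, base, config)
    baseline_prev = prevalence(baseline_traj.final_state, Group.CHILD)
    results: List[SweepResult] = []
    for scenario in scenarios:
        results.append(
            SweepResult(scenario.label, BASELINE_LABEL, baseline_prev, baseline_traj)
        )
        factors = scenario.factors(discount)
        for alt in alternatives:
            totals = total_impacts(alt.impacts(magnitude), factors)
            schedule = intervention_schedule(base, totals, factors, config.horizon)
            try:
                traj = integrate(initial, schedule, config)
            except ValueError as exc:
                raise ValueError(f"{scenario.label} / {alt.name}: {exc}") from exc
            results.append(
                SweepResult(
                    scenario.label,
                    alt.name,
                    prevalence(traj.final_state, Group.CHILD),
                    traj,
                )
            )
    return results


def rank_alternatives(
    results: Sequence[SweepResult], scenario: Union[Scenario, str]
) -> List[SweepResult]:
    """Alternatives of one scenario, best (lowest final prevalence) first.

    Ties break alphabetically by alternative name. The baseline row is
    excluded from the ranking.
    """
    label = scenario.label if isinstance(scenario, Scenario) else scenario
    rows = [
        r for r in results
        if r.scenario == label and r.alternative != BASELINE_LABEL
    ]
    if not rows:
        raise ValueError(f"no results for scenario {label!r}")
    return sorted(rows, key=lambda r: (r.final_child_prevalence_pct, r.alternative))


def sweep_to_dataframe(results: Sequence[SweepResult]) -> pd.DataFrame:
    """Long format with per-scenario rank (baseline rows unranked)."""
    ranks: Dict[Tuple[str, str], int] = {}
    for label in sorted({r.scenario for r in results}):
        for pos, r in enumerate(rank_alternatives(results, label), start=1):
            ranks[(label, r.alternative)] = pos
    return pd.DataFrame(
        {
            "scenario": [r.scenario for r in results],
            "alternative": [r.alternative for r in results],
            "final_prevalence_pct": [r.final_child_prevalence_pct for r in results],
            "rank": [ranks.get((r.scenario, r.alternative)) for r in results],
        }
    )
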