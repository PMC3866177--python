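"""Core stock-and-flow model of social transmission of obesity-related behaviors.

The population is split into two closed age groups (adults, children), each
divided into normal-weight, overweight and obese compartments expressed as
proportions of the group. Normal-weight individuals adopt unhealthy behaviors
through social contact with overweight/obese individuals (mass-action terms
``beta * N * (S + O)``); children are exposed both to peers and to adults,
while adults are exposed only to adults — there is no child-to-adult
transmission. Overweight individuals progress to obesity at a constant per-week
rate, and overweight/obese individuals who engage in weight-loss behaviors
recover one category at a rate set by the engaged fraction of the stock and the
average time a transition takes.

All rates are per week; the standard simulation horizon is 10 years
(520 weeks).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, fields
from typing import Callable, Union

import numpy as np
import pandas as pd

# Tolerances. SIMPLEX_ATOL bounds float noise accepted on the group simplex
# constraints at construction; STEP_ATOL bounds conservation drift during
# integration; NEGATIVE_STOCK_LIMIT is the point past which a negative stock is
# treated as a model/step-size error rather than roundoff.
SIMPLEX_ATOL = 1e-9
STEP_ATOL = 1e-8
NEGATIVE_STOCK_LIMIT = -1e-6

#: Standard 10-year horizon in weeks.
DEFAULT_HORIZON_WEEKS = 520.0
#: Default fixed integration step (weeks), the system-dynamics convention.
DEFAULT_DT_WEEKS = 0.25


class Group(str, enum.Enum):
    """Age group selector for prevalence summaries."""

    ADULT = "adult"
    CHILD = "child"


def _as_group(group: Union[Group, str]) -> Group:
    return Group(group)


@dataclass(frozen=True)
class PopulationState:
    """The six stocks, as proportions of each (closed) age group.

    ``n_*`` are normal weight, ``ow_*`` overweight, ``ob_*`` obese. Adult
    stocks sum to 1 and child stocks sum to 1.
    """

    n_adult: float
    ow_adult: float
    ob_adult: float
    n_child: float
    ow_child: float
    ob_child: float

    def __post_init__(self) -> None:
        vals = self.to_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("PopulationState fields must be finite")
        for f, v in zip(fields(self), vals):
            if v < -SIMPLEX_ATOL or v > 1.0 + SIMPLEX_ATOL:
                raise ValueError(f"{f.name} = {v} outside [0, 1]")
        adult = vals[:3].sum()
        child = vals[3:].sum()
        if abs(adult - 1.0) > SIMPLEX_ATOL:
            raise ValueError(f"adult stocks sum to {adult}, expected 1")
        if abs(child - 1.0) > SIMPLEX_ATOL:
            raise ValueError(f"child stocks sum to {child}, expected 1")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.n_adult, self.ow_adult, self.ob_adult,
             self.n_child, self.ow_child, self.ob_child],
            dtype=float,
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "PopulationState":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class BehaviorParams:
    """Behavioral rate/time parameters of the transition equations.

    beta_aa, beta_cc, beta_ac
        Adult-to-adult, child-to-child and adult-to-child social transmission
        rates (per week).
    gamma_a, gamma_c
        Per-week rates at which overweight adults/children become obese.
    rho_awl, rho_cwl
        Proportions of overweight adults/children engaging in weight-loss
        behaviors (diet plus sufficient physical activity).
    eps_awl, eps_cwl
        Same, for obese adults/children.
    p_sa, p_sc, p_oa, p_oc
        Average times (weeks) for an engaged overweight adult/child to return
        to normal weight and for an engaged obese adult/child to return to
        overweight.
    """

    beta_aa: float
    beta_cc: float
    beta_ac: float
    gamma_a: float
    gamma_c: float
    rho_awl: float
    rho_cwl: float
    eps_awl: float
    eps_cwl: float
    p_sa: float
    p_sc: float
    p_oa: float
    p_oc: float

    _RATES = ("beta_aa", "beta_cc", "beta_ac", "gamma_a", "gamma_c")
    _PROPORTIONS = ("rho_awl", "rho_cwl", "eps_awl", "eps_cwl")
    _TIMES = ("p_sa", "p_sc", "p_oa", "p_oc")

    def __post_init__(self) -> None:
        for name in self._RATES + self._PROPORTIONS + self._TIMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in self._PROPORTIONS:
            v = getattr(self, name)
            if v > 1:
                raise ValueError(f"{name} is a proportion and must be <= 1, got {v}")
        for name in self._TIMES:
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} is a transition time and must be > 0, got {v}")


@dataclass(frozen=True)
class StateDerivative:
    """Right-hand side of the transition equations, week^-1 per stock."""

    n_adult: float
    ow_adult: float
    ob_adult: float
    n_child: float
    ow_child: float
    ob_child: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.n_adult, self.ow_adult, self.ob_adult,
             self.n_child, self.ow_child, self.ob_child],
            dtype=float,
        )


class Integrator(str, enum.Enum):
    EULER = "euler"
    RK4 = "rk4"


@dataclass(frozen=True)
class SimulationConfig:
    """Fixed-step integration controls.

    ``dt`` is the step in weeks, ``horizon`` the total simulated time,
    ``record_every`` the sampling interval of the output trajectory. Both
    ``horizon`` and ``record_every`` must be integer multiples of ``dt``.
    """

    dt: float = DEFAULT_DT_WEEKS
    horizon: float = DEFAULT_HORIZON_WEEKS
    integrator: Integrator = Integrator.EULER
    record_every: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if not (math.isfinite(self.horizon) and self.horizon > 0):
            raise ValueError(f"horizon must be > 0, got {self.horizon}")
        object.__setattr__(self, "integrator", Integrator(self.integrator))
        if self._ratio(self.horizon, self.dt) is None:
            raise ValueError(
                f"horizon ({self.horizon}) must be a positive multiple of dt ({self.dt})"
            )
        if self._ratio(self.record_every, self.dt) is None:
            raise ValueError(
                f"record_every ({self.record_every}) must be a multiple of dt ({self.dt})"
            )

    @staticmethod
    def _ratio(a: float, b: float) -> Union[int, None]:
        r = a / b
        n = round(r)
        if n >= 1 and abs(r - n) < 1e-9:
            return n
        return None

    @property
    def n_steps(self) -> int:
        return self._ratio(self.horizon, self.dt)  # type: ignore[return-value]

    @property
    def record_stride(self) -> int:
        return self._ratio(self.record_every, self.dt)  # type: ignore[return-value]


@dataclass(frozen=True)
class Trajectory:
    """Recorded simulation output: times (weeks) and a (T, 6) stock matrix.

    Columns follow PopulationState field order.
    """

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if times.ndim != 1 or states.shape != (times.size, 6):
            raise ValueError("times must be 1-D and states (len(times), 6)")
        if times.size == 0:
            raise ValueError("trajectory must be non-empty")
        if times[0] != 0.0 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing, starting at 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    def state_at(self, i: int) -> PopulationState:
        return PopulationState.from_array(self.states[i])

    @property
    def initial_state(self) -> PopulationState:
        return self.state_at(0)

    @property
    def final_state(self) -> PopulationState:
        return self.state_at(-1)

    def prevalence_series(self, group: Union[Group, str]) -> np.ndarray:
        """Percent overweight+obese in the group at every recorded time."""
        g = _as_group(group)
        block = self.states[:, :3] if g is Group.ADULT else self.states[:, 3:]
        return 100.0 * block[:, 1:].sum(axis=1) / block.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy frame: time_weeks, the six stocks, and both prevalence series."""
        cols = [f.name for f in fields(PopulationState)]
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "time_weeks", self.times)
        df["adult_prevalence_pct"] = self.prevalence_series(Group.ADULT)
        df["child_prevalence_pct"] = self.prevalence_series(Group.CHILD)
        return df


# ---------------------------------------------------------------------------
# Transition equations
# ---------------------------------------------------------------------------

def _rhs(x: np.ndarray, p: BehaviorParams) -> np.ndarray:
    """Raw right-hand side on a length-6 stock vector (fast path)."""
    n_a, s_a, o_a, n_c, s_c, o_c = x
    # Adult flows: infection is frequency-normalized mass action; recovery is
    # the engaged fraction of the stock, each transition taking p weeks.
    infect_a = p.beta_aa * n_a * (s_a + o_a)
    rec_sa = p.rho_awl * s_a / p.p_sa
    rec_oa = p.eps_awl * o_a / p.p_oa
    prog_a = p.gamma_a * s_a
    # Child flows: exposure to overweight/obese peers and adults, no
    # child-to-adult term anywhere in the adult equations above.
    infect_c = (p.beta_cc * (s_c + o_c) + p.beta_ac * (s_a + o_a)) * n_c
    rec_sc = p.rho_cwl * s_c / p.p_sc
    rec_oc = p.eps_cwl * o_c / p.p_oc
    prog_c = p.gamma_c * s_c
    return np.array(
        [
            -infect_a + rec_sa,
            infect_a - prog_a - rec_sa + rec_oa,
            prog_a - rec_oa,
            -infect_c + rec_sc,
            infect_c - prog_c - rec_sc + rec_oc,
            prog_c - rec_oc,
        ]
    )


def derivatives(state: PopulationState, params: BehaviorParams) -> StateDerivative:
    """Evaluate the transition equations at ``state``.

    Adult and child components each sum to zero (closed groups).
    """
    return StateDerivative(*(float(v) for v in _rhs(state.to_array(), params)))


ParamSchedule = Callable[[float], BehaviorParams]


def integrate(
    initial: PopulationState,
    schedule: Union[BehaviorParams, ParamSchedule],
    config: SimulationConfig = SimulationConfig(),
) -> Trajectory:
    """Integrate the model over ``config.horizon`` weeks.

    ``schedule`` is either a constant BehaviorParams or a callable mapping
    time (weeks) to BehaviorParams, which is how time-varying intervention
    effects enter the model. Fixed-step Euler (default) or classical RK4.

    Raises ValueError if a stock drops below ``NEGATIVE_STOCK_LIMIT``
    (step size too large for the parameters) or the state becomes non-finite.
    """
    if isinstance(schedule, BehaviorParams):
        const = schedule
        params_at: ParamSchedule = lambda t: const  # noqa: E731
    else:
        params_at = schedule

    dt = config.dt
    x = initial.to_array()
    times = [0.0]
    states = [x.copy()]
    for k in range(config.n_steps):
        t = k * dt
        if config.integrator is Integrator.EULER:
            x = x + dt * _rhs(x, params_at(t))
        else:
            k1 = _rhs(x, params_at(t))
            p_mid = params_at(t + dt / 2.0)
            k2 = _rhs(x + dt / 2.0 * k1, p_mid)
            k3 = _rhs(x + dt / 2.0 * k2, p_mid)
            k4 = _rhs(x + dt * k3, params_at(t + dt))
            x = x + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite state at t={t + dt} weeks")
        if x.min() < NEGATIVE_STOCK_LIMIT:
            raise ValueError(
                f"stock went below {NEGATIVE_STOCK_LIMIT} at t={t + dt} weeks; "
                "reduce dt"
            )
        if (
            abs(x[:3].sum() - 1.0) > STEP_ATOL
            or abs(x[3:].sum() - 1.0) > STEP_ATOL
        ):
            raise ValueError(f"group conservation violated at t={t + dt} weeks")
        x = np.clip(x, 0.0, 1.0)
        if (k + 1) % config.record_stride == 0:
            times.append((k + 1) * dt)
            states.append(x.copy())
    return Trajectory(np.array(times), np.array(states))


def prevalence(state: PopulationState, group: Union[Group, str]) -> float:
    """Percent overweight+obese in the chosen group: 100*(S+O)/(N+S+O)."""
    g = _as_group(group)
    if g is Group.ADULT:
        n, s, o = state.n_adult, state.ow_adult, state.ob_adult
    else:
        n, s, o = state.n_child, state.ow_child, state.ob_child
    return 100.0 * (s + o) / (n + s + o)


def growth_factor(traj: Trajectory, group: Union[Group, str]) -> float:
    """Final over initial prevalence for the group.

    The 10-year childhood value of this ratio is the model's behavioral
    pattern check against observed US surveillance trends.
    """
    series = traj.prevalence_series(group)
    if series[0] == 0.0:
        raise ValueError("growth factor undefined: initial prevalence is 0")
    return float(series[-1] / series[0])
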