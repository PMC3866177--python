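"""Configuration: baseline parameter values, JSON loading, validation.

The baseline values below parameterize the no-intervention model. Initial
stocks follow US 2009-2010 survey-scale prevalences; progression rates come
from the published cohort incidences (16%/4 yr adults, 4.3%/28 mo children);
transmission rates sit at the midpoint of the sensitivity range, with the
adult-to-child rate 50% higher than child-to-child; transition times come
from the transition-time formulas on plausible summary inputs; engagement
proportions are survey-scale placeholders calibrated so the no-intervention
10-year run reproduces the observed childhood prevalence growth pattern.
They are placeholders for unavailable published baseline values, and every
one is overridable from the config file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Optional, Union

from .interventions import DEFAULT_DISCOUNT, DEFAULT_MAGNITUDE
from .model import BehaviorParams, PopulationState, SimulationConfig

DEFAULT_CONFIG: Dict[str, Dict[str, Any]] = {
    "initial_state": {
        "n_adult": 0.31,
        "ow_adult": 0.33,
        "ob_adult": 0.36,
        "n_child": 0.665,
        "ow_child": 0.170,
        "ob_child": 0.165,
    },
    "params": {
        # transmission (per week): grid midpoint; adult-to-child 50% higher
        "beta_aa": 0.0015,
        "beta_cc": 0.0015,
        "beta_ac": 0.00225,
        # progression (per week): published cohort incidences
        "gamma_a": 0.000769,
        "gamma_c": 0.000354,
        # weight-loss engagement proportions (diet AND >=250 active min/week)
        "rho_awl": 0.10,
        "eps_awl": 0.10,
        "rho_cwl": 0.06,
        "eps_cwl": 0.06,
        # transition times (weeks): (change needed / yearly expected) * 52
        "p_sa": 56.73,   # 6.0 kg excess / 5.5 kg per year
        "p_oa": 122.91,  # 13.0 kg excess / 5.5 kg per year
        "p_sc": 52.0,    # 1.7 BMI units / 1.7 per year
        "p_oc": 104.0,   # 3.4 BMI units / 1.7 per year
    },
    "simulation": {
        "dt": 0.25,
        "horizon": 520.0,
        "integrator": "euler",
        "record_every": 1.0,
    },
    "interventions": {
        "magnitude": DEFAULT_MAGNITUDE,
        "discount": DEFAULT_DISCOUNT,
        # impact factors used by `simulate` with an explicit alternative;
        # scenario sweeps override them from the scenario catalog
        "psi_a": 0.50,
        "psi_c": 0.25,
    },
}


@dataclass(frozen=True)
class Config:
    """Validated full configuration."""

    initial_state: PopulationState
    params: BehaviorParams
    simulation: SimulationConfig
    magnitude: float
    discount: float
    psi_a: float
    psi_c: float
    raw: Dict[str, Dict[str, Any]] = field(repr=False, default_factory=dict)


def _merge_section(name: str, user: Mapping[str, Any]) -> Dict[str, Any]:
    defaults = DEFAULT_CONFIG[name]
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section '{name}'; "
            f"allowed: {sorted(defaults)}"
        )
    return {**defaults, **user}


def build_config(data: Optional[Mapping[str, Mapping[str, Any]]] = None) -> Config:
    """Validate a (possibly partial) config mapping, filling defaults.

    Unknown sections or keys are rejected with the offending name; value
    constraints are enforced by the domain types and reported with the key
    and constraint.
    """
    data = dict(data or {})
    unknown = set(data) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(
            f"unknown config section(s) {sorted(unknown)}; "
            f"allowed: {sorted(DEFAULT_CONFIG)}"
        )
    merged = {name: _merge_section(name, data.get(name, {})) for name in DEFAULT_CONFIG}
    iv = merged["interventions"]
    for key in ("magnitude", "discount", "psi_a", "psi_c"):
        v = iv[key]
        if not 0 <= v <= 1:
            raise ValueError(f"{key} must be in [0, 1], got {v}")
    return Config(
        initial_state=PopulationState(**merged["initial_state"]),
        params=BehaviorParams(**merged["params"]),
        simulation=SimulationConfig(**merged["simulation"]),
        magnitude=float(iv["magnitude"]),
        discount=float(iv["discount"]),
        psi_a=float(iv["psi_a"]),
        psi_c=float(iv["psi_c"]),
        raw=merged,
    )


def load_config(path: Optional[Union[str, Path]] = None) -> Config:
    """Load and validate a JSON config file; with no path, return defaults."""
    if path is None:
        return build_config()
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a JSON object")
    return build_config(data)
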