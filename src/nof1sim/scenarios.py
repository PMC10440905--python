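"""Study scenarios: crossover design parameters and carry-over/interaction switches.

Four scenarios span the 2x2 grid of {carry-over present, Activity-by-treatment
interaction present}:

====  ==========  ===========  =======================================
id    carry-over  interaction  carry-over parameters
====  ==========  ===========  =======================================
1     no          no           tau = gamma = 1
2     yes         no           tau1=6, gamma1=3, tau2=5, gamma2=4
3     no          yes          tau = gamma = 1
4     yes         yes          tau1=6, gamma1=3, tau2=5, gamma2=4
====  ==========  ===========  =======================================

The treatment effects on the pain outcome are -2 (treatment 1) and -4
(treatment 2) versus no treatment, i.e. a true effect difference of 2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources

from .errors import ConfigError
from .graph import CausalGraph, parse_graph

CARRY_OVER_TAU = (6.0, 5.0)
CARRY_OVER_GAMMA = (3.0, 4.0)
DEFAULT_W_AT = 1.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Design and generation parameters for one simulated study scenario."""

    scenario_id: int = 1
    carry_over: bool = False
    activity_interaction: bool = False
    missingness: bool = False
    blocks: int = 2
    periods_per_block: int = 2
    period_length: int = 28
    population_size: int = 1000
    treatment_effects: tuple[float, float] = (-2.0, -4.0)
    tau: tuple[float, float] = (1.0, 1.0)
    gamma: tuple[float, float] = (1.0, 1.0)
    w_at: float = 0.0
    effect_modifier: str = "activity"
    noise_scale: float = 1.0
    ordinal_outcome: bool = True
    outcome_floor: float = 0.0
    outcome_ceiling: float = 10.0
    missing_rate: float = 0.10
    missing_block_length: int = 10
    # None -> take the baseline-drift parameters from the graph's latent node
    drift_mean: float | None = None
    innovation_sd: float | None = None

    def __post_init__(self):
        if self.blocks < 1 or self.period_length < 1:
            raise ConfigError("blocks and period_length must be positive")
        if self.periods_per_block != 2:
            raise ConfigError("each block holds exactly one period per treatment")
        if any(t < 1 for t in self.tau) or any(g < 1 for g in self.gamma):
            raise ConfigError("tau and gamma must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")

    @property
    def n_days(self) -> int:
        return self.blocks * self.periods_per_block * self.period_length

    @property
    def true_effect_difference(self) -> float:
        """E[O | treatment 1] - E[O | treatment 2] at full exposure."""
        return self.treatment_effects[0] - self.treatment_effects[1]

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)


def scenario_config(scenario_id: int, **overrides) -> ScenarioConfig:
    """The :class:`ScenarioConfig` for one of the four study scenarios.

    Keyword overrides replace any field of the returned config (e.g.
    ``period_length=7`` or ``missingness=True``).
    """
    if scenario_id not in (1, 2, 3, 4):
        raise ConfigError(f"unknown scenario id {scenario_id!r}; expected 1..4")
    carry = scenario_id in (2, 4)
    interact = scenario_id in (3, 4)
    cfg = ScenarioConfig(
        scenario_id=scenario_id,
        carry_over=carry,
        activity_interaction=interact,
        tau=CARRY_OVER_TAU if carry else (1.0, 1.0),
        gamma=CARRY_OVER_GAMMA if carry else (1.0, 1.0),
        w_at=DEFAULT_W_AT if interact else 0.0,
    )
    bad = set(overrides) - {f.name for f in dataclasses.fields(ScenarioConfig)}
    if bad:
        raise ConfigError(f"unknown scenario overrides: {sorted(bad)}")
    return cfg.replace(**overrides) if overrides else cfg


def load_backpain_graph() -> CausalGraph:
    """The packaged default causal graph for the low-back-pain study."""
    text = resources.files("nof1sim.configs").joinpath("backpain.yaml").read_text()
    return parse_graph(text)
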