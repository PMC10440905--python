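"""Generation of per-day N-of-1 trial trajectories.

The simulator draws each patient's crossover schedule (blocks of two
treatment periods in random order), evolves the exponential-decay exposure
state of each treatment, integrates a latent Wiener-process baseline drift,
computes all covariates from the causal graph's linear structural equations,
and assembles the daily ordinal pain outcome.  Two dropout mechanisms can
mark days as missing row-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, Nof1SimError
from .graph import CausalGraph, topological_order
from .scenarios import ScenarioConfig
from .utils import as_rng, child_seeds

KEY_COLUMNS = ["patient_id", "day", "block", "period", "treatment"]


@dataclass(frozen=True)
class StudyDesign:
    """A per-day treatment schedule: labels in {1, 2} plus block/period indices."""

    treatment: np.ndarray
    block: np.ndarray
    period: np.ndarray

    @property
    def n_days(self) -> int:
        return len(self.treatment)

    @property
    def day(self) -> np.ndarray:
        return np.arange(1, self.n_days + 1)


def generate_design(seed, config: ScenarioConfig) -> StudyDesign:
    """Randomize a crossover schedule: per block, order AB or BA uniformly.

    With the default configuration this yields 2 blocks x 2 periods x 28 days
    = 112 days.
    """
    if config.blocks < 1 or config.period_length < 1:
        raise ConfigError("blocks and period_length must be positive")
    rng = as_rng(seed)
    m = config.period_length
    treatment, block, period = [], [], []
    for b in range(config.blocks):
        order = (1, 2) if rng.integers(0, 2) == 0 else (2, 1)
        for p, label in enumerate(order):
            treatment.extend([label] * m)
            block.extend([b + 1] * m)
            period.extend([b * 2 + p + 1] * m)
    return StudyDesign(
        treatment=np.asarray(treatment, dtype=np.int64),
        block=np.asarray(block, dtype=np.int64),
        period=np.asarray(period, dtype=np.int64),
    )


def exposure_decay(treatment_series, tau: float, gamma: float, e0: float = 0.0) -> np.ndarray:
    """Exponential-decay exposure E_k of one treatment along its on/off series.

        E_k^t = E_k^{t-1} + (1 - E_k^{t-1})/tau * T_k^t
                          - E_k^{t-1}/gamma * (1 - T_k^t)

    Under continuous exposure E rises toward 1 at rate 1/tau (wash-in); off
    treatment it decays toward 0 at rate 1/gamma (wash-out).  Returns the
    full path including the start value, so the output has one more entry
    than the input; E^0 defaults to 0 (no treatment effect at study start).
    """
    if tau < 1 or gamma < 1:
        raise ConfigError("tau and gamma must be >= 1 (the recursion stays in [0, 1])")
    t = np.asarray(treatment_series, dtype=float)
    if t.ndim != 1:
        raise ConfigError("treatment_series must be one-dimensional")
    if np.any((t != 0.0) & (t != 1.0)):
        raise ConfigError("treatment_series must be binary (0/1)")
    out = np.empty(len(t) + 1)
    out[0] = e = float(e0)
    for i, on in enumerate(t):
        e = e + (1.0 - e) / tau * on - e / gamma * (1.0 - on)
        out[i + 1] = e
    return out


def simulate_underlying_state(n_days: int, drift_mean: float, innovation_sd: float,
                              seed=None, u0: float = 0.0) -> np.ndarray:
    """Latent baseline state: discrete-time Wiener process with drift.

    U^0 = ``u0`` and U^t = U^{t-1} + N(drift_mean, innovation_sd**2); returns
    the path of length ``n_days + 1`` including U^0.
    """
    if innovation_sd < 0:
        raise ConfigError("innovation_sd must be >= 0")
    rng = as_rng(seed)
    increments = rng.normal(drift_mean, innovation_sd, size=n_days)
    out = np.empty(n_days + 1)
    out[0] = u0
    out[1:] = u0 + np.cumsum(increments)
    return out


def _lagged(values: np.ndarray, lag: int) -> np.ndarray:
    """Shift a daily series by ``lag`` days, padding the pre-study days with 0."""
    if lag == 0:
        return values
    out = np.zeros_like(values, dtype=float)
    if lag < len(values):
        out[lag:] = values[:-lag]
    return out


def _activity_center(graph: CausalGraph, config: ScenarioConfig) -> float:
    """Population mean of the effect-modifier node used to centre the interaction.

    Computed analytically assuming non-treatment parents of the modifier have
    mean zero: noise mean plus 0.5 times each lagged treatment edge weight
    (the treatment-2 indicator averages 1/2 under the randomized design).
    """
    node = graph.nodes[config.effect_modifier]
    center = node.noise_mean
    for e in graph.in_edges(config.effect_modifier):
        if graph.nodes[e.source].role == "treatment" and e.lag >= 1:
            center += 0.5 * e.weight
    return center


def _simulate_patient_arrays(graph: CausalGraph, design: StudyDesign,
                             config: ScenarioConfig, rng) -> dict[str, np.ndarray]:
    n = design.n_days
    t1 = (design.treatment == 1).astype(float)
    t2 = (design.treatment == 2).astype(float)
    e1 = exposure_decay(t1, config.tau[0], config.gamma[0])[1:]
    e2 = exposure_decay(t2, config.tau[1], config.gamma[1])[1:]
    treatment_name = graph.treatment
    outcome_name = graph.outcome
    values: dict[str, np.ndarray] = {}
    order = topological_order(graph)
    for name in order:
        node = graph.nodes[name]
        if node.role == "treatment":
            values[name] = design.treatment.astype(float)
            continue
        in_edges = graph.in_edges(name)
        if not in_edges:
            if node.distribution is None:
                raise ConfigError(f"node {name!r} has no parents and no distribution")
            dist = node.distribution
            if dist.kind == "wiener":
                drift = config.drift_mean if config.drift_mean is not None else dist.params[0]
                sd = (config.innovation_sd if config.innovation_sd is not None
                      else dist.params[1]) * config.noise_scale
                values[name] = simulate_underlying_state(n, drift, sd, rng)[1:]
            elif node.role == "constant":
                values[name] = np.full(n, float(dist.sample(rng)))
            else:
                values[name] = np.asarray(dist.sample(rng, size=n), dtype=float)
            if node.binary_threshold is not None:
                values[name] = (values[name] >= node.binary_threshold).astype(float)
            continue
        contrib = np.zeros(n)
        for e in in_edges:
            src = graph.nodes[e.source]
            if src.role == "treatment":
                if name == outcome_name:
                    continue  # direct treatment effect handled below
                if e.lag == 0:
                    # both treatments affect these targets equally; with no
                    # untreated days the on-treatment indicator is constant 1
                    contrib += e.weight
                elif config.activity_interaction:
                    # lagged treatment edges carry the treatment-2 contrast
                    # and are switched on with the interaction scenarios
                    contrib += e.weight * _lagged(t2, e.lag)
            else:
                if e.source not in values:
                    raise ConfigError(
                        f"lagged edge {e.source}->{name}: source must precede the "
                        "target in the zero-lag topological order"
                    )
                contrib += e.weight * _lagged(values[e.source], e.lag)
        sd = node.noise_sd * config.noise_scale
        if node.role == "constant":
            noise = node.noise_mean + sd * rng.normal()
        else:
            noise = node.noise_mean + sd * rng.normal(size=n)
        vals = contrib + noise
        if name == outcome_name and treatment_name is not None:
            eff1, eff2 = config.treatment_effects
            if config.activity_interaction and config.w_at != 0.0:
                mod = config.w_at * (
                    values[config.effect_modifier] - _activity_center(graph, config)
                )
                vals = vals + (eff1 + mod) * e1 + (eff2 + mod) * e2
            else:
                vals = vals + eff1 * e1 + eff2 * e2
            if config.ordinal_outcome:
                vals = np.round(np.clip(vals, config.outcome_floor, config.outcome_ceiling))
        elif node.binary_threshold is not None:
            vals = (vals >= node.binary_threshold).astype(float)
        values[name] = vals
    return values


def simulate_patient(graph: CausalGraph, design: StudyDesign, config: ScenarioConfig,
                     seed=None, patient_id: int = 0) -> pd.DataFrame:
    """Simulate one patient's daily record under ``design``.

    Exogenous nodes are drawn from their declared distributions, endogenous
    nodes computed in topological order from the weighted structural
    equations (with step-function thresholding for binary nodes), and the
    outcome combines covariate effects, the latent baseline drift and the
    per-treatment effects scaled by the exposure state.
    """
    rng = as_rng(seed)
    values = _simulate_patient_arrays(graph, design, config, rng)
    cols: dict[str, np.ndarray] = {
        "patient_id": np.full(design.n_days, patient_id, dtype=np.int64),
        "day": design.day,
        "block": design.block,
        "period": design.period,
        "treatment": design.treatment,
    }
    for name, node in graph.nodes.items():
        if node.observed and node.role not in ("treatment", "outcome"):
            cols[name] = values[name]
    cols[graph.outcome] = values[graph.outcome]
    cols["missing"] = np.zeros(design.n_days, dtype=bool)
    return pd.DataFrame(cols)


@dataclass
class Cohort:
    """A simulated population: one long-format table of patient-day rows."""

    data: pd.DataFrame
    config: ScenarioConfig | None = None
    seed: int | None = None
    graph: CausalGraph | None = field(default=None, repr=False)

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    @property
    def patient_ids(self) -> np.ndarray:
        return self.data["patient_id"].unique()

    def patients(self):
        """Iterate (patient_id, per-patient frame) in id order."""
        yield from self.data.groupby("patient_id", sort=True)

    def subset(self, patient_ids) -> pd.DataFrame:
        return self.data[self.data["patient_id"].isin(np.asarray(patient_ids))].copy()

    def time_varying_columns(self) -> list[str]:
        """Measurement columns masked row-wise by the dropout mechanisms."""
        if self.graph is not None:
            cols = [
                n.name for n in self.graph.nodes.values()
                if n.observed and n.role == "time_varying"
                and n.name in self.data.columns
            ]
            cols.append(self.graph.outcome)
            return cols
        return [c for c in self.data.columns if c not in KEY_COLUMNS + ["missing"]]


def simulate_cohort(graph: CausalGraph, config: ScenarioConfig, n_patients: int,
                    seed=None) -> Cohort:
    """Simulate ``n_patients`` independent trials with per-patient randomized designs.

    Each patient receives an independent sub-seed derived from the master
    seed through counter-based spawning, so cohorts are bit-reproducible and
    patients mutually independent.
    """
    if n_patients < 1:
        raise ConfigError("n_patients must be >= 1")
    seeds = child_seeds(seed, n_patients)
    frames = []
    for pid, sub in enumerate(seeds):
        rng = as_rng(sub)
        design = generate_design(rng, config)
        frames.append(simulate_patient(graph, design, config, rng, patient_id=pid))
    data = pd.concat(frames, ignore_index=True)
    master = seed if isinstance(seed, (int, np.integer)) else None
    return Cohort(data=data, config=config, seed=master, graph=graph)


def missingness_mask(n_days: int, rng, rate: float = 0.10,
                     block_length: int | None = 10) -> np.ndarray:
    """Boolean dropout mask for one patient's record.

    Mechanism 1 (random drop-out): each day t is deleted with probability
    p_t = c*t, linear in time, with c chosen so the expected deleted fraction
    equals ``rate``.  Mechanism 2 (vacation): one uniformly placed run of
    exactly ``block_length`` consecutive days.  Either mechanism can be
    disabled with ``rate=0`` / ``block_length=None``.
    """
    mask = np.zeros(n_days, dtype=bool)
    if rate > 0:
        t = np.arange(1, n_days + 1)
        p = np.minimum(2.0 * rate / (n_days + 1) * t, 1.0)
        mask |= rng.random(n_days) < p
    if block_length:
        if n_days < block_length:
            raise Nof1SimError(
                f"record of {n_days} days is too short for a {block_length}-day "
                "missing block"
            )
        start = int(rng.integers(0, n_days - block_length + 1))
        mask[start:start + block_length] = True
    return mask


def apply_missingness(cohort: Cohort, seed=None, rate: float | None = None,
                      block_length: int | None = 10) -> Cohort:
    """Mark days missing row-wise under the two dropout mechanisms.

    The underlying values are retained alongside the mask; writing the table
    to CSV emits NA for the masked measurement cells.
    """
    if rate is None:
        rate = cohort.config.missing_rate if cohort.config is not None else 0.10
    data = cohort.data.copy()
    pids = np.sort(data["patient_id"].unique())
    seeds = child_seeds(seed, len(pids))
    missing = data["missing"].to_numpy().copy()
    index_by_pid = data.groupby("patient_id", sort=True).indices
    for pid, sub in zip(pids, seeds):
        idx = index_by_pid[pid]
        order = np.argsort(data["day"].to_numpy()[idx], kind="stable")
        idx = idx[order]
        mask = missingness_mask(len(idx), as_rng(sub), rate=rate,
                                block_length=block_length)
        missing[idx] |= mask
    data["missing"] = missing
    return Cohort(data=data, config=cohort.config, seed=cohort.seed, graph=cohort.graph)
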