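"""Linear-Gaussian Bayesian-network estimation of the treatment effect.

Every node -- including 0/1-coded binary ones -- is modeled as Gaussian
given its parents, with a weak ridge-type Gaussian prior on the parent
weights (``prior_weight`` pseudo-observations; the posterior mean reduces to
OLS as the prior weight goes to 0).  The average treatment effect
difference is estimated by intervention sampling: the treatment node is
clamped to each arm on the mutilated graph, 1000 forward samples are drawn
per arm (confounders sampled from their fitted model, so both arms share the
same confounder distribution), and the difference of mean outcomes is
reported.

The *time-adjusted* variant augments the data with lag-1 copies of the
treatment and outcome, wired as: lagged treatment -> {treatment, activity,
outcome}, lagged outcome -> outcome, plus activity -> treatment so Activity
is adjusted for as a confounder.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ..errors import ConfigError, EstimationError, SchemaError
from ..graph import CausalGraph
from ..scenarios import load_backpain_graph
from ..utils import as_rng
from .base import BaseResults, OUTCOME, TREATMENT, as_frame

LAG_SUFFIX = "_lag1"


def augment_lags(data, lag: int = 1) -> pd.DataFrame:
    """Add within-patient lagged treatment/outcome columns; drop un-lagged days.

    The first ``lag`` days of every patient are removed because their lag
    values would predate the study.
    """
    df = as_frame(data).copy()
    for _, sub in df.groupby("patient_id"):
        if not sub["day"].is_monotonic_increasing:
            raise SchemaError("days must be sorted within patient before lagging")
    grouped = df.groupby("patient_id")
    for col in (TREATMENT, OUTCOME):
        df[col + LAG_SUFFIX] = grouped[col].shift(lag)
    df = df[grouped.cumcount() >= lag]
    return df.reset_index(drop=True)


def bn_structure(graph: CausalGraph, columns, time_adjust: bool = False) -> nx.DiGraph:
    """The network skeleton fitted to the data: observed zero-lag DAG, plus
    the lag-1 nodes/edges when ``time_adjust``."""
    cols = set(columns)
    g = nx.DiGraph()
    g.add_nodes_from(n for n in graph.nodes if n in cols)
    for e in graph.edges:
        if e.lag == 0 and e.source in cols and e.target in cols:
            g.add_edge(e.source, e.target)
    if time_adjust:
        t_lag, o_lag = TREATMENT + LAG_SUFFIX, OUTCOME + LAG_SUFFIX
        g.add_nodes_from([t_lag, o_lag])
        g.add_edge(t_lag, TREATMENT)
        if "activity" in cols:
            g.add_edge(t_lag, "activity")
            g.add_edge("activity", TREATMENT)
        g.add_edge(t_lag, OUTCOME)
        g.add_edge(o_lag, OUTCOME)
    return g


@dataclass
class NodeFit:
    parents: list[str]
    intercept: float
    coefs: np.ndarray
    resid_sd: float


@dataclass
class FittedNetwork:
    """Per-node linear-Gaussian conditionals over a DAG."""

    structure: nx.DiGraph
    nodes: dict[str, NodeFit]
    treatment: str = TREATMENT
    outcome: str = OUTCOME

    @property
    def order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.structure))


def fit_network(data, graph, prior_weight: float = 1.0,
                time_adjust: bool = False) -> FittedNetwork:
    """Fit each node's conditional by penalized least squares.

    ``graph`` may be a :class:`CausalGraph` (its observed zero-lag structure
    is used) or a prebuilt ``networkx.DiGraph``.  The prior adds
    ``prior_weight`` to the normal-equation diagonal of the parent weights
    (intercepts are unpenalized); a parentless node's intercept is the
    correspondingly shrunk sample mean.  Complete cases per node.
    """
    df = as_frame(data)
    if "missing" in df.columns:
        df = df[~df["missing"].astype(bool)]
    if isinstance(graph, CausalGraph):
        structure = bn_structure(graph, df.columns, time_adjust=time_adjust)
    else:
        structure = graph
    if prior_weight < 0:
        raise ConfigError("prior_weight must be >= 0")
    fits: dict[str, NodeFit] = {}
    for node in structure.nodes:
        parents = sorted(structure.predecessors(node))
        cols = [node] + parents
        sub = df[cols].dropna()
        y = sub[node].to_numpy(dtype=float)
        n = len(y)
        if n == 0:
            raise EstimationError(f"no complete cases to fit node {node!r}")
        if not parents:
            intercept = float(y.sum() / (n + prior_weight))
            resid = y - intercept
            sd = float(np.sqrt((resid @ resid) / max(n - 1, 1)))
            fits[node] = NodeFit([], intercept, np.empty(0), sd)
            continue
        X = np.column_stack([np.ones(n)] + [sub[p].to_numpy(dtype=float)
                                            for p in parents])
        p = X.shape[1]
        penalty = np.diag([0.0] + [prior_weight] * len(parents))
        M = X.T @ X + penalty
        if prior_weight == 0 and np.linalg.matrix_rank(X) < p:
            raise EstimationError(f"rank-deficient parent design for node {node!r}")
        try:
            beta = np.linalg.solve(M, X.T @ y)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(
                f"rank-deficient parent design for node {node!r}") from exc
        resid = y - X @ beta
        sd = float(np.sqrt((resid @ resid) / max(n - p, 1)))
        fits[node] = NodeFit(parents, float(beta[0]), beta[1:], sd)
    return FittedNetwork(structure=structure, nodes=fits)


@dataclass
class AteSample:
    """Per-arm forward samples of the outcome and their mean difference."""

    outcomes_arm1: np.ndarray
    outcomes_arm2: np.ndarray
    arms: tuple[float, float]

    @property
    def mean_arm1(self) -> float:
        return float(self.outcomes_arm1.mean())

    @property
    def mean_arm2(self) -> float:
        return float(self.outcomes_arm2.mean())

    @property
    def difference(self) -> float:
        return self.mean_arm1 - self.mean_arm2


def _forward_sample(network: FittedNetwork, arm: float, n_samples: int, rng):
    values: dict[str, np.ndarray] = {}
    for node in network.order:
        if node == network.treatment:
            values[node] = np.full(n_samples, float(arm))
            continue
        fit = network.nodes.get(node)
        if fit is None:
            raise EstimationError(f"node {node!r} on a sampling path was not fitted")
        mean = fit.intercept
        if fit.parents:
            mean = fit.intercept + sum(
                w * values[p] for w, p in zip(fit.coefs, fit.parents))
        values[node] = mean + rng.normal(0.0, fit.resid_sd, size=n_samples)
    return values[network.outcome]


def estimate_ate(network: FittedNetwork, n_samples: int = 1000, seed=None,
                 arms: tuple[float, float] = (1.0, 2.0)) -> AteSample:
    """Intervention sampling of the mean outcome difference between arms.

    The treatment node is clamped to each arm value on the mutilated graph
    and ``n_samples`` forward samples drawn per arm; the returned difference
    is mean(outcome | do(arm 1)) - mean(outcome | do(arm 2)).
    """
    rng = as_rng(seed)
    o1 = _forward_sample(network, arms[0], n_samples, rng)
    o2 = _forward_sample(network, arms[1], n_samples, rng)
    return AteSample(o1, o2, arms)


def total_effect(network: FittedNetwork, source: str | None = None,
                 target: str | None = None) -> float:
    """Closed-form total causal effect per unit of ``source`` on ``target``:
    the sum over all directed paths of the products of fitted edge weights."""
    source = source or network.treatment
    target = target or network.outcome
    weights = {
        (p, node): w
        for node, fit in network.nodes.items()
        for p, w in zip(fit.parents, fit.coefs)
    }
    out = 0.0
    for path in nx.all_simple_paths(network.structure, source, target):
        out += float(np.prod([weights[(a, b)] for a, b in zip(path, path[1:])]))
    return out


class BayesianNetworkATE:
    """Model object: Bayesian-network ATE estimation, with or without lags."""

    def __init__(self, data, graph: CausalGraph | None = None,
                 time_adjust: bool = False, prior_weight: float = 1.0):
        self.graph = graph if graph is not None else load_backpain_graph()
        self.time_adjust = bool(time_adjust)
        self.prior_weight = prior_weight
        df = as_frame(data)
        self.df = augment_lags(df) if self.time_adjust else df

    def fit(self, n_samples: int = 1000, seed=None) -> "BayesianNetworkResults":
        network = fit_network(self.df, self.graph, prior_weight=self.prior_weight,
                              time_adjust=self.time_adjust)
        ate = estimate_ate(network, n_samples=n_samples, seed=seed)
        return BayesianNetworkResults(network, ate, self.time_adjust)


class BayesianNetworkResults(BaseResults):
    def __init__(self, network: FittedNetwork, ate_sample: AteSample, time_adjust: bool):
        self.network = network
        self.ate_sample = ate_sample
        self.time_adjust = time_adjust

    @property
    def method(self) -> str:  # type: ignore[override]
        return "bn_time" if self.time_adjust else "bn"

    @property
    def effect_difference(self) -> float:
        return self.ate_sample.difference

    def _extra(self):
        return {
            "mean_outcome_arm1": self.ate_sample.mean_arm1,
            "mean_outcome_arm2": self.ate_sample.mean_arm2,
            "n_samples": len(self.ate_sample.outcomes_arm1),
        }
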