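"""Declarative causal data-generating model: nodes, weighted/lagged edges, DAG checks.

The generator is parameterized by a directed graph of linear structural
equations.  Each endogenous node is a weighted sum of its parents plus
Gaussian noise (optionally thresholded to produce a binary variable);
exogenous nodes are drawn from a declared distribution.  Zero-lag edges must
form a DAG; lagged edges (``lag >= 1``) reference earlier time points and may
therefore point "backwards" without creating a cycle.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import networkx as nx
import yaml

from .errors import ConfigError, GraphCycleError

NODE_ROLES = ("constant", "time_varying", "treatment", "outcome")
DISTRIBUTIONS = ("bernoulli", "gaussian", "poisson", "uniform", "wiener")

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Distribution:
    """An exogenous sampling distribution.

    kinds and params:
      bernoulli(p) | gaussian(mean, sd) | poisson(lam) | uniform(low, high)
      | wiener(drift, sd)  -- a discrete-time random walk (used for the
        latent baseline-drift state; the simulator integrates it over days).
    """

    kind: str
    params: tuple[float, ...]

    def __post_init__(self):
        if self.kind not in DISTRIBUTIONS:
            raise ConfigError(f"unknown distribution kind {self.kind!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.kind == "bernoulli" and not 0.0 <= self.params[0] <= 1.0:
            raise ConfigError("bernoulli probability must be in [0, 1]")
        if self.kind in ("gaussian", "wiener") and self.params[1] < 0:
            raise ConfigError(f"{self.kind} sd must be >= 0")
        if self.kind == "poisson" and self.params[0] < 0:
            raise ConfigError("poisson rate must be >= 0")

    def sample(self, rng, size=None):
        if self.kind == "bernoulli":
            return rng.binomial(1, self.params[0], size=size).astype(float)
        if self.kind == "gaussian":
            return rng.normal(self.params[0], self.params[1], size=size)
        if self.kind == "poisson":
            return rng.poisson(self.params[0], size=size).astype(float)
        if self.kind == "uniform":
            return rng.uniform(self.params[0], self.params[1], size=size)
        raise ConfigError(f"distribution {self.kind!r} cannot be sampled directly")


@dataclass(frozen=True)
class NodeSpec:
    """One variable of the structural model.

    ``distribution`` is used when the node has no incoming edges (exogenous
    draw); otherwise the node value is the weighted parent sum plus noise
    ``N(noise_mean, noise_sd**2)``.  ``binary_threshold`` applies the step
    function 1[value >= threshold] after summation.  ``observed=False`` keeps
    the node out of the emitted data table (latent state).
    """

    name: str
    role: str = "time_varying"
    distribution: Distribution | None = None
    noise_mean: float = 0.0
    noise_sd: float = 1.0
    binary_threshold: float | None = None
    observed: bool = True

    def __post_init__(self):
        if self.role not in NODE_ROLES:
            raise ConfigError(f"node {self.name!r}: unknown role {self.role!r}")
        if self.noise_sd < 0:
            raise ConfigError(f"node {self.name!r}: noise sd must be >= 0")


@dataclass(frozen=True)
class EdgeSpec:
    """A weighted causal effect of ``source`` on ``target`` at lag ``lag``."""

    source: str
    target: str
    weight: float
    lag: int = 0

    def __post_init__(self):
        if self.lag < 0:
            raise ConfigError(f"edge {self.source}->{self.target}: lag must be >= 0")
        object.__setattr__(self, "weight", float(self.weight))
        object.__setattr__(self, "lag", int(self.lag))


@dataclass
class CausalGraph:
    """A validated collection of node and edge specifications.

    ``tau``/``gamma`` are the default per-treatment wash-in/wash-out
    parameters of the exponential-decay exposure (both 1 = no carry-over) and
    ``w_at`` the Activity-by-treatment effect-modifier weight; scenario
    configurations normally override them at simulation time.
    """

    nodes: dict[str, NodeSpec] = field(default_factory=dict)
    edges: list[EdgeSpec] = field(default_factory=list)
    tau: tuple[float, float] = (1.0, 1.0)
    gamma: tuple[float, float] = (1.0, 1.0)
    w_at: float = 0.0

    def __post_init__(self):
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.nodes:
                    raise ConfigError(
                        f"edge {e.source}->{e.target} references undeclared node "
                        f"{endpoint!r}"
                    )
        outcomes = [n for n in self.nodes.values() if n.role == "outcome"]
        if self.nodes and len(outcomes) != 1:
            raise ConfigError(
                f"exactly one node must have role='outcome' (found {len(outcomes)})"
            )
        treatments = [n for n in self.nodes.values() if n.role == "treatment"]
        if len(treatments) > 1:
            raise ConfigError("at most one node may have role='treatment'")
        if any(t < 1 for t in self.tau) or any(g < 1 for g in self.gamma):
            raise ConfigError("wash-in tau and wash-out gamma must be >= 1")
        # acyclicity of the zero-lag subgraph
        g = self.zero_lag_digraph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = [u for u, _ in nx.find_cycle(g)]
            raise GraphCycleError(cycle)

    def zero_lag_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(
            (e.source, e.target, {"weight": e.weight})
            for e in self.edges
            if e.lag == 0
        )
        return g

    def in_edges(self, name: str) -> list[EdgeSpec]:
        return [e for e in self.edges if e.target == name]

    @property
    def outcome(self) -> str:
        return next(n.name for n in self.nodes.values() if n.role == "outcome")

    @property
    def treatment(self) -> str | None:
        return next(
            (n.name for n in self.nodes.values() if n.role == "treatment"), None
        )

    def observed_covariates(self) -> list[str]:
        """Observed nodes other than treatment and outcome, declaration order."""
        return [
            n.name
            for n in self.nodes.values()
            if n.observed and n.role not in ("treatment", "outcome")
        ]

    def replace(self, **kwargs) -> "CausalGraph":
        return replace(self, **kwargs)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        nodes = []
        for n in self.nodes.values():
            d: dict = {"name": n.name, "role": n.role}
            if n.distribution is not None:
                d["distribution"] = {
                    "kind": n.distribution.kind,
                    "params": list(n.distribution.params),
                }
            d["noise"] = {"mean": n.noise_mean, "sd": n.noise_sd}
            if n.binary_threshold is not None:
                d["binary_threshold"] = n.binary_threshold
            if not n.observed:
                d["observed"] = False
            nodes.append(d)
        edges = [
            {"source": e.source, "target": e.target, "weight": e.weight, "lag": e.lag}
            for e in self.edges
        ]
        return {
            "schema": SCHEMA_VERSION,
            "nodes": nodes,
            "edges": edges,
            "carry_over": {
                "tau": list(self.tau),
                "gamma": list(self.gamma),
            },
            "activity_interaction_weight": self.w_at,
        }


def serialize_graph(graph: CausalGraph) -> str:
    """YAML text for ``graph``; ``parse_graph`` round-trips it exactly."""
    buf = io.StringIO()
    yaml.safe_dump(graph.to_dict(), buf, sort_keys=False)
    return buf.getvalue()


def _node_from_dict(d: dict) -> NodeSpec:
    if "name" not in d:
        raise ConfigError(f"node entry without a name: {d!r}")
    dist = None
    if "distribution" in d:
        dd = d["distribution"]
        try:
            dist = Distribution(dd["kind"], tuple(dd["params"]))
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"node {d['name']!r}: malformed distribution: {dd!r}") from exc
    noise = d.get("noise", {})
    return NodeSpec(
        name=str(d["name"]),
        role=d.get("role", "time_varying"),
        distribution=dist,
        noise_mean=float(noise.get("mean", 0.0)),
        noise_sd=float(noise.get("sd", 1.0)),
        binary_threshold=(
            float(d["binary_threshold"]) if d.get("binary_threshold") is not None else None
        ),
        observed=bool(d.get("observed", True)),
    )


def _edge_from_dict(d: dict) -> EdgeSpec:
    try:
        weight = float(d.get("weight", 1.0))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"malformed edge weight in {d!r}") from exc
    try:
        return EdgeSpec(str(d["source"]), str(d["target"]), weight, int(d.get("lag", 0)))
    except KeyError as exc:
        raise ConfigError(f"edge entry missing source/target: {d!r}") from exc


def parse_dagitty(text: str) -> list[tuple[str, str]]:
    """Parse DAGitty-style ``A -> B`` lines into (source, target) pairs."""
    pairs = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip().rstrip(";")
        if not line or line.startswith(("dag", "{", "}")):
            continue
        if "->" not in line:
            raise ConfigError(f"cannot parse edge line {raw!r}")
        left, right = (part.strip() for part in line.split("->", 1))
        if not left or not right:
            raise ConfigError(f"cannot parse edge line {raw!r}")
        pairs.append((left, right))
    return pairs


def parse_graph(config) -> CausalGraph:
    """Build a validated :class:`CausalGraph` from config text or a dict.

    Accepts YAML/JSON text (or an already-parsed mapping) following the
    ``schema: 1`` layout with a ``nodes:`` table and an ``edges:`` list.
    Edges may alternatively be given as a DAGitty-style edge list under the
    ``dagitty`` key (one ``src -> dst`` per line) with optional per-edge
    weights in a ``weights: {"src -> dst": w}`` mapping.
    """
    if isinstance(config, str):
        try:
            data = yaml.safe_load(config)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse graph config: {exc}") from exc
    else:
        data = config
    if not isinstance(data, dict):
        raise ConfigError("graph config must be a mapping")
    nodes = {}
    for nd in data.get("nodes", []):
        node = _node_from_dict(nd)
        if node.name in nodes:
            raise ConfigError(f"duplicate node {node.name!r}")
        nodes[node.name] = node
    edges = [_edge_from_dict(ed) for ed in data.get("edges", [])]
    if "dagitty" in data:
        weights = data.get("weights", {})
        for src, dst in parse_dagitty(data["dagitty"]):
            key = f"{src} -> {dst}"
            edges.append(EdgeSpec(src, dst, float(weights.get(key, 1.0)), 0))
    carry = data.get("carry_over", {})
    return CausalGraph(
        nodes=nodes,
        edges=edges,
        tau=tuple(carry.get("tau", (1.0, 1.0))),
        gamma=tuple(carry.get("gamma", (1.0, 1.0))),
        w_at=float(data.get("activity_interaction_weight", 0.0)),
    )


def topological_order(graph: CausalGraph) -> list[str]:
    """Topological order of the zero-lag subgraph, ties broken lexicographically.

    Every zero-lag edge goes from an earlier to a later list position, and the
    output is deterministic for a fixed graph.
    """
    g = graph.zero_lag_digraph()
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = [u for u, _ in nx.find_cycle(g)]
        raise GraphCycleError(cycle) from None
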