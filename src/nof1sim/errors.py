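"""Exception hierarchy for nof1sim."""


class Nof1SimError(Exception):
    """Base class for all package errors."""


class ConfigError(Nof1SimError):
    """Invalid model/scenario configuration (bad parameters, unknown names)."""


class GraphCycleError(ConfigError):
    """The zero-lag subgraph contains a directed cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(
            "cycle in zero-lag graph: " + " -> ".join(self.cycle + [self.cycle[0]])
        )


class SchemaError(Nof1SimError):
    """A data table does not conform to the expected long-format schema."""


class EstimationError(Nof1SimError):
    """An estimator could not produce a fit (rank deficiency, empty groups, ...)."""


class BracketingError(EstimationError):
    """A root search interval does not bracket a sign change."""
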