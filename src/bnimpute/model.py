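"""Model/Results interface over the structure-learning machinery.

:class:`BayesianNetwork` is built from data (a :class:`MixedDataset` or a
pandas DataFrame) together with a score and constraints; ``fit`` runs the
structure search and returns a :class:`StructureResults` carrying the
best-fit DAG, its score, per-edge significance and a summary table;
``fit_average`` runs the bootstrap and returns an
:class:`AverageNetworkResults` with per-pair strength/direction records.
Missing data is handled before fitting through ``impute`` (network-guided
nearest neighbour) or ``reduce`` (complete cases).
"""

from __future__ import annotations

import pandas as pd

from .averaging import (
    AverageNetwork,
    bootstrap_average,
    edge_significance_lrt,
    strength_threshold,
)
from .dataset import ConfigurationError, MixedDataset, VariableSpec
from .graphs import ConstraintSet, NetworkStructure, cpdag, validate_structure
from .impute import ImputationConfig, impute
from .scoring import ScoreSpec
from .search import SearchConfig, exhaustive_search, greedy_search

__all__ = ["BayesianNetwork", "StructureResults", "AverageNetworkResults"]


class BayesianNetwork:
    """A score-based Bayesian network model of a mixed dataset.

    Parameters
    ----------
    data : MixedDataset
        The individuals-by-variables table (may contain missing values;
        see ``impute``/``reduce``).
    score : str or ScoreSpec
        ``"loglik"``, ``"aic"`` or ``"bic"`` (default).
    constraints : ConstraintSet, optional
        White/black lists and soft directed-edge priors.
    """

    def __init__(self, data: MixedDataset, score="bic", constraints=None):
        self.data = data
        self.score = score if isinstance(score, ScoreSpec) else ScoreSpec(score)
        self.constraints = constraints or ConstraintSet()
        self.constraints.check_nodes(data.names)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        discrete=(),
        genetic=(),
        score="bic",
        constraints=None,
    ):
        """Build from a DataFrame, declaring discrete/genetic columns by
        name; everything else is treated as continuous."""
        discrete, genetic = set(discrete), set(genetic)
        variables = [
            VariableSpec(
                c,
                "discrete" if c in discrete else "continuous",
                genetic=c in genetic,
            )
            for c in frame.columns
        ]
        return cls(MixedDataset(variables, frame), score, constraints)

    # -- missing-data handling ----------------------------------------------

    def impute(self, config: ImputationConfig = None):
        """Network-guided nearest-neighbour imputation; returns a new
        model on the completed data (provenance on ``.provenance_``)."""
        filled, prov = impute(self.data, config, self.constraints)
        new = BayesianNetwork(filled, self.score, self.constraints)
        new.provenance_ = prov
        return new

    def reduce(self):
        """Complete-case model (the "Reduced" strategy)."""
        return BayesianNetwork(
            self.data.complete_rows(), self.score, self.constraints
        )

    # -- fitting -------------------------------------------------------------

    def fit(self, method="greedy", config: SearchConfig = None, max_nodes=5):
        """Search for the best-fit structure.

        ``method`` is ``"greedy"`` (hill climbing with restarts) or
        ``"exhaustive"`` (global optimum, small networks only).
        """
        config = config or SearchConfig()
        if method == "greedy":
            dag, score = greedy_search(
                self.data, self.score, self.constraints, config
            )
        elif method == "exhaustive":
            dag, score = exhaustive_search(
                self.data, self.score, self.constraints, max_nodes=max_nodes
            )
        else:
            raise ConfigurationError(f"unknown fit method {method!r}")
        return StructureResults(self, dag, score, method, config)

    def fit_average(self, B=1000, config: SearchConfig = None, seed=0):
        """Bootstrap model averaging; returns per-pair strength and
        direction summaries."""
        avg = bootstrap_average(
            self.data, self.score, self.constraints,
            config or SearchConfig(), B=B, seed=seed,
        )
        return AverageNetworkResults(self, avg)


class StructureResults:
    """Best-fit structure, its score and per-edge diagnostics."""

    def __init__(self, model, dag, score, method, config):
        self.model = model
        self.dag: NetworkStructure = dag
        self.score = score
        self.method = method
        self.config = config

    def validate(self):
        return validate_structure(self.dag, self.model.constraints)

    def cpdag(self):
        """Equivalence-class representative of the fitted structure."""
        return cpdag(self.dag)

    def edge_significance(self, edge):
        """Likelihood-ratio chi-square for one fitted edge."""
        return edge_significance_lrt(
            self.model.data, self.dag, edge, self.model.score
        )

    def summary(self) -> str:
        lines = [
            "Bayesian network structure fit",
            f"  individuals: {self.model.data.n}",
            f"  variables:   {self.model.data.p}",
            f"  score ({self.model.score.type}): {self.score:.4f}",
            f"  search:      {self.method}",
            f"  edges:       {len(self.dag.edges)}",
            "",
            f"{'from':<16}{'to':<16}{'chi2':>10}{'df':>4}{'p':>12}",
        ]
        for u, v in sorted(self.dag.edges):
            sig = self.edge_significance((u, v))
            if sig.available:
                lines.append(
                    f"{u:<16}{v:<16}{sig.chi2:>10.3f}{sig.df:>4}"
                    f"{sig.p_value:>12.3g}"
                )
            else:
                lines.append(f"{u:<16}{v:<16}{'n/a':>10}{'':>4}{'':>12}")
        return "\n".join(lines)

    def to_dot(self):
        attrs = {}
        for u, v in self.dag.edges:
            sig = self.edge_significance((u, v))
            if sig.available:
                width = 1.0 + min(4.0, sig.chi2 / 10.0)
                attrs[(u, v)] = {"penwidth": f"{width:.2f}"}
        return self.dag.to_dot(edge_attrs=attrs)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v in sorted(self.dag.edges):
            sig = self.edge_significance((u, v))
            rows.append(
                {"from": u, "to": v, "chi2": sig.chi2, "df": sig.df,
                 "p_value": sig.p_value}
            )
        return pd.DataFrame(rows, columns=["from", "to", "chi2", "df", "p_value"])


class AverageNetworkResults:
    """Bootstrap average network: strengths, directions and thresholds."""

    def __init__(self, model, average: AverageNetwork):
        self.model = model
        self.average = average

    @property
    def table(self) -> pd.DataFrame:
        return self.average.to_frame()

    def strength_threshold(self) -> float:
        return strength_threshold(self.average)

    def directed_edge_probability(self, u, v, decimals=None):
        return self.average.pair(u, v).edge_probability(u, v, decimals)

    def consensus(self, threshold=None) -> NetworkStructure:
        return self.average.consensus(threshold)

    def to_dot(self, threshold=None) -> str:
        return self.average.to_dot(threshold)

    def summary(self) -> str:
        frame = self.table
        lines = [
            "Bootstrap average network",
            f"  bootstraps:  {self.average.B}",
            f"  pairs seen:  {len(frame)}",
        ]
        try:
            lines.append(f"  threshold:   {self.strength_threshold():.3f}")
        except ValueError:
            pass
        lines.append("")
        lines.append(frame.to_string(index=False))
        return "\n".join(lines)
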