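"""Synthetic-data generators: structural models, scenario catalogue and
missingness injectors.

Continuous nodes follow a linear-Gaussian structural equation
``child = sum beta * parent + N(0, sd^2)`` with unit noise by default;
the effect strength beta is the key difficulty dial of every scenario.
Discrete nodes are sampled from conditional probability tables; SNP nodes
are Binomial(2, allele frequency) allele dosages stored as continuous
genetic variables.  Data are drawn by ancestral sampling in topological
order, so ``beta = 0`` makes a child marginally independent of that
parent.

Missingness injectors reproduce the benchmark patterns: a fixed count of
individuals missing a single variable, a fixed count split across a set
of variables (each individual missing exactly one), a per-variable
missingness probability, and a MAR mechanism in which the missingness
probability depends on a fully observed covariate through a logistic
link.  MNAR mechanisms are deliberately absent: the imputation method
assumes MAR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ConfigurationError, MixedDataset, VariableSpec
from .graphs import NetworkStructure

__all__ = [
    "ContinuousNode",
    "DiscreteNode",
    "SnpNode",
    "SimulationModel",
    "MissingnessPattern",
    "simulate",
    "inject_missingness",
    "builtin_scenario",
    "Scenario",
    "linear_gaussian_model",
    "SCENARIOS",
    "read_gaussian_network",
    "write_gaussian_network",
]


@dataclass
class ContinuousNode:
    """Linear-Gaussian local model: betas maps parent name -> coefficient."""

    betas: dict = field(default_factory=dict)
    noise_sd: float = 1.0
    intercept: float = 0.0


@dataclass
class DiscreteNode:
    """Multinomial local model.

    ``cpt`` maps a tuple of parent levels (ordered as ``parents``) to a
    probability vector over ``levels``; root nodes use the empty tuple.
    """

    levels: tuple
    parents: tuple = ()
    cpt: dict = field(default_factory=dict)

    def validate(self):
        for key, probs in self.cpt.items():
            probs = np.asarray(probs, dtype=float)
            if len(probs) != len(self.levels):
                raise ConfigurationError(
                    f"CPT row {key} has {len(probs)} entries for "
                    f"{len(self.levels)} levels"
                )
            if abs(probs.sum() - 1.0) > 1e-6:
                raise ConfigurationError(f"CPT row {key} sums to {probs.sum()}")


@dataclass
class SnpNode:
    """Biallelic SNP: dosage ~ Binomial(2, allele_freq), coded continuous."""

    allele_freq: float = 0.5


@dataclass
class SimulationModel:
    """A generating structural model over a network structure."""

    structure: NetworkStructure
    nodes: dict

    def __post_init__(self):
        order = self.structure.topological_order()
        if order is None:
            raise ConfigurationError("simulation structure is cyclic")
        for name in self.structure.node_names:
            if name not in self.nodes:
                raise ConfigurationError(f"no local model for node {name!r}")
        self._order = order

    @property
    def variables(self):
        return self.structure.variables


def simulate(model: SimulationModel, n: int, seed: int = 0) -> MixedDataset:
    """Ancestral sampling of ``n`` individuals; bit-reproducible by seed."""
    rng = np.random.default_rng(seed)
    columns: dict = {}
    for name in model._order:
        node = model.nodes[name]
        parents = sorted(model.structure.parents(name))
        if isinstance(node, SnpNode):
            columns[name] = rng.binomial(2, node.allele_freq, size=n).astype(float)
        elif isinstance(node, ContinuousNode):
            x = rng.normal(0.0, node.noise_sd, size=n) + node.intercept
            for p_ in parents:
                beta = node.betas.get(p_, 0.0)
                parent_col = columns[p_]
                if isinstance(parent_col[0], str):
                    raise ConfigurationError(
                        f"continuous node {name!r} has discrete parent {p_!r}"
                    )
                x = x + beta * parent_col
            columns[name] = x
        elif isinstance(node, DiscreteNode):
            node.validate()
            if tuple(sorted(node.parents)) != tuple(parents):
                raise ConfigurationError(
                    f"CPT parents of {name!r} do not match structure"
                )
            out = np.empty(n, dtype=object)
            if not parents:
                probs = np.asarray(node.cpt[()], dtype=float)
                idx = rng.choice(len(node.levels), size=n, p=probs)
                out[:] = np.asarray(node.levels, dtype=object)[idx]
            else:
                pcols = [columns[p_] for p_ in node.parents]
                keys = pd.MultiIndex.from_arrays(pcols)
                for cfg_key, probs in node.cpt.items():
                    sel = np.asarray(keys == cfg_key)
                    k = int(sel.sum())
                    if k:
                        idx = rng.choice(
                            len(node.levels), size=k, p=np.asarray(probs, float)
                        )
                        out[sel] = np.asarray(node.levels, dtype=object)[idx]
                if any(v is None for v in out):
                    raise ConfigurationError(
                        f"CPT of {name!r} does not cover every parent "
                        f"configuration in the sample"
                    )
            columns[name] = out
        else:
            raise ConfigurationError(f"unknown node model for {name!r}")
    frame = pd.DataFrame(
        {v.name: columns[v.name] for v in model.variables}
    )
    return MixedDataset(model.variables, frame)


@dataclass
class MissingnessPattern:
    """A missingness specification over named variables.

    Modes: ``fixed_count_single_variable`` (exactly ``count`` individuals
    lose the one variable), ``split_across_variables`` (exactly ``count``
    individuals each lose exactly one of the variables, allocated round
    robin), ``per_variable_probability`` (each entry masked independently
    with its variable's probability), ``mar_logistic`` (entry masked with
    probability expit(intercept + slope * standardised covariate)).
    """

    mode: str
    variables: tuple = ()
    count: int = 0
    probabilities: dict = field(default_factory=dict)
    covariate: str = None
    intercept: float = 0.0
    slope: float = 1.0

    @classmethod
    def fixed_count(cls, variable, count):
        return cls("fixed_count_single_variable", (variable,), count=count)

    @classmethod
    def split(cls, variables, count):
        return cls("split_across_variables", tuple(variables), count=count)

    @classmethod
    def probability(cls, probabilities):
        return cls(
            "per_variable_probability",
            tuple(probabilities),
            probabilities=dict(probabilities),
        )

    @classmethod
    def mar(cls, variables, covariate, intercept=0.0, slope=1.0):
        return cls(
            "mar_logistic",
            tuple(variables),
            covariate=covariate,
            intercept=intercept,
            slope=slope,
        )

    @classmethod
    def none(cls):
        return cls("none")


def inject_missingness(
    data: MixedDataset, pattern: MissingnessPattern, seed: int = 0
) -> MixedDataset:
    """Mask entries of ``data`` per the pattern; fixed-count modes are
    exact, probability modes exact in expectation."""
    for v in pattern.variables:
        if v not in data:
            raise ConfigurationError(f"pattern references unknown variable {v!r}")
    rng = np.random.default_rng(seed)
    frame = data.frame.copy()
    n = data.n
    if pattern.mode == "none":
        return data.copy()
    if pattern.mode in ("fixed_count_single_variable", "split_across_variables"):
        if pattern.count > n:
            raise ConfigurationError(
                f"requested {pattern.count} missing individuals from {n}"
            )
        rows = rng.choice(n, size=pattern.count, replace=False)
        targets = pattern.variables
        for k, r in enumerate(rows):
            var = targets[k % len(targets)]
            frame.iloc[int(r), frame.columns.get_loc(var)] = np.nan
    elif pattern.mode == "per_variable_probability":
        for var, p_ in pattern.probabilities.items():
            hit = rng.random(n) < p_
            frame.loc[hit, var] = np.nan
    elif pattern.mode == "mar_logistic":
        cov = pd.to_numeric(data.frame[pattern.covariate]).to_numpy(float)
        z = (cov - cov.mean()) / (cov.std() or 1.0)
        prob = 1.0 / (1.0 + np.exp(-(pattern.intercept + pattern.slope * z)))
        for var in pattern.variables:
            if var == pattern.covariate:
                raise ConfigurationError("MAR covariate must stay observed")
            hit = rng.random(n) < prob
            frame.loc[hit, var] = np.nan
    else:
        raise ConfigurationError(f"unknown missingness mode {pattern.mode!r}")
    return MixedDataset(data.variables, frame)


def linear_gaussian_model(
    edges, beta=0.5, genetic=(), snp_nodes=(), allele_freq=0.5, noise_sd=1.0
) -> SimulationModel:
    """Uniform-effect linear-Gaussian model over the given directed edges.

    ``snp_nodes`` are generated as Binomial(2, allele_freq) dosages and
    flagged genetic along with any names in ``genetic``.
    """
    names = sorted({u for e in edges for u in e})
    snp_nodes = set(snp_nodes)
    genetic = set(genetic) | snp_nodes
    variables = [
        VariableSpec(n_, "continuous", genetic=n_ in genetic) for n_ in names
    ]
    structure = NetworkStructure(variables, edges)
    nodes = {}
    for name in names:
        if name in snp_nodes:
            nodes[name] = SnpNode(allele_freq)
        else:
            betas = {u: beta for (u, v) in edges if v == name}
            nodes[name] = ContinuousNode(betas=betas, noise_sd=noise_sd)
    return SimulationModel(structure, nodes)


@dataclass
class Scenario:
    """A catalogue entry: complete data, observed (masked) data, the
    generating structure, and the missingness pattern used."""

    name: str
    full: MixedDataset
    data: MixedDataset
    truth: NetworkStructure
    pattern: MissingnessPattern


def _three_node(edges, stars):
    return {"edges": edges, "stars": stars, "n_default": 2000, "miss": 1800}


# The 3-variable catalogue entries and the soft-prior demonstration
# network are documented stand-ins for figure-only benchmark models: six
# small structures covering chains, forks and colliders, with 1800 of
# 2000 individuals missing exactly one entry (one starred column, or
# split alternately across the starred pair).
_CATALOGUE = {
    "fig1A": _three_node([("A", "B"), ("B", "C")], ["C"]),
    "fig1B": _three_node([("A", "B"), ("B", "C")], ["A"]),
    "fig1C": _three_node([("A", "B"), ("C", "B")], ["B"]),
    "fig1D": _three_node([("B", "A"), ("B", "C")], ["B"]),
    "fig1E": _three_node([("A", "B"), ("B", "C")], ["A", "C"]),
    "fig1F": _three_node([("A", "B"), ("C", "B")], ["A", "C"]),
}


def builtin_scenario(name: str, beta: float = 0.5, n: int = None, seed: int = 0):
    """Generate a catalogued benchmark scenario.

    Returns a :class:`Scenario` carrying the complete data, the data with
    the scenario's missingness applied, the generating DAG and the
    pattern.  ``n`` defaults to the scenario's standard sample size.
    """
    if name in _CATALOGUE:
        entry = _CATALOGUE[name]
        n = entry["n_default"] if n is None else n
        count = entry["miss"] if n == entry["n_default"] else int(round(0.9 * n))
        model = linear_gaussian_model(entry["edges"], beta)
        full = simulate(model, n, seed)
        stars = entry["stars"]
        pattern = (
            MissingnessPattern.fixed_count(stars[0], count)
            if len(stars) == 1
            else MissingnessPattern.split(stars, count)
        )
        data = inject_missingness(full, pattern, seed=seed + 1)
        return Scenario(name, full, data, model.structure, pattern)

    if name in ("fig2", "fig2_ae"):
        n = 2000 if n is None else n
        count = 1800 if n == 2000 else int(round(0.9 * n))
        edges = [("A", "B"), ("C", "B"), ("C", "D"), ("E", "D")]
        model = linear_gaussian_model(edges, beta)
        full = simulate(model, n, seed)
        stars = ("B", "D") if name == "fig2" else ("A", "E")
        pattern = MissingnessPattern.split(stars, count)
        data = inject_missingness(full, pattern, seed=seed + 1)
        return Scenario(name, full, data, model.structure, pattern)

    if name == "chain5":
        n = 2000 if n is None else n
        count = 1800 if n == 2000 else int(round(0.9 * n))
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")]
        model = linear_gaussian_model(edges, beta)
        full = simulate(model, n, seed)
        pattern = MissingnessPattern.split(("B", "D"), count)
        data = inject_missingness(full, pattern, seed=seed + 1)
        return Scenario(name, full, data, model.structure, pattern)

    if name == "omics31":
        # 20 SNP dosages -> 10 expression variables (2 SNP parents each,
        # round robin) -> 1 trait; expression entries missing with
        # probability 0.2
        n = 300 if n is None else n
        snps = [f"snp{i}" for i in range(1, 21)]
        exprs = [f"ex{i}" for i in range(1, 11)]
        edges = []
        for i, ex in enumerate(exprs):
            edges.append((snps[2 * i], ex))
            edges.append((snps[2 * i + 1], ex))
            edges.append((ex, "trait"))
        model = linear_gaussian_model(edges, beta, snp_nodes=snps)
        full = simulate(model, n, seed)
        pattern = MissingnessPattern.probability({e: 0.2 for e in exprs})
        data = inject_missingness(full, pattern, seed=seed + 1)
        return Scenario(name, full, data, model.structure, pattern)

    if name == "prior4":
        # two causes A, B of X, with X driving Y; priors usually go on
        # B->X and X->Y
        n = 500 if n is None else n
        edges = [("A", "X"), ("B", "X"), ("X", "Y")]
        model = linear_gaussian_model(edges, beta)
        full = simulate(model, n, seed)
        return Scenario(name, full, full.copy(), model.structure,
                        MissingnessPattern.none())

    if name == "prior6":
        # soft-prior demonstration network: a hub B feeding two branches
        n = 500 if n is None else n
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("B", "E"), ("E", "F")]
        model = linear_gaussian_model(edges, beta)
        full = simulate(model, n, seed)
        return Scenario(name, full, full.copy(), model.structure,
                        MissingnessPattern.none())

    raise ConfigurationError(f"unknown scenario {name!r}")


SCENARIOS = tuple(sorted(_CATALOGUE)) + (
    "fig2",
    "fig2_ae",
    "chain5",
    "omics31",
    "prior4",
    "prior6",
)


def write_gaussian_network(model: SimulationModel, path):
    """Plain-text Gaussian network: ``node<TAB>noise_sd<TAB>p:beta,...``."""
    with open(path, "w") as fh:
        for name in model.structure.node_names:
            node = model.nodes[name]
            if isinstance(node, SnpNode):
                fh.write(f"{name}\tsnp:{node.allele_freq}\t\n")
                continue
            if not isinstance(node, ContinuousNode):
                raise ConfigurationError("only continuous/SNP nodes supported")
            terms = ",".join(
                f"{p}:{b}" for p, b in sorted(node.betas.items())
            )
            fh.write(f"{name}\t{node.noise_sd}\t{terms}\n")


def read_gaussian_network(path) -> SimulationModel:
    """Read the plain-text Gaussian network format."""
    nodes = {}
    edges = []
    names = []
    snps = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ConfigurationError(
                    f"{path} line {lineno}: expected node<TAB>sd<TAB>terms"
                )
            name, sd = parts[0], parts[1]
            names.append(name)
            if sd.startswith("snp:"):
                nodes[name] = SnpNode(float(sd.split(":", 1)[1]))
                snps.add(name)
                continue
            betas = {}
            if len(parts) > 2 and parts[2].strip():
                for term in parts[2].split(","):
                    pname, b = term.split(":")
                    betas[pname] = float(b)
                    edges.append((pname, name))
            nodes[name] = ContinuousNode(betas=betas, noise_sd=float(sd))
    variables = [
        VariableSpec(n_, "continuous", genetic=n_ in snps) for n_ in names
    ]
    return SimulationModel(NetworkStructure(variables, edges), nodes)
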