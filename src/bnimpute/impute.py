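"""Network-guided nearest-neighbour imputation of missing data.

Missing entries are imputed per index individual, independently:

1.  A ``subset_fraction`` (default 90%) sample of individuals is drawn
    without replacement — from all individuals (default variant, with any
    remaining missing entries in the subset filled by values sampled with
    replacement from the variable's observed values) or from the fully
    observed individuals only (``complete_training``).
2.  A best-fit network is learned on that subset by greedy search with
    the BIC score.  A fresh subset (and hence network) is drawn for every
    index individual, which propagates model uncertainty into the
    imputation.
3.  For each missing variable z, the *nearby variables* are the variables
    adjacent to z in the inner network that are observed for the index
    individual.  A continuous child y of a continuous z with other
    continuous parents x is replaced by the adjusted variable
    v = y - sum_x beta_x x (coefficients from OLS of y on all its
    continuous parents including z), which tracks z more specifically
    than y does.  Distances are squared differences over variance for
    continuous variables and 0/1 mismatch for discrete ones.
4.  The nearest neighbour's observed value is copied in.  Ties are broken
    uniformly at random; with no nearby variables (or no eligible
    candidate) a random individual observing z donates.

The goal is accurate recovery of the *network*, not maximally accurate
reconstruction of individual values: donors are always real individuals,
so imputed values are genuine observed values and the joint structure of
the data is disturbed as little as possible.

The ``all_nn`` variant skips the network and uses every observed variable
of the index individual as a nearby variable (plain nearest-neighbour
imputation, kept as a comparison method).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ConfigurationError, MixedDataset
from .graphs import ConstraintSet, NetworkStructure
from .scoring import GaussianScoreEngine, ScoreSpec, make_scorer
from .search import SearchConfig, _ConstraintMasks, _greedy_core

__all__ = [
    "ImputationConfig",
    "NearbyVariableSet",
    "NearbyVariable",
    "impute",
    "select_nearby_variables",
    "nn_distance",
    "find_nearest_neighbour",
]

_VARIANTS = ("default", "complete_training", "all_nn")


@dataclass
class ImputationConfig:
    """Settings for the imputation run.

    ``subset_fraction`` is the share of individuals in each training
    subset (the inner best-fit network's data); ``floor(fraction * n)``
    rows, never fewer than 2.
    """

    subset_fraction: float = 0.9
    variant: str = "default"
    seed: int = 0
    score: ScoreSpec = field(default_factory=ScoreSpec)
    # the inner network only steers neighbour selection, so its search
    # runs a lighter restart policy than a final model fit
    search: SearchConfig = field(
        default_factory=lambda: SearchConfig(
            random_restarts=2, jitter_restarts=2, jitter_moves=3
        )
    )

    def __post_init__(self):
        if not 0.0 < self.subset_fraction <= 1.0:
            raise ConfigurationError("subset_fraction must be in (0, 1]")
        if self.variant not in _VARIANTS:
            raise ConfigurationError(
                f"variant must be one of {_VARIANTS}, got {self.variant!r}"
            )


@dataclass
class NearbyVariable:
    """One distance contributor for a (index individual, target) pair.

    ``values`` is aligned with the dataset's rows; NaN marks rows where
    the (possibly adjusted) variable cannot be evaluated.  For an
    adjusted variable, ``source`` names the child y it was derived from
    and ``coefficients`` the subtracted beta_x terms.
    """

    name: str
    values: np.ndarray
    index_value: float
    variance: float
    discrete: bool
    adjusted: bool = False
    source: str = None
    coefficients: dict = field(default_factory=dict)


@dataclass
class NearbyVariableSet:
    """Nearby variables for imputing one target of one index individual."""

    index_row: int
    target: str
    items: list


def _adjusted_variable(data, y, z, cont_parents, index_pos, num, obs):
    """Build the adjusted nearby variable v for child y of target z.

    OLS of y on all its continuous parents (including z) over rows where
    every regression variable is observed; parents missing for the index
    individual are simply not subtracted.  Underdetermined fits fall back
    to the unadjusted child.
    """
    names = data.names
    col = {n: names.index(n) for n in [y] + cont_parents}
    used_x = [
        x
        for x in cont_parents
        if x != z and obs[index_pos, col[x]]
    ]
    if not used_x:
        return None  # v = y unchanged
    fit_cols = [col[v_] for v_ in cont_parents]
    rows = obs[:, col[y]] & obs[:, fit_cols].all(axis=1)
    m = int(rows.sum())
    if m < len(cont_parents) + 2:
        warnings.warn(
            f"adjustment for child {y!r} of {z!r} underdetermined "
            f"({m} rows); using unadjusted variable"
        )
        return None
    Z = np.column_stack([np.ones(m), num[rows][:, fit_cols]])
    coef, _, _, _ = np.linalg.lstsq(Z, num[rows, col[y]], rcond=None)
    betas = dict(zip(cont_parents, coef[1:]))
    use_rows = obs[:, col[y]] & obs[:, [col[x] for x in used_x]].all(axis=1)
    vals = np.where(use_rows, num[:, col[y]], np.nan).astype(float)
    for x in used_x:
        vals = vals - np.where(use_rows, num[:, col[x]], np.nan) * betas[x]
    return NearbyVariable(
        name=f"{y}.adj",
        values=vals,
        index_value=float(vals[index_pos]),
        variance=float(np.nanvar(vals)),
        discrete=False,
        adjusted=True,
        source=y,
        coefficients={x: float(betas[x]) for x in used_x},
    )


def select_nearby_variables(
    dag: NetworkStructure,
    data: MixedDataset,
    index_pos: int,
    target: str,
) -> NearbyVariableSet:
    """Nearby variables of ``target`` for the individual at ``index_pos``.

    Adjacent variables (parents and children in the inner network)
    observed for the index individual; continuous children of a
    continuous target are replaced by their regression-adjusted version
    when they have other observed continuous parents.  A discrete target
    gets no adjustment (the required regression has no defined partition).
    """
    num = data.numeric_values()
    obs = data.observed_mask
    names = data.names
    items = []
    target_cont = data.spec(target).is_continuous
    for name in sorted(dag.adjacent(target)):
        j = names.index(name)
        if not obs[index_pos, j]:
            continue
        item = None
        if (
            target_cont
            and data.spec(name).is_continuous
            and target in dag.parents(name)
        ):
            cont_parents = sorted(
                p for p in dag.parents(name) if data.spec(p).is_continuous
            )
            if len(cont_parents) > 1:  # other parents besides z exist
                item = _adjusted_variable(
                    data, name, target, cont_parents, index_pos, num, obs
                )
        if item is None:
            vals = np.where(obs[:, j], num[:, j], np.nan)
            spec_j = data.spec(name)
            item = NearbyVariable(
                name=name,
                values=vals,
                index_value=float(num[index_pos, j]),
                variance=float(np.nanvar(vals)),
                discrete=spec_j.is_discrete,
            )
        items.append(item)
    return NearbyVariableSet(index_row=index_pos, target=target, items=items)


def _all_distances(nearby: NearbyVariableSet, n: int) -> np.ndarray:
    """Distance from the index individual to every row (NaN where some
    nearby variable is unavailable)."""
    total = np.zeros(n)
    for item in nearby.items:
        if item.discrete:
            d = (item.values != item.index_value).astype(float)
            d[np.isnan(item.values)] = np.nan
        else:
            if item.variance <= 0:
                warnings.warn(
                    f"nearby variable {item.name!r} has zero variance; "
                    f"it cannot discriminate"
                )
                d = np.where(np.isnan(item.values), np.nan, 0.0)
            else:
                d = (item.values - item.index_value) ** 2 / item.variance
        total = total + d
    return total


def nn_distance(candidate_pos: int, nearby: NearbyVariableSet) -> float:
    """Distance between the index individual and one candidate row: sum
    over nearby variables of squared difference over variance
    (continuous) or 0/1 mismatch (discrete)."""
    total = 0.0
    for item in nearby.items:
        val = item.values[candidate_pos]
        if math.isnan(val):
            raise ValueError(
                f"candidate {candidate_pos} does not observe {item.name!r}"
            )
        if item.discrete:
            total += 0.0 if val == item.index_value else 1.0
        elif item.variance > 0:
            total += (val - item.index_value) ** 2 / item.variance
    return total


def find_nearest_neighbour(
    data: MixedDataset,
    index_pos: int,
    target: str,
    nearby: NearbyVariableSet,
    rng=None,
):
    """Position of the donor: argmin distance over candidates that
    observe the target and every nearby variable; exact ties and the
    empty-candidate fallback are resolved uniformly at random."""
    rng = rng if rng is not None else np.random.default_rng()
    obs = data.observed_mask
    tcol = data.names.index(target)
    observers = np.nonzero(obs[:, tcol])[0]
    if observers.size == 0:
        raise ConfigurationError(f"no individual observes {target!r}")
    dist = _all_distances(nearby, data.n)
    eligible = obs[:, tcol] & ~np.isnan(dist)
    eligible[index_pos] = False
    cand = np.nonzero(eligible)[0]
    if not nearby.items or cand.size == 0:
        pool = observers[observers != index_pos]
        if pool.size == 0:
            raise ConfigurationError(f"no donor available for {target!r}")
        return int(rng.choice(pool)), float("nan")
    d = dist[cand]
    dmin = d.min()
    ties = cand[d == dmin]
    donor = int(ties[0]) if ties.size == 1 else int(rng.choice(ties))
    return donor, float(dmin)


def _fit_inner_network(subset_num, variables, masks, spec, search_cfg, rng):
    """Greedy BIC search on the (filled) training subset."""
    if all(v.is_continuous for v in variables):
        scorer = GaussianScoreEngine(subset_num, spec)
    else:
        frame = pd.DataFrame(index=range(len(subset_num)))
        for j, v in enumerate(variables):
            colv = subset_num[:, j]
            if v.is_continuous:
                frame[v.name] = colv
            else:
                frame[v.name] = pd.Series(colv).map(
                    lambda c: v.levels[int(c)]
                )
        scorer = make_scorer(MixedDataset(variables, frame), spec)
    cfg = SearchConfig(
        random_restarts=search_cfg.random_restarts,
        jitter_restarts=search_cfg.jitter_restarts,
        jitter_moves=search_cfg.jitter_moves,
        seed=int(rng.integers(2**31 - 1)),
        max_iterations=search_cfg.max_iterations,
        random_edge_prob=search_cfg.random_edge_prob,
    )
    edges, _ = _greedy_core(scorer, masks, cfg)
    return NetworkStructure(variables, edges)


def impute(
    data: MixedDataset,
    cfg: ImputationConfig = None,
    constraints: ConstraintSet = None,
):
    """Impute every missing entry; returns ``(complete dataset, provenance)``.

    Observed entries are never altered, donors contribute only their
    originally observed values (never freshly imputed ones), and each
    index individual is handled independently, so the result for one
    individual does not depend on the processing order of the others.
    Provenance rows use 1-based individual identifiers.

    Missingness is assumed MAR: the probability an entry is missing may
    depend only on observed values of other variables.
    """
    cfg = cfg or ImputationConfig()
    constraints = constraints or ConstraintSet()
    mask = data.observed_mask
    prov_cols = ["individual", "variable", "donor", "distance", "nearby"]
    if mask.all():
        return data.copy(), pd.DataFrame(columns=prov_cols)
    for j, v in enumerate(data.variables):
        if mask[:, j].any():
            continue
        raise ConfigurationError(
            f"variable {v.name!r} has no observed values and cannot be imputed"
        )

    # canonical row order (sorted original identifiers) makes the result
    # independent of the physical row order of the input
    order = np.argsort(data.row_ids, kind="stable")
    dc = data.take_rows(order)
    num = dc.numeric_values()
    obs = dc.observed_mask
    n, p = num.shape
    variables = dc.variables
    names = dc.names
    all_cont = all(v.is_continuous for v in variables)
    masks = _ConstraintMasks(variables, constraints)
    obs_vals = [num[obs[:, j], j] for j in range(p)]

    if cfg.variant == "complete_training":
        pool = np.nonzero(obs.all(axis=1))[0]
        if pool.size < 2:
            raise ConfigurationError(
                "complete_training requires at least 2 complete rows"
            )
    else:
        pool = np.arange(n)
    m = max(2, int(math.floor(cfg.subset_fraction * pool.size)))

    out = num.copy()
    prov = []
    index_rows = np.nonzero(~obs.all(axis=1))[0]
    row_ids = dc.row_ids
    for i in index_rows:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(int(row_ids[i]),))
        )
        if cfg.variant == "all_nn":
            dag = None
        else:
            subset = rng.choice(pool, size=m, replace=False)
            sub = num[subset].copy()
            if cfg.variant == "default":
                for j in range(p):
                    holes = np.isnan(sub[:, j])
                    k = int(holes.sum())
                    if k:
                        sub[holes, j] = rng.choice(obs_vals[j], size=k, replace=True)
            dag = _fit_inner_network(
                sub, variables, masks, cfg.score, cfg.search, rng
            )
        for j in np.nonzero(~obs[i])[0]:
            z = names[j]
            if cfg.variant == "all_nn":
                items = []
                for k in range(p):
                    if k == j or not obs[i, k]:
                        continue
                    vals = np.where(obs[:, k], num[:, k], np.nan)
                    items.append(
                        NearbyVariable(
                            name=names[k],
                            values=vals,
                            index_value=float(num[i, k]),
                            variance=float(np.nanvar(vals)),
                            discrete=variables[k].is_discrete,
                        )
                    )
                nearby = NearbyVariableSet(index_row=int(i), target=z, items=items)
            else:
                nearby = select_nearby_variables(dag, dc, int(i), z)
            donor, dist = find_nearest_neighbour(dc, int(i), z, nearby, rng)
            out[i, j] = num[donor, j]
            prov.append(
                {
                    "individual": int(row_ids[i]) + 1,
                    "variable": z,
                    "donor": int(row_ids[donor]) + 1,
                    "distance": dist,
                    "nearby": ",".join(item.name for item in nearby.items),
                }
            )

    # write imputed codes back into the original frame (original row order)
    frame = data.frame.copy()
    inv = np.empty_like(order)
    inv[order] = np.arange(n)
    for j, v in enumerate(variables):
        col_out = out[inv, j]
        if v.is_continuous:
            frame[v.name] = col_out
        else:
            frame[v.name] = [v.levels[int(c)] for c in col_out]
    return MixedDataset(data.variables, frame), pd.DataFrame(prov, columns=prov_cols)
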