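"""Bootstrap model averaging of network structures.

The data are resampled with replacement B times (1000 by default) and the
best-fit network refitted on each resample.  For every unordered node pair
the *strength* is the proportion of resamples whose best-fit network
contains an edge between the pair, and the *direction* is the proportion
of those appearances in the reference direction (lexicographically smaller
node first), defined only for pairs that ever appear.  The probability of
a directed edge is strength x direction.

A data-driven strength threshold separates noise arcs from significant
ones by matching the empirical strength distribution to an idealised
two-point distribution (noise at 0, significant arcs at 1) in L1 distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MixedDataset
from .graphs import ConstraintSet, NetworkStructure
from .scoring import (
    DegenerateFitError,
    ScoreSpec,
    local_score,
)
from .search import SearchConfig, greedy_search

__all__ = [
    "AverageNetwork",
    "bootstrap_average",
    "directed_edge_probability",
    "strength_threshold",
    "edge_significance_lrt",
    "EdgeSignificance",
]


def directed_edge_probability(strength: float, direction: float, decimals=None):
    """Probability of the directed edge: strength x direction.

    ``decimals`` reproduces table display: round half away from zero to
    the given number of decimal places.
    """
    if not (0.0 <= strength <= 1.0) or not (0.0 <= direction <= 1.0):
        raise ValueError(
            f"strength and direction must lie in [0, 1]; got "
            f"({strength}, {direction})"
        )
    prob = strength * direction
    if decimals is None:
        return prob
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(prob)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class PairRecord:
    """Bootstrap tallies for one unordered node pair.

    ``node1 < node2`` lexicographically; ``direction`` is the proportion
    of appearances oriented node1 -> node2, NaN if the pair never appears.
    """

    node1: str
    node2: str
    strength: float
    direction: float
    count_forward: int
    count_backward: int

    @property
    def appearances(self) -> int:
        return self.count_forward + self.count_backward

    def edge_probability(self, u, v, decimals=None):
        """Directed-edge probability for orientation u -> v."""
        if {u, v} != {self.node1, self.node2}:
            raise ValueError(f"pair record is for ({self.node1}, {self.node2})")
        d = self.direction if (u, v) == (self.node1, self.node2) else 1.0 - self.direction
        if math.isnan(d):
            return 0.0
        return directed_edge_probability(self.strength, d, decimals)


@dataclass
class AverageNetwork:
    """Per-pair bootstrap strength and direction summaries."""

    nodes: list
    records: list
    B: int

    def pair(self, u, v) -> PairRecord:
        a, b = sorted((u, v))
        for r in self.records:
            if (r.node1, r.node2) == (a, b):
                return r
        return PairRecord(a, b, 0.0, float("nan"), 0, 0)

    def to_frame(self) -> pd.DataFrame:
        """Table sorted by strength descending then lexicographically."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "node1": r.node1,
                    "node2": r.node2,
                    "strength": r.strength,
                    "direction": r.direction,
                    "edge_probability": (
                        r.strength * r.direction
                        if not math.isnan(r.direction)
                        else 0.0
                    ),
                }
            )
        frame = pd.DataFrame(
            rows,
            columns=["node1", "node2", "strength", "direction", "edge_probability"],
        )
        if len(frame):
            frame = frame.sort_values(
                ["strength", "node1", "node2"], ascending=[False, True, True]
            ).reset_index(drop=True)
        return frame

    def consensus(self, threshold=None) -> NetworkStructure:
        """Structure keeping pairs with strength >= threshold, oriented to
        the majority direction (reference direction on an exact tie)."""
        if threshold is None:
            threshold = strength_threshold(self)
        edges = set()
        for r in self.records:
            if r.strength >= threshold and r.appearances > 0:
                if r.count_forward >= r.count_backward:
                    edges.add((r.node1, r.node2))
                else:
                    edges.add((r.node2, r.node1))
        return NetworkStructure(self.nodes, edges)

    def to_dot(self, threshold=None) -> str:
        """DOT export of the consensus network; weak edges are omitted via
        the strength threshold."""
        dag = self.consensus(threshold)
        attrs = {}
        for u, v in dag.edges:
            r = self.pair(u, v)
            attrs[(u, v)] = {"label": f"{r.strength:.2f}"}
        return dag.to_dot(edge_attrs=attrs)


def bootstrap_average(
    data: MixedDataset,
    spec: ScoreSpec = ScoreSpec(),
    constraints: ConstraintSet = None,
    cfg: SearchConfig = None,
    B: int = 1000,
    seed: int = 0,
) -> AverageNetwork:
    """Bootstrap the data B times and tally best-fit edges per pair.

    One master seed spawns an independent substream per resample, so
    increasing B extends rather than reshuffles the resample sequence.
    A resample on which every structure is degenerate is recorded as an
    empty network with a warning.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    cfg = cfg or SearchConfig()
    constraints = constraints or ConstraintSet()
    # canonical row order: the resample stream attaches to row identities,
    # so the result is invariant to the physical row order of the input
    data = data.take_rows(np.argsort(data.row_ids, kind="stable"))
    forward: dict = {}
    backward: dict = {}
    streams = np.random.SeedSequence(seed).spawn(B)
    for b in range(B):
        rng = np.random.default_rng(streams[b])
        rows = rng.integers(0, data.n, size=data.n)
        resample = data.take_rows(rows)
        sub_cfg = SearchConfig(
            random_restarts=cfg.random_restarts,
            jitter_restarts=cfg.jitter_restarts,
            jitter_moves=cfg.jitter_moves,
            seed=int(rng.integers(2**31 - 1)),
            max_iterations=cfg.max_iterations,
            random_edge_prob=cfg.random_edge_prob,
        )
        try:
            dag, _ = greedy_search(resample, spec, constraints, sub_cfg)
            edges = dag.edges
        except DegenerateFitError:
            warnings.warn(f"resample {b}: degenerate fits; recording empty network")
            edges = set()
        for u, v in edges:
            pair = (u, v) if u < v else (v, u)
            if (u, v) == pair:
                forward[pair] = forward.get(pair, 0) + 1
            else:
                backward[pair] = backward.get(pair, 0) + 1
    records = []
    for pair in sorted(set(forward) | set(backward)):
        f = forward.get(pair, 0)
        r = backward.get(pair, 0)
        appear = f + r
        records.append(
            PairRecord(
                pair[0],
                pair[1],
                strength=appear / B,
                direction=(f / appear) if appear else float("nan"),
                count_forward=f,
                count_backward=r,
            )
        )
    return AverageNetwork(nodes=data.variables, records=records, B=B)


def strength_threshold(avg: AverageNetwork) -> float:
    """Data-driven significance threshold on arc strengths.

    Chooses the threshold t (among observed strength values) minimising
    the L1 distance between the empirical CDF of strengths and the
    idealised two-point CDF in which arcs below t sit at strength 0 and
    arcs at or above t sit at 1.  Smallest t wins ties.  Arcs with
    strength >= t are retained.
    """
    strengths = np.array(
        sorted(r.strength for r in avg.records), dtype=float
    )
    if strengths.size == 0:
        raise ValueError("average network has no recorded pairs")
    if np.allclose(strengths, strengths[0]):
        warnings.warn("all strengths identical; threshold equals that value")
        return float(strengths[0])
    N = strengths.size
    # empirical CDF F(x) is a step function; integrate |F - phi| exactly
    knots = np.concatenate([[0.0], np.unique(strengths), [1.0]])
    cdf_vals = np.searchsorted(strengths, knots[:-1], side="right") / N
    widths = np.diff(knots)

    best_t, best_l1 = None, math.inf
    for t in np.unique(strengths):
        phi = np.searchsorted(strengths, t, side="left") / N  # share below t
        l1 = float(np.sum(np.abs(cdf_vals - phi) * widths))
        if l1 < best_l1 - 1e-12:
            best_t, best_l1 = float(t), l1
    return best_t


@dataclass
class EdgeSignificance:
    """Likelihood-ratio significance of one edge: chi2, df, p-value.

    ``available`` is False when the edge-removed refit is degenerate.
    """

    chi2: float = float("nan")
    df: int = 0
    p_value: float = float("nan")
    available: bool = True


def edge_significance_lrt(
    data: MixedDataset,
    dag: NetworkStructure,
    edge,
    spec: ScoreSpec = ScoreSpec(),
) -> EdgeSignificance:
    """Chi-square test of one edge: remove it and compare maximised log
    likelihoods; df is the child's parameter-count difference.  Used to
    scale plot line widths, so no multiplicity control is applied."""
    u, v = edge
    if (u, v) not in dag.edges:
        raise ValueError(f"edge {u}->{v} not in network")
    ll_spec = ScoreSpec("loglik")
    parents = dag.parents(v)
    try:
        full, d_full = local_score(data, v, parents, ll_spec)
        reduced, d_red = local_score(data, v, parents - {u}, ll_spec)
    except DegenerateFitError:
        return EdgeSignificance(available=False)
    chi2 = max(0.0, 2.0 * (full - reduced))
    df = d_full - d_red
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return EdgeSignificance(chi2=chi2, df=df, p_value=p, available=True)
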