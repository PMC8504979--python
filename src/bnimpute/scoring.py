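"""Decomposable network scores for mixed discrete/continuous data.

Local distributions follow the conditional-Gaussian convention: discrete
nodes are multinomial given discrete parents; continuous nodes are Gaussian
linear regressions on their continuous parents, fitted separately within
each configuration of their discrete parents.  A discrete node may not have
a continuous parent.

The network score is the sum of local scores (decomposability):

    loglik : log L-hat
    aic    : log L-hat - d
    bic    : log L-hat - (d / 2) * ln n

with d the number of free parameters.  Variance estimates are maximum
likelihood (denominator n), so the score is a maximised likelihood.  Scores
are negative for non-degenerate continuous data and larger is better.

Soft constraints enter the BIC only, as the weighted score

    WeightedScore = BIC + sum over prior edges e present of ln p(e)

with the reverse direction of a prior edge contributing ln(1 - p(e)); a
present edge with prior 0 drives the score to -inf and the network is
rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataset import ConfigurationError, MixedDataset
from .graphs import ConstraintSet, NetworkStructure

__all__ = [
    "ScoreSpec",
    "DegenerateFitError",
    "local_score",
    "network_score",
    "score_delta",
    "edge_prior_log",
    "GaussianScoreEngine",
    "make_scorer",
]

_LOG_2PI = math.log(2.0 * math.pi)
#: relative tolerance below which a residual variance counts as zero
_VAR_RTOL = 1e-12
#: largest variable count for which the all-subsets score table is built
_TABLE_MAX_P = 6


@dataclass(frozen=True)
class ScoreSpec:
    """Which score to use: ``loglik``, ``aic`` or ``bic`` (default)."""

    type: str = "bic"

    def __post_init__(self):
        if self.type not in ("loglik", "aic", "bic"):
            raise ConfigurationError(f"unknown score type {self.type!r}")

    def penalise(self, loglik: float, d: int, n: int) -> float:
        if self.type == "loglik":
            return loglik
        if self.type == "aic":
            return loglik - d
        return loglik - 0.5 * d * math.log(n)


class DegenerateFitError(ValueError):
    """A local fit cannot be carried out (too few rows in a discrete-parent
    configuration, or a zero-variance regression residual).

    Callers treat the candidate parent set as inadmissible; a degenerate
    fit never aborts a search.
    """


def _gaussian_loglik(rss: float, m: int) -> float:
    sigma2 = rss / m
    return -0.5 * m * (_LOG_2PI + math.log(sigma2) + 1.0)


def _fit_group(y: np.ndarray, X: np.ndarray) -> float:
    """RSS of OLS of y on [1, X]; raises DegenerateFitError when singular
    in a way that matters (handled by caller via the variance check)."""
    m = len(y)
    if X.shape[1] == 0:
        mu = y.mean()
        return float(((y - mu) ** 2).sum())
    Z = np.column_stack([np.ones(m), X])
    coef, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ coef
    return float(resid @ resid)


def local_score(data: MixedDataset, node: str, parents, spec: ScoreSpec):
    """Local score of ``node`` given ``parents``: ``(score, d)``.

    Requires the involved columns to be fully observed (callers pass
    complete or imputed data).  Raises :class:`DegenerateFitError` for
    inadmissible fits and :class:`ConfigurationError` for a discrete node
    with a continuous parent.
    """
    parents = sorted(parents)
    node_spec = data.spec(node)
    involved = [node] + parents
    cols = {name: data.frame[name] for name in involved}
    for name in involved:
        if cols[name].isna().any():
            raise ConfigurationError(
                f"column {name!r} has missing values; score requires "
                f"complete data (impute or reduce first)"
            )
    n = data.n
    if n == 0:
        raise DegenerateFitError("no rows")

    if node_spec.is_discrete:
        bad = [p for p in parents if data.spec(p).is_continuous]
        if bad:
            raise ConfigurationError(
                f"discrete node {node!r} cannot have continuous parents {bad}"
            )
        r = node_spec.n_levels
        q = 1
        for p in parents:
            q *= data.spec(p).n_levels
        if parents:
            grouped = cols[node].groupby([cols[p] for p in parents], observed=True)
            counts = grouped.value_counts()
        else:
            counts = cols[node].value_counts()
        ll = 0.0
        # N_jk * ln(N_jk / N_j.) summed over parent configs j and levels k
        if parents:
            totals = counts.groupby(level=list(range(len(parents)))).transform("sum")
        else:
            totals = counts.sum()
        nz = counts[counts > 0]
        ll = float((nz * np.log(nz / (totals[nz.index] if parents else totals))).sum())
        return spec.penalise(ll, (r - 1) * q, n), (r - 1) * q

    # continuous node
    cont_parents = [p for p in parents if data.spec(p).is_continuous]
    disc_parents = [p for p in parents if data.spec(p).is_discrete]
    y_all = cols[node].to_numpy(dtype=float)
    X_all = (
        np.column_stack([cols[p].to_numpy(dtype=float) for p in cont_parents])
        if cont_parents
        else np.empty((n, 0))
    )
    c = len(cont_parents)
    scale = max(1.0, float(np.mean(y_all**2)))
    if not disc_parents:
        if n < c + 2:
            raise DegenerateFitError(
                f"{node}: {n} rows cannot support {c + 2} parameters"
            )
        rss = _fit_group(y_all, X_all)
        if rss <= n * _VAR_RTOL * scale:
            raise DegenerateFitError(f"{node}: zero residual variance")
        ll = _gaussian_loglik(rss, n)
        d = c + 2
        return spec.penalise(ll, d, n), d

    q = 1
    for p in disc_parents:
        q *= data.spec(p).n_levels
    keys = [cols[p] for p in disc_parents]
    groups = (
        cols[node].groupby(keys, observed=True).indices
        if disc_parents
        else {(): np.arange(n)}
    )
    ll = 0.0
    for _, idx in sorted(groups.items(), key=lambda kv: str(kv[0])):
        m = len(idx)
        if m < c + 2:
            raise DegenerateFitError(
                f"{node}: parent configuration with {m} rows cannot support "
                f"{c + 2} parameters"
            )
        rss = _fit_group(y_all[idx], X_all[idx])
        if rss <= m * _VAR_RTOL * scale:
            raise DegenerateFitError(f"{node}: zero residual variance in group")
        ll += _gaussian_loglik(rss, m)
    d = q * (c + 2)
    return spec.penalise(ll, d, n), d


def edge_prior_log(constraints: ConstraintSet, u: str, v: str) -> float:
    """ln of the prior probability attached to directed edge u -> v
    (0.0 when the pair carries no prior)."""
    if constraints is None:
        return 0.0
    if (u, v) in constraints.soft_priors:
        p = constraints.soft_priors[(u, v)]
    elif (v, u) in constraints.soft_priors:
        p = 1.0 - constraints.soft_priors[(v, u)]
    else:
        return 0.0
    return math.log(p) if p > 0 else -math.inf


def network_score(
    data: MixedDataset,
    dag: NetworkStructure,
    spec: ScoreSpec = ScoreSpec(),
    constraints: ConstraintSet = None,
) -> float:
    """Sum of local scores plus, for BIC with soft priors, the weighted
    prior term.  Soft priors with a non-BIC score are a configuration
    error (the weighting is derived from the BIC approximation)."""
    if constraints is not None and constraints.soft_priors and spec.type != "bic":
        raise ConfigurationError(
            "soft priors require the BIC score (weighted-score derivation)"
        )
    total = 0.0
    for v in dag.node_names:
        s, _ = local_score(data, v, dag.parents(v), spec)
        total += s
    if constraints is not None:
        total += constraints.prior_log_term(dag.edges)
    return total


def score_delta(
    data: MixedDataset,
    dag: NetworkStructure,
    move,
    spec: ScoreSpec = ScoreSpec(),
    constraints: ConstraintSet = None,
    cache: dict = None,
):
    """Score change of a single valid arc move, recomputing only affected
    local scores.  ``move`` is ``(kind, u, v)`` with kind in
    {"add", "delete", "reverse"}.  Bit-identical to full rescoring.
    """
    if cache is None:
        cache = {}

    def local(child, parents):
        key = (child, frozenset(parents))
        if key not in cache:
            cache[key] = local_score(data, child, parents, spec)[0]
        return cache[key]

    kind, u, v = move
    pv = dag.parents(v)
    delta = 0.0
    if kind == "add":
        delta = local(v, pv | {u}) - local(v, pv)
        delta += edge_prior_log(constraints, u, v)
    elif kind == "delete":
        delta = local(v, pv - {u}) - local(v, pv)
        delta -= edge_prior_log(constraints, u, v)
    elif kind == "reverse":
        pu = dag.parents(u)
        delta = local(v, pv - {u}) - local(v, pv)
        delta += local(u, pu | {v}) - local(u, pu)
        delta += edge_prior_log(constraints, v, u) - edge_prior_log(
            constraints, u, v
        )
    else:
        raise ValueError(f"unknown move kind {kind!r}")
    return delta


# ---------------------------------------------------------------------------
# scorer objects used by the search module
# ---------------------------------------------------------------------------


class GaussianScoreEngine:
    """Fast local scores for all-continuous complete data.

    Works from the Gram matrix of the intercept-augmented data.  For a
    parent set S the residual cross-product matrix is the Schur complement
    of the (intercept + S) block, whose diagonal gives the RSS of every
    other variable regressed on S at once; this also yields all single-
    parent-addition scores for a child in one vectorised step.

    Degenerate fits (zero residual variance, or fewer rows than
    parameters) are reported as ``-inf`` scores, which search treats as
    inadmissible.
    """

    def __init__(self, X: np.ndarray, spec: ScoreSpec = ScoreSpec()):
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ConfigurationError("engine requires complete data")
        self.n, self.p = X.shape
        Z = np.column_stack([np.ones(self.n), X])
        self.G = Z.T @ Z
        self.spec = spec
        self._scale = np.maximum(1.0, np.diag(self.G)[1:] / max(self.n, 1))
        self._resid_cache: dict = {}
        self._local_cache: dict = {}
        self._add_cache: dict = {}
        self._table = None
        if 0 < self.p <= _TABLE_MAX_P:
            self._build_table()

    def _residual_direct(self, mask: int) -> np.ndarray:
        """Residual cross-products of all variables given the parent set
        ``mask`` (plus intercept), by one Schur-complement solve."""
        S = [0] + [i + 1 for i in range(self.p) if mask >> i & 1]
        G = self.G
        GS = G[:, S]
        GSS = GS[S, :]
        try:
            sol = np.linalg.solve(GSS, GS.T)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(GSS, GS.T, rcond=None)[0]
        return G - GS @ sol

    def _residual(self, mask: int) -> np.ndarray:
        """Memoized residual matrix, derived from the predecessor set
        (lowest parent removed) by a single sweep update when the pivot
        is well conditioned, else recomputed directly."""
        R = self._resid_cache.get(mask)
        if R is not None:
            return R
        if mask == 0:
            R = self._residual_direct(0)
        else:
            k = (mask & -mask).bit_length() - 1
            Rp = self._residual(mask & (mask - 1))
            d = Rp[k + 1, k + 1]
            if d > self.n * 1e-9 * max(self._scale[k], 1.0):
                col = Rp[:, k + 1]
                R = Rp - np.outer(col, col) / d
            else:  # (near-)collinear pivot: sweep would be unstable
                R = self._residual_direct(mask)
        self._resid_cache[mask] = R
        return R

    def _score_from_rss(self, rss: float, k: int, child: int) -> float:
        if self.n < k + 2 or rss <= self.n * _VAR_RTOL * self._scale[child]:
            return -math.inf
        ll = _gaussian_loglik(rss, self.n)
        return self.spec.penalise(ll, k + 2, self.n)

    def _build_table(self):
        """Eager all-subsets score table for small p.

        Walks the subset lattice once, deriving each residual matrix from
        its predecessor by a single Schur-complement (sweep) update; one
        pass yields the scores of every child under every parent set, so
        hill climbs and exhaustive enumeration become table lookups.
        """
        p, n = self.p, self.n
        nmask = 1 << p
        T = np.full((p, nmask), -math.inf)
        store = [None] * nmask
        store[0] = self._residual(0)
        base = -0.5 * n * (_LOG_2PI + 1.0)
        logn = math.log(n)
        floors = n * _VAR_RTOL * self._scale
        for mask in range(nmask):
            Rm = store[mask]
            if Rm is None:
                continue
            k = bin(mask).count("1")
            if n >= k + 2:
                diag = Rm.diagonal()[1:]
                ok = diag > floors
                ll = base - 0.5 * n * np.log(
                    np.where(ok, diag, 1.0) / n
                )
                if self.spec.type == "aic":
                    ll = ll - (k + 2)
                elif self.spec.type == "bic":
                    ll = ll - 0.5 * (k + 2) * logn
                T[:, mask] = np.where(ok, ll, -math.inf)
                rest, i = mask, 0
                while rest:
                    if rest & 1:
                        T[i, mask] = -math.inf
                    rest >>= 1
                    i += 1
            else:
                T[:, mask] = -math.inf
            # extend to supersets by sweeping in each higher unset bit once
            for j in range(p):
                bit = 1 << j
                if mask & bit or store[mask | bit] is not None:
                    continue
                d = Rm[j + 1, j + 1]
                if d <= floors[j]:
                    continue  # collinear: supersets through j stay -inf
                col = Rm[:, j + 1]
                store[mask | bit] = Rm - np.outer(col, col) / d
        bits = 1 << np.arange(p, dtype=np.int64)
        self._ormask = np.bitwise_or(
            np.arange(nmask, dtype=np.int64)[:, None], bits[None, :]
        )
        self._table = T

    def local(self, child: int, mask: int) -> float:
        """Spec-adjusted local score of ``child`` given parent bitmask."""
        if self._table is not None:
            return float(self._table[child, mask])
        key = (child, mask)
        s = self._local_cache.get(key)
        if s is None:
            R = self._residual(mask)
            k = bin(mask).count("1")
            s = self._score_from_rss(float(R[child + 1, child + 1]), k, child)
            self._local_cache[key] = s
        return s

    def local_additions(self, child: int, mask: int) -> np.ndarray:
        """Vector over all variables u of local(child, mask | {u}).

        Entries for u == child are ``-inf``; entries for u already in
        mask equal ``local(child, mask)`` (callers mask existing edges).
        Cached per (child, mask).
        """
        if self._table is not None:
            return self._table[child, self._ormask[mask]]
        key = (child, mask)
        cached = self._add_cache.get(key)
        if cached is not None:
            return cached
        R = self._residual(mask)
        c = child + 1
        diag = R.diagonal()[1:]
        cross = R[c, 1:]
        rss0 = R[c, c]
        k = bin(mask).count("1") + 1
        floor = self.n * _VAR_RTOL * self._scale[child]
        if self.n < k + 2:
            out = np.full(self.p, -math.inf)
        else:
            rss = rss0 - cross * cross / np.maximum(diag, 1e-300)
            ok = (diag > 0) & (rss > floor)
            ll = -0.5 * self.n * (
                _LOG_2PI + 1.0 + np.log(np.where(ok, rss, 1.0) / self.n)
            )
            if self.spec.type == "aic":
                ll -= k + 2
            elif self.spec.type == "bic":
                ll -= 0.5 * (k + 2) * math.log(self.n)
            out = np.where(ok, ll, -math.inf)
        out[child] = -math.inf
        rest, i = mask, 0
        while rest:
            if rest & 1:
                out[i] = -math.inf
            rest >>= 1
            i += 1
        out.setflags(write=False)
        self._add_cache[key] = out
        return out


class MixedScorer:
    """Generic scorer over a MixedDataset, caching (child, mask) scores.

    Same interface as :class:`GaussianScoreEngine`, implemented through
    :func:`local_score`; used whenever discrete variables are modelled.
    """

    def __init__(self, data: MixedDataset, spec: ScoreSpec = ScoreSpec()):
        self.data = data
        self.spec = spec
        self.p = data.p
        self.n = data.n
        self.names = data.names
        self._cache: dict = {}

    def local(self, child: int, mask: int) -> float:
        key = (child, mask)
        s = self._cache.get(key)
        if s is None:
            parents = [self.names[i] for i in range(self.p) if mask >> i & 1]
            try:
                s = local_score(self.data, self.names[child], parents, self.spec)[0]
            except DegenerateFitError:
                s = -math.inf
            self._cache[key] = s
        return s

    def local_additions(self, child: int, mask: int) -> np.ndarray:
        out = np.full(self.p, -math.inf)
        child_spec = self.data.variables[child]
        for u in range(self.p):
            if u == child or mask >> u & 1:
                continue
            if child_spec.is_discrete and self.data.variables[u].is_continuous:
                continue  # mixed-parent rule; caller masks this too
            try:
                out[u] = self.local(child, mask | (1 << u))
            except ConfigurationError:
                out[u] = -math.inf
        return out


def make_scorer(data: MixedDataset, spec: ScoreSpec = ScoreSpec()):
    """Pick the fast Gaussian engine when every variable is continuous,
    otherwise the generic mixed scorer.  Both expose the same interface
    and produce identical scores on continuous data."""
    if all(v.is_continuous for v in data.variables):
        return GaussianScoreEngine(data.numeric_values(), spec)
    return MixedScorer(data, spec)
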