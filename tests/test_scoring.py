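"""Local and network scores: closed forms, decomposability, weighted score."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from bnimpute import (
    ConfigurationError,
    ConstraintSet,
    DegenerateFitError,
    MixedDataset,
    NetworkStructure,
    ScoreSpec,
    VariableSpec,
    cpdag,
    local_score,
    network_score,
    score_delta,
)
from bnimpute.scoring import GaussianScoreEngine, make_scorer

from conftest import make_dataset


def single_continuous(values):
    return make_dataset({"x": np.asarray(values, dtype=float)})


class TestLocalScoreClosedForms:
    def test_gaussian_marginal_pm_one(self):
        # values {-1, +1}: sigma2_hat = 1, logL = -(n/2)(ln 2pi + 1)
        ds = single_continuous([-1.0, 1.0])
        ll, d = local_score(ds, "x", [], ScoreSpec("loglik"))
        assert ll == pytest.approx(-(math.log(2 * math.pi) + 1.0), abs=1e-9)
        bic, d = local_score(ds, "x", [], ScoreSpec("bic"))
        assert bic == pytest.approx(-2.83788 - math.log(2), abs=1e-4)
        assert d == 2  # mean + variance

    def test_multinomial_counts_3_1(self):
        ds = make_dataset({"y": ["a", "a", "a", "b"]}, discrete={"y"})
        ll, d = local_score(ds, "y", [], ScoreSpec("loglik"))
        assert ll == pytest.approx(3 * math.log(0.75) + math.log(0.25), abs=1e-12)
        assert d == 1

    def test_zero_rss_degenerate(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        ds = make_dataset({"x": x, "y": 2 * x})  # exact linear dependence
        with pytest.raises(DegenerateFitError):
            local_score(ds, "y", ["x"], ScoreSpec("bic"))

    def test_continuous_regression_matches_numpy_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=120)
        y = 1.0 + 0.8 * x + rng.normal(size=120)
        ds = make_dataset({"x": x, "y": y})
        Z = np.column_stack([np.ones(120), x])
        beta = np.linalg.lstsq(Z, y, rcond=None)[0]
        rss = float(((y - Z @ beta) ** 2).sum())
        expect = -0.5 * 120 * (math.log(2 * math.pi * rss / 120) + 1)
        ll, d = local_score(ds, "y", ["x"], ScoreSpec("loglik"))
        assert ll == pytest.approx(expect, rel=1e-12)
        assert d == 3  # slope + intercept + variance

    def test_conditional_gaussian_groups_match_oracle(self):
        """Continuous child with one binary discrete parent: per-group
        Gaussian likelihoods summed, parameters q * 2."""
        rng = np.random.default_rng(4)
        g = np.where(rng.random(200) < 0.5, "u", "v")
        x = np.where(g == "u", 0.0, 1.5) + rng.normal(size=200)
        ds = make_dataset({"g": g, "x": x}, discrete={"g"})
        expect = 0.0
        for lev in ("u", "v"):
            sub = x[g == lev]
            m = len(sub)
            rss = float(((sub - sub.mean()) ** 2).sum())
            expect += -0.5 * m * (math.log(2 * math.pi * rss / m) + 1)
        ll, d = local_score(ds, "x", ["g"], ScoreSpec("loglik"))
        assert ll == pytest.approx(expect, rel=1e-12)
        assert d == 4  # 2 groups x (intercept + variance)

    def test_rare_group_is_degenerate(self):
        # a parent configuration with fewer rows than parameters
        ds = make_dataset(
            {"g": ["u"] * 40 + ["v"], "x": np.r_[np.random.default_rng(1).normal(size=40), 0.0]},
            discrete={"g"},
        )
        with pytest.raises(DegenerateFitError):
            local_score(ds, "x", ["g"], ScoreSpec("bic"))

    def test_discrete_child_continuous_parent_rejected(self):
        ds = make_dataset({"x": [0.1, 0.2, 0.3, 0.4], "y": ["a", "b", "a", "b"]},
                          discrete={"y"})
        with pytest.raises(ConfigurationError):
            local_score(ds, "y", ["x"], ScoreSpec("bic"))


class TestNetworkScore:
    def test_decomposability_and_penalty_ordering(self, mixed4):
        dag = NetworkStructure(mixed4.variables, [("g", "x"), ("x", "y")])
        total = {}
        for t in ("loglik", "aic", "bic"):
            spec = ScoreSpec(t)
            parts = sum(
                local_score(mixed4, v, dag.parents(v), spec)[0]
                for v in dag.node_names
            )
            total[t] = network_score(mixed4, dag, spec)
            assert total[t] == pytest.approx(parts, rel=1e-12)
        # penalties are nonnegative and BIC's dominates AIC's for n >= 8
        assert total["loglik"] >= total["aic"] >= total["bic"]

    def test_scores_negative_on_simulator_output(self, cont3):
        dag = NetworkStructure(cont3.variables, [("A", "B"), ("B", "C")])
        for t in ("loglik", "aic", "bic"):
            assert network_score(cont3, dag, ScoreSpec(t)) < 0


class TestWeightedScore:
    def test_empty_priors_equals_plain_bic(self, cont3):
        dag = NetworkStructure(cont3.variables, [("A", "B")])
        assert network_score(cont3, dag, ScoreSpec(), ConstraintSet()) == (
            network_score(cont3, dag, ScoreSpec())
        )

    def test_prior_one_adds_nothing(self, cont3):
        dag = NetworkStructure(cont3.variables, [("A", "B")])
        cs = ConstraintSet(soft_priors={("A", "B"): 1.0})
        assert network_score(cont3, dag, ScoreSpec(), cs) == pytest.approx(
            network_score(cont3, dag, ScoreSpec()), rel=1e-12
        )

    def test_orientation_difference_is_log_odds(self):
        """With score-equivalent Gaussian BIC, the two orientations differ
        by exactly ln(p / (1 - p))."""
        rng = np.random.default_rng(9)
        a = rng.normal(size=300)
        b = 0.5 * a + rng.normal(size=300)
        ds = make_dataset({"A": a, "B": b})
        cs = ConstraintSet(soft_priors={("A", "B"): 0.8})
        fwd = NetworkStructure(ds.variables, [("A", "B")])
        rev = NetworkStructure(ds.variables, [("B", "A")])
        diff = network_score(ds, fwd, ScoreSpec(), cs) - network_score(
            ds, rev, ScoreSpec(), cs
        )
        assert diff == pytest.approx(math.log(4.0), abs=1e-8)

    def test_prior_zero_rejects_network(self, cont3):
        dag = NetworkStructure(cont3.variables, [("A", "B")])
        cs = ConstraintSet(soft_priors={("A", "B"): 0.0})
        assert network_score(cont3, dag, ScoreSpec(), cs) == -math.inf

    def test_priors_require_bic(self, cont3):
        dag = NetworkStructure(cont3.variables, [("A", "B")])
        cs = ConstraintSet(soft_priors={("A", "B"): 0.7})
        with pytest.raises(ConfigurationError):
            network_score(cont3, dag, ScoreSpec("aic"), cs)

    def test_half_prior_shifts_by_direction_independent_constant(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=200)
        b = 0.4 * a + rng.normal(size=200)
        ds = make_dataset({"A": a, "B": b})
        cs = ConstraintSet(soft_priors={("A", "B"): 0.5})
        for dag in (
            NetworkStructure(ds.variables, [("A", "B")]),
            NetworkStructure(ds.variables, [("B", "A")]),
        ):
            shift = network_score(ds, dag, ScoreSpec(), cs) - network_score(
                ds, dag, ScoreSpec()
            )
            assert shift == pytest.approx(math.log(0.5), rel=1e-12)


class TestScoreDelta:
    @pytest.mark.parametrize("fixture", ["cont3", "mixed4"])
    def test_delta_matches_full_rescore(self, fixture, request):
        data = request.getfixturevalue(fixture)
        rng = np.random.default_rng(5)
        names = data.names
        dag = NetworkStructure(data.variables)
        cache = {}
        spec = ScoreSpec("bic")
        checked = 0
        for _ in range(100):
            u, v = rng.choice(names, size=2, replace=False)
            if data.spec(u).is_continuous and data.spec(v).is_discrete:
                continue
            if dag.has_edge(u, v):
                kind = "delete" if rng.random() < 0.6 else "reverse"
                if kind == "reverse" and (
                    data.spec(v).is_continuous and data.spec(u).is_discrete
                ):
                    kind = "delete"
            elif dag.has_edge(v, u):
                continue
            else:
                kind = "add"
            before = network_score(data, dag, spec)
            trial = dag.copy()
            if kind == "add":
                trial.add_edge(u, v)
            elif kind == "delete":
                trial.remove_edge(u, v)
            else:
                trial.remove_edge(u, v)
                trial.add_edge(v, u)
            if not trial.is_acyclic():
                continue
            try:
                after = network_score(data, trial, spec)
            except DegenerateFitError:
                continue
            delta = score_delta(data, dag, (kind, u, v), spec, cache=cache)
            assert delta == pytest.approx(after - before, abs=1e-9)
            dag = trial
            checked += 1
        assert checked > 30

    def test_inverse_moves_cancel(self, cont3):
        dag = NetworkStructure(cont3.variables, [("A", "B")])
        cache = {}
        d1 = score_delta(cont3, dag, ("delete", "A", "B"), cache=cache)
        dag2 = dag.copy()
        dag2.remove_edge("A", "B")
        d2 = score_delta(cont3, dag2, ("add", "A", "B"), cache=cache)
        assert d1 + d2 == pytest.approx(0.0, abs=1e-12)


class TestScoreEquivalence:
    def test_gaussian_bic_constant_within_equivalence_class(self):
        """All-continuous complete data: every DAG in a Markov class gets
        the same score; classes generically differ."""
        from test_graphs import all_dags

        rng = np.random.default_rng(12)
        a = rng.normal(size=250)
        b = 0.5 * a + rng.normal(size=250)
        c = 0.5 * b + rng.normal(size=250)
        ds = make_dataset({"A": a, "B": b, "C": c})
        by_class = {}
        for dag in all_dags("ABC"):
            dag = NetworkStructure(ds.variables, dag.edges)
            s = network_score(ds, dag, ScoreSpec("bic"))
            by_class.setdefault(cpdag(dag), []).append(s)
        assert len(by_class) == 11  # equivalence classes on 3 nodes
        for scores in by_class.values():
            assert max(scores) - min(scores) < 1e-8
        reps = sorted(s[0] for s in by_class.values())
        assert min(np.diff(reps)) > 1e-6  # distinct classes differ


class TestEngineAgreement:
    @pytest.mark.parametrize("p", [4, 8])  # table path and lazy path
    def test_engine_matches_local_score(self, p):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(150, p))
        for j in range(1, p):
            X[:, j] += 0.4 * X[:, j - 1]
        ds = make_dataset({f"v{i}": X[:, i] for i in range(p)})
        spec = ScoreSpec("bic")
        engine = make_scorer(ds, spec)
        assert isinstance(engine, GaussianScoreEngine)
        rng2 = np.random.default_rng(1)
        for _ in range(40):
            child = int(rng2.integers(p))
            mask = int(rng2.integers(1 << p)) & ~(1 << child)
            parents = [f"v{i}" for i in range(p) if mask >> i & 1]
            expect, _ = local_score(ds, f"v{child}", parents, spec)
            assert engine.local(child, mask) == pytest.approx(expect, abs=1e-7)
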