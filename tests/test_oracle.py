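import itertools

import numpy as np
import pytest

from reactoracle import (
    ANOMALY_THRESHOLD,
    ChemicalSpace,
    Compound,
    Experiment,
    MCMCConfig,
    Observation,
    ObservationLog,
    Posterior,
    ReactivityVector,
    Theory,
    anomaly_shortlist,
    parsimonious_explanation,
    replay_exploration,
    select_disruptive,
    surprise_trace,
)
from reactoracle.oracle import SurpriseTrace
from reactoracle.synthetic import make_diels_alder_space, simulate_log
from reactoracle.theory import CompiledTheory


def planted_posterior(space, membership, reactivity, n=4, noise=None, k=None):
    """Posterior of identical draws at explicit parameter values."""
    kwargs = {} if noise is None else {"noise": noise}
    theory = Theory(id="planted", k=k or membership.shape[1], arities=(2,), **kwargs)
    compiled = CompiledTheory(theory, space)
    theta = compiled.pack(membership, {2: reactivity})
    chain = np.tile(theta, (2, n // 2, 1))
    return Posterior(compiled, chain, seed=0)


@pytest.fixture(scope="module")
def three_space():
    return ChemicalSpace(tuple(Compound(c, "") for c in "abc"), arities=(2,))


class TestSurpriseTrace:
    def test_certain_outcome_has_zero_surprise(self, three_space):
        from reactoracle.theory import NoiseModel

        m = np.array([[1.0], [1.0], [0.0]])
        r = np.array([[1.0]])
        post = planted_posterior(three_space, m, r, noise=NoiseModel(0.0, 0.0))
        log = ObservationLog(
            three_space, [Observation(Experiment(("a", "b")), ReactivityVector.binary(1), 0)]
        )
        config = MCMCConfig(seed=1, chains=2, warmup=100, draws=100)
        trace = surprise_trace(post.theory, log, config, online=False, posterior=post)
        assert np.isclose(trace.a_posteriori[0], 0.0, atol=1e-9)

    def test_a_priori_invariant_to_observation_order(self, three_space, fast_config):
        theory = Theory(id="t", k=2, arities=(2,))
        exps = [Experiment(("a", "b")), Experiment(("a", "c")), Experiment(("b", "c"))]
        fwd = ObservationLog(
            three_space,
            [Observation(e, ReactivityVector.binary(i == 0), i) for i, e in enumerate(exps)],
        )
        rev = ObservationLog(
            three_space,
            [
                Observation(e, ReactivityVector.binary(i == 0), 2 - i)
                for i, e in enumerate(exps)
            ],
        )
        tf = surprise_trace(theory, fwd, fast_config, online=False)
        tr = surprise_trace(theory, rev, fast_config, online=False)
        # same experiments in reversed order: entry-wise match after reversal
        assert np.allclose(tf.a_priori, tr.a_priori[::-1], atol=1e-12)

    def test_online_chain_rule_additivity(self, three_space):
        """With pure importance reweighting (no refits), the online surprises
        telescope to the negative log joint predictive likelihood."""
        theory = Theory(id="t", k=2, arities=(2,))
        exps = [Experiment(("a", "b")), Experiment(("a", "c")), Experiment(("b", "c"))]
        log = ObservationLog(
            three_space,
            [Observation(e, ReactivityVector.binary(i != 1), i) for i, e in enumerate(exps)],
        )
        config = MCMCConfig(seed=5, chains=2, warmup=100, draws=500)
        trace = surprise_trace(theory, log, config, online=True, refit_every=10**6)
        compiled = CompiledTheory(theory, three_space)
        prior = Posterior.from_prior(compiled, config.chains * config.draws, seed=config.seed,
                                     chains=config.chains)
        per_draw = prior.predictive_outcome_probability(
            list(log.experiments), log.outcome_matrix(), per_draw=True
        )
        joint = -np.log(np.mean(np.prod(per_draw, axis=1)))
        assert np.isclose(trace.online.sum(), joint, atol=1e-6)

    def test_validation(self, three_space):
        obs = (Observation(Experiment(("a", "b")), ReactivityVector.binary(1), 0),)
        with pytest.raises(ValueError):
            SurpriseTrace(obs, np.array([1.0, 2.0]), np.array([0.5]))
        with pytest.raises(ValueError):
            SurpriseTrace(obs, np.array([-0.5]), np.array([0.5]))


class TestAnomalyShortlist:
    def make_trace(self, three_space, values):
        obs = tuple(
            Observation(e, ReactivityVector.binary(1), i)
            for i, e in enumerate(
                [Experiment(("a", "b")), Experiment(("a", "c")), Experiment(("b", "c"))]
            )
        )
        return SurpriseTrace(obs, np.zeros(3), np.array(values))

    def test_threshold_filtering_and_sorting(self, three_space):
        trace = self.make_trace(three_space, [0.5, 5.0, 4.0])
        hits = anomaly_shortlist(trace)
        assert [s for _, s in hits] == [5.0, 4.0]
        assert anomaly_shortlist(trace, threshold=10.0) == []
        assert len(anomaly_shortlist(trace, threshold=0.0)) == 3

    def test_single_observation_below_threshold(self, three_space):
        trace = self.make_trace(three_space, [0.1, 0.0, 0.0])
        assert anomaly_shortlist(trace) == []


class TestSelectDisruptive:
    def test_hand_enumerated_two_draw_case(self, three_space):
        # two equally weighted draws with known pair probabilities
        m = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        theory = Theory(id="t2", k=2, arities=(2,))
        compiled = CompiledTheory(theory, three_space)
        r_a = np.array([[0.0, 0.9], [0.9, 0.0]])
        r_b = np.array([[0.0, 0.1], [0.1, 0.0]])
        th1 = compiled.pack(m, {2: r_a})
        th2 = compiled.pack(m, {2: r_b})
        chain = np.stack([th1, th2])[None, :, :]  # 1 chain, 2 draws
        post = Posterior(compiled, chain, seed=0)
        exps = [Experiment(("a", "b")), Experiment(("a", "c"))]
        batch = compiled.batch(exps)
        p = np.stack(
            [compiled.probabilities(t, batch)[:, 0] for t in (th1, th2)]
        )  # (2 draws, 2 exps)
        ranking = select_disruptive(post, exps, exps)
        scores = dict(zip(ranking.experiments, ranking.scores))
        # manual reweighting for candidate 0 against remaining exp 1
        base = p.mean(axis=0)
        expected = {}
        for j, other in ((0, 1), (1, 0)):
            s = 0.0
            for outcome in (0, 1):
                w = p[:, j] if outcome else 1 - p[:, j]
                if w.sum() <= 0:
                    continue
                shifted = (w @ p[:, other]) / w.sum()
                s += (w.mean()) * abs(shifted - base[other])
            expected[exps[j]] = s
        for e in exps:
            assert np.isclose(scores[e], expected[e], atol=1e-12)

    def test_degenerate_candidates_score_zero(self, three_space):
        m = np.array([[1.0], [1.0], [0.0]])
        post = planted_posterior(three_space, m, np.array([[0.5]]))
        exps = [Experiment(("a", "b")), Experiment(("a", "c"))]
        ranking = select_disruptive(post, exps, exps)
        # identical draws: no branch can reweight anything
        assert np.allclose(ranking.scores, 0.0)

    def test_empty_remaining_beyond_candidate(self, three_space):
        m = np.array([[1.0], [1.0], [0.0]])
        post = planted_posterior(three_space, m, np.array([[0.5]]))
        only = [Experiment(("a", "b"))]
        ranking = select_disruptive(post, only, only)
        assert np.allclose(ranking.scores, 0.0)

    def test_candidates_must_be_in_remaining(self, three_space):
        m = np.array([[1.0], [1.0], [0.0]])
        post = planted_posterior(three_space, m, np.array([[0.5]]))
        with pytest.raises(ValueError):
            select_disruptive(post, [Experiment(("a", "b"))], [Experiment(("a", "c"))])

    def test_scores_invariant_to_property_relabeling(self, three_space, rng):
        theory = Theory(id="t2", k=2, arities=(2,))
        compiled = CompiledTheory(theory, three_space)
        thetas = []
        for _ in range(6):
            m = rng.random((3, 2))
            from reactoracle.theory import symmetric_tensor

            r = symmetric_tensor(rng.random(3), 2, 2)
            thetas.append((m, r))
        exps = [Experiment(("a", "b")), Experiment(("a", "c")), Experiment(("b", "c"))]

        def ranking_for(perm):
            packed = [
                compiled.pack(m[:, perm], {2: r[np.ix_(perm, perm)]}) for m, r in thetas
            ]
            chain = np.stack(packed)[None, :, :]
            return select_disruptive(Posterior(compiled, chain, seed=0), exps, exps)

        base = ranking_for([0, 1])
        swapped = ranking_for([1, 0])
        assert base.experiments == swapped.experiments
        assert np.allclose(base.scores, swapped.scores, atol=1e-12)


class TestReplay:
    def small_setup(self):
        fx = make_diels_alder_space()
        theory = Theory(id="da", k=3, arities=(2,))
        config = MCMCConfig(seed=21, chains=2, warmup=200, draws=200)
        return fx, theory, config

    def test_random_strategy_reproducible(self):
        fx, theory, config = self.small_setup()
        kwargs = dict(
            steps=5, strategy="random", refit_every=3, experiments=fx["experiments"]
        )
        r1 = replay_exploration(theory, fx["space"], fx["outcome_source"], config, **kwargs)
        r2 = replay_exploration(theory, fx["space"], fx["outcome_source"], config, **kwargs)
        assert r1.events == r2.events

    def test_constant_zero_source_discovers_nothing(self):
        fx, theory, config = self.small_setup()
        result = replay_exploration(
            theory,
            fx["space"],
            lambda e: ReactivityVector.binary(0),
            config,
            steps=6,
            strategy="random",
            refit_every=4,
            experiments=fx["experiments"],
        )
        assert result.discoveries == []

    def test_steps_beyond_space_stop_early(self):
        fx, theory, config = self.small_setup()
        pool = fx["experiments"][:4]
        result = replay_exploration(
            theory,
            fx["space"],
            fx["outcome_source"],
            config,
            steps=50,
            strategy="random",
            refit_every=2,
            experiments=pool,
            repeat_attempts=False,
        )
        assert len(result.events) == 4

    def test_surprising_observation_scheduled_twice(self):
        fx, theory, config = self.small_setup()
        # an absurdly low threshold makes every observation "surprising":
        # each distinct experiment must then be attempted exactly twice
        result = replay_exploration(
            theory,
            fx["space"],
            fx["outcome_source"],
            config,
            steps=6,
            strategy="random",
            refit_every=3,
            experiments=fx["experiments"],
            anomaly_threshold=-1.0,
        )
        seen = [e["experiment"] for e in result.events]
        assert len(seen) == 6
        assert all(seen.count(x) == 2 for x in set(seen))
        repeats = [e["repeat"] for e in result.events]
        assert sum(repeats) == 3

    def test_disruptive_strategy_runs(self):
        fx, theory, config = self.small_setup()
        result = replay_exploration(
            theory,
            fx["space"],
            fx["outcome_source"],
            config,
            steps=3,
            strategy="disruptive",
            refit_every=2,
            experiments=fx["experiments"],
        )
        assert len(result.events) == 3
        assert all(e["strategy"] == "disruptive" for e in result.events)


class TestParsimoniousExplanation:
    def test_single_rule_uses_two_properties(self):
        space = ChemicalSpace(tuple(Compound(c, "") for c in "abcd"), arities=(2,))
        reactive = {frozenset({"a", "b"})}

        def source(e):
            return ReactivityVector.binary(frozenset(e.ids) in reactive)

        log = simulate_log(space, source, experiments=None)
        # self-pairs unreactive force two distinct properties for the rule
        log = simulate_log(
            space,
            source,
            experiments=__import__("reactoracle").enumerate_experiments(
                space, (2,), include_self_pairs=True
            ),
        )
        theory = Theory(id="mini", k=4, arities=(2,))
        expl = parsimonious_explanation(theory, log, seed=3, restarts=8)
        assert expl.n_properties == 2
        assert expl.compound_properties["a"] == 1
        assert expl.compound_properties["b"] == 1
        assert expl.compound_properties["c"] == 0

    def test_unreactive_log_needs_no_properties(self, three_space):
        log = simulate_log(three_space, lambda e: ReactivityVector.binary(0))
        theory = Theory(id="null", k=3, arities=(2,))
        expl = parsimonious_explanation(theory, log, seed=1, restarts=4)
        assert expl.n_properties == 0
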