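import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reactoracle import (
    ChemicalSpace,
    Compound,
    NoiseModel,
    ObservationLog,
    Observation,
    ReactivityVector,
    Theory,
    bit_probability,
    component_matrix,
    compound_membership_from_bits,
    log_likelihood,
    reaction_probability,
)
from reactoracle.theory import (
    CompiledTheory,
    ShapeError,
    mode_components,
    property_modes,
    symmetric_tensor,
    unique_entries,
)


def brute_force_reaction_probability(rows, r):
    """Independent enumeration over unordered property multisets, OR-ing the
    distinct reagent-to-index assignments inside each multiset."""
    k = len(rows[0])
    arity = len(rows)
    p_no = 1.0
    for combo in itertools.combinations_with_replacement(range(k), arity):
        no_fire = 1.0
        for perm in set(itertools.permutations(combo)):
            term = r[combo]
            for row, idx in zip(rows, perm):
                term *= row[idx]
            no_fire *= 1.0 - term
        p_no *= no_fire
    return 1.0 - p_no


class TestComponentMatrix:
    def test_annihilation_identity_and_value(self):
        z = np.zeros(2)
        assert np.allclose(component_matrix(z, z, np.ones((2, 2))), 0)
        assert np.allclose(component_matrix(np.ones(1), np.ones(1), np.ones((1, 1))), 1)
        assert np.allclose(
            component_matrix(np.array([0.5]), np.array([0.5]), np.array([[0.8]])), 0.2
        )

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            component_matrix(np.ones(2), np.ones(3), np.ones((2, 2)))


class TestReactionProbability:
    def test_examples(self):
        assert reaction_probability([np.zeros(3), np.ones(3)], np.ones((3, 3))) == 0
        assert np.isclose(
            reaction_probability([np.array([0.5]), np.array([0.5])], np.array([[0.8]])), 0.2
        )
        r = np.array([[0.0, 1.0], [1.0, 0.0]])
        p = reaction_probability([np.array([1.0, 0.0]), np.array([0.0, 1.0])], r)
        assert np.isclose(p, 1.0, atol=1e-9)

    @pytest.mark.parametrize("k", [1, 2])
    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_enumeration(self, k, trial, rng):
        rows = [rng.random(k) for _ in range(2)]
        r = symmetric_tensor(rng.random(k * (k + 1) // 2), k, 2)
        assert np.isclose(
            reaction_probability(rows, r),
            brute_force_reaction_probability(rows, r),
            atol=1e-12,
        )

    @pytest.mark.parametrize("arity", [2, 3, 4])
    def test_invariant_under_reagent_permutation(self, arity, rng):
        k = 3
        rows = [rng.random(k) for _ in range(arity)]
        n_unique = len(property_modes(k, arity))
        r = symmetric_tensor(rng.random(n_unique), k, arity)
        base = reaction_probability(rows, r)
        for perm in itertools.permutations(range(arity)):
            assert np.isclose(reaction_probability([rows[i] for i in perm], r), base, atol=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_every_parameter(self, seed):
        rng = np.random.default_rng(seed)
        k = 2
        rows = [rng.random(k) * 0.9 for _ in range(2)]
        ru = rng.random(3) * 0.9
        base = reaction_probability(rows, symmetric_tensor(ru, k, 2))
        for i, j in itertools.product(range(2), range(k)):
            bumped = [row.copy() for row in rows]
            bumped[i][j] += 0.05
            assert reaction_probability(bumped, symmetric_tensor(ru, k, 2)) >= base - 1e-12
        for m in range(3):
            ru2 = ru.copy()
            ru2[m] += 0.05
            assert reaction_probability(rows, symmetric_tensor(ru2, k, 2)) >= base - 1e-12

    def test_bounds_at_extremes(self):
        for rows in itertools.product([np.zeros(2), np.ones(2)], repeat=3):
            p = reaction_probability(list(rows), np.ones((2, 2, 2)))
            assert 0.0 <= p <= 1.0

    def test_arity_mismatch(self):
        with pytest.raises(ShapeError):
            reaction_probability([np.ones(2), np.ones(2), np.ones(2)], np.ones((2, 2)))


class TestFingerprintMembership:
    def test_noisy_or_over_bits(self):
        m = np.array([[0.7, 0.0], [0.5, 0.0], [0.5, 0.0]])
        assert np.allclose(compound_membership_from_bits([], m), 0)
        assert np.allclose(compound_membership_from_bits([0], m), [0.7, 0.0])
        assert np.allclose(compound_membership_from_bits([1, 2], m), [0.75, 0.0])

    def test_unknown_bit(self):
        m = np.ones((2, 1)) * 0.5
        with pytest.raises(KeyError):
            compound_membership_from_bits([5], m)
        with pytest.raises(KeyError):
            compound_membership_from_bits([123], m, basis=[7, 9])


class TestBitProbability:
    def test_limits_and_noise_floor(self):
        rows = [np.zeros(1), np.zeros(1)]
        r = np.ones((1, 1))
        em = np.ones((1, 2))
        assert bit_probability(rows, r, em, NoiseModel(0.0, 0.0), bit=0) == 0
        rows = [np.ones(1), np.ones(1)]
        assert np.isclose(bit_probability(rows, r, em, NoiseModel(0.0, 0.0), bit=1), 1, atol=1e-9)

    def test_half_component(self):
        # one mode with component 0.5, full emission, 1% noise both ways
        rows = [np.ones(1), np.array([0.5])]
        p = bit_probability(rows, np.ones((1, 1)), np.ones((1, 1)), NoiseModel(0.01, 0.01), bit=0)
        assert np.isclose(p, 0.01 + 0.98 * 0.5)

    def test_bit_out_of_range(self):
        with pytest.raises(IndexError):
            bit_probability([np.ones(1)] * 2, np.ones((1, 1)), np.ones((1, 2)), NoiseModel(), bit=5)


def binary_theory(k=2, arities=(2,), **kw):
    return Theory(id="t", k=k, arities=arities, **kw)


def small_space(n=3):
    return ChemicalSpace(tuple(Compound(f"c{i}", "") for i in range(n)), arities=(2,))


def make_log(space, rows):
    return ObservationLog(
        space,
        [
            Observation(e, ReactivityVector.binary(y), t)
            for t, (e, y) in enumerate(rows)
        ],
    )


class TestLogLikelihood:
    def test_empty_additive_and_value(self):
        from reactoracle import Experiment

        space = small_space(3)
        theory = binary_theory(k=1, noise=NoiseModel(0.0, 0.0))
        m = np.full((3, 1), np.sqrt(0.5))
        theta = {"membership": m, "reactivity": {2: np.array([[1.0]])}}
        empty = ObservationLog(space)
        assert log_likelihood(empty, theta, theory) == 0
        e = Experiment(("c0", "c1"))
        one = make_log(space, [(e, 1)])
        ll1 = log_likelihood(one, theta, theory)
        assert np.isclose(ll1, np.log(0.5))
        two = ObservationLog(
            space,
            [
                Observation(e, ReactivityVector.binary(1), 0),
                Observation(e, ReactivityVector.binary(1), 1),
            ],
        )
        assert np.isclose(log_likelihood(two, theta, theory), 2 * ll1)

    def test_clamping_avoids_infinities(self):
        from reactoracle import Experiment

        space = small_space(2)
        theory = binary_theory(k=1, noise=NoiseModel(0.0, 0.0))
        theta = {"membership": np.zeros((2, 1)), "reactivity": {2: np.array([[0.0]])}}
        log = make_log(space, [(Experiment(("c0", "c1")), 1)])
        value = log_likelihood(log, theta, theory)
        assert np.isfinite(value) and value < -15

    def test_label_switching_invariance(self, rng):
        space = small_space(4)
        theory = binary_theory(k=3)
        compiled = CompiledTheory(theory, space)
        log = make_log(
            space,
            [(e, int(rng.random() < 0.5)) for e in __import__("reactoracle").enumerate_experiments(space)],
        )
        m = rng.random((4, 3))
        r = symmetric_tensor(rng.random(6), 3, 2)
        base = log_likelihood(log, {"membership": m, "reactivity": {2: r}}, theory)
        for perm in itertools.permutations(range(3)):
            perm = list(perm)
            m2 = m[:, perm]
            r2 = r[np.ix_(perm, perm)]
            assert np.isclose(
                log_likelihood(log, {"membership": m2, "reactivity": {2: r2}}, theory),
                base,
                atol=1e-10,
            )

    def test_label_switching_multibit_emission(self, rng):
        space = small_space(3)
        theory = Theory(id="mb", k=2, arities=(2,), width=3)
        compiled = CompiledTheory(theory, space)
        modes = [tuple(m) for m in property_modes(2, 2)]
        m = rng.random((3, 2))
        ru = rng.random(len(modes))
        em = rng.random((len(modes), 3))
        exps = __import__("reactoracle").enumerate_experiments(space)
        log = ObservationLog(
            space,
            [
                Observation(e, ReactivityVector(tuple(rng.integers(0, 2, 3))), t)
                for t, e in enumerate(exps)
            ],
        )
        batch, y = compiled.batch_for_log(log)
        base = compiled.log_likelihood(
            compiled.pack(m, {2: symmetric_tensor(ru, 2, 2)}, em), batch, y
        )
        perm = [1, 0]
        mode_map = [modes.index(tuple(sorted(perm[i] for i in mo))) for mo in modes]
        ru2 = np.empty_like(ru)
        em2 = np.empty_like(em)
        for src, dst in enumerate(mode_map):
            ru2[dst] = ru[src]
            em2[dst] = em[src]
        permuted = compiled.pack(m[:, perm], {2: symmetric_tensor(ru2, 2, 2)}, em2)
        assert np.isclose(compiled.log_likelihood(permuted, batch, y), base, atol=1e-10)


class TestSymmetricTensors:
    @pytest.mark.parametrize("k,arity", [(2, 2), (3, 3), (2, 4)])
    def test_round_trip_and_symmetry(self, k, arity, rng):
        n = len(property_modes(k, arity))
        u = rng.random(n)
        full = symmetric_tensor(u, k, arity)
        for perm in itertools.permutations(range(arity)):
            assert np.array_equal(np.transpose(full, perm), full)
        assert np.allclose(unique_entries(full, arity), u)

    def test_mode_components_or_within_mode(self):
        # off-diagonal mode {0,1} with asymmetric memberships: OR of both
        # reagent-to-index assignments
        rows = [np.array([1.0, 0.2]), np.array([0.3, 1.0])]
        r = symmetric_tensor(np.array([0.0, 1.0, 0.0]), 2, 2)
        comp = mode_components(rows, r)
        expected = 1 - (1 - 1.0 * 1.0) * (1 - 0.2 * 0.3)
        assert np.isclose(comp[1], expected)


class TestCompiledTheory:
    def test_parameter_count_and_pack(self, rng):
        space = small_space(5)
        theory = Theory(id="mb", k=3, arities=(2, 3), width=4)
        compiled = CompiledTheory(theory, space)
        n_modes = 6 + 10
        assert compiled.ndim == 5 * 3 + 6 + 10 + n_modes * 4
        m = rng.random((5, 3))
        r2 = symmetric_tensor(rng.random(6), 3, 2)
        r3 = symmetric_tensor(rng.random(10), 3, 3)
        em = rng.random((n_modes, 4))
        theta = compiled.pack(m, {2: r2, 3: r3}, em)
        assert np.allclose(compiled.block(theta, "membership"), m)
        assert np.allclose(compiled.reactivity_tensor(theta, 3), r3)
        assert np.allclose(compiled.block(theta, "emission"), em)

    def test_binary_probability_matches_reaction_probability(self, rng):
        space = small_space(3)
        theory = binary_theory(k=2, noise=NoiseModel(0.0, 0.0))
        compiled = CompiledTheory(theory, space)
        m = rng.random((3, 2))
        r = symmetric_tensor(rng.random(3), 2, 2)
        theta = compiled.pack(m, {2: r})
        exps = __import__("reactoracle").enumerate_experiments(space)
        batch = compiled.batch(exps)
        p = compiled.probabilities(theta, batch)[:, 0]
        for e, pi in zip(exps, p):
            rows = [m[space.index(c)] for c in e.reagents]
            assert np.isclose(pi, reaction_probability(rows, r), atol=1e-12)

    def test_fingerprint_basis_rows(self):
        space = ChemicalSpace(
            (
                Compound("x", "", fingerprint=frozenset({10})),
                Compound("y", "", fingerprint=frozenset({10, 20})),
            ),
            arities=(2,),
        )
        from reactoracle import FingerprintScheme

        theory = Theory(
            id="fp",
            basis="fingerprint_bit",
            k=1,
            arities=(2,),
            fingerprint=FingerprintScheme("morgan"),
        )
        compiled = CompiledTheory(theory, space)
        assert compiled.entities == (10, 20)
        theta = compiled.pack(np.array([[0.5], [0.5]]), {2: np.array([[1.0]])})
        rows = compiled.compound_rows(theta)
        assert np.isclose(rows[0, 0], 0.5)
        assert np.isclose(rows[1, 0], 0.75)


class TestNoiseModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            NoiseModel(0.6, 0.0)
        with pytest.raises(ValueError):
            NoiseModel(0.0, -0.1)

    def test_theory_round_trip(self, tmp_path):
        theory = Theory(
            id="rt",
            k=4,
            arities=(3, 2),
            width=8,
            prior_overrides={"reactivity": (0.5, 50.0)},
            noise=NoiseModel(0.02, 0.03),
        )
        path = tmp_path / "theory.json"
        theory.to_json(path)
        assert Theory.from_json(path) == theory
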