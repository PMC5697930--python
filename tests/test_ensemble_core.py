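import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gr_eam import (
    DEFAULT_RT,
    CouplingSpec,
    DomainSpec,
    ModelError,
    ObservableUndefinedError,
    ProteinModel,
    ensemble,
    enumerate_states,
    interaction_energy,
    observable_activity,
    observable_affinity,
    r_linker_dbd_model,
    relative_observables,
    state_free_energy,
)
from gr_eam.perturbation import Perturbation, apply_perturbation

from conftest import (
    ABLATED_ACTIVITY,
    ABLATED_AFFINITY,
    ABLATED_Q,
    REF_ACTIVITY,
    REF_AFFINITY,
    REF_Q,
)
from oracles import brute_force_observables, brute_force_probabilities


def flat_model(n, name="m", flags=True):
    domains = []
    for i in range(n):
        domains.append(
            DomainSpec(
                f"d{i}",
                0.0,
                is_functional=flags and i == 0 and n > 1,
                is_binding=flags and i == n - 1,
            )
        )
    return ProteinModel(name=name, domains=tuple(domains))


@st.composite
def random_models(draw, max_n=4):
    """Random domain networks: stabilities and couplings in [-5, 5] kcal/mol."""
    n = draw(st.integers(1, max_n))
    stab = st.floats(-5, 5, allow_nan=False)
    domains = tuple(
        DomainSpec(
            f"d{i}",
            draw(stab),
            is_functional=(i == 0 and n > 1),
            is_binding=(i == n - 1),
        )
        for i in range(n)
    )
    pairs = [(f"d{i}", f"d{j}") for i in range(n) for j in range(i + 1, n)]
    chosen = draw(st.lists(st.sampled_from(pairs), unique=True) if pairs else st.just([]))
    couplings = tuple(CouplingSpec(p, draw(stab)) for p in chosen)
    return ProteinModel(name="rand", domains=domains, couplings=couplings)


class TestModelValidation:
    def test_duplicate_domain_names_rejected(self):
        with pytest.raises(ModelError):
            ProteinModel("x", (DomainSpec("a", 0.0), DomainSpec("a", 1.0)))

    def test_coupling_to_unknown_domain_rejected(self):
        with pytest.raises(ModelError):
            ProteinModel(
                "x", (DomainSpec("a", 0.0),), (CouplingSpec(("a", "ghost"), 1.0),)
            )

    def test_two_binding_domains_rejected(self):
        with pytest.raises(ModelError):
            ProteinModel(
                "x",
                (DomainSpec("a", 0.0, is_binding=True), DomainSpec("b", 0.0, is_binding=True)),
            )

    def test_nonpositive_thermal_energy_rejected(self):
        with pytest.raises(ModelError):
            ProteinModel("x", (DomainSpec("a", 0.0),), thermal_energy=0.0)


class TestEnumeration:
    @pytest.mark.parametrize("n,expected", [(1, 2), (2, 4), (3, 8), (4, 16)])
    def test_state_count_is_two_to_the_n(self, n, expected):
        states = enumerate_states(flat_model(n))
        assert len(states) == expected
        assert len(set(states)) == expected

    def test_binary_counting_order_first_domain_most_significant(self):
        states = enumerate_states(flat_model(2))
        assert states == [(0, 0), (0, 1), (1, 0), (1, 1)]


class TestInteractionEnergy:
    @pytest.mark.parametrize(
        "j,si,sj,expected",
        [(-2.0, 1, 1, -2.0), (5.0, 1, 0, 0.0), (5.0, 0, 1, 0.0), (0.0, 1, 1, 0.0)],
    )
    def test_contributes_only_when_both_folded(self, j, si, sj, expected):
        assert interaction_energy(j, si, sj) == expected

    def test_invalid_indicator_rejected(self):
        with pytest.raises(ModelError):
            interaction_energy(1.0, 2, 1)

    def test_j_is_minus_delta_g(self):
        assert CouplingSpec(("a", "b"), 1.5).j_energy == -1.5


class TestStateFreeEnergy:
    def test_reference_state_is_exactly_zero(self, model_a):
        assert state_free_energy(model_a, (0, 0, 0)) == 0.0

    def test_single_folded_domain(self):
        m = ProteinModel("x", (DomainSpec("a", 1.0),))
        assert state_free_energy(m, (1,)) == -1.0

    def test_cofolded_pair_adds_coupling(self):
        m = ProteinModel(
            "x",
            (DomainSpec("a", 1.0), DomainSpec("b", 2.0)),
            (CouplingSpec(("a", "b"), 0.5),),
        )
        assert state_free_energy(m, (1, 1)) == pytest.approx(-3.5, abs=1e-15)

    def test_wrong_length_rejected(self, model_a):
        with pytest.raises(ModelError):
            state_free_energy(model_a, (0, 1))


class TestEnsemble:
    def test_uniform_when_all_parameters_zero(self):
        res = ensemble(flat_model(3))
        for s in res.states:
            assert s.probability == pytest.approx(1 / 8, abs=1e-15)

    def test_two_domain_single_coupling_exact_weights(self):
        # stabilities 0, dg = RT ln 2 -> weights (1, 1, 1, 2), Q = 5
        m = ProteinModel(
            "x",
            (
                DomainSpec("F", 0.0, is_functional=True),
                DomainSpec("DBD", 0.0, is_binding=True),
            ),
            (CouplingSpec(("F", "DBD"), DEFAULT_RT * math.log(2)),),
        )
        res = ensemble(m)
        assert [s.weight for s in res.states] == pytest.approx([1, 1, 1, 2], abs=1e-12)
        assert res.partition_function == pytest.approx(5.0, abs=1e-12)
        assert res.states[-1].probability == pytest.approx(0.4, abs=1e-12)
        assert observable_activity(res, m) == pytest.approx(0.4, abs=1e-12)
        assert observable_affinity(res, m) == pytest.approx(0.6, abs=1e-12)

    def test_zero_coupling_factorizes(self):
        m = ProteinModel(
            "x",
            (
                DomainSpec("F", 0.0, is_functional=True),
                DomainSpec("DBD", 0.0, is_binding=True),
            ),
            (CouplingSpec(("F", "DBD"), 0.0),),
        )
        res = ensemble(m)
        assert res.states[-1].probability == pytest.approx(0.25, abs=1e-12)

    def test_reference_frustrated_set_exact_rationals(self, model_a):
        res = ensemble(model_a)
        assert res.partition_function == pytest.approx(REF_Q, abs=1e-12)
        assert res.activity == pytest.approx(REF_ACTIVITY, abs=1e-12)
        assert res.affinity == pytest.approx(REF_AFFINITY, abs=1e-12)
        # hand-enumerable weights, (R, F, D) binary counting order
        expected_weights = [1, 1, 1, 2, 4, 16, 1 / 8, 1]
        got = [s.weight for s in res.states]
        assert got == pytest.approx(expected_weights, rel=1e-12)

    def test_extreme_energies_stay_finite(self):
        m = ProteinModel("x", (DomainSpec("a", 2000.0), DomainSpec("b", -2000.0)))
        res = ensemble(m)
        assert all(math.isfinite(s.probability) for s in res.states)
        assert sum(s.probability for s in res.states) == pytest.approx(1.0, abs=1e-12)


class TestObservables:
    def test_all_zero_three_domain_symmetry(self):
        m = flat_model(3)
        res = ensemble(m)
        assert observable_affinity(res, m) == pytest.approx(0.5, abs=1e-12)
        assert observable_activity(res, m) == pytest.approx(0.25, abs=1e-12)

    def test_affinity_undefined_without_binding_domain(self):
        m = flat_model(2, flags=False)
        res = ensemble(m)
        with pytest.raises(ObservableUndefinedError):
            observable_affinity(res, m)

    def test_activity_undefined_without_functional_domain(self, ref_params):
        m = r_linker_dbd_model(ref_params["dG_R"], ref_params["dG_D"], ref_params["dg_RD"])
        res = ensemble(m)
        with pytest.raises(ObservableUndefinedError):
            observable_activity(res, m)
        assert 0.0 <= observable_affinity(res, m) <= 1.0


class TestRelativeObservables:
    def test_self_normalization_is_unity(self, model_a):
        rel = relative_observables([model_a], "A")
        assert rel.loc["A", "activity_rel"] == pytest.approx(1.0, abs=1e-12)
        assert rel.loc["A", "affinity_rel"] == pytest.approx(1.0, abs=1e-12)

    def test_identical_models_both_unity(self, model_a):
        import dataclasses

        twin = dataclasses.replace(model_a, name="A2")
        rel = relative_observables([model_a, twin], "A")
        assert rel.loc["A2", "activity_rel"] == pytest.approx(1.0, abs=1e-12)
        assert rel.loc["A2", "affinity_rel"] == pytest.approx(1.0, abs=1e-12)

    def test_coupling_ablated_variant_exact_ratios(self, model_a):
        import dataclasses

        ablated = apply_perturbation(
            model_a, Perturbation("coupling_scale", ("R", "DBD"), 0.0)
        )
        variant = dataclasses.replace(ablated, name="A_ablated")
        rel = relative_observables([model_a, variant], "A")
        assert rel.loc["A_ablated", "activity_rel"] == pytest.approx(
            ABLATED_ACTIVITY / REF_ACTIVITY, abs=1e-12
        )
        assert rel.loc["A_ablated", "affinity_rel"] == pytest.approx(
            ABLATED_AFFINITY / REF_AFFINITY, abs=1e-12
        )

    def test_unknown_reference_rejected(self, model_a):
        with pytest.raises(ModelError):
            relative_observables([model_a], "nope")


class TestEnsembleProperties:
    @settings(max_examples=100, derandomize=True)
    @given(random_models())
    def test_probabilities_normalize_and_match_bruteforce(self, model):
        res = ensemble(model)
        assert sum(s.probability for s in res.states) == pytest.approx(1.0, abs=1e-12)
        oracle = brute_force_probabilities(model)
        for s in res.states:
            assert s.probability == pytest.approx(oracle[s.indicators], abs=1e-10)
        # reference state invariants
        assert res.states[0].free_energy == 0.0
        assert res.states[0].weight == 1.0

    @settings(max_examples=100, derandomize=True)
    @given(random_models(max_n=4))
    def test_activity_never_exceeds_affinity(self, model):
        res = ensemble(model)
        if res.activity is not None and res.affinity is not None:
            assert res.activity <= res.affinity + 1e-12

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=4))
    def test_uncoupled_domains_factorize(self, stabilities):
        m = ProteinModel(
            "x", tuple(DomainSpec(f"d{i}", s) for i, s in enumerate(stabilities))
        )
        res = ensemble(m)
        rt = m.thermal_energy
        marginals = [
            math.exp(s / rt) / (1 + math.exp(s / rt)) for s in stabilities
        ]
        for state in res.states:
            expected = 1.0
            for si, p1 in zip(state.indicators, marginals):
                expected *= p1 if si else (1 - p1)
            assert state.probability == pytest.approx(expected, abs=1e-10)

    def test_activity_monotone_in_direct_coupling(self, model_a):
        grid = np.linspace(-3.0, 3.0, 25)
        activities = []
        for g in grid:
            m = model_a.with_coupling(("F", "DBD"), float(g))
            res = ensemble(m)
            activities.append(observable_activity(res, m))
        assert all(b >= a - 1e-12 for a, b in zip(activities, activities[1:]))
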