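import math

import numpy as np
import pandas as pd
import pytest

from gr_eam import (
    BudgetExceededError,
    InfeasibleSpaceError,
    IsoformDataset,
    ModelError,
    ParameterAxis,
    ParameterSpace,
    grid_search,
    gr_isoform_family,
    objective,
    profile_likelihood,
    propagate_uncertainty,
    recovery_parameter_space,
    relative_observables,
)
from gr_eam.family import default_truth_params
from gr_eam.synthetic_data import GroundTruth, generate_isoform_dataset

from oracles import brute_force_grid_search, brute_force_nll

TRUTH = default_truth_params()


def noiseless_dataset(family, err=0.05):
    """Dataset whose observed values equal the truth's predictions exactly."""
    rel = relative_observables(family.build_models(TRUTH), family.reference)
    frame = pd.DataFrame(
        {
            "activity_rel": rel["activity_rel"],
            "activity_err": err * rel["activity_rel"],
            "affinity_rel": rel["affinity_rel"],
            "affinity_err": err * rel["affinity_rel"],
        }
    )
    return IsoformDataset(frame=frame, reference=family.reference)


def tiny_space(n_shared=2, rt_ln2=0.411036278):
    """Coarse space for brute-force cross-checks: truth on-grid."""
    a = rt_ln2

    def axis(name, truth_val, others):
        return ParameterAxis(name, tuple([truth_val] + others))

    return ParameterSpace(
        (
            ParameterAxis.fixed("dG_R_A", TRUTH["dG_R_A"]),
            ParameterAxis.fixed("dG_R_B", TRUTH["dG_R_B"]),
            ParameterAxis.fixed("dG_R_C1", TRUTH["dG_R_C1"]),
            ParameterAxis.fixed("dG_R_C2", TRUTH["dG_R_C2"]),
            axis("dG_F", TRUTH["dG_F"], [a]),
            axis("dG_D", TRUTH["dG_D"], [-a]),
            axis("dg_RF", TRUTH["dg_RF"], [0.0]),
            axis("dg_RD", TRUTH["dg_RD"], [0.0]),
            axis("dg_FD", TRUTH["dg_FD"], [-a, a]),
        )
    )


class TestDataset:
    def test_missing_reference_row_rejected(self, family):
        data = noiseless_dataset(family)
        frame = data.frame.drop("C3")
        with pytest.raises(ModelError):
            IsoformDataset(frame=frame, reference="C3")

    def test_nonpositive_errors_rejected(self, family):
        frame = noiseless_dataset(family).frame.copy()
        frame.loc["A", "activity_err"] = 0.0
        with pytest.raises(ModelError):
            IsoformDataset(frame=frame, reference="C3")

    def test_csv_round_trip(self, family, tmp_path):
        data = noiseless_dataset(family)
        path = tmp_path / "iso.csv"
        data.to_csv(path)
        back = IsoformDataset.from_csv(path)
        assert back.reference == "C3"
        pd.testing.assert_frame_equal(back.frame, data.frame)


class TestObjective:
    def test_zero_at_generating_parameters(self, family):
        assert objective(TRUTH, noiseless_dataset(family), family) == pytest.approx(
            0.0, abs=1e-18
        )

    def test_single_residual_direct_evaluation(self, family):
        # one construct, one discrepant observable: ((0.2)/0.1)^2 / 2 = 2.0
        rel = relative_observables(family.build_models(TRUTH), family.reference)
        pred_act = rel.loc["A", "activity_rel"]
        pred_aff = rel.loc["A", "affinity_rel"]
        frame = pd.DataFrame.from_dict(
            {
                "A": {
                    "activity_rel": pred_act + 0.2,
                    "activity_err": 0.1,
                    "affinity_rel": pred_aff,
                    "affinity_err": 0.1,
                },
                "C3": {
                    "activity_rel": 1.0,
                    "activity_err": 0.1,
                    "affinity_rel": 1.0,
                    "affinity_err": 0.1,
                },
            },
            orient="index",
        )
        data = IsoformDataset(frame=frame, reference="C3")
        assert objective(TRUTH, data, family) == pytest.approx(2.0, abs=1e-9)

    def test_doubling_errors_quarters_objective(self, family):
        data = noiseless_dataset(family)
        frame = data.frame.copy()
        frame["activity_rel"] = frame["activity_rel"] * 1.1
        frame["affinity_rel"] = frame["affinity_rel"] * 0.9
        d1 = IsoformDataset(frame=frame, reference="C3")
        frame2 = frame.copy()
        frame2[["activity_err", "affinity_err"]] *= 2.0
        d2 = IsoformDataset(frame=frame2, reference="C3")
        assert objective(TRUTH, d2, family) == pytest.approx(
            objective(TRUTH, d1, family) / 4.0, rel=1e-12
        )

    def test_invariant_to_row_ordering(self, family):
        data = noiseless_dataset(family)
        frame = data.frame * 1.0
        frame["activity_rel"] *= 1.07
        shuffled = IsoformDataset(frame=frame.iloc[::-1], reference="C3")
        plain = IsoformDataset(frame=frame, reference="C3")
        assert objective(TRUTH, shuffled, family) == pytest.approx(
            objective(TRUTH, plain, family), rel=1e-12
        )

    def test_matches_bruteforce_oracle(self, family):
        frame = noiseless_dataset(family).frame * 1.0
        frame["affinity_rel"] *= 0.93
        data = IsoformDataset(frame=frame, reference="C3")
        off_truth = dict(TRUTH, dg_FD=0.0, dG_F=0.3)
        assert objective(off_truth, data, family) == pytest.approx(
            brute_force_nll(off_truth, data, family), rel=1e-9
        )


class TestGridSearch:
    def test_one_point_grid_returns_that_point(self, family):
        space = ParameterSpace(
            tuple(ParameterAxis.fixed(n, TRUTH[n]) for n in family.parameter_names)
        )
        data = noiseless_dataset(family)
        fit = grid_search(space, data, family)
        assert fit.best_params == {n: TRUTH[n] for n in family.parameter_names}
        assert fit.objective == pytest.approx(0.0, abs=1e-18)

    def test_matches_bruteforce_search_on_coarse_grid(self, family):
        frame = noiseless_dataset(family).frame * 1.0
        frame["activity_rel"] *= 1.12
        frame["affinity_rel"] *= 0.95
        data = IsoformDataset(frame=frame, reference="C3")
        space = tiny_space()
        fit = grid_search(space, data, family)
        oracle_params, oracle_obj = brute_force_grid_search(space, data, family)
        assert fit.objective == pytest.approx(oracle_obj, rel=1e-9)
        for n in space.names:
            assert fit.best_params[n] == pytest.approx(oracle_params[n], abs=1e-12)

    def test_noise_free_on_grid_truth_recovered_exactly(self, family):
        truth = GroundTruth(family=family, params=TRUTH, noise_sd=1e-12, seed=7)
        data = generate_isoform_dataset(truth)
        fit = grid_search(recovery_parameter_space(), data, family)
        for n, v in TRUTH.items():
            assert fit.best_params[n] == pytest.approx(v, abs=1e-9)

    def test_budget_refusal_reports_required_size(self, family):
        space = tiny_space()
        data = noiseless_dataset(family)
        with pytest.raises(BudgetExceededError) as err:
            grid_search(space, data, family, budget=3)
        assert err.value.required == space.size
        assert str(space.size) in str(err.value)

    def test_refining_near_argmin_never_worsens(self, family):
        frame = noiseless_dataset(family).frame * 1.0
        frame["activity_rel"] *= 1.08
        data = IsoformDataset(frame=frame, reference="C3")
        space = tiny_space()
        fit = grid_search(space, data, family)
        refined = space
        for name in ("dg_FD", "dG_F"):
            axis = space.axis(name)
            best = fit.best_params[name]
            extra = tuple(sorted(set(axis.values) | {best + 0.05, best - 0.05}))
            refined = refined.replace_axis(ParameterAxis(name, extra))
        fit2 = grid_search(refined, data, family)
        assert fit2.objective <= fit.objective + 1e-12

    def test_sign_constraint_filters_axis(self):
        axis = ParameterAxis("dg_FD", (-1.0, -0.5, 0.5, 1.0), sign="+")
        assert axis.values == (0.5, 1.0)
        with pytest.raises(InfeasibleSpaceError):
            ParameterAxis("dg_FD", (-1.0, -0.5), sign="+")


class TestProfiles:
    def test_profile_minimum_equals_global_objective(self, family):
        frame = noiseless_dataset(family).frame * 1.0
        frame["affinity_rel"] *= 1.05
        data = IsoformDataset(frame=frame, reference="C3")
        space = tiny_space()
        fit = grid_search(space, data, family)
        for name in ("dg_FD", "dG_F", "dG_D"):
            curve = fit.profiles[name]
            assert curve["objective"].min() == pytest.approx(fit.objective, rel=1e-12)
            assert fit.objective <= curve["objective"].min() + 1e-15

    def test_profile_minimized_at_truth_for_identifiable_noise_free_data(self, family):
        truth = GroundTruth(family=family, params=TRUTH, noise_sd=1e-12, seed=3)
        data = generate_isoform_dataset(truth)
        curve = profile_likelihood(recovery_parameter_space(), data, family, "dg_RF")
        best_val = curve.loc[curve["objective"].idxmin(), "value"]
        assert best_val == pytest.approx(TRUTH["dg_RF"], abs=1e-9)

    def test_unused_parameter_has_flat_profile(self, family):
        # a dataset containing only the reference construct constrains nothing
        full = noiseless_dataset(family)
        frame = full.frame.loc[["C3"]]
        data = IsoformDataset(frame=frame, reference="C3")
        space = tiny_space()
        fit = grid_search(space, data, family)
        curve = fit.profiles["dg_FD"]
        assert np.allclose(curve["objective"], fit.objective, atol=1e-15)


class TestUncertaintyPropagation:
    def make_fit(self, family, err=0.05):
        data = noiseless_dataset(family, err=err)
        fit = grid_search(recovery_parameter_space(), data, family, profiles=False)
        return data, fit

    def test_same_seed_reproduces_exactly(self, family):
        data, fit = self.make_fit(family)
        a = propagate_uncertainty(fit, data, n_draws=25, seed=11)
        b = propagate_uncertainty(fit, data, n_draws=25, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_vanishing_errors_give_vanishing_spread(self, family):
        data, fit = self.make_fit(family, err=1e-15)
        out = propagate_uncertainty(fit, data, n_draws=10, seed=1)
        assert (out[["activity_rel_sd", "affinity_rel_sd"]] < 1e-9).all().all()

    def test_spread_grows_with_error_scale(self, family):
        data1, fit1 = self.make_fit(family, err=0.05)
        data2, fit2 = self.make_fit(family, err=0.10)
        s1 = propagate_uncertainty(fit1, data1, n_draws=60, seed=5)
        s2 = propagate_uncertainty(fit2, data2, n_draws=60, seed=5)
        assert (
            s2.loc["A", "affinity_rel_sd"] + s2.loc["B", "affinity_rel_sd"]
            > s1.loc["A", "affinity_rel_sd"] + s1.loc["B", "affinity_rel_sd"]
        )

    def test_requires_at_least_two_draws(self, family):
        data, fit = self.make_fit(family)
        with pytest.raises(ModelError):
            propagate_uncertainty(fit, data, n_draws=1, seed=0)
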