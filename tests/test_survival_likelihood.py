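"""Interval-censored normal likelihood, design matrix, and log-posterior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vialmix.data_model import TreatmentCell
from vialmix.survival import (
    ModelSpec,
    build_design_matrix,
    dataset_log_likelihood,
    design_matrix,
    interval_log_prob,
    log_posterior,
)

TABLE1_BETA = {
    "Intercept": 104.64,
    "SexM": -25.80,
    "SelU": -3.89,
    "SelC": -17.92,
    "CueCs": -7.56,
    "SelC:CueCs": 3.58,
}


class TestIntervalLogProb:
    def test_total_probability_is_one(self):
        assert interval_log_prob(5.0, 2.0, -np.inf, np.inf) == pytest.approx(0.0)

    def test_right_censoring_at_mean_is_half(self):
        assert interval_log_prob(100.0, 10.0, 100.0, np.inf) == pytest.approx(
            math.log(0.5)
        )

    def test_one_sigma_interval(self):
        # P(|Z| <= 1) = erf(1/sqrt(2)) = 0.6826894921; log = -0.3817151463
        assert interval_log_prob(100.0, 10.0, 90.0, 110.0) == pytest.approx(
            math.log(math.erf(1.0 / math.sqrt(2.0))), abs=1e-12
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            interval_log_prob(0.0, 1.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            interval_log_prob(0.0, 0.0, 0.0, 1.0)

    def test_deep_tail_matches_log_cdf(self):
        from scipy.special import log_ndtr

        # an interval far in the upper tail must stay finite and accurate
        got = interval_log_prob(0.0, 1.0, 30.0, np.inf)
        assert got == pytest.approx(float(log_ndtr(-30.0)), rel=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        mu=st.floats(-50, 150),
        sigma=st.floats(0.5, 40),
        cuts=st.lists(st.floats(-200, 400), min_size=1, max_size=8, unique=True),
    )
    def test_partition_exponentiates_to_one(self, mu, sigma, cuts):
        edges = [-np.inf, *sorted(cuts), np.inf]
        total = sum(
            math.exp(interval_log_prob(mu, sigma, lo, hi))
            for lo, hi in zip(edges[:-1], edges[1:])
        )
        assert total == pytest.approx(1.0, abs=1e-10)


class TestDatasetLogLik:
    def spec(self):
        return ModelSpec(
            response="toy", fixed_terms=[], reference_levels={}, random_groups=()
        )

    def test_worked_three_fly_vial(self, toy_vial_factory):
        """One death in (90,100], one in (100,110], one censored at 110,
        mu=100, sigma=10: 2 ln(0.341345) + ln(0.158655) ~ -3.991."""
        rec = toy_vial_factory(boundaries=(90.0, 100.0, 110.0), deaths=(0, 1, 1),
                               n_censored=1)
        ll = dataset_log_likelihood(
            {"Intercept": 100.0}, {"resid": 10.0}, {}, [rec], self.spec()
        )
        assert ll == pytest.approx(-3.991, abs=1e-3)
        from scipy.special import ndtr

        exact = 2 * math.log(ndtr(1.0) - ndtr(0.0)) + math.log(1 - ndtr(1.0))
        assert ll == pytest.approx(exact, rel=1e-12)

    def test_linear_in_counts(self, toy_vial_factory):
        r1 = toy_vial_factory(deaths=(0, 1, 1), n_censored=1)
        r2 = toy_vial_factory(deaths=(0, 2, 2), n_censored=2)
        r2.n_start = 6
        args = ({"Intercept": 97.0}, {"resid": 12.0}, {})
        assert dataset_log_likelihood(*args, [r2], self.spec()) == pytest.approx(
            2 * dataset_log_likelihood(*args, [r1], self.spec())
        )

    def test_equals_per_fly_brute_force(self, small_survival_dataset):
        """The count-weighted likelihood equals the per-fly product on a
        small instance (every fly enumerated individually)."""
        records, _, _ = small_survival_dataset
        subset = records[:3]
        assert sum(r.n_start for r in subset) <= 40
        spec = ModelSpec(
            response="toy",
            fixed_terms=["sex"],
            reference_levels={"sex": "F"},
            random_groups=(),
        )
        beta = {"Intercept": 90.0, "SexM": -15.0}
        ll = dataset_log_likelihood(beta, {"resid": 15.0}, {}, subset, spec)
        brute = 0.0
        for r in subset:
            mu = 90.0 + (-15.0 if r.cell.sex == "M" else 0.0)
            edges = [0.0, *r.boundaries]
            for i, d in enumerate(r.deaths):
                lo = -np.inf if i == 0 else edges[i]
                for _ in range(d):
                    brute += interval_log_prob(mu, 15.0, lo, edges[i + 1])
            for _ in range(r.n_censored):
                brute += interval_log_prob(mu, 15.0, r.boundaries[-1], np.inf)
        assert ll == pytest.approx(brute, abs=1e-9)

    def test_group_effects_must_cover_data(self, toy_vial_factory):
        spec = ModelSpec(
            response="toy", fixed_terms=[], reference_levels={},
            random_groups=("line",),
        )
        with pytest.raises(ValueError, match="line"):
            dataset_log_likelihood(
                {"Intercept": 100.0}, {"resid": 10.0}, {"line": {}},
                [toy_vial_factory()], spec,
            )


class TestDesignMatrix:
    def table1_spec(self):
        return ModelSpec(
            response="starvation",
            fixed_terms=["sex", "regime", "cue", "regime:cue"],
            reference_levels={"sex": "F", "regime": "R", "cue": "none"},
            random_groups=("line", "vial"),
        )

    def test_reference_cell_row(self):
        X, names, _ = design_matrix(
            [TreatmentCell(regime="R", sex="F", cue="none")],
            ["sex", "regime", "cue"],
            {"sex": "F", "regime": "R", "cue": "none"},
        )
        assert names[0] == "Intercept"
        assert X[0].tolist() == [1.0, 0.0, 0.0, 0.0, 0.0]

    def test_table1_linear_predictor_for_male_control_shocked(self):
        """(M, C, cold shock) under the published estimates:
        104.64 - 25.80 - 17.92 - 7.56 + 3.58 = 56.94 h."""
        spec = self.table1_spec()
        X, names, _ = design_matrix(
            [TreatmentCell(regime="C", sex="M", cue="cold_shock")],
            spec.fixed_terms,
            spec.reference_levels,
        )
        beta = np.array([TABLE1_BETA.get(n, 0.0) for n in names])
        assert float(X[0] @ beta) == pytest.approx(56.94)

    def test_dropping_factor_removes_exactly_its_columns(self):
        cells = [TreatmentCell(regime=r, sex=s, cue="none") for r in "RUC" for s in "FM"]
        X_full, names_full, _ = design_matrix(
            cells, ["sex", "regime"], {"sex": "F", "regime": "R"}
        )
        X_red, names_red, _ = design_matrix(cells, ["regime"], {"regime": "R"})
        assert set(names_full) - set(names_red) == {"SexM"}
        assert X_red.shape[1] == X_full.shape[1] - 1

    def test_not_applicable_level_is_an_error(self):
        with pytest.raises(ValueError, match="sex"):
            design_matrix(
                [TreatmentCell(regime="R")], ["sex"], {"sex": "F"}
            )

    def test_age_is_centered(self, small_survival_dataset):
        records, _, _ = small_survival_dataset
        spec = ModelSpec(
            response="toy",
            fixed_terms=["age"],
            reference_levels={},
            random_groups=(),
        )
        X, names = build_design_matrix(records, spec)
        assert names == ["Intercept", "age"]
        assert abs(X[:, 1].mean()) < 1e-9


class TestLogPosterior:
    def test_zero_data_returns_prior_only(self):
        spec = ModelSpec(
            response="toy", fixed_terms=[], reference_levels={}, random_groups=(),
            priors={"beta_scale": 10.0, "sigma_scale": 5.0},
        )
        lp = log_posterior(
            {"beta": {"Intercept": 2.0}, "sigma_resid": 3.0}, [], spec
        )
        assert lp == pytest.approx(-0.5 * (2.0 / 10.0) ** 2 - 0.5 * (3.0 / 5.0) ** 2)

    def test_matches_sum_of_parts_on_two_vial_toy(self, toy_vial_factory):
        spec = ModelSpec(
            response="toy", fixed_terms=[], reference_levels={},
            random_groups=("line",),
            priors={"beta_scale": 100.0, "sigma_scale": 20.0},
        )
        recs = [toy_vial_factory(vial_id="a", line_id=1),
                toy_vial_factory(vial_id="b", line_id=2)]
        params = {
            "beta": {"Intercept": 100.0},
            "sigma_resid": 10.0,
            "sigma_line": 2.0,
            "u_line": {1: 1.0, 2: -0.5},
        }
        lp = log_posterior(params, recs, spec)
        ll = dataset_log_likelihood(
            params["beta"], {"resid": 10.0}, {"line": params["u_line"]}, recs, spec
        )
        prior = (
            -0.5 * (100.0 / 100.0) ** 2
            - 0.5 * (10.0 / 20.0) ** 2
            - 0.5 * (2.0 / 20.0) ** 2
            + sum(
                -0.5 * (u / 2.0) ** 2 - math.log(2.0)
                for u in params["u_line"].values()
            )
        )
        assert lp == pytest.approx(ll + prior, rel=1e-12)

    def test_zero_line_scale_with_zero_effects_matches_no_line_model(
        self, toy_vial_factory
    ):
        priors = {"beta_scale": 100.0, "sigma_scale": 20.0}
        spec_line = ModelSpec(
            response="toy", fixed_terms=[], reference_levels={},
            random_groups=("line",), priors=priors,
        )
        spec_none = ModelSpec(
            response="toy", fixed_terms=[], reference_levels={},
            random_groups=(), priors=priors,
        )
        recs = [toy_vial_factory()]
        base = {"beta": {"Intercept": 100.0}, "sigma_resid": 10.0}
        lp_line = log_posterior(
            {**base, "sigma_line": 0.0, "u_line": {1: 0.0}}, recs, spec_line
        )
        lp_none = log_posterior(base, recs, spec_none)
        assert lp_line == pytest.approx(lp_none)

    def test_nonfinite_named(self):
        spec = ModelSpec(
            response="toy", fixed_terms=[], reference_levels={}, random_groups=()
        )
        with pytest.raises(ValueError, match="Intercept"):
            log_posterior(
                {"beta": {"Intercept": math.inf}, "sigma_resid": 1.0}, [], spec
            )
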