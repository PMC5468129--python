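"""Sampler correctness: grid-oracle cross-checks, determinism, invariances."""

import numpy as np
import pytest

from vialmix.data_model import VialIntervalRecord
from vialmix.sampler import PosteriorDraws, summarize
from vialmix.simulate import ScheduleSpec, SurvivalSimParams, simulate_survival_experiment
from vialmix.survival import ModelSpec, fit_mcmc, grid_posterior_oracle


def toy_records(seed=3, n_vials=12):
    params = SurvivalSimParams(
        beta={"Intercept": 100.0},
        sigma_resid=12.0,
        sigma_line=0.0,
        sigma_vial=0.0,
        vials_per_cell=1,
        flies_per_vial=(10, 12),
        schedule={"F": ScheduleSpec(6, 12, 120), "M": ScheduleSpec(6, 12, 120)},
        seed=seed,
    )
    records, _ = simulate_survival_experiment(params)
    return records[:n_vials]


NO_RE_SPEC = ModelSpec(
    response="toy", fixed_terms=[], reference_levels={}, random_groups=()
)


def mcse(summary, draws, name):
    ess = summary.table.loc[name, "ess"]
    if not np.isfinite(ess):
        ess = draws.draws.shape[0] * draws.draws.shape[1] / 10
    return summary.table.loc[name, "sd"] / np.sqrt(max(ess, 4.0))


class TestGridOracle:
    def test_symmetric_toy_mean_at_symmetry_point(self, toy_vial_factory):
        # one death on each side of 100 with symmetric boundaries
        rec = toy_vial_factory(
            boundaries=(90.0, 100.0, 110.0, 200.0), deaths=(0, 1, 1, 0), n_censored=0
        )
        out = grid_posterior_oracle(
            [rec],
            ModelSpec(
                response="toy", fixed_terms=[], reference_levels={},
                random_groups=(), priors={"beta_scale": 1e6},
            ),
            free={"Intercept": (60.0, 140.0)},
            fixed_sigma_resid=10.0,
            n_grid=401,
        )
        assert out["Intercept"]["mean"] == pytest.approx(100.0, abs=0.05)

    def test_grid_refinement_converges(self):
        records = toy_records()
        coarse = grid_posterior_oracle(
            records, NO_RE_SPEC, free={"Intercept": (80, 120)},
            fixed_sigma_resid=12.0, n_grid=101,
        )
        fine = grid_posterior_oracle(
            records, NO_RE_SPEC, free={"Intercept": (80, 120)},
            fixed_sigma_resid=12.0, n_grid=201,
        )
        assert coarse["Intercept"]["mean"] == pytest.approx(
            fine["Intercept"]["mean"], abs=1e-3
        )
        assert coarse["Intercept"]["sd"] == pytest.approx(
            fine["Intercept"]["sd"], abs=1e-3
        )

    def test_rejects_more_than_two_free(self):
        with pytest.raises(ValueError):
            grid_posterior_oracle(
                toy_records(), NO_RE_SPEC,
                free={"a": (0, 1), "b": (0, 1), "c": (0, 1)},
            )


class TestMcmcAgainstOracle:
    def test_one_parameter_toy(self):
        records = toy_records()
        oracle = grid_posterior_oracle(
            records, NO_RE_SPEC, free={"Intercept": (80, 120)},
            fixed_sigma_resid=12.0, n_grid=401,
        )
        draws = fit_mcmc(
            records, NO_RE_SPEC, chains=2, warmup=400, iterations=1200,
            seed=5, fixed={"sigma_resid": 12.0},
        )
        s = summarize(draws)
        err = abs(s.table.loc["Intercept", "mean"] - oracle["Intercept"]["mean"])
        assert err < 3 * mcse(s, draws, "Intercept")

    def test_two_parameter_toy(self):
        records = toy_records()
        oracle = grid_posterior_oracle(
            records, NO_RE_SPEC,
            free={"Intercept": (80, 120), "sigma_resid": (4, 30)}, n_grid=161,
        )
        draws = fit_mcmc(
            records, NO_RE_SPEC, chains=2, warmup=500, iterations=1500, seed=6
        )
        s = summarize(draws)
        for name in ("Intercept", "sigma_resid"):
            err = abs(s.table.loc[name, "mean"] - oracle[name]["mean"])
            assert err < 3 * mcse(s, draws, name), name


class TestSamplerProperties:
    def test_bit_reproducible_and_seed_stable(self):
        records = toy_records()
        d1 = fit_mcmc(records, NO_RE_SPEC, chains=2, warmup=300, iterations=400, seed=9)
        d2 = fit_mcmc(records, NO_RE_SPEC, chains=2, warmup=300, iterations=400, seed=9)
        assert np.array_equal(d1.draws, d2.draws)
        d3 = fit_mcmc(records, NO_RE_SPEC, chains=2, warmup=300, iterations=400, seed=10)
        s1, s3 = summarize(d1), summarize(d3)
        err = abs(
            s1.table.loc["Intercept", "mean"] - s3.table.loc["Intercept", "mean"]
        )
        assert err < 3 * (mcse(s1, d1, "Intercept") + mcse(s3, d3, "Intercept"))

    def test_shifting_boundaries_shifts_intercept(self):
        """Adding c hours to every inspection time moves the intercept by
        about c and leaves the sex contrast unchanged."""
        params = SurvivalSimParams(
            beta={"Intercept": 80.0, "SexM": -10.0},
            sigma_resid=10.0, sigma_line=0.0, sigma_vial=0.0,
            vials_per_cell=2, flies_per_vial=(12, 14),
            schedule={"F": ScheduleSpec(6, 12, 120), "M": ScheduleSpec(6, 12, 120)},
            seed=11,
        )
        records, _ = simulate_survival_experiment(params)
        spec = ModelSpec(
            response="toy", fixed_terms=["sex"], reference_levels={"sex": "F"},
            random_groups=(),
        )
        c = 25.0
        shifted = [
            VialIntervalRecord(
                vial_id=r.vial_id, line_id=r.line_id, cell=r.cell,
                start_age_h=r.start_age_h, n_start=r.n_start,
                boundaries=tuple(b + c for b in r.boundaries),
                deaths=r.deaths, n_censored=r.n_censored,
            )
            for r in records
        ]
        kw = dict(chains=2, warmup=400, iterations=800)
        s0 = summarize(fit_mcmc(records, spec, seed=3, **kw))
        s1 = summarize(fit_mcmc(shifted, spec, seed=3, **kw))
        shift = s1.table.loc["Intercept", "mean"] - s0.table.loc["Intercept", "mean"]
        assert shift == pytest.approx(c, abs=1.0)
        assert s1.table.loc["SexM", "mean"] == pytest.approx(
            s0.table.loc["SexM", "mean"], abs=1.0
        )

    def test_single_chain_diagnostics_unavailable(self):
        records = toy_records()
        with pytest.warns(RuntimeWarning, match="chains"):
            draws = fit_mcmc(
                records, NO_RE_SPEC, chains=1, warmup=200, iterations=200, seed=1
            )
        s = summarize(draws)
        assert not s.diagnostics_available
        assert np.isnan(s.table.loc["Intercept", "rhat"])


class TestSummarize:
    def make_draws(self, arr):
        arr = np.asarray(arr, dtype=float)[None, :, None]
        arr = np.repeat(arr, 2, axis=0)
        return PosteriorDraws(draws=arr, names=["x"], seed=0, settings={})

    def test_constant_draws(self):
        s = summarize(self.make_draws([3.0] * 50), diagnostics=False)
        assert s.table.loc["x", "mean"] == 3.0
        assert s.table.loc["x", "ci_low"] == s.table.loc["x", "ci_high"] == 3.0

    def test_symmetric_draws_not_significant(self):
        s = summarize(self.make_draws([-1.0, 1.0] * 50), diagnostics=False)
        assert s.table.loc["x", "mean"] == pytest.approx(0.0)
        assert not bool(s.table.loc["x", "significant"])
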