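"""Fecundity NB GLMM, egg-to-adult binomial GLMM, physiology Gaussian LMM."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from vialmix.data_model import TreatmentCell, VialBinomialRecord
from vialmix.glmm import (
    eclosion_binomial_from_vials,
    fit_binomial_glmm,
    fit_fecundity_models,
    fit_gaussian_lmm,
    fit_negbin_glmm,
)
from vialmix.pipeline import default_eclosion_spec, default_fecundity_spec
from vialmix.simulate import (
    BinomialSimParams,
    CountSimParams,
    paperlike_fecundity_params,
    simulate_eclosion,
    simulate_fecundity,
    simulate_line_traits,
)
from vialmix.survival import ModelSpec

LMM_SPEC = ModelSpec(
    response="dry_weight",
    fixed_terms=["regime", "sex", "regime:sex"],
    reference_levels={"regime": "C", "sex": "F"},
    random_groups=("line",),
)


class TestNegBin:
    def test_intercept_recovery_at_published_effect_sizes(self):
        """A dataset generated at the early-fecundity effect table must
        recover the log-intercept 2.97 (implied mean ~19.5 eggs)."""
        recs, _ = simulate_fecundity(paperlike_fecundity_params("early", seed=12))
        fit = fit_negbin_glmm(
            recs, default_fecundity_spec(), chains=2, warmup=500, iterations=900,
            seed=13,
        )
        row = fit.terms.loc["Intercept"]
        assert row["ci_low"] < 2.97 < row["ci_high"]
        assert math.exp(row["mean"]) == pytest.approx(math.exp(2.97), rel=0.15)
        assert fit.dispersion == pytest.approx(5.0, rel=0.5)

    def test_poisson_limit_dispersion_grows(self):
        recs, _ = simulate_fecundity(
            CountSimParams(
                beta={"Intercept": 3.0}, dispersion=1e7, sigma_line=0.0,
                females_per_cell=25, seed=5,
            )
        )
        fit = fit_negbin_glmm(
            recs, default_fecundity_spec(), chains=2, warmup=400, iterations=500,
            seed=6,
        )
        assert fit.dispersion > 30.0
        import statsmodels.api as sm

        from vialmix.survival import build_design_matrix

        X, names = build_design_matrix(recs, default_fecundity_spec())
        y = np.array([r.eggs for r in recs])
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        for i, name in enumerate(names):
            assert fit.terms.loc[name, "mean"] == pytest.approx(
                pois.params[i], abs=0.06
            ), name

    def test_record_order_invariance(self):
        recs, _ = simulate_fecundity(paperlike_fecundity_params("early", seed=3))
        fit_a = fit_negbin_glmm(
            recs, default_fecundity_spec(), chains=2, warmup=400, iterations=600,
            seed=9,
        )
        rng = np.random.default_rng(0)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        fit_b = fit_negbin_glmm(
            shuffled, default_fecundity_spec(), chains=2, warmup=400,
            iterations=600, seed=9,
        )
        for name in fit_a.terms.index:
            sd = max(fit_a.terms.loc[name, "sd"], 1e-3)
            assert abs(
                fit_a.terms.loc[name, "mean"] - fit_b.terms.loc[name, "mean"]
            ) < 0.5 * sd, name

    def test_early_and_midlife_fit_separately(self):
        early, _ = simulate_fecundity(paperlike_fecundity_params("early", seed=1))
        mid_params = paperlike_fecundity_params("midlife", seed=2)
        mid, _ = simulate_fecundity(
            mid_params,
            design=[
                (TreatmentCell(regime=r, sex="F", cue=c, starv=s), "midlife_14d")
                for r in "RUC"
                for c in ("none", "cold_shock")
                for s in ("none", "starved")
            ],
        )
        fits = fit_fecundity_models(
            early + mid, default_fecundity_spec(), chains=2, warmup=300,
            iterations=400, seed=4,
        )
        assert set(fits) == {"early", "midlife"}
        assert fits["early"].terms.loc["Intercept", "mean"] > fits[
            "midlife"
        ].terms.loc["Intercept", "mean"]

    def test_all_zero_cell_warns_but_fits(self):
        recs, _ = simulate_fecundity(
            CountSimParams(
                beta={"Intercept": 2.0, "CueCs": -1.0}, dispersion=5.0,
                sigma_line=0.0, females_per_cell=3, seed=7,
            )
        )
        for r in recs:
            if r.cell.cue == "cold_shock":
                r.eggs = 0
        with pytest.warns(RuntimeWarning, match="all-zero"):
            fit = fit_negbin_glmm(
                recs, default_fecundity_spec(), chains=2, warmup=150,
                iterations=150, seed=2,
            )
        assert np.isfinite(fit.terms["mean"]).all()


class TestBinomial:
    def test_symmetric_intercept_recovers_half(self):
        recs, _ = simulate_eclosion(
            BinomialSimParams(
                beta={"Intercept": 0.0}, sigma_line=0.0, vials_per_cell=10,
                eggs_per_vial=(8, 12), seed=3,
            )
        )
        fit = fit_binomial_glmm(
            recs, default_eclosion_spec(), chains=2, warmup=400, iterations=600,
            seed=4,
        )
        row = fit.terms.loc["Intercept"]
        assert row["ci_low"] < 0.0 < row["ci_high"]
        p_hat = 1.0 / (1.0 + math.exp(-row["mean"]))
        assert p_hat == pytest.approx(0.5, abs=0.05)

    def test_all_success_separation_flagged_and_finite(self):
        recs = [
            VialBinomialRecord(
                vial_id=f"v{i}", line_id=1 + i % 6,
                cell=TreatmentCell(regime="R", starv="none"),
                n_success=8, n_total=8,
            )
            for i in range(24)
        ]
        spec = ModelSpec(
            response="eclosion", fixed_terms=[], reference_levels={},
            random_groups=("line",),
        )
        fit = fit_binomial_glmm(recs, spec, chains=2, warmup=300, iterations=300,
                                seed=1)
        assert any("separation" in n for n in fit.notes)
        est = fit.terms.loc["Intercept", "mean"]
        assert np.isfinite(est) and 1.0 / (1.0 + math.exp(-est)) > 0.95

    def test_zero_trial_vials_excluded(self, caplog):
        recs, _ = simulate_eclosion(BinomialSimParams(beta={"Intercept": 1.0}, seed=8))
        recs[0].n_total = 0
        recs[0].n_success = 0
        import logging

        with caplog.at_level(logging.INFO, logger="vialmix.glmm"):
            fit_binomial_glmm(
                recs, default_eclosion_spec(), chains=2, warmup=100,
                iterations=100, seed=2,
            )
        assert any("zero-trial" in m for m in caplog.messages)

    def test_from_devtime_vials(self, toy_vial_factory):
        rec = toy_vial_factory(deaths=(2, 3, 1), n_censored=2)
        out = eclosion_binomial_from_vials([rec])
        assert out[0].n_success == 6 and out[0].n_total == 8


class TestGaussianLmm:
    MEANS = {
        ("R", "F"): 1.2, ("R", "M"): 0.9, ("U", "F"): 1.1,
        ("U", "M"): 0.85, ("C", "F"): 1.0, ("C", "M"): 0.8,
    }

    def test_zero_noise_reproduces_cell_means_exactly(self):
        recs = simulate_line_traits(self.MEANS, 0.0, seed=1)
        fit = fit_gaussian_lmm(recs, LMM_SPEC)
        assert fit.terms.loc["Intercept", "mean"] == pytest.approx(1.0, abs=1e-8)
        assert fit.terms.loc["SelR", "mean"] == pytest.approx(0.2, abs=1e-8)
        assert fit.terms.loc["SexM", "mean"] == pytest.approx(-0.2, abs=1e-8)
        assert fit.terms.loc["SelR:SexM", "mean"] == pytest.approx(-0.1, abs=1e-8)

    def test_matches_ols_when_no_line_variance(self):
        recs = simulate_line_traits(self.MEANS, 0.0, seed=2, sigma_within=0.05)
        fit = fit_gaussian_lmm(recs, LMM_SPEC)
        import statsmodels.api as sm

        from vialmix.survival import design_matrix

        cells = [TreatmentCell(regime=r.regime, sex=r.sex) for r in recs]
        X, names, _ = design_matrix(
            cells, LMM_SPEC.fixed_terms, LMM_SPEC.reference_levels
        )
        ols = sm.OLS([r.value for r in recs], X).fit()
        for i, name in enumerate(names):
            assert fit.terms.loc[name, "mean"] == pytest.approx(
                ols.params[i], abs=0.02
            ), name

    def test_variance_decomposition_on_balanced_data(self):
        recs = simulate_line_traits(
            self.MEANS, 0.3, seed=3, sigma_within=0.2, n_lines_per_regime=60
        )
        fit = fit_gaussian_lmm(recs, LMM_SPEC)
        assert fit.sigma_line == pytest.approx(0.3, abs=0.06)
        assert fit.sigma_resid == pytest.approx(0.2, abs=0.04)

    def test_refuses_fewer_than_two_lines_per_regime(self):
        recs = simulate_line_traits(self.MEANS, 0.1, seed=4, n_lines_per_regime=1)
        with pytest.raises(ValueError, match="2 lines"):
            fit_gaussian_lmm(recs, LMM_SPEC)

    def test_agrees_with_lme4_reference(self, tmp_path):
        """Independent cross-check: lme4's lmer on the same balanced data
        must give the same fixed effects and similar variance components."""
        recs = simulate_line_traits(
            self.MEANS, 0.08, seed=5, sigma_within=0.05
        )
        fit = fit_gaussian_lmm(recs, LMM_SPEC)
        df = pd.DataFrame(
            {
                "value": [r.value for r in recs],
                "regime": [r.regime for r in recs],
                "sex": [r.sex for r in recs],
                "line": [r.line_id for r in recs],
            }
        )
        csv = tmp_path / "traits.csv"
        df.to_csv(csv, index=False)
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$regime <- factor(d$regime, levels=c("C","R","U"))
            d$sex <- factor(d$sex, levels=c("F","M"))
            m <- lmer(value ~ regime*sex + (1|line), data=d, REML=TRUE)
            fe <- fixef(m)
            vc <- as.data.frame(VarCorr(m))
            cat(paste(fe, collapse=","), "\\n")
            cat(paste(vc$sdcor, collapse=","), "\\n")
            """
        )
        res = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=180
        )
        assert res.returncode == 0, res.stderr
        out_lines = [l for l in res.stdout.strip().splitlines() if l.strip()]
        fe = [float(x) for x in out_lines[0].split(",")]
        sdcor = [float(x) for x in out_lines[1].split(",")]
        # lmer order: (Intercept), regimeR, regimeU, sexM, regimeR:sexM, regimeU:sexM
        ours = fit.terms["mean"]
        for got, name in zip(
            fe, ["Intercept", "SelR", "SelU", "SexM", "SelR:SexM", "SelU:SexM"]
        ):
            assert ours.loc[name] == pytest.approx(got, abs=1e-4), name
        assert fit.sigma_line == pytest.approx(sdcor[0], abs=0.02)
        assert fit.sigma_resid == pytest.approx(sdcor[1], abs=0.02)
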