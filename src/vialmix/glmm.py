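"""Remaining estimation stages: fecundity, egg-to-adult survival, physiology.

* Fecundity: Bayesian negative-binomial mixed regression on the log
  scale, mean-shape parameterization (variance = mu + mu^2/shape), with a
  replicate-line random intercept. Early (4/7 d) and mid-life (14 d) egg
  counts are fitted as separate models; the reference cell is the benign
  control regime without cold shock or starvation.
* Egg-to-adult survival: logit-link binomial mixed model over per-vial
  (eclosed, eggs) counts, line random intercept (vial optional).
* Physiology traits: Gaussian linear mixed model with one observation per
  line x sex, so the line intercept is what links a line's female and
  male measurements. Estimated by REML via statsmodels MixedLM.

The two Bayesian fits reuse the package's blocked adaptive MCMC backend,
so their credible intervals are exact posterior quantiles rather than
Wald approximations; the Gaussian stage is classical REML.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special as sc

from .data_model import FecundityRecord, LineTraitRecord, VialBinomialRecord
from .sampler import AuxSpec, GroupSpec, MixedModelMCMC, PosteriorDraws, summarize
from .survival import ModelSpec, build_design_matrix, design_matrix
from .data_model import TreatmentCell

__all__ = [
    "CountModelSummary",
    "LmmSummary",
    "fit_negbin_glmm",
    "fit_binomial_glmm",
    "fit_fecundity_models",
    "fit_gaussian_lmm",
    "eclosion_binomial_from_vials",
]

log = logging.getLogger(__name__)


@dataclass
class CountModelSummary:
    """Per-term estimates on the log (or logit) scale with 95% CIs and
    significance flags, plus dispersion and random-effect SD estimates."""

    terms: pd.DataFrame  # index term: mean, ci_low, ci_high, significant, rhat, ess
    dispersion: float | None
    sigma_line: float
    backend: str
    converged: bool
    draws: PosteriorDraws | None = None
    notes: tuple[str, ...] = ()

    def __getitem__(self, term: str) -> pd.Series:
        return self.terms.loc[term]


@dataclass
class LmmSummary:
    """Gaussian LMM estimates: per-term mean and 95% CI, residual SD and
    grouping SD."""

    terms: pd.DataFrame
    sigma_resid: float
    sigma_line: float
    backend: str = "statsmodels-MixedLM(REML)"

    def __getitem__(self, term: str) -> pd.Series:
        return self.terms.loc[term]


# ---------------------------------------------------------------------------
# Negative-binomial mixed regression (fecundity)
# ---------------------------------------------------------------------------


def _nb_row_loglik(y: np.ndarray):
    def row_loglik(eta: np.ndarray, aux: Mapping[str, float]) -> np.ndarray:
        k = aux["dispersion"]
        m = np.exp(np.clip(eta, -30.0, 30.0))
        return (
            sc.gammaln(y + k)
            - sc.gammaln(k)
            - sc.gammaln(y + 1.0)
            + k * (np.log(k) - np.log(k + m))
            + y * (eta - np.log(k + m))
        )

    return row_loglik


def _nb_row_curvature(y: np.ndarray):
    """First/second derivatives of the NB log-likelihood in eta (concave),
    backing the Laplace proposal for the (beta, z) block."""

    def curvature(eta: np.ndarray, aux: Mapping[str, float]):
        k = aux["dispersion"]
        m = np.exp(np.clip(eta, -30.0, 30.0))
        frac = m / (k + m)
        d1 = y - (y + k) * frac
        d2 = -(y + k) * k * frac / (k + m)
        return d1, d2

    return curvature


def _dispersion_log_prior(ls: float) -> float:
    # half-normal(0, 1) on 1/shape, so shape -> infinity (the Poisson
    # limit) stays reachable when the data demand it; includes Jacobian
    inv = math.exp(-ls)
    return -0.5 * inv**2 - ls


def _mcmc_count_summary(
    draws: PosteriorDraws, term_names: Sequence[str], extra: Sequence[str]
) -> tuple[pd.DataFrame, dict]:
    summ = summarize(draws, params=list(term_names) + list(extra))
    table = summ.table.loc[list(term_names)]
    other = {name: float(summ.table.loc[name, "mean"]) for name in extra}
    return table, {"converged": summ.converged, **other}


def fit_negbin_glmm(
    records: Sequence[FecundityRecord],
    spec: ModelSpec,
    chains: int = 4,
    warmup: int = 800,
    iterations: int = 800,
    seed: int = 0,
) -> CountModelSummary:
    """Bayesian NB mixed model of egg counts with a line random intercept.

    All-zero treatment cells are tolerated with a warning (the log link
    keeps the likelihood finite); the estimates are posterior means with
    equal-tailed 95% credible intervals.
    """
    if "line" not in spec.random_groups:
        raise ValueError("spec must include the line random intercept")
    y = np.array([float(r.eggs) for r in records])
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("egg counts must be non-negative integers")
    X, names = build_design_matrix(records, spec)
    cell_keys = {tuple(row) for row in X}
    for key in cell_keys:
        mask = np.all(X == np.array(key), axis=1)
        if np.all(y[mask] == 0):
            warnings.warn(
                "a treatment cell has all-zero egg counts; fit proceeds",
                RuntimeWarning,
                stacklevel=2,
            )
            break
    line_ids = sorted({r.line_id for r in records})
    line_index = {l: i for i, l in enumerate(line_ids)}
    obs_line = np.array([line_index[r.line_id] for r in records])

    beta0, *_ = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)
    beta_scale = float(spec.priors.get("beta_scale", 5.0))
    sigma_scale = float(spec.priors.get("sigma_scale", 1.0))
    mcmc = MixedModelMCMC(
        X_rows=X,
        row_loglik=_nb_row_loglik(y),
        beta_names=names,
        beta_prior_scale=np.full(len(names), beta_scale),
        beta_init=beta0,
        groups=[
            GroupSpec(
                name="line",
                obs_index=obs_line,
                n_groups=len(line_ids),
                labels=[str(l) for l in line_ids],
                sigma_prior_scale=sigma_scale,
                sigma_init=0.1,
            )
        ],
        auxes=[AuxSpec(name="dispersion", init=5.0, log_prior=_dispersion_log_prior)],
        row_curvature=_nb_row_curvature(y),
    )
    draws = mcmc.run(chains=chains, warmup=warmup, iterations=iterations, seed=seed)
    table, meta = _mcmc_count_summary(draws, names, ["dispersion", "sigma_line"])
    return CountModelSummary(
        terms=table,
        dispersion=meta["dispersion"],
        sigma_line=meta["sigma_line"],
        backend="vialmix-MCMC(NB)",
        converged=meta["converged"],
        draws=draws,
    )


def fit_fecundity_models(
    records: Sequence[FecundityRecord], spec: ModelSpec, **kw
) -> dict[str, CountModelSummary]:
    """Separate early (4/7 d, pooled) and mid-life (14 d) fecundity fits."""
    early = [r for r in records if r.age_class in ("early_4d", "early_7d")]
    mid = [r for r in records if r.age_class == "midlife_14d"]
    out = {}
    if early:
        out["early"] = fit_negbin_glmm(early, spec, **kw)
    if mid:
        out["midlife"] = fit_negbin_glmm(mid, spec, **kw)
    return out


# ---------------------------------------------------------------------------
# Binomial mixed regression (egg-to-adult survival)
# ---------------------------------------------------------------------------


def eclosion_binomial_from_vials(records) -> list[VialBinomialRecord]:
    """Collapse developmental-time vials to (eclosed, eggs) counts: the
    interval deaths are eclosions; censored individuals never eclosed."""
    return [
        VialBinomialRecord(
            vial_id=r.vial_id,
            line_id=r.line_id,
            cell=r.cell,
            n_success=int(sum(r.deaths)),
            n_total=r.n_start,
        )
        for r in records
    ]


def fit_binomial_glmm(
    records: Sequence[VialBinomialRecord],
    spec: ModelSpec,
    chains: int = 4,
    warmup: int = 800,
    iterations: int = 800,
    seed: int = 0,
) -> CountModelSummary:
    """Bayesian logit-link binomial mixed model of per-vial survival.

    Zero-trial vials are excluded with a log entry. Complete separation
    (e.g. all-success data) is handled by the normal prior on the
    coefficients and flagged in ``notes``.
    """
    notes: list[str] = []
    kept = []
    for r in records:
        if r.n_total == 0:
            log.info("excluding zero-trial vial %s", r.vial_id)
            continue
        if r.n_success > r.n_total:
            raise ValueError(f"vial {r.vial_id}: successes exceed trials")
        kept.append(r)
    if not kept:
        raise ValueError("no vials with trials > 0")
    succ = np.array([float(r.n_success) for r in kept])
    tot = np.array([float(r.n_total) for r in kept])
    if np.all(succ == tot) or np.all(succ == 0):
        notes.append("complete separation: estimates shrink to the prior scale")
    X, names = build_design_matrix(kept, spec)
    line_ids = sorted({r.line_id for r in kept})
    line_index = {l: i for i, l in enumerate(line_ids)}
    obs_line = np.array([line_index[r.line_id] for r in kept])

    def row_loglik(eta: np.ndarray, aux: Mapping[str, float]) -> np.ndarray:
        return succ * eta - tot * np.logaddexp(0.0, eta)

    def row_curvature(eta: np.ndarray, aux: Mapping[str, float]):
        pr = sc.expit(eta)
        return succ - tot * pr, -tot * pr * (1.0 - pr)

    p_emp = np.clip((succ + 0.5) / (tot + 1.0), 1e-3, 1 - 1e-3)
    beta0, *_ = np.linalg.lstsq(X, np.log(p_emp / (1 - p_emp)), rcond=None)
    beta_scale = float(spec.priors.get("beta_scale", 5.0))
    sigma_scale = float(spec.priors.get("sigma_scale", 1.0))
    groups = [
        GroupSpec(
            name="line",
            obs_index=obs_line,
            n_groups=len(line_ids),
            labels=[str(l) for l in line_ids],
            sigma_prior_scale=sigma_scale,
            sigma_init=0.1,
        )
    ]
    if "vial" in spec.random_groups:
        groups.append(
            GroupSpec(
                name="vial",
                obs_index=np.arange(len(kept)),
                n_groups=len(kept),
                labels=[r.vial_id for r in kept],
                sigma_prior_scale=sigma_scale,
                sigma_init=0.1,
            )
        )
    mcmc = MixedModelMCMC(
        X_rows=X,
        row_loglik=row_loglik,
        beta_names=names,
        beta_prior_scale=np.full(len(names), beta_scale),
        beta_init=beta0,
        groups=groups,
        row_curvature=row_curvature,
    )
    draws = mcmc.run(chains=chains, warmup=warmup, iterations=iterations, seed=seed)
    table, meta = _mcmc_count_summary(draws, names, ["sigma_line"])
    return CountModelSummary(
        terms=table,
        dispersion=None,
        sigma_line=meta["sigma_line"],
        backend="vialmix-MCMC(binomial)",
        converged=meta["converged"],
        draws=draws,
        notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# Gaussian LMM (physiology traits)
# ---------------------------------------------------------------------------


def fit_gaussian_lmm(
    records: Sequence[LineTraitRecord], spec: ModelSpec
) -> LmmSummary:
    """REML linear mixed model for one-value-per-line-per-sex traits.

    Because each line contributes a single value per sex, the line random
    intercept is identified by the covariance between a line's two sex
    measurements. Refuses to fit with fewer than 2 lines per regime.
    """
    per_regime: dict[str, set[int]] = {}
    for r in records:
        per_regime.setdefault(r.regime, set()).add(r.line_id)
    if any(len(v) < 2 for v in per_regime.values()):
        raise ValueError("need at least 2 lines per regime to fit")
    cells = [TreatmentCell(regime=r.regime, sex=r.sex) for r in records]
    X, names, _ = design_matrix(cells, spec.fixed_terms, spec.reference_levels)
    y = np.array([float(r.value) for r in records])
    groups = np.array([r.line_id for r in records])

    from statsmodels.regression.mixed_linear_model import MixedLM

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(endog=y, exog=X, groups=groups)
        res = model.fit(reml=True)
    k = len(names)
    ci = res.conf_int()[:k]
    table = pd.DataFrame(
        {
            "mean": np.asarray(res.fe_params)[:k],
            "ci_low": np.asarray(ci)[:, 0],
            "ci_high": np.asarray(ci)[:, 1],
        },
        index=names,
    )
    table["significant"] = (table["ci_low"] > 0) | (table["ci_high"] < 0)
    table.index.name = "term"
    return LmmSummary(
        terms=table,
        sigma_resid=float(np.sqrt(res.scale)),
        sigma_line=float(np.sqrt(np.asarray(res.cov_re)[0, 0])),
    )
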