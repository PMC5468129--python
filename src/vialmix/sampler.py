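"""Blocked adaptive Metropolis-within-Gibbs for hierarchical models.

The models in this package share one shape: a linear predictor
``eta = X beta + sum_g sigma_g z_g[group(row)]`` feeding a row-wise
log-likelihood (interval-censored normal, negative binomial, binomial),
with standard-normal non-centered group deviates ``z_g`` and half-normal
priors on the group scales. The sampler updates, per sweep:

* ``beta`` jointly, with a Haario-style adapted proposal covariance;
* each group's ``z_g`` site-wise but fully vectorized (the groups'
  conditional likelihoods factorize over rows), with per-site scales
  adapted toward 0.44 acceptance;
* each ``log sigma_g`` and each auxiliary parameter (residual SD,
  dispersion) by scalar random-walk steps.

All adaptation happens during warmup only, so the sampling phase is a
fixed Markov kernel. Chains are seeded independently from one
``SeedSequence``; results are bit-reproducible for a given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupSpec",
    "AuxSpec",
    "MixedModelMCMC",
    "PosteriorDraws",
    "PosteriorSummary",
    "summarize",
]

_RHAT_GATE = 1.05
_ESS_GATE = 100.0


@dataclass
class GroupSpec:
    """One normal random-intercept grouping (e.g. line, vial)."""

    name: str
    obs_index: np.ndarray  # (n_rows,) int: group index per likelihood row
    n_groups: int
    labels: Sequence[str]
    sigma_prior_scale: float
    sigma_init: float
    sigma_fixed: float | None = None  # if not None, sigma is held fixed


@dataclass
class AuxSpec:
    """A positive-scale auxiliary parameter sampled on the log scale.

    ``log_prior`` receives the *log* of the parameter and must include the
    Jacobian of the log transform.
    """

    name: str
    init: float
    log_prior: Callable[[float], float]
    fixed: float | None = None


@dataclass
class PosteriorDraws:
    """MCMC output: draws indexed by (chain, iteration, parameter)."""

    draws: np.ndarray
    names: list[str]
    seed: int
    settings: dict
    accept_rates: dict = field(default_factory=dict)

    def get(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.names.index(name)]

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]


def _half_normal_logpdf(x: float, scale: float) -> float:
    if x < 0:
        return -np.inf
    return -0.5 * (x / scale) ** 2


class MixedModelMCMC:
    """Generic sampler over ``eta = X beta + sum_g sigma_g z_g``.

    Parameters
    ----------
    X_rows : (n_rows, p) design matrix, already expanded to likelihood rows.
    row_loglik : callable ``(eta, aux) -> per-row log-likelihood`` where
        ``aux`` maps auxiliary-parameter names to values.
    groups, auxes : structure and priors of the random parts.
    beta_prior_scale : per-coefficient normal prior SD.
    beta_init : starting point (jittered per chain).
    """

    def __init__(
        self,
        X_rows: np.ndarray,
        row_loglik: Callable[[np.ndarray, Mapping[str, float]], np.ndarray],
        beta_names: Sequence[str],
        beta_prior_scale: np.ndarray,
        beta_init: np.ndarray,
        groups: Sequence[GroupSpec] = (),
        auxes: Sequence[AuxSpec] = (),
        row_curvature: Callable[
            [np.ndarray, Mapping[str, float]], tuple[np.ndarray, np.ndarray]
        ]
        | None = None,
    ) -> None:
        self.X = np.asarray(X_rows, dtype=float)
        self.row_loglik = row_loglik
        self.row_curvature = row_curvature
        self.beta_names = list(beta_names)
        self.p = self.X.shape[1]
        self.beta_prior_scale = np.broadcast_to(
            np.asarray(beta_prior_scale, dtype=float), (self.p,)
        ).copy()
        self.beta_init = np.asarray(beta_init, dtype=float)
        self.groups = list(groups)
        self.auxes = list(auxes)
        if row_curvature is not None:
            # dense [X | group indicators] design for the Laplace block
            n = self.X.shape[0]
            cols = [self.X]
            for g in self.groups:
                ind = np.zeros((n, g.n_groups))
                ind[np.arange(n), g.obs_index] = 1.0
                cols.append(ind)
            self._Xfull = np.hstack(cols)

    # -- parameter bookkeeping ------------------------------------------------

    def parameter_names(self) -> list[str]:
        names = list(self.beta_names)
        for a in self.auxes:
            names.append(a.name)
        for g in self.groups:
            names.append(f"sigma_{g.name}")
        for g in self.groups:
            names.extend(f"u_{g.name}[{lab}]" for lab in g.labels)
        return names

    def _beta_logprior(self, beta: np.ndarray) -> float:
        return float(-0.5 * np.sum((beta / self.beta_prior_scale) ** 2))

    # -- main loop ------------------------------------------------------------

    def run(
        self,
        chains: int = 4,
        warmup: int = 1000,
        iterations: int = 1000,
        seed: int = 0,
    ) -> PosteriorDraws:
        if chains < 1:
            raise ValueError("chains must be >= 1")
        names = self.parameter_names()
        seqs = np.random.SeedSequence(seed).spawn(chains)
        all_draws = np.empty((chains, iterations, len(names)))
        acc: dict[str, list[float]] = {}
        for c in range(chains):
            draws_c, acc_c = self._run_chain(
                np.random.default_rng(seqs[c]), warmup, iterations
            )
            all_draws[c] = draws_c
            for k, v in acc_c.items():
                acc.setdefault(k, []).append(v)
        return PosteriorDraws(
            draws=all_draws,
            names=names,
            seed=seed,
            settings={"chains": chains, "warmup": warmup, "iterations": iterations},
            accept_rates={k: float(np.mean(v)) for k, v in acc.items()},
        )

    def _run_chain(self, rng: np.random.Generator, warmup: int, iterations: int):
        p = self.p
        beta = self.beta_init + 0.1 * np.abs(self.beta_init + 1.0) * rng.standard_normal(p)
        z = [rng.standard_normal(g.n_groups) * 0.1 for g in self.groups]
        log_sigma = [
            np.log(g.sigma_fixed if g.sigma_fixed is not None else g.sigma_init)
            if (g.sigma_fixed is None or g.sigma_fixed > 0)
            else -np.inf
            for g in self.groups
        ]
        log_aux = [
            np.log(a.fixed if a.fixed is not None else a.init) for a in self.auxes
        ]

        def sigma(i: int) -> float:
            return float(np.exp(log_sigma[i])) if np.isfinite(log_sigma[i]) else 0.0

        def aux_dict() -> dict[str, float]:
            return {a.name: float(np.exp(log_aux[i])) for i, a in enumerate(self.auxes)}

        def compute_eta() -> np.ndarray:
            eta = self.X @ beta
            for i, g in enumerate(self.groups):
                eta = eta + sigma(i) * z[i][g.obs_index]
            return eta

        eta = compute_eta()
        rows = self.row_loglik(eta, aux_dict())
        if not np.all(np.isfinite(rows)):
            raise FloatingPointError("non-finite log-likelihood at initialization")

        # proposal scales
        beta_lambda = 0.1
        beta_mean = beta.copy()
        beta_cov = np.diag(np.maximum(self.beta_prior_scale, 1e-3) ** 2) * 1e-4
        beta_chol = np.linalg.cholesky(beta_cov + 1e-12 * np.eye(p))
        z_scales = [np.full(g.n_groups, 0.5) for g in self.groups]
        sig_scales = [0.3] * len(self.groups)
        aux_scales = [0.3] * len(self.auxes)

        n_keep = iterations
        out = np.empty((n_keep, len(self.parameter_names())))
        acc_count = {"beta": 0.0, **{f"sigma_{g.name}": 0.0 for g in self.groups}}
        n_total = warmup + iterations

        def laplace_update(beta, z, eta, rows):
            """Independence MH for the joint (beta, z) block, proposing from
            a multivariate-t (df=6) centered on the Laplace mode at the
            current scales. The heavy tails keep states reachable when the
            hyperparameters have drifted since the mode was computed."""
            df = 6.0
            scales = [sigma(i) for i in range(len(self.groups))]
            colscale = np.concatenate(
                [np.ones(p)]
                + [np.full(g.n_groups, scales[i]) for i, g in enumerate(self.groups)]
            )
            Xs = self._Xfull * colscale
            prior_prec = np.concatenate(
                [1.0 / self.beta_prior_scale**2]
                + [np.ones(g.n_groups) for g in self.groups]
            )
            v = np.concatenate([beta] + z)
            auxv = aux_dict()
            m = v.copy()
            H = None
            for _ in range(12):
                eta_m = Xs @ m
                d1, d2 = self.row_curvature(eta_m, auxv)
                grad = Xs.T @ d1 - prior_prec * m
                H = (Xs.T * (-d2)) @ Xs + np.diag(prior_prec)
                try:
                    step = np.linalg.solve(H, grad)
                except np.linalg.LinAlgError:
                    return beta, z, eta, rows, 0.0
                m = m + step
                if np.max(np.abs(step)) < 1e-8:
                    break
            try:
                L = np.linalg.cholesky(H)
            except np.linalg.LinAlgError:
                return beta, z, eta, rows, 0.0

            def logpost(vv, eta_vv, rows_vv):
                return float(np.sum(rows_vv) - 0.5 * np.sum(prior_prec * vv**2))

            def logq(vv):
                d = vv - m
                q2 = float(d @ (H @ d))
                return -0.5 * (df + v.size) * np.log1p(q2 / df)

            g = rng.gamma(df / 2.0, 2.0 / df)
            v_prop = m + np.linalg.solve(L.T, rng.standard_normal(v.size)) / np.sqrt(g)
            eta_prop = Xs @ v_prop
            rows_prop = self.row_loglik(eta_prop, auxv)
            logr = (
                logpost(v_prop, eta_prop, rows_prop)
                - logpost(v, eta, rows)
                + logq(v)
                - logq(v_prop)
            )
            a_prob = min(1.0, np.exp(min(logr, 0.0))) if np.isfinite(logr) else 0.0
            if rng.random() < a_prob:
                beta = v_prop[:p]
                z_new, k0 = [], p
                for g in self.groups:
                    z_new.append(v_prop[k0 : k0 + g.n_groups])
                    k0 += g.n_groups
                return beta, z_new, eta_prop, rows_prop, a_prob
            return beta, z, eta, rows, a_prob

        for t in range(n_total):
            adapting = t < warmup
            gamma = 1.0 / (t + 10) ** 0.6

            if self.row_curvature is not None:
                # the independence move does the bulk of the mixing; the
                # random-walk blocks below still run as a local fallback
                beta, z, eta, rows, a_prob = laplace_update(beta, z, eta, rows)
                if not adapting:
                    acc_count["beta"] += a_prob / iterations

            # ---- beta block (adaptive random walk) ----
            prop = beta + beta_lambda * (beta_chol @ rng.standard_normal(p))
            eta_prop = eta + self.X @ (prop - beta)
            rows_prop = self.row_loglik(eta_prop, aux_dict())
            logr = (
                np.sum(rows_prop) - np.sum(rows)
                + self._beta_logprior(prop) - self._beta_logprior(beta)
            )
            a_prob = min(1.0, np.exp(min(logr, 0.0))) if np.isfinite(logr) else 0.0
            if rng.random() < a_prob:
                beta, eta, rows = prop, eta_prop, rows_prop
                if not adapting and self.row_curvature is None:
                    acc_count["beta"] += 1.0 / iterations
            if adapting:
                beta_lambda *= np.exp(gamma * (a_prob - 0.234))
                # running moments for the proposal covariance
                delta = beta - beta_mean
                beta_mean = beta_mean + gamma * delta
                beta_cov = beta_cov + gamma * (np.outer(delta, delta) - beta_cov)
                if t % 25 == 24:
                    try:
                        beta_chol = np.linalg.cholesky(
                            beta_cov * (2.38**2 / p) + 1e-10 * np.eye(p)
                        )
                    except np.linalg.LinAlgError:
                        pass

            # ---- group z blocks (vectorized site updates) ----
            for i, g in enumerate(self.groups):
                s = sigma(i)
                if s == 0.0:
                    continue
                zp = z[i] + z_scales[i] * rng.standard_normal(g.n_groups)
                eta_prop = eta + s * (zp - z[i])[g.obs_index]
                rows_prop = self.row_loglik(eta_prop, aux_dict())
                delta_g = np.bincount(
                    g.obs_index, weights=rows_prop - rows, minlength=g.n_groups
                ) + 0.5 * (z[i] ** 2 - zp**2)
                a_probs = np.exp(np.minimum(delta_g, 0.0))
                accept = rng.random(g.n_groups) < a_probs
                if np.any(accept):
                    z[i] = np.where(accept, zp, z[i])
                    row_mask = accept[g.obs_index]
                    eta[row_mask] = eta_prop[row_mask]
                    rows[row_mask] = rows_prop[row_mask]
                if adapting:
                    z_scales[i] *= np.exp(gamma * (a_probs - 0.44))

            # ---- group sigma updates (non-centered step, then a centered
            # interweaving step that holds u = sigma * z fixed; the pair
            # mixes where either parameterization alone is sticky) ----
            for i, g in enumerate(self.groups):
                if g.sigma_fixed is not None:
                    continue
                ls_prop = log_sigma[i] + sig_scales[i] * rng.standard_normal()
                s_old, s_new = sigma(i), float(np.exp(ls_prop))
                eta_prop = eta + (s_new - s_old) * z[i][g.obs_index]
                rows_prop = self.row_loglik(eta_prop, aux_dict())
                logr = (
                    np.sum(rows_prop) - np.sum(rows)
                    + _half_normal_logpdf(s_new, g.sigma_prior_scale)
                    - _half_normal_logpdf(s_old, g.sigma_prior_scale)
                    + ls_prop - log_sigma[i]  # Jacobian of log transform
                )
                a_prob = min(1.0, np.exp(min(logr, 0.0))) if np.isfinite(logr) else 0.0
                if rng.random() < a_prob:
                    log_sigma[i] = ls_prop
                    eta, rows = eta_prop, rows_prop
                    if not adapting:
                        acc_count[f"sigma_{g.name}"] += 1.0 / iterations

                # centered step: u fixed, so eta and rows are unchanged
                u = sigma(i) * z[i]
                ss = float(np.sum(u**2))
                ls2 = log_sigma[i] + sig_scales[i] * rng.standard_normal()
                s_old, s_new = sigma(i), float(np.exp(ls2))

                def cen_logpost(s: float, ls: float) -> float:
                    return (
                        -g.n_groups * ls
                        - ss / (2.0 * s * s)
                        + _half_normal_logpdf(s, g.sigma_prior_scale)
                        + ls
                    )

                logr2 = cen_logpost(s_new, ls2) - cen_logpost(s_old, log_sigma[i])
                a_prob2 = (
                    min(1.0, np.exp(min(logr2, 0.0))) if np.isfinite(logr2) else 0.0
                )
                if rng.random() < a_prob2:
                    log_sigma[i] = max(ls2, -18.0)
                    z[i] = u / sigma(i)
                if adapting:
                    sig_scales[i] *= np.exp(gamma * (0.5 * (a_prob + a_prob2) - 0.44))

            # ---- auxiliary parameters ----
            for i, a in enumerate(self.auxes):
                if a.fixed is not None:
                    continue
                la_prop = log_aux[i] + aux_scales[i] * rng.standard_normal()
                aux_prop = aux_dict()
                aux_prop[a.name] = float(np.exp(la_prop))
                rows_prop = self.row_loglik(eta, aux_prop)
                logr = (
                    np.sum(rows_prop) - np.sum(rows)
                    + a.log_prior(la_prop) - a.log_prior(log_aux[i])
                )
                a_prob = min(1.0, np.exp(min(logr, 0.0))) if np.isfinite(logr) else 0.0
                if rng.random() < a_prob:
                    log_aux[i] = la_prop
                    rows = rows_prop
                if adapting:
                    aux_scales[i] *= np.exp(gamma * (a_prob - 0.44))

            # ---- store ----
            if not adapting:
                k = t - warmup
                vals = [beta]
                vals.append(np.exp(log_aux) if self.auxes else np.empty(0))
                vals.append(
                    np.array([sigma(i) for i in range(len(self.groups))])
                    if self.groups
                    else np.empty(0)
                )
                for i in range(len(self.groups)):
                    vals.append(sigma(i) * z[i])
                out[k] = np.concatenate(vals)

        return out, acc_count


# ---------------------------------------------------------------------------
# Posterior summaries and convergence diagnostics
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, 95% equal-tailed credible interval,
    split-chain R-hat and bulk ESS, and a ``significant`` flag (CI excludes
    zero) — the machine twin of an effect table."""

    table: pd.DataFrame
    converged: bool
    diagnostics_available: bool

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    @property
    def terms(self) -> list[str]:
        return list(self.table.index)


def summarize(
    draws: PosteriorDraws,
    params: Sequence[str] | None = None,
    ci: float = 0.95,
    diagnostics: bool = True,
) -> PosteriorSummary:
    """Summarize posterior draws.

    By default group-level deviations (``u_*``) are excluded; pass their
    names in ``params`` to summarize them too. Diagnostics need >= 2 chains;
    with a single chain they are reported as NaN and flagged unavailable.
    """
    import arviz as az

    if params is None:
        params = [n for n in draws.names if not n.startswith("u_")]
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    multi = draws.n_chains >= 2
    for name in params:
        arr = draws.get(name)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite draws for {name}")
        mean = float(arr.mean())
        lo, hi = (float(x) for x in np.quantile(arr, [lo_q, hi_q]))
        if diagnostics and multi:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = float(az.rhat(arr))
                ess = float(az.ess(arr))
        else:
            rhat, ess = np.nan, np.nan
        rows.append(
            {
                "mean": mean,
                "sd": float(arr.std()),
                "ci_low": lo,
                "ci_high": hi,
                "rhat": rhat,
                "ess": ess,
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    table = pd.DataFrame(rows, index=list(params))
    table.index.name = "term"
    if diagnostics and multi:
        bad = (table["rhat"] > _RHAT_GATE) | (table["ess"] < _ESS_GATE)
        converged = not bool(bad.any())
        if not converged:
            warnings.warn(
                "convergence diagnostics failed for: "
                + ", ".join(table.index[bad]),
                RuntimeWarning,
                stacklevel=2,
            )
    else:
        converged = True
    return PosteriorSummary(
        table=table, converged=converged, diagnostics_available=diagnostics and multi
    )
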