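"""Hierarchical Bayesian beta regression (logit mean link, log precision).

Likelihood: ``y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi)`` with
``logit(mu_i) = x_i' beta + sum_k z_{g(i),k} * tau_k * u_{ik}`` where the
``z`` are non-centered standard-normal group deviations (or the group
effects themselves under ``centered_groups``), ``tau_k`` are
group-level standard deviations with half-Student-t(3, 0, 2.5) priors,
fixed-effect slopes carry Normal(0, 1) priors (a wider Normal on the
intercept), and ``phi`` a Half-Normal(0, 10) or Exponential(1) prior.
Sampling is NUTS; convergence is gated on split-R-hat < 1.01 and bulk/tail
ESS > 400 for every parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from ._kernels import beta_terms
from .design import DesignMatrix, RegressionSpec
from .nuts import run_chains

__all__ = ["PosteriorSummary", "ConvergenceError", "fit_beta_hierarchical"]


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, report: pd.DataFrame):
        super().__init__(message + "\n" + report.to_string())
        self.report = report


class _BetaGLMM:
    """Parameter packing and analytic log-posterior gradient."""

    def __init__(self, design: DesignMatrix, spec: RegressionSpec):
        self.design = design
        self.spec = spec
        self.X = design.X
        self.y = design.y
        if np.any((self.y <= 0) | (self.y >= 1)):
            raise ValueError("response must lie strictly inside (0, 1); apply the squeeze transform")
        self.n, self.p = self.X.shape
        self.centered = spec.centered_groups
        self.has_groups = design.Z is not None and design.n_groups > 1
        self.K = design.Z.shape[1] if self.has_groups else 0
        self.G = design.n_groups if self.has_groups else 0
        self.dim = self.p + self.G * self.K + self.K + 1
        self.beta_prior_sd = np.full(self.p, spec.slope_prior_sd)
        self.beta_prior_sd[0] = spec.intercept_prior_sd
        self.logy = np.log(self.y)
        self.log1my = np.log1p(-self.y)

    # -- packing ------------------------------------------------------------
    def unpack(self, theta: np.ndarray):
        p, G, K = self.p, self.G, self.K
        beta = theta[:p]
        z = theta[p: p + G * K].reshape(G, K) if self.has_groups else None
        log_tau = theta[p + G * K: p + G * K + K] if self.has_groups else None
        log_phi = theta[-1]
        return beta, z, log_tau, log_phi

    def eta(self, beta, z, tau):
        eta = self.X @ beta
        if self.has_groups:
            b = z if self.centered else z * tau  # (G, K) group effects
            eta = eta + np.einsum("nk,nk->n", self.design.Z, b[self.design.group_codes])
        return eta

    def logp_grad(self, theta: np.ndarray):
        beta, z, log_tau, log_phi = self.unpack(theta)
        tau = np.exp(log_tau) if self.has_groups else None
        phi = np.exp(log_phi)
        eta = self.eta(beta, z, tau)
        loglik, w, dl_dphi = beta_terms(self.logy, self.log1my, eta, phi)

        grad = np.empty_like(theta)
        grad[: self.p] = self.X.T @ w - beta / self.beta_prior_sd**2
        logp = loglik - 0.5 * np.sum((beta / self.beta_prior_sd) ** 2)

        if self.has_groups:
            gc = self.design.group_codes
            sums = np.stack(
                [np.bincount(gc, weights=self.design.Z[:, k] * w, minlength=self.G)
                 for k in range(self.K)], axis=1,
            )  # (G, K) of d loglik / d (group effect on eta)
            df, sc = self.spec.group_sd_prior_df, self.spec.group_sd_prior_scale
            if self.centered:
                # z holds the group effects u directly; u ~ N(0, tau^2)
                grad_z = sums - z / tau**2
                logp += -0.5 * np.sum((z / tau) ** 2) - self.G * np.sum(log_tau)
                grad_ltau = np.sum((z / tau) ** 2, axis=0) - self.G
            else:
                # non-centered: u = tau * z with z ~ N(0, 1)
                grad_z = sums * tau - z
                logp += -0.5 * np.sum(z**2)
                grad_ltau = tau * np.sum(sums * z, axis=0)
            # half-Student-t(df, 0, scale) prior on tau, sampled as log_tau
            grad_ltau += -(df + 1.0) * tau**2 / (df * sc**2 + tau**2) + 1.0
            logp += np.sum(-(df + 1.0) / 2.0 * np.log1p(tau**2 / (df * sc**2)) + log_tau)
            s = self.p
            grad[s: s + self.G * self.K] = grad_z.ravel()
            grad[s + self.G * self.K: s + self.G * self.K + self.K] = grad_ltau

        if self.spec.phi_prior == "half_normal":
            logp += -0.5 * (phi / 10.0) ** 2
            dprior = -phi / 100.0
        else:
            logp += -phi
            dprior = -1.0
        logp += log_phi  # Jacobian of the log transform
        grad[-1] = phi * (dl_dphi + dprior) + 1.0
        return logp, grad

    def pointwise_loglik(self, beta_draws: np.ndarray, z_draws, tau_draws, phi_draws) -> np.ndarray:
        """(draws, n) matrix of per-observation log densities."""
        D = beta_draws.shape[0]
        out = np.empty((D, self.n))
        for d in range(D):
            eta = self.X @ beta_draws[d]
            if self.has_groups:
                bmat = z_draws[d] if self.centered else z_draws[d] * tau_draws[d]
                eta = eta + np.einsum("nk,nk->n", self.design.Z, bmat[self.design.group_codes])
            mu = expit(np.clip(eta, -35.0, 35.0))
            phi = phi_draws[d]
            a, b = mu * phi, (1.0 - mu) * phi
            out[d] = (gammaln(phi) - gammaln(a) - gammaln(b)
                      + (a - 1.0) * self.logy + (b - 1.0) * self.log1my)
        return out


@dataclass
class PosteriorSummary:
    """Draws, diagnostics and cell-mean machinery for one fitted model."""

    idata: az.InferenceData
    design: DesignMatrix
    spec: RegressionSpec
    diagnostics: pd.DataFrame
    converged: bool
    phi_prior: str

    def beta_draws(self) -> np.ndarray:
        """(total draws, p) flattened fixed-effect draws."""
        b = self.idata.posterior["beta"].values
        return b.reshape(-1, b.shape[-1])

    def cell_mean_draws(self, cell: Mapping[str, str]) -> np.ndarray:
        """Posterior draws of the population-level cell mean (probability scale)."""
        x = self.design.row_for(cell)
        return expit(self.beta_draws() @ x)

    def cell_means(self, cells: Sequence[Mapping[str, str]]) -> pd.DataFrame:
        rows = []
        for cell in cells:
            d = self.cell_mean_draws(cell)
            rows.append({
                **{str(k): str(v) for k, v in cell.items()},
                "mean": d.mean(),
                "q17": np.quantile(d, 0.17), "q83": np.quantile(d, 0.83),
                "q2.5": np.quantile(d, 0.025), "q97.5": np.quantile(d, 0.975),
            })
        return pd.DataFrame(rows)

    def fixed_effects(self) -> pd.DataFrame:
        b = self.beta_draws()
        return pd.DataFrame({
            "term": self.design.colnames,
            "mean": b.mean(axis=0),
            "sd": b.std(axis=0),
            "q2.5": np.quantile(b, 0.025, axis=0),
            "q97.5": np.quantile(b, 0.975, axis=0),
        })


def _diagnostics_table(idata: az.InferenceData) -> pd.DataFrame:
    rhat = az.rhat(idata)
    ess_bulk = az.ess(idata, method="bulk")
    ess_tail = az.ess(idata, method="tail")
    rows = []
    for var in rhat.data_vars:
        r = np.atleast_1d(rhat[var].values).ravel()
        eb = np.atleast_1d(ess_bulk[var].values).ravel()
        et = np.atleast_1d(ess_tail[var].values).ravel()
        for i in range(r.size):
            rows.append({"parameter": f"{var}[{i}]", "rhat": r[i],
                         "ess_bulk": eb[i], "ess_tail": et[i]})
    return pd.DataFrame(rows)


def fit_beta_hierarchical(design: DesignMatrix, spec: RegressionSpec) -> PosteriorSummary:
    """Fit the model by NUTS and return draws + diagnostics.

    Raises :class:`ConvergenceError` when ``spec.check_diagnostics`` is set
    and any parameter shows split-R-hat >= 1.01 or ESS <= 400.
    """
    model = _BetaGLMM(design, spec)

    # warm start: OLS on the logit scale plus moment-matched precision
    logit_y = np.log(design.y) - np.log1p(-design.y)
    beta0, *_ = np.linalg.lstsq(design.X, logit_y, rcond=None)
    resid = logit_y - design.X @ beta0
    resid_var = max(np.var(resid), 1e-3)
    mu_bar = float(np.mean(design.y))
    phi0 = max(mu_bar * (1 - mu_bar) * 4.0 / resid_var, 2.0)  # crude delta-method guess
    u0 = tau0 = None
    if model.has_groups:
        gc = design.group_codes
        counts = np.bincount(gc, minlength=model.G)
        u0 = np.bincount(gc, weights=resid, minlength=model.G) / np.maximum(counts, 1)
        u0 = 0.8 * u0  # mild shrinkage toward zero
        tau0 = float(np.clip(u0.std(), 0.1, 2.0))

    def init(rng):
        theta = np.zeros(model.dim)
        theta[: model.p] = beta0 + 0.05 * rng.standard_normal(model.p)
        theta[-1] = np.log(phi0) + 0.05 * rng.standard_normal()
        if model.has_groups:
            # group-effect warm start: empirical residual means in the intercept
            # column, small jitter elsewhere
            z0 = np.zeros((model.G, model.K))
            z0[:, 0] = u0 if model.centered else u0 / tau0
            z0 += 0.05 * rng.standard_normal(z0.shape)
            theta[model.p: model.p + model.G * model.K] = z0.ravel()
            theta[model.p + model.G * model.K: -1] = np.log(tau0) + 0.05 * rng.standard_normal(model.K)
        return theta

    with np.errstate(over="ignore", invalid="ignore"):
        chains = run_chains(
            model.logp_grad, init, model.dim,
            chains=spec.chains, n_warmup=spec.warmup, n_draws=spec.draws,
            seed=spec.seed, target_accept=spec.target_accept,
            shared_warmup=spec.shared_warmup,
        )
    draws = np.stack([c.draws for c in chains])  # (chains, draws, dim)
    C, D, _ = draws.shape
    p, G, K = model.p, model.G, model.K
    posterior = {"beta": draws[:, :, :p], "phi": np.exp(draws[:, :, -1])}
    if model.has_groups:
        posterior["z"] = draws[:, :, p: p + G * K].reshape(C, D, G, K)
        posterior["tau"] = np.exp(draws[:, :, p + G * K: p + G * K + K])

    flat = draws.reshape(C * D, -1)
    beta_d = flat[:, :p]
    z_d = flat[:, p: p + G * K].reshape(C * D, G, K) if model.has_groups else None
    tau_d = np.exp(flat[:, p + G * K: p + G * K + K]) if model.has_groups else None
    phi_d = np.exp(flat[:, -1])
    ll = model.pointwise_loglik(beta_d, z_d, tau_d, phi_d).reshape(C, D, model.n)

    idata = az.from_dict(
        posterior=posterior,
        log_likelihood={"y": ll},
        sample_stats={
            "diverging": np.stack([c.diverging for c in chains]),
            "acceptance_rate": np.stack([c.accept_stat for c in chains]),
        },
    )
    diag = _diagnostics_table(idata)
    bad = diag[(diag["rhat"] >= 1.01) | (diag["ess_bulk"] <= 400) | (diag["ess_tail"] <= 400)]
    converged = bad.empty
    summary = PosteriorSummary(
        idata=idata, design=design, spec=spec, diagnostics=diag,
        converged=converged, phi_prior=spec.phi_prior,
    )
    if spec.check_diagnostics and not converged:
        raise ConvergenceError(
            f"{len(bad)} parameter(s) failed convergence gates (R-hat < 1.01, ESS > 400)", bad
        )
    return summary
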