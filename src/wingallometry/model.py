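"""Hierarchical Bayesian model of wing-length allometry.

For one model population (HY, spring AHY or autumn AHY), individual scaled
log wing length w is regressed on scaled log body size z within each
species-year cell y, controlling for sex s and a sex-by-size interaction:

    w_hat = beta0_y + beta1_y * z + n0_p * s + n1_p * s * z
    w     ~ Normal(w_hat, sigma_w)

The species-year allometric intercepts beta0_y and slopes beta1_y are
simultaneously regressed, through species-specific coefficient rows of the
matrices I0 and I1, on the species-year design matrix G (constant, scaled
climate covariates, scaled year):

    beta*_y ~ Normal(I*[p, :] . G[y, :], tau*)
    I*[p,c] ~ Normal(mu*[c], sigma*[c])
    n*_p    ~ Normal(m_n*, s_n*)

with weakly informative hyperpriors mu, m_n ~ Normal(0, 2) and every scale
(sigma_w, tau*, sigma*[c], s_n*) ~ half-Cauchy(0, 5). The global climate/year
effects mu are the quantities of scientific interest.

Inference is NUTS with analytic gradients. Because the likelihood is
Gaussian and linear in the cell-level parameters, it is collapsed onto
per-(cell, sex) sufficient statistics, making each gradient evaluation
independent of the number of specimens. Each hierarchy level (beta, I, n)
is parameterized centered or non-centered depending on whether the data or
the level prior dominate it - decided automatically by an empirical-Bayes
moment pre-pass that also initializes the chains and the mass matrix.
Scale parameters sample on the log scale.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import HAVE_NUMBA, logp_grad_kernel
from .climate import CovariateTable, ModelSpec
from .nuts import sample_nuts

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorConfig:
    """Hyperprior scales: Normal(0, normal_scale) for location hyperparameters,
    half-Cauchy(0, cauchy_scale) for every scale parameter."""

    normal_scale: float = 2.0
    cauchy_scale: float = 5.0

    def __post_init__(self):
        if not (self.normal_scale > 0 and self.cauchy_scale > 0):
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    n_chains: int = 4
    n_iterations: int = 4000
    n_warmup: int = 2000
    seed: int = 0
    target_accept: float = 0.9
    max_treedepth: int = 10
    rhat_threshold: float = 1.05

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for the Rhat diagnostic")
        if not (0 < self.n_warmup < self.n_iterations):
            raise ValueError("require 0 < n_warmup < n_iterations")
        if not (0.0 < self.target_accept < 1.0):
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass
class ModelParameters:
    """One full set of model unknowns (a point, or the truth of a simulation).

    Array index conventions: ``cells`` orders the species-year pairs for
    ``beta0``/``beta1``; ``species`` orders the rows of ``I0``/``I1`` and the
    sex effects; ``columns`` orders covariates (constant first, year last).
    """

    cells: list[tuple[str, int]]
    species: list[str]
    columns: list[str]
    beta0: np.ndarray
    beta1: np.ndarray
    n0: np.ndarray
    n1: np.ndarray
    I0: np.ndarray
    I1: np.ndarray
    mu0: np.ndarray
    mu1: np.ndarray
    sigma0: np.ndarray
    sigma1: np.ndarray
    tau0: float
    tau1: float
    sigma_w: float
    m_n0: float = 0.0
    m_n1: float = 0.0
    s_n0: float = 1.0
    s_n1: float = 1.0


def linear_predictor(beta0, beta1, n0, n1, z, s):
    """Individual-level expected scaled wing length."""
    return beta0 + beta1 * z + n0 * s + n1 * s * z


def beta_hat(I_row, G_row):
    """Climate-predicted allometric parameter: inner product of a species'
    effect row with a species-year design row (constant entry first)."""
    I_row = np.asarray(I_row, dtype=float)
    G_row = np.asarray(G_row, dtype=float)
    if I_row.shape != G_row.shape:
        raise ValueError(
            f"length mismatch: I has {I_row.shape}, G has {G_row.shape}"
        )
    return float(np.dot(I_row, G_row))


def _norm_logpdf(x, loc, scale):
    x = np.asarray(x, dtype=float)
    return -0.5 * ((x - loc) / scale) ** 2 - np.log(scale) - 0.5 * _LOG_2PI


def _half_cauchy_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        return -np.inf
    return np.sum(
        math.log(2.0 / (math.pi * scale)) - np.log1p((x / scale) ** 2)
    )


def log_joint_density(
    params: ModelParameters,
    data: pd.DataFrame,
    G: CovariateTable,
    priors: PriorConfig = PriorConfig(),
) -> float:
    """Sum of all log densities of the model at ``params`` (constrained space).

    ``data`` needs columns ``species, year, sex_code, z, w``. Non-positive
    scale parameters put the point outside the support: returns -inf rather
    than raising.
    """
    scales = np.concatenate([
        np.atleast_1d(params.sigma0), np.atleast_1d(params.sigma1),
        [params.tau0, params.tau1, params.sigma_w, params.s_n0, params.s_n1],
    ])
    if np.any(scales <= 0):
        return -np.inf

    cell_index = {c: i for i, c in enumerate(params.cells)}
    sp_index = {s: i for i, s in enumerate(params.species)}

    total = 0.0
    # observation level
    for row in data.itertuples(index=False):
        j = cell_index[(row.species, int(row.year))]
        p = sp_index[row.species]
        w_hat = linear_predictor(
            params.beta0[j], params.beta1[j], params.n0[p], params.n1[p],
            row.z, row.sex_code,
        )
        total += float(_norm_logpdf(row.w, w_hat, params.sigma_w))
    # species-year level
    for j, (sp, year) in enumerate(params.cells):
        p = sp_index[sp]
        g = G.row(sp, year)
        total += float(_norm_logpdf(params.beta0[j],
                                    beta_hat(params.I0[p], g), params.tau0))
        total += float(_norm_logpdf(params.beta1[j],
                                    beta_hat(params.I1[p], g), params.tau1))
    # species level
    total += float(np.sum(_norm_logpdf(params.n0, params.m_n0, params.s_n0)))
    total += float(np.sum(_norm_logpdf(params.n1, params.m_n1, params.s_n1)))
    total += float(np.sum(_norm_logpdf(params.I0, params.mu0[None, :],
                                       params.sigma0[None, :])))
    total += float(np.sum(_norm_logpdf(params.I1, params.mu1[None, :],
                                       params.sigma1[None, :])))
    # hyper level
    ns = priors.normal_scale
    total += float(np.sum(_norm_logpdf(params.mu0, 0.0, ns)))
    total += float(np.sum(_norm_logpdf(params.mu1, 0.0, ns)))
    total += float(_norm_logpdf(params.m_n0, 0.0, ns))
    total += float(_norm_logpdf(params.m_n1, 0.0, ns))
    cs = priors.cauchy_scale
    total += _half_cauchy_logpdf(np.atleast_1d(params.sigma0), cs)
    total += _half_cauchy_logpdf(np.atleast_1d(params.sigma1), cs)
    total += _half_cauchy_logpdf(params.tau0, cs)
    total += _half_cauchy_logpdf(params.tau1, cs)
    total += _half_cauchy_logpdf(params.sigma_w, cs)
    total += _half_cauchy_logpdf(params.s_n0, cs)
    total += _half_cauchy_logpdf(params.s_n1, cs)
    return float(total)


class _ModelData:
    """Sufficient statistics and index bookkeeping for one population fit."""

    def __init__(self, data: pd.DataFrame, G: CovariateTable):
        data = data.copy()
        data["year"] = data["year"].astype(int)
        g_index = set(G.table.index)
        cells_data = set(zip(data["species"], data["year"]))
        common = sorted(cells_data & g_index)
        dropped_data = sorted(cells_data - g_index)
        if dropped_data:
            logger.warning(
                "%d species-year cell(s) in the specimen data have no design "
                "row and were dropped: %s", len(dropped_data), dropped_data[:5],
            )
        if not common:
            raise ValueError("no species-year cells shared between data and G")
        self.cells: list[tuple[str, int]] = common
        self.species: list[str] = sorted({sp for sp, _ in common})
        self.columns: list[str] = list(G.column_spec)
        sp_idx_map = {s: i for i, s in enumerate(self.species)}
        self.sp_idx = np.array([sp_idx_map[sp] for sp, _ in common])
        # cells are sorted by species then year so species blocks are contiguous
        self.sp_starts = np.searchsorted(self.sp_idx, np.arange(len(self.species)))
        self.G = np.array([G.row(sp, y) for sp, y in common])

        J = len(common)
        cell_idx_map = {c: i for i, c in enumerate(common)}
        keys = list(zip(data["species"], data["year"]))
        keep = np.array([k in cell_idx_map for k in keys])
        data = data[keep]
        j = np.array([cell_idx_map[k] for k in zip(data["species"], data["year"])])
        s = data["sex_code"].to_numpy(dtype=int)
        if not np.isin(s, (0, 1)).all():
            raise ValueError("sex_code must be 0/1")
        z = data["z"].to_numpy(dtype=float)
        w = data["w"].to_numpy(dtype=float)
        flat = j * 2 + s
        size = J * 2

        def acc(vals):
            return np.bincount(flat, weights=vals, minlength=size).reshape(J, 2)

        self.N = acc(np.ones_like(z))
        self.Sz = acc(z)
        self.Szz = acc(z * z)
        self.Sw = acc(w)
        self.Swz = acc(w * z)
        self.Sww = acc(w * w)
        self.n_obs = int(self.N.sum())
        self.w_sd = float(np.std(w)) if len(w) > 1 else 1.0


def _empirical_bayes(md: _ModelData) -> dict:
    """Moment estimates of every model level from per-cell least squares.

    Used to (i) decide centered vs non-centered parameterization per level,
    (ii) start the chains inside the typical set, and (iii) seed the mass
    matrix. All quantities are rough; the sampler owns the inference.
    """
    J, S, C = len(md.cells), len(md.species), len(md.columns)
    b_ols = np.zeros((J, 4))
    unit_var = np.zeros((J, 4))     # parameter variances per unit sigma_w^2
    ssr_tot, dof_tot = 0.0, 0
    for j in range(J):
        n0c, n1c = md.N[j]
        a = np.array([
            [n0c + n1c, md.Sz[j].sum(), n1c, md.Sz[j, 1]],
            [md.Sz[j].sum(), md.Szz[j].sum(), md.Sz[j, 1], md.Szz[j, 1]],
            [n1c, md.Sz[j, 1], n1c, md.Sz[j, 1]],
            [md.Sz[j, 1], md.Szz[j, 1], md.Sz[j, 1], md.Szz[j, 1]],
        ])
        y = np.array([md.Sw[j].sum(), md.Swz[j].sum(), md.Sw[j, 1], md.Swz[j, 1]])
        a_inv = np.linalg.pinv(a, hermitian=True)
        coef = a_inv @ y
        b_ols[j] = coef
        unit_var[j] = np.maximum(np.diag(a_inv), 1e-12)
        rank = int(np.linalg.matrix_rank(a))
        ssr = float(md.Sww[j].sum() - coef @ y)
        if n0c + n1c > rank:
            ssr_tot += max(ssr, 0.0)
            dof_tot += int(n0c + n1c) - rank
    sigma_w2 = ssr_tot / dof_tot if dof_tot > 0 else md.w_sd ** 2
    sigma_w2 = float(np.clip(sigma_w2, 1e-6, None))
    v_beta = sigma_w2 * unit_var[:, :2]                  # (J, 2)

    # species-level regressions of the OLS betas on G
    I_hat = np.zeros((2, S, C))
    resid_var = np.full((2, S), np.nan)
    se_I = np.full((2, S, C), np.nan)
    for s_i in range(S):
        lo = md.sp_starts[s_i]
        hi = md.sp_starts[s_i + 1] if s_i + 1 < S else J
        Gs = md.G[lo:hi]
        gram_inv = np.linalg.pinv(Gs.T @ Gs, hermitian=True)
        for k in range(2):
            yk = b_ols[lo:hi, k]
            coef = gram_inv @ (Gs.T @ yk)
            I_hat[k, s_i] = coef
            n_s = hi - lo
            if n_s > C:
                resid = yk - Gs @ coef
                resid_var[k, s_i] = float(resid @ resid) / (n_s - C)
                se_I[k, s_i] = resid_var[k, s_i] * np.diag(gram_inv)

    med_v = np.median(v_beta, axis=0)                    # (2,)
    tau2 = np.empty(2)
    for k in range(2):
        rv = resid_var[k][~np.isnan(resid_var[k])]
        tau2[k] = (max(float(np.median(rv)) - med_v[k], 1e-4)
                   if rv.size else 0.01)

    mu_hat = I_hat.mean(axis=1)                          # (2, C)
    sigma2 = np.empty((2, C))
    for k in range(2):
        var_across = I_hat[k].var(axis=0, ddof=1) if S > 1 else np.ones(C)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            se_mean = np.nanmean(se_I[k], axis=0)
        se_mean = np.where(np.isnan(se_mean), 0.0, se_mean)
        sigma2[k] = np.maximum(var_across - se_mean, 1e-4)

    # sex-effect level: per-species averages of the per-cell sex terms
    n_hat = np.zeros((2, S))
    se_n = np.zeros((2, S))
    for s_i in range(S):
        lo = md.sp_starts[s_i]
        hi = md.sp_starts[s_i + 1] if s_i + 1 < S else J
        for k in range(2):
            n_hat[k, s_i] = b_ols[lo:hi, 2 + k].mean()
            se_n[k, s_i] = sigma_w2 * unit_var[lo:hi, 2 + k].mean() / (hi - lo)
    s_n2 = np.empty(2)
    for k in range(2):
        var_across = n_hat[k].var(ddof=1) if S > 1 else 0.01
        s_n2[k] = max(var_across - se_n[k].mean(), 1e-4)

    return {
        "b_ols": b_ols,
        "v_beta": v_beta,
        "sigma_w": math.sqrt(sigma_w2),
        "I_hat": I_hat,
        "mu_hat": mu_hat,
        "sigma": np.sqrt(sigma2),
        "tau": np.sqrt(tau2),
        "n_hat": n_hat,
        "se_n": se_n,
        "s_n": np.sqrt(s_n2),
        "m_n": n_hat.mean(axis=1),
        # a level is centered when the data pin it down more tightly than
        # its hierarchical prior scale does
        "centered_beta": bool(np.median(v_beta) < float(np.mean(tau2))),
        "centered_I": (bool(np.nanmean(se_I[~np.isnan(se_I)]) < float(np.mean(sigma2)))
                       if not np.all(np.isnan(se_I)) else False),
        "centered_n": bool(np.mean(se_n) < float(np.mean(s_n2))),
    }


class _LogPosterior:
    """Unconstrained log posterior and analytic gradient.

    ``centered`` holds per-level flags for the beta, I and n levels; a
    centered block stores the natural parameter, a non-centered block stores
    the standardized offset. Scales are log-transformed.
    """

    _SCALARS = ("m_n0", "m_n1", "lt0", "lt1", "lsw", "lsn0", "lsn1")

    def __init__(self, md: _ModelData, priors: PriorConfig,
                 prior_only: bool = False,
                 centered: dict[str, bool] | None = None,
                 eb: dict | None = None):
        self.md = md
        self.priors = priors
        self.prior_only = prior_only
        self.centered = {"beta": False, "I": False, "n": False}
        if centered:
            self.centered.update(centered)
        self.eb = eb
        self._use_kernel = HAVE_NUMBA
        J, S, C = len(md.cells), len(md.species), len(md.columns)
        self.J, self.S, self.C = J, S, C
        sizes = {
            "b0": J, "b1": J,
            "I0": S * C, "I1": S * C,
            "n0": S, "n1": S,
            "mu0": C, "mu1": C,
            "m_n0": 1, "m_n1": 1,
            "lt0": 1, "lt1": 1, "lsw": 1, "lsn0": 1, "lsn1": 1,
            "ls0": C, "ls1": C,
        }
        self.slices: dict[str, slice] = {}
        off = 0
        for name, n in sizes.items():
            self.slices[name] = slice(off, off + n)
            off += n
        self.dim = off

    # -- packing helpers -------------------------------------------------
    def unpack(self, q: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        for name, sl in self.slices.items():
            v = q[sl]
            if name in ("I0", "I1"):
                v = v.reshape(self.S, self.C)
            elif name in self._SCALARS:
                v = v[0]
            out[name] = v
        return out

    def _natural(self, u: dict):
        """Natural-scale parameters from an unpacked point."""
        md = self.md
        tau = (math.exp(u["lt0"]), math.exp(u["lt1"]))
        s_n = (math.exp(u["lsn0"]), math.exp(u["lsn1"]))
        sigma = (np.exp(u["ls0"]), np.exp(u["ls1"]))
        if self.centered["I"]:
            I = (u["I0"], u["I1"])
        else:
            I = (u["mu0"][None, :] + sigma[0][None, :] * u["I0"],
                 u["mu1"][None, :] + sigma[1][None, :] * u["I1"])
        bhat = (np.einsum("jc,jc->j", I[0][md.sp_idx], md.G),
                np.einsum("jc,jc->j", I[1][md.sp_idx], md.G))
        if self.centered["beta"]:
            beta = (u["b0"], u["b1"])
        else:
            beta = (bhat[0] + tau[0] * u["b0"], bhat[1] + tau[1] * u["b1"])
        if self.centered["n"]:
            n = (u["n0"], u["n1"])
        else:
            n = (u["m_n0"] + s_n[0] * u["n0"], u["m_n1"] + s_n[1] * u["n1"])
        return beta, bhat, I, n, tau, s_n, sigma, math.exp(u["lsw"])

    def constrain(self, q: np.ndarray) -> ModelParameters:
        """Map an unconstrained point to the natural parameterization."""
        u = self.unpack(q)
        beta, _, I, n, tau, s_n, sigma, sigma_w = self._natural(u)
        return ModelParameters(
            cells=self.md.cells, species=self.md.species, columns=self.md.columns,
            beta0=np.array(beta[0]), beta1=np.array(beta[1]),
            n0=np.array(n[0]), n1=np.array(n[1]),
            I0=np.array(I[0]), I1=np.array(I[1]),
            mu0=u["mu0"].copy(), mu1=u["mu1"].copy(),
            sigma0=sigma[0], sigma1=sigma[1],
            tau0=tau[0], tau1=tau[1], sigma_w=sigma_w,
            m_n0=float(u["m_n0"]), m_n1=float(u["m_n1"]),
            s_n0=s_n[0], s_n1=s_n[1],
        )

    # -- density ---------------------------------------------------------
    def logp_and_grad(self, q: np.ndarray):
        """Log posterior and gradient; compiled kernel when numba is present."""
        if self._use_kernel:
            md = self.md
            return logp_grad_kernel(
                q, self.J, self.S, self.C,
                self.centered["beta"], self.centered["I"], self.centered["n"],
                self.prior_only,
                md.N, md.Sz, md.Szz, md.Sw, md.Swz, md.Sww, md.G,
                md.sp_idx, float(md.n_obs),
                self.priors.normal_scale ** 2, self.priors.cauchy_scale ** 2,
                math.log(2.0 / (math.pi * self.priors.cauchy_scale)),
            )
        return self.logp_and_grad_numpy(q)

    def logp_and_grad_numpy(self, q: np.ndarray):
        md = self.md
        u = self.unpack(q)
        ns2 = self.priors.normal_scale ** 2
        cs2 = self.priors.cauchy_scale ** 2
        sl = self.slices

        # far outside any reasonable scale range: treat as off-support so the
        # step-size search / divergent trajectories cannot overflow exp()
        log_scales = np.concatenate([
            [u["lt0"], u["lt1"], u["lsw"], u["lsn0"], u["lsn1"]],
            u["ls0"], u["ls1"],
        ])
        if np.any(np.abs(log_scales) > 50.0):
            return -np.inf, np.zeros(self.dim)

        (beta0, beta1), (bhat0, bhat1), (I0, I1), (n0, n1), \
            (tau0, tau1), (s_n0, s_n1), (sigma0, sigma1), sigma_w = \
            self._natural(u)

        grad = np.zeros(self.dim)
        logp = 0.0

        if self.prior_only:
            dbeta0 = np.zeros(self.J)
            dbeta1 = np.zeros(self.J)
            dn0_s = np.zeros(self.S)
            dn1_s = np.zeros(self.S)
            dlsw_lik = 0.0
        else:
            # intercept/slope of the within-cell regression, by sex
            a = np.stack([beta0, beta0 + n0[md.sp_idx]], axis=1)     # (J, 2)
            b = np.stack([beta1, beta1 + n1[md.sp_idx]], axis=1)
            rsum = md.Sw - a * md.N - b * md.Sz
            rz = md.Swz - a * md.Sz - b * md.Szz
            ssr = float(np.sum(
                md.Sww - 2 * a * md.Sw - 2 * b * md.Swz
                + a * a * md.N + 2 * a * b * md.Sz + b * b * md.Szz
            ))
            inv_var = 1.0 / (sigma_w * sigma_w)
            logp += (-0.5 * md.n_obs * _LOG_2PI - md.n_obs * u["lsw"]
                     - 0.5 * ssr * inv_var)
            dlla = rsum * inv_var
            dllb = rz * inv_var
            dbeta0 = dlla.sum(axis=1)
            dbeta1 = dllb.sum(axis=1)
            dn0_s = np.add.reduceat(dlla[:, 1], md.sp_starts)
            dn1_s = np.add.reduceat(dllb[:, 1], md.sp_starts)
            dlsw_lik = -md.n_obs + ssr * inv_var

        # ---- beta level: beta*_y ~ Normal(bhat*_y, tau*) ----
        if self.centered["beta"]:
            rb0 = (beta0 - bhat0) / tau0
            rb1 = (beta1 - bhat1) / tau1
            logp += (-0.5 * float(np.dot(rb0, rb0))
                     - 0.5 * float(np.dot(rb1, rb1))
                     - self.J * (u["lt0"] + u["lt1"]) - self.J * _LOG_2PI)
            grad[sl["b0"]] = dbeta0 - rb0 / tau0
            grad[sl["b1"]] = dbeta1 - rb1 / tau1
            dbhat0 = rb0 / tau0
            dbhat1 = rb1 / tau1
            dlt0_level = float(np.dot(rb0, rb0)) - self.J
            dlt1_level = float(np.dot(rb1, rb1)) - self.J
        else:
            v0, v1 = u["b0"], u["b1"]
            logp += (-0.5 * float(np.dot(v0, v0))
                     - 0.5 * float(np.dot(v1, v1)) - self.J * _LOG_2PI)
            grad[sl["b0"]] = -v0 + tau0 * dbeta0
            grad[sl["b1"]] = -v1 + tau1 * dbeta1
            dbhat0 = dbeta0
            dbhat1 = dbeta1
            dlt0_level = tau0 * float(np.dot(dbeta0, v0))
            dlt1_level = tau1 * float(np.dot(dbeta1, v1))

        # gradient reaching the natural I matrices through bhat
        dI0_nat = np.add.reduceat(dbhat0[:, None] * md.G, md.sp_starts, axis=0)
        dI1_nat = np.add.reduceat(dbhat1[:, None] * md.G, md.sp_starts, axis=0)

        # ---- species-effect level: I*[s,c] ~ Normal(mu*[c], sigma*[c]) ----
        if self.centered["I"]:
            r0 = (I0 - u["mu0"][None, :]) / sigma0[None, :]
            r1 = (I1 - u["mu1"][None, :]) / sigma1[None, :]
            logp += (-0.5 * float(np.sum(r0 * r0)) - 0.5 * float(np.sum(r1 * r1))
                     - self.S * float(np.sum(u["ls0"] + u["ls1"]))
                     - self.S * self.C * _LOG_2PI)
            grad[sl["I0"]] = (dI0_nat - r0 / sigma0[None, :]).ravel()
            grad[sl["I1"]] = (dI1_nat - r1 / sigma1[None, :]).ravel()
            dmu0 = np.sum(r0 / sigma0[None, :], axis=0)
            dmu1 = np.sum(r1 / sigma1[None, :], axis=0)
            dls0_level = np.sum(r0 * r0 - 1.0, axis=0)
            dls1_level = np.sum(r1 * r1 - 1.0, axis=0)
        else:
            v0, v1 = u["I0"], u["I1"]
            logp += (-0.5 * float(np.sum(v0 * v0)) - 0.5 * float(np.sum(v1 * v1))
                     - self.S * self.C * _LOG_2PI)
            grad[sl["I0"]] = (-v0 + sigma0[None, :] * dI0_nat).ravel()
            grad[sl["I1"]] = (-v1 + sigma1[None, :] * dI1_nat).ravel()
            dmu0 = dI0_nat.sum(axis=0)
            dmu1 = dI1_nat.sum(axis=0)
            dls0_level = sigma0 * np.sum(dI0_nat * v0, axis=0)
            dls1_level = sigma1 * np.sum(dI1_nat * v1, axis=0)

        # hyper-means mu ~ Normal(0, normal_scale)
        logp += (-0.5 * float(np.dot(u["mu0"], u["mu0"])) / ns2
                 - 0.5 * float(np.dot(u["mu1"], u["mu1"])) / ns2
                 - 2 * self.C * (0.5 * _LOG_2PI + math.log(self.priors.normal_scale)))
        grad[sl["mu0"]] = dmu0 - u["mu0"] / ns2
        grad[sl["mu1"]] = dmu1 - u["mu1"] / ns2

        # ---- sex-effect level: n*_p ~ Normal(m_n*, s_n*) ----
        if self.centered["n"]:
            rn0 = (n0 - u["m_n0"]) / s_n0
            rn1 = (n1 - u["m_n1"]) / s_n1
            logp += (-0.5 * float(np.dot(rn0, rn0)) - 0.5 * float(np.dot(rn1, rn1))
                     - self.S * (u["lsn0"] + u["lsn1"]) - self.S * _LOG_2PI)
            grad[sl["n0"]] = dn0_s - rn0 / s_n0
            grad[sl["n1"]] = dn1_s - rn1 / s_n1
            dm_n0 = float(np.sum(rn0)) / s_n0
            dm_n1 = float(np.sum(rn1)) / s_n1
            dlsn0_level = float(np.dot(rn0, rn0)) - self.S
            dlsn1_level = float(np.dot(rn1, rn1)) - self.S
        else:
            v0, v1 = u["n0"], u["n1"]
            logp += (-0.5 * float(np.dot(v0, v0)) - 0.5 * float(np.dot(v1, v1))
                     - self.S * _LOG_2PI)
            grad[sl["n0"]] = -v0 + s_n0 * dn0_s
            grad[sl["n1"]] = -v1 + s_n1 * dn1_s
            dm_n0 = float(np.sum(dn0_s))
            dm_n1 = float(np.sum(dn1_s))
            dlsn0_level = s_n0 * float(np.dot(dn0_s, v0))
            dlsn1_level = s_n1 * float(np.dot(dn1_s, v1))

        logp += (-0.5 * (u["m_n0"] ** 2 + u["m_n1"] ** 2) / ns2
                 - 2 * (0.5 * _LOG_2PI + math.log(self.priors.normal_scale)))
        grad[sl["m_n0"]] = dm_n0 - u["m_n0"] / ns2
        grad[sl["m_n1"]] = dm_n1 - u["m_n1"] / ns2

        # ---- half-Cauchy priors on scales, with log-transform Jacobian ----
        def hc(sigma, log_sigma):
            lp = (math.log(2.0 / (math.pi * self.priors.cauchy_scale))
                  - math.log1p(sigma * sigma / cs2) + log_sigma)
            dlog = 1.0 - 2.0 * sigma * sigma / (cs2 + sigma * sigma)
            return lp, dlog

        for scale, lname, dlevel in (
            (tau0, "lt0", dlt0_level), (tau1, "lt1", dlt1_level),
            (sigma_w, "lsw", dlsw_lik),
            (s_n0, "lsn0", dlsn0_level), (s_n1, "lsn1", dlsn1_level),
        ):
            lp, d = hc(scale, u[lname])
            logp += lp
            grad[sl[lname]] = dlevel + d
        for sig, lname, dlevel in ((sigma0, "ls0", dls0_level),
                                   (sigma1, "ls1", dls1_level)):
            logp += float(np.sum(
                math.log(2.0 / (math.pi * self.priors.cauchy_scale))
                - np.log1p(sig * sig / cs2) + u[lname]
            ))
            grad[sl[lname]] = (
                dlevel + 1.0 - 2.0 * sig * sig / (cs2 + sig * sig)
            )
        return logp, grad

    # -- warmup helpers ---------------------------------------------------
    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """A starting point, at the empirical-Bayes estimates when available."""
        sl = self.slices
        q = 0.1 * rng.standard_normal(self.dim)
        eb = self.eb
        if eb is None:
            w_sd = max(self.md.w_sd, 0.1)
            q[sl["lsw"]] = math.log(w_sd) + 0.1 * rng.standard_normal()
            for name in ("lt0", "lt1", "lsn0", "lsn1"):
                q[sl[name]] = math.log(0.3) + 0.1 * rng.standard_normal()
            for name in ("ls0", "ls1"):
                n = sl[name].stop - sl[name].start
                q[sl[name]] = math.log(0.3) + 0.1 * rng.standard_normal(n)
            return q

        def logc(x):
            return np.log(np.clip(x, 1e-3, 10.0))

        jit = rng.standard_normal
        tau = np.clip(eb["tau"], 1e-3, 10.0)
        s_n = np.clip(eb["s_n"], 1e-3, 10.0)
        sigma = np.clip(eb["sigma"], 1e-3, 10.0)
        q[sl["lsw"]] = logc(eb["sigma_w"]) + 0.05 * jit()
        q[sl["lt0"]] = math.log(tau[0]) + 0.05 * jit()
        q[sl["lt1"]] = math.log(tau[1]) + 0.05 * jit()
        q[sl["lsn0"]] = math.log(s_n[0]) + 0.05 * jit()
        q[sl["lsn1"]] = math.log(s_n[1]) + 0.05 * jit()
        q[sl["ls0"]] = np.log(sigma[0]) + 0.05 * jit(self.C)
        q[sl["ls1"]] = np.log(sigma[1]) + 0.05 * jit(self.C)
        q[sl["mu0"]] = eb["mu_hat"][0] + 0.02 * jit(self.C)
        q[sl["mu1"]] = eb["mu_hat"][1] + 0.02 * jit(self.C)
        q[sl["m_n0"]] = eb["m_n"][0] + 0.02 * jit()
        q[sl["m_n1"]] = eb["m_n"][1] + 0.02 * jit()
        for k, name in ((0, "I0"), (1, "I1")):
            if self.centered["I"]:
                vals = eb["I_hat"][k] + 0.02 * jit((self.S, self.C))
            else:
                vals = np.clip(
                    (eb["I_hat"][k] - eb["mu_hat"][k][None, :])
                    / sigma[k][None, :], -2.0, 2.0,
                ) + 0.1 * jit((self.S, self.C))
            q[sl[name]] = vals.ravel()
        for k, name in ((0, "n0"), (1, "n1")):
            if self.centered["n"]:
                vals = eb["n_hat"][k] + 0.02 * jit(self.S)
            else:
                vals = np.clip(
                    (eb["n_hat"][k] - eb["m_n"][k]) / s_n[k], -2.0, 2.0,
                ) + 0.1 * jit(self.S)
            q[sl[name]] = vals
        bhat = np.einsum("jc,jc->j", eb["I_hat"][0][self.md.sp_idx], self.md.G), \
            np.einsum("jc,jc->j", eb["I_hat"][1][self.md.sp_idx], self.md.G)
        for k, name in ((0, "b0"), (1, "b1")):
            if self.centered["beta"]:
                vals = eb["b_ols"][:, k] + 0.02 * jit(self.J)
            else:
                vals = np.clip(
                    (eb["b_ols"][:, k] - bhat[k]) / tau[k], -2.0, 2.0,
                ) + 0.1 * jit(self.J)
            q[sl[name]] = vals
        return q

    def initial_inv_mass(self, q: np.ndarray) -> np.ndarray:
        """Approximate posterior variances (diagonal inverse mass) at ``q``.

        Gauss-Newton diagonal: likelihood curvature from the sufficient
        statistics propagated through the current parameterization, plus
        level-prior curvature. Gives warmup a well-conditioned starting
        metric; windowed adaptation refines it.
        """
        md = self.md
        u = self.unpack(q)
        sw2 = math.exp(2 * u["lsw"])
        tau0, tau1 = math.exp(u["lt0"]), math.exp(u["lt1"])
        s_n0, s_n1 = math.exp(u["lsn0"]), math.exp(u["lsn1"])
        sigma0, sigma1 = np.exp(u["ls0"]), np.exp(u["ls1"])
        ns2 = self.priors.normal_scale ** 2

        h_b0 = md.N.sum(axis=1) / sw2                       # (J,)
        h_b1 = md.Szz.sum(axis=1) / sw2
        h_n0 = np.add.reduceat(md.N[:, 1], md.sp_starts) / sw2    # (S,)
        h_n1 = np.add.reduceat(md.Szz[:, 1], md.sp_starts) / sw2
        g2 = md.G * md.G
        if self.prior_only:
            h_b0 = np.zeros(self.J)
            h_b1 = np.zeros(self.J)
            h_n0 = np.zeros(self.S)
            h_n1 = np.zeros(self.S)

        prec = np.ones(self.dim)
        sl = self.slices
        if self.centered["beta"]:
            prec[sl["b0"]] = h_b0 + 1.0 / tau0 ** 2
            prec[sl["b1"]] = h_b1 + 1.0 / tau1 ** 2
            # I sees beta only through the level prior
            h_bhat0 = np.full(self.J, 1.0 / tau0 ** 2)
            h_bhat1 = np.full(self.J, 1.0 / tau1 ** 2)
        else:
            prec[sl["b0"]] = 1.0 + tau0 ** 2 * h_b0
            prec[sl["b1"]] = 1.0 + tau1 ** 2 * h_b1
            h_bhat0 = h_b0
            h_bhat1 = h_b1
        h_i0 = np.add.reduceat(h_bhat0[:, None] * g2, md.sp_starts, axis=0)
        h_i1 = np.add.reduceat(h_bhat1[:, None] * g2, md.sp_starts, axis=0)
        if self.centered["I"]:
            prec[sl["I0"]] = (1.0 / sigma0[None, :] ** 2 + h_i0).ravel()
            prec[sl["I1"]] = (1.0 / sigma1[None, :] ** 2 + h_i1).ravel()
            prec[sl["mu0"]] = 1.0 / ns2 + self.S / sigma0 ** 2
            prec[sl["mu1"]] = 1.0 / ns2 + self.S / sigma1 ** 2
        else:
            prec[sl["I0"]] = (1.0 + sigma0[None, :] ** 2 * h_i0).ravel()
            prec[sl["I1"]] = (1.0 + sigma1[None, :] ** 2 * h_i1).ravel()
            prec[sl["mu0"]] = 1.0 / ns2 + h_i0.sum(axis=0)
            prec[sl["mu1"]] = 1.0 / ns2 + h_i1.sum(axis=0)
        if self.centered["n"]:
            prec[sl["n0"]] = 1.0 / s_n0 ** 2 + h_n0
            prec[sl["n1"]] = 1.0 / s_n1 ** 2 + h_n1
            prec[sl["m_n0"]] = 1.0 / ns2 + self.S / s_n0 ** 2
            prec[sl["m_n1"]] = 1.0 / ns2 + self.S / s_n1 ** 2
        else:
            prec[sl["n0"]] = 1.0 + s_n0 ** 2 * h_n0
            prec[sl["n1"]] = 1.0 + s_n1 ** 2 * h_n1
            prec[sl["m_n0"]] = 1.0 / ns2 + h_n0.sum()
            prec[sl["m_n1"]] = 1.0 / ns2 + h_n1.sum()
        prec[sl["lsw"]] = max(2.0, 2.0 * self.md.n_obs) if not self.prior_only else 2.0
        for name in ("lt0", "lt1"):
            prec[sl[name]] = max(2.0, 0.5 * self.J)
        for name in ("lsn0", "lsn1", "ls0", "ls1"):
            prec[sl[name]] = max(2.0, 0.5 * self.S)
        return 1.0 / prec


@dataclass
class PosteriorDraws:
    """Posterior draws of all model parameters, with provenance.

    ``draws`` maps parameter names to arrays whose first two axes are
    (chain, iteration): e.g. ``mu0`` is (chains, kept, C), ``I1`` is
    (chains, kept, S, C), ``beta0`` is (chains, kept, J).
    """

    draws: dict[str, np.ndarray]
    cells: list[tuple[str, int]]
    species: list[str]
    columns: list[str]
    spec: ModelSpec | None
    config: SamplerConfig
    diagnostics: dict = field(default_factory=dict)

    def get(self, name: str) -> np.ndarray:
        if name not in self.draws:
            raise KeyError(
                f"parameter {name!r} not in draws; have {sorted(self.draws)}"
            )
        return self.draws[name]

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains: shape (chain*iteration, ...)."""
        d = self.get(name)
        return d.reshape(d.shape[0] * d.shape[1], *d.shape[2:])

    @property
    def n_kept(self) -> int:
        first = next(iter(self.draws.values()))
        return first.shape[0] * first.shape[1]

    def save(self, path) -> None:
        """Serialize draws plus index metadata as grouped arrays (.npz)."""
        meta = {
            "cells_species": np.array([c[0] for c in self.cells]),
            "cells_year": np.array([c[1] for c in self.cells]),
            "species": np.array(self.species),
            "columns": np.array(self.columns),
        }
        np.savez_compressed(path, **self.draws, **meta)

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        """Rebuild draws (without sampler provenance) from a saved archive."""
        with np.load(path, allow_pickle=False) as arc:
            meta_keys = {"cells_species", "cells_year", "species", "columns"}
            draws = {k: arc[k] for k in arc.files if k not in meta_keys}
            cells = [(str(s), int(y)) for s, y in
                     zip(arc["cells_species"], arc["cells_year"])]
            n_ch, n_it = draws["mu0"].shape[:2]
            return cls(
                draws=draws, cells=cells,
                species=[str(s) for s in arc["species"]],
                columns=[str(c) for c in arc["columns"]],
                spec=None,
                config=SamplerConfig(n_chains=max(n_ch, 2),
                                     n_iterations=2 * n_it, n_warmup=n_it),
                diagnostics={"loaded_from": str(path)},
            )


def fit_robust(
    data: pd.DataFrame,
    G: CovariateTable,
    spec: ModelSpec | None = None,
    config: SamplerConfig = SamplerConfig(),
    priors: PriorConfig = PriorConfig(),
    *,
    max_retries: int = 2,
    **fit_kwargs,
) -> PosteriorDraws:
    """:func:`fit`, refitting on a failed convergence flag.

    Short-warmup NUTS adaptation occasionally misfires on hierarchical
    funnels (a stuck chain, inflated split-Rhat). The standard remedy is to
    rerun with a higher acceptance target; this wrapper does that once
    (by default) with a fresh derived seed, recording the retry count in the
    diagnostics. The retry decision keys on the convergence diagnostics
    only.
    """
    import dataclasses

    draws = fit(data, G, spec, config, priors, **fit_kwargs)
    retries = 0
    while not draws.diagnostics["converged"] and retries < max_retries:
        retries += 1
        config = dataclasses.replace(
            config,
            seed=(config.seed + 10_007 * retries) % (2 ** 31),
            target_accept=min(0.99, config.target_accept + 0.04),
        )
        logger.warning("refitting after convergence failure "
                       "(retry %d, target_accept %.2f)", retries,
                       config.target_accept)
        draws = fit(data, G, spec, config, priors, **fit_kwargs)
    draws.diagnostics["retries"] = retries
    return draws


def rhat(per_chain_draws: np.ndarray) -> float:
    """Split-chain potential scale reduction statistic.

    Input is (chains, iterations); each chain is split in half, and Rhat
    compares between- to within-split-chain variance. Returns +inf when any
    split chain has zero variance (degenerate input), not an exception.
    """
    x = np.asarray(per_chain_draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need (chains >= 2, iterations >= 4) draws")
    n = x.shape[1] // 2
    splits = np.concatenate([x[:, :n], x[:, x.shape[1] - n:]], axis=0)
    within = splits.var(axis=1, ddof=1)
    if np.any(within == 0):
        return math.inf
    w = within.mean()
    means = splits.mean(axis=1)
    b = n * means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


def _rhat_all(draws: dict[str, np.ndarray]) -> dict[str, float]:
    """Max split-Rhat over the scalar components of each parameter array."""
    out = {}
    for name, arr in draws.items():
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        worst = -math.inf
        for k in range(flat.shape[2]):
            worst = max(worst, rhat(flat[:, :, k]))
        out[name] = worst
    return out


def fit(
    data: pd.DataFrame,
    G: CovariateTable,
    spec: ModelSpec | None = None,
    config: SamplerConfig = SamplerConfig(),
    priors: PriorConfig = PriorConfig(),
    *,
    prior_only: bool = False,
    parameterization: str | dict = "auto",
) -> PosteriorDraws:
    """Sample the posterior of the allometry hierarchy with NUTS.

    ``data`` must have columns ``species, year, sex_code, z, w`` (one row per
    specimen of a single model population); ``G`` supplies one design row per
    species-year cell. Cells present on only one side are dropped with a
    warning. Draws are deterministic given ``config.seed``. Convergence
    problems (max Rhat above threshold, divergent transitions) complete with
    warnings and set ``diagnostics['converged'] = False``; they never fail
    silently.

    ``parameterization``: ``"auto"`` (per-level centered/non-centered chosen
    by an empirical-Bayes moment pre-pass), ``"centered"``,
    ``"noncentered"``, or a dict with boolean keys ``beta``, ``I``, ``n``.
    """
    md = _ModelData(data, G)
    eb = None
    if prior_only:
        centered = {"beta": False, "I": False, "n": False}
    elif isinstance(parameterization, dict):
        centered = {"beta": False, "I": False, "n": False}
        centered.update(parameterization)
        eb = _empirical_bayes(md)
    elif parameterization == "auto":
        eb = _empirical_bayes(md)
        centered = {k: eb[f"centered_{k}"] for k in ("beta", "I", "n")}
    elif parameterization in ("centered", "noncentered"):
        flag = parameterization == "centered"
        centered = {"beta": flag, "I": flag, "n": flag}
        eb = _empirical_bayes(md)
    else:
        raise ValueError(
            "parameterization must be 'auto', 'centered', 'noncentered' or a dict"
        )
    logger.info("parameterization: %s", centered)
    post = _LogPosterior(md, priors, prior_only=prior_only,
                         centered=centered, eb=eb)
    n_kept = config.n_iterations - config.n_warmup

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chain_results = []
    for ch in range(config.n_chains):
        rng = np.random.default_rng(seeds[ch])
        q0 = post.initial_point(rng)
        chain_results.append(
            sample_nuts(
                post.logp_and_grad, q0,
                n_iterations=config.n_iterations,
                n_warmup=config.n_warmup,
                rng=rng,
                target_accept=config.target_accept,
                max_treedepth=config.max_treedepth,
                inv_mass0=post.initial_inv_mass(q0),
            )
        )

    # unpack unconstrained draws into constrained parameter arrays
    names_shapes = {
        "beta0": (len(md.cells),), "beta1": (len(md.cells),),
        "n0": (len(md.species),), "n1": (len(md.species),),
        "I0": (len(md.species), len(md.columns)),
        "I1": (len(md.species), len(md.columns)),
        "mu0": (len(md.columns),), "mu1": (len(md.columns),),
        "sigma0": (len(md.columns),), "sigma1": (len(md.columns),),
        "tau0": (), "tau1": (), "sigma_w": (),
        "m_n0": (), "m_n1": (), "s_n0": (), "s_n1": (),
    }
    draws = {
        name: np.empty((config.n_chains, n_kept) + shape)
        for name, shape in names_shapes.items()
    }
    for ch, res in enumerate(chain_results):
        for it in range(n_kept):
            p = post.constrain(res.samples[it])
            for name in names_shapes:
                draws[name][ch, it] = getattr(p, name)

    rhats = _rhat_all(draws)
    max_rhat = max(rhats.values())
    n_div = sum(r.n_divergent for r in chain_results)
    converged = bool(max_rhat < config.rhat_threshold)
    if not converged:
        logger.warning("convergence flag: max split-Rhat %.3f exceeds %.3f",
                       max_rhat, config.rhat_threshold)
    if n_div > 0:
        logger.warning("%d divergent transition(s) after warmup", n_div)
    diagnostics = {
        "rhat": rhats,
        "max_rhat": float(max_rhat),
        "divergences": int(n_div),
        "converged": converged,
        "parameterization": centered,
        "step_sizes": [float(r.step_size) for r in chain_results],
        "mean_accept": [float(r.mean_accept) for r in chain_results],
        "mean_treedepth": [float(r.tree_depths[config.n_warmup:].mean())
                           for r in chain_results],
        "seed": int(config.seed),
    }
    return PosteriorDraws(
        draws=draws, cells=md.cells, species=md.species, columns=md.columns,
        spec=spec, config=config, diagnostics=diagnostics,
    )
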