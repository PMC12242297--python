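"""Bayesian errors-in-variables trend models for isotopic time series.

The observation model for a response ``Y`` (an amino-acid delta-15N value
or a trophic-minus-source difference, per mil) is

    Y_i = s(t_i) + beta1 * Z_i + eta_i + eps_i

where ``s`` is a smooth (P-spline) or linear function of calendar time,
``Z_i`` is the latent true fish size with a normal prior from osteometrics
(mean x_i, sd sigma_x_i), ``eta_i`` is the known per-observation machine
sd, and ``eps_i ~ N(0, sigma^2)`` is residual scatter. The true date t_i
is only known to lie in a dating window [t0_i, t1_i], uniform a priori.

Inference strategy: the latent sizes are Gaussian and enter linearly, so
they are marginalized exactly into the observation variance
(``eta_i^2 + sigma^2 + beta1^2 sigma_x_i^2``). For the linear model the
uniform latent time integrates in closed form (a difference of normal
CDFs), and for the P-spline model the spline coefficients are conjugate
Gaussian given the smoothing parameter. What remains is a posterior over
at most four hyperparameters, sampled with an affine-invariant ensemble
sampler (emcee) in several independent ensembles for convergence
diagnostics; exact conditional draws of the latent times, latent sizes
and spline coefficients are then reconstructed per posterior draw. This
yields draws from the same joint posterior as full MCMC over all latents,
without the dimensionality.

For the smooth model the latent times are not sampled (fixing them is
what makes the spline marginalization exact); instead
:func:`sensitivity_over_time_imputations` refits under different point
imputations of the dating windows and compares the conditional trends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import linalg, special

from .constants import PP_OFFSET, TEF_PRIOR_MEAN, TEF_PRIOR_SD, aa_column, aa_sd_column
from .splines import SplineBasis, build_spline_basis

logger = logging.getLogger(__name__)

__all__ = [
    "RESPONSES",
    "OFFSET_PROXIES",
    "TrendConfig",
    "ModelFit",
    "TrendPrediction",
    "SensitivityResult",
    "compute_response",
    "compute_responses",
    "fit_trend_gam",
    "fit_linear_eiv",
    "sensitivity_over_time_imputations",
    "refine_dating",
    "tp_transform",
    "predict_trend",
]

# response name -> (kind, constituent columns)
RESPONSES: dict[str, tuple[str, tuple[str, ...]]] = {
    "D15N_Glx_Phe": ("diff", ("Glx", "Phe")),
    "D15N_Glx_Lys": ("diff", ("Glx", "Lys")),
    "D15N_Pro_Phe": ("diff", ("Pro", "Phe")),
    "D15N_Pro_Lys": ("diff", ("Pro", "Lys")),
    "d15N_Phe": ("single", ("Phe",)),
    "d15N_Lys": ("single", ("Lys",)),
    "d15N_coll": ("bulk", ()),
}

#: Responses that are trophic-minus-source offsets, i.e. valid inputs to
#: the trophic-position transform.
OFFSET_PROXIES: tuple[str, ...] = tuple(
    name for name, (kind, _) in RESPONSES.items() if kind == "diff"
)


@dataclass
class TrendConfig:
    """Configuration for the errors-in-variables trend models.

    Prior scales are weakly informative on the per-mil scale of the
    (internally centred) response; ``prior_beta1_scale`` applies to the
    size slope per standard deviation of ETL, ``prior_beta0_scale`` to the
    linear time slope in per mil per year.
    """

    response: str = "D15N_Glx_Phe"
    k: int = 10
    penalty_order: int = 2
    prior_alpha_scale: float = 25.0
    prior_beta1_scale: float = 10.0
    prior_beta0_scale: float = 1.0
    prior_sigma_scale: float = 5.0
    prior_tau_scale: float = 5.0
    prior_null_scale: float = 25.0  # ridge on spline-coefficient null space
    machine_sd_column: str | None = None
    pp_offset: float = PP_OFFSET
    tef_mean: float = TEF_PRIOR_MEAN
    tef_sd: float = TEF_PRIOR_SD
    imputation: str = "midpoint"  # midpoint | t0 | t1 | random
    chains: int = 4
    walkers: int = 16
    warmup: int = 500
    steps: int = 500
    n_draws: int = 2000
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(
                f"unknown response {self.response!r}; one of {sorted(RESPONSES)}"
            )
        if self.k < 4:
            raise ValueError("basis dimension k must be at least 4")
        for name in (
            "prior_alpha_scale",
            "prior_beta1_scale",
            "prior_beta0_scale",
            "prior_sigma_scale",
            "prior_tau_scale",
            "prior_null_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tef_sd <= 0:
            raise ValueError("tef_sd must be positive")
        if self.imputation.split(":")[0] not in {"midpoint", "t0", "t1", "random"}:
            raise ValueError(f"unknown imputation strategy {self.imputation!r}")


def compute_response(record, response: str) -> tuple[float, float]:
    """Response value and machine sd for one specimen record.

    Differences combine the constituent machine sds in quadrature; single
    amino-acid and bulk responses pass their value and sd through.
    Missing constituents raise ``KeyError`` (table-level processing skips
    and logs such records instead, see :func:`compute_responses`).
    """
    kind, parts = RESPONSES[response]
    get = record.get if hasattr(record, "get") else record.__getitem__
    if kind == "bulk":
        val, sd = get("d15N_bulk"), get("d15N_bulk_sd", 0.0)
    elif kind == "single":
        val = get(aa_column(parts[0]))
        sd = get(aa_sd_column(parts[0]), 0.0)
    else:
        a, b = parts
        va, vb = get(aa_column(a)), get(aa_column(b))
        if va is None or vb is None or pd.isna(va) or pd.isna(vb):
            raise KeyError(f"missing constituent for {response}")
        val = va - vb
        sd = float(
            np.hypot(get(aa_sd_column(a), 0.0) or 0.0, get(aa_sd_column(b), 0.0) or 0.0)
        )
    if val is None or pd.isna(val):
        raise KeyError(f"missing value for {response}")
    return float(val), float(0.0 if sd is None or pd.isna(sd) else sd)


def compute_responses(records: pd.DataFrame, response: str,
                      machine_sd_column: str | None = None) -> pd.DataFrame:
    """Per-record response values; records with missing constituents are
    dropped with a logged reason. Returns columns ``y`` and ``eta_sd``."""
    rows, dropped = {}, []
    for idx, row in records.iterrows():
        try:
            val, sd = compute_response(row, response)
        except KeyError as err:
            dropped.append((idx, str(err)))
            continue
        if machine_sd_column is not None and pd.notna(row.get(machine_sd_column)):
            sd = float(row[machine_sd_column])
        rows[idx] = (val, sd)
    if dropped:
        logger.info(
            "compute_responses(%s): skipped %d records (%s ...)",
            response, len(dropped), dropped[0][1],
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=["y", "eta_sd"])


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class _PreparedData:
    index: pd.Index
    y: np.ndarray          # centred response
    y_mean: float
    eta: np.ndarray        # machine sd per record
    t0: np.ndarray
    t1: np.ndarray
    zbar: np.ndarray       # standardized size prior mean
    sigma_z: np.ndarray    # standardized size prior sd
    size_center: float
    size_scale: float
    records: pd.DataFrame


def _prepare(records: pd.DataFrame, config: TrendConfig) -> _PreparedData:
    for col in ("t0", "t1", "etl_mean"):
        if col not in records.columns:
            raise ValueError(f"records lack required column {col!r}")
    resp = compute_responses(records, config.response, config.machine_sd_column)
    df = records.loc[resp.index].copy()
    df["y"], df["eta_sd"] = resp["y"], resp["eta_sd"]
    ok = df[["y", "t0", "t1", "etl_mean"]].notna().all(axis=1)
    df = df.loc[ok]
    if (df["t1"] < df["t0"]).any():
        raise ValueError("dating windows with t1 < t0")
    if df["etl_mean"].isna().all() or len(df) == 0:
        raise ValueError("all specimen sizes missing")
    if len(df) < 10:
        raise ValueError(f"need at least 10 usable records, got {len(df)}")
    etl_sd = df["etl_sd"].fillna(0.0).to_numpy(float) if "etl_sd" in df else np.zeros(len(df))
    size = df["etl_mean"].to_numpy(float)
    center = float(size.mean())
    scale = float(size.std(ddof=0)) or 1.0
    y = df["y"].to_numpy(float)
    y_mean = float(y.mean())
    return _PreparedData(
        index=df.index,
        y=y - y_mean,
        y_mean=y_mean,
        eta=df["eta_sd"].to_numpy(float),
        t0=df["t0"].to_numpy(float),
        t1=df["t1"].to_numpy(float),
        zbar=(size - center) / scale,
        sigma_z=etl_sd / scale,
        size_center=center,
        size_scale=scale,
        records=df,
    )


def _impute_times(d: _PreparedData, strategy: str, seed: int) -> np.ndarray:
    base = strategy.split(":")[0]
    if base == "midpoint":
        return (d.t0 + d.t1) / 2
    if base == "t0":
        return d.t0.copy()
    if base == "t1":
        return d.t1.copy()
    if base == "random":
        tag = strategy.split(":")[1] if ":" in strategy else "0"
        rng = np.random.default_rng([seed % (2**31), abs(hash(tag)) % (2**31)])
        return rng.uniform(d.t0, d.t1)
    raise ValueError(f"unknown imputation strategy {strategy!r}")


# ---------------------------------------------------------------------------
# posterior containers


@dataclass
class ModelFit:
    """Posterior draws and diagnostics from a trend-model fit."""

    kind: str                       # "gam" | "linear"
    response: str
    posterior: dict[str, np.ndarray]
    diagnostics: pd.DataFrame       # parameter, rhat, ess
    diagnostics_failed: bool
    config: TrendConfig
    data: _PreparedData
    basis: SplineBasis | None = None
    times: np.ndarray | None = None  # imputed times (gam)
    t_ref: float = 0.0               # time centring (linear)

    @property
    def n_draws(self) -> int:
        return len(self.posterior["sigma"])

    @property
    def time_span(self) -> tuple[float, float]:
        if self.kind == "gam":
            return self.basis.domain
        mid = (self.data.t0 + self.data.t1) / 2
        return float(mid.min()), float(mid.max())

    def curve_draws(self, times) -> np.ndarray:
        """Draws of the trend s(t) at mean size (n_draws x len(times))."""
        t = np.asarray(times, dtype=float)
        if self.kind == "gam":
            B = self.basis.design(t)
            out = self.posterior["alpha"][:, None] + self.posterior["b"] @ B.T
        else:
            out = (
                self.posterior["alpha"][:, None]
                + self.posterior["beta0"][:, None] * (t - self.t_ref)[None, :]
            )
        return out + self.data.y_mean

    def draws_dataframe(self) -> pd.DataFrame:
        """Scalar-parameter draws as a table (for serialization)."""
        cols = {
            name: draws
            for name, draws in self.posterior.items()
            if np.ndim(draws) == 1
        }
        return pd.DataFrame(cols)


def _halfnormal_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return -0.5 * (x / scale) ** 2


def _run_ensembles(
    log_prob: Callable[[np.ndarray], np.ndarray],
    init_center: np.ndarray,
    init_scale: np.ndarray,
    config: TrendConfig,
    param_names: Sequence[str],
) -> tuple[dict[str, np.ndarray], pd.DataFrame, bool]:
    """Run independent emcee ensembles; return flat draws + diagnostics.

    Each "chain" is a separate ensemble started from its own seed; R-hat
    and effective sample size are computed across ensembles, which are
    genuinely independent (walkers within one ensemble are coupled by the
    affine-invariant moves and are not treated as chains).
    """
    ndim = len(init_center)
    per_chain = max(config.n_draws // config.chains, 1)
    chains = []
    for c in range(config.chains):
        rs = np.random.RandomState((config.seed + 7919 * c) % (2**31))
        p0 = init_center + init_scale * rs.randn(config.walkers, ndim)
        sampler = emcee.EnsembleSampler(
            config.walkers, ndim, log_prob, vectorize=True
        )
        state = emcee.State(p0, random_state=rs.get_state())
        sampler.run_mcmc(state, config.warmup + config.steps, progress=False)
        chain = sampler.get_chain(discard=config.warmup)  # (steps, walkers, ndim)
        # thin over steps but keep the whole ensemble at each kept step:
        # walkers at one step are near-independent, successive steps are not
        n_keep_steps = max(per_chain // config.walkers, 1)
        step_idx = np.linspace(0, chain.shape[0] - 1, n_keep_steps).astype(int)
        flat = chain[step_idx].reshape(-1, ndim)
        chains.append(flat[:per_chain] if len(flat) >= per_chain else flat)
    arr = np.stack(chains)  # (chains, per_chain, ndim)
    post = az.from_dict(
        posterior={name: arr[:, :, j] for j, name in enumerate(param_names)}
    )
    rhat = az.rhat(post)
    ess = az.ess(post)
    diag = pd.DataFrame(
        {
            "parameter": list(param_names),
            "rhat": [float(rhat[n].values) for n in param_names],
            "ess": [float(ess[n].values) for n in param_names],
        }
    )
    failed = bool(
        (diag["rhat"] > config.rhat_threshold).any()
        or (diag["ess"] < config.ess_threshold).any()
    )
    flat_all = arr.reshape(-1, ndim)
    draws = {name: flat_all[:, j].copy() for j, name in enumerate(param_names)}
    return draws, diag, failed


def _draw_latent_sizes(
    rng: np.random.Generator,
    d: _PreparedData,
    resid: np.ndarray,      # (ndraw, n): y - alpha - trend part
    beta1: np.ndarray,      # (ndraw,)
    sigma: np.ndarray,      # (ndraw,)
) -> np.ndarray:
    """Exact conditional draws of the latent (standardized) sizes."""
    e_var = sigma[:, None] ** 2 + d.eta[None, :] ** 2
    with np.errstate(divide="ignore"):
        prior_prec = np.where(d.sigma_z > 0, 1.0 / d.sigma_z**2, np.inf)[None, :]
    lik_prec = beta1[:, None] ** 2 / e_var
    post_prec = prior_prec + lik_prec
    num = np.where(
        np.isinf(prior_prec),
        0.0,
        d.zbar[None, :] * prior_prec,
    ) + beta1[:, None] * resid / e_var
    exact = np.isinf(prior_prec)
    mean = np.where(exact, d.zbar[None, :], num / post_prec)
    sd = np.where(exact, 0.0, 1.0 / np.sqrt(post_prec))
    return mean + sd * rng.standard_normal(mean.shape)


# ---------------------------------------------------------------------------
# the P-spline (GAM) model


def fit_trend_gam(records: pd.DataFrame, config: TrendConfig) -> ModelFit:
    """Fit the Bayesian P-spline errors-in-variables trend model.

    Times are fixed by the configured imputation strategy (the spline
    coefficients are then conjugate and can be marginalized exactly);
    latent sizes are marginalized into the observation variance. The
    sampled hyperparameters are (alpha, beta1, log sigma, log tau), where
    tau is the random-walk scale of the penalized coefficients (large tau
    = wiggly, small tau = smooth).

    The returned fit carries per-parameter R-hat / ESS; if any diagnostic
    misses its configured threshold, ``diagnostics_failed`` is set and a
    warning is logged — the fit never fails silently.
    """
    d = _prepare(records, config)
    t_imp = _impute_times(d, config.imputation, config.seed)
    if np.ptp(t_imp) <= 0:
        raise ValueError("degenerate time span after imputation")
    B, S, basis = build_spline_basis(t_imp, config.k, config.penalty_order)
    lam_S, _ = np.linalg.eigh(S)
    lam_S = np.clip(lam_S, 0, None)
    k = config.k
    c2 = config.prior_null_scale**2
    y, eta, zbar, sz = d.y, d.eta, d.zbar, d.sigma_z
    n = len(y)

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        out = np.empty(len(theta))
        for w, (alpha, beta1, log_sigma, log_tau) in enumerate(theta):
            if abs(log_sigma) > 15 or abs(log_tau) > 15:
                out[w] = -np.inf
                continue
            sigma, tau = np.exp(log_sigma), np.exp(log_tau)
            v = eta**2 + sigma**2 + (beta1 * sz) ** 2
            W = 1.0 / v
            r = y - alpha - beta1 * zbar
            K = S / tau**2 + np.eye(k) / c2
            M = K + (B.T * W) @ B
            try:
                cho = linalg.cho_factor(M, lower=True)
            except linalg.LinAlgError:
                out[w] = -np.inf
                continue
            u = B.T @ (W * r)
            quad = float(r @ (W * r) - u @ linalg.cho_solve(cho, u))
            logdet_K = float(np.sum(np.log(lam_S / tau**2 + 1.0 / c2)))
            logdet_M = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
            ll = -0.5 * (quad + np.sum(np.log(v)) + logdet_M - logdet_K + n * np.log(2 * np.pi))
            lp = (
                -0.5 * (alpha / config.prior_alpha_scale) ** 2
                - 0.5 * (beta1 / config.prior_beta1_scale) ** 2
                + _halfnormal_logpdf(sigma, config.prior_sigma_scale) + log_sigma
                + _halfnormal_logpdf(tau, config.prior_tau_scale) + log_tau
            )
            out[w] = ll + lp
        return out

    sd_y = float(np.std(y)) or 1.0
    init = np.array([0.0, 0.0, np.log(0.5 * sd_y), np.log(sd_y)])
    scale = np.array([0.1 * sd_y, 0.1, 0.2, 0.2])
    draws, diag, failed = _run_ensembles(
        log_prob, init, scale, config, ["alpha", "beta1", "log_sigma", "log_tau"]
    )
    if failed:
        logger.warning(
            "fit_trend_gam(%s): CONVERGENCE DIAGNOSTICS FAILED\n%s",
            config.response, diag.to_string(index=False),
        )

    alpha, beta1 = draws["alpha"], draws["beta1"]
    sigma, tau = np.exp(draws["log_sigma"]), np.exp(draws["log_tau"])
    rng = np.random.default_rng((config.seed + 104729) % (2**31))

    # exact conditional draws of the spline coefficients
    ndraw = len(alpha)
    b = np.empty((ndraw, k))
    for j in range(ndraw):
        v = eta**2 + sigma[j] ** 2 + (beta1[j] * sz) ** 2
        W = 1.0 / v
        r = y - alpha[j] - beta1[j] * zbar
        K = S / tau[j] ** 2 + np.eye(k) / c2
        M = K + (B.T * W) @ B
        L = np.linalg.cholesky(M)
        mean = linalg.cho_solve((L, True), B.T @ (W * r))
        b[j] = mean + linalg.solve_triangular(L, rng.standard_normal(k), lower=True, trans="T")

    resid = y[None, :] - alpha[:, None] - b @ B.T
    z = _draw_latent_sizes(rng, d, resid, beta1, sigma)
    posterior = {
        "alpha": alpha,
        "beta1": beta1 / d.size_scale,  # per mm
        "beta1_std": beta1,             # per sd of ETL
        "sigma": sigma,
        "tau": tau,
        "b": b,
        "Z": d.size_center + d.size_scale * z,
    }
    return ModelFit(
        kind="gam",
        response=config.response,
        posterior=posterior,
        diagnostics=diag,
        diagnostics_failed=failed,
        config=config,
        data=d,
        basis=basis,
        times=t_imp,
    )


# ---------------------------------------------------------------------------
# the linear model with fully latent times


def fit_linear_eiv(records: pd.DataFrame, config: TrendConfig) -> ModelFit:
    """Fit the linear errors-in-variables model with fully latent times.

    ``Y_i ~ N(alpha + beta0 t_i + beta1 Z_i, eta_i^2 + sigma^2)`` with
    ``t_i ~ U(t0_i, t1_i)`` and ``Z_i ~ N(x_i, sigma_x_i^2)``. Both latent
    vectors are marginalized in closed form, the four remaining
    hyperparameters are sampled, and exact conditional draws of t_i (a
    truncated normal on the window) and Z_i are reconstructed per
    posterior draw — so the full posterior, including per-specimen dates,
    is available (see :func:`refine_dating`).
    """
    d = _prepare(records, config)
    t_ref = float(((d.t0 + d.t1) / 2).mean())
    a_c, b_c = d.t0 - t_ref, d.t1 - t_ref
    y, eta, zbar, sz = d.y, d.eta, d.zbar, d.sigma_z

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        out = np.empty(len(theta))
        for w, (alpha, beta0, beta1, log_sigma) in enumerate(theta):
            if abs(log_sigma) > 15:
                out[w] = -np.inf
                continue
            sigma = np.exp(log_sigma)
            v = eta**2 + sigma**2 + (beta1 * sz) ** 2
            s = np.sqrt(v)
            mu0 = alpha + beta1 * zbar
            ll_i = _log_window_integral_density(y, mu0, beta0, a_c, b_c, s)
            if not np.all(np.isfinite(ll_i)):
                out[w] = -np.inf
                continue
            lp = (
                -0.5 * (alpha / config.prior_alpha_scale) ** 2
                - 0.5 * (beta0 / config.prior_beta0_scale) ** 2
                - 0.5 * (beta1 / config.prior_beta1_scale) ** 2
                + _halfnormal_logpdf(sigma, config.prior_sigma_scale) + log_sigma
            )
            out[w] = float(np.sum(ll_i)) + lp
        return out

    sd_y = float(np.std(y)) or 1.0
    init = np.array([0.0, 0.0, 0.0, np.log(0.5 * sd_y)])
    scale = np.array([0.1 * sd_y, 1e-4, 0.1, 0.2])
    draws, diag, failed = _run_ensembles(
        log_prob, init, scale, config, ["alpha", "beta0", "beta1", "log_sigma"]
    )
    if failed:
        logger.warning(
            "fit_linear_eiv(%s): CONVERGENCE DIAGNOSTICS FAILED\n%s",
            config.response, diag.to_string(index=False),
        )
    alpha, beta0, beta1 = draws["alpha"], draws["beta0"], draws["beta1"]
    sigma = np.exp(draws["log_sigma"])
    rng = np.random.default_rng((config.seed + 224737) % (2**31))

    t = _draw_latent_times(rng, y, alpha, beta0, beta1, sigma, eta, zbar, sz, a_c, b_c)
    assert np.all(t >= a_c[None, :] - 1e-6) and np.all(t <= b_c[None, :] + 1e-6), (
        "latent time draw escaped its dating window"
    )
    t = np.clip(t, a_c[None, :], b_c[None, :])
    resid = y[None, :] - alpha[:, None] - beta0[:, None] * t
    z = _draw_latent_sizes(rng, d, resid, beta1, sigma)
    posterior = {
        "alpha": alpha,
        "beta0": beta0,
        "beta1": beta1 / d.size_scale,
        "beta1_std": beta1,
        "sigma": sigma,
        "t": t + t_ref,
        "Z": d.size_center + d.size_scale * z,
    }
    return ModelFit(
        kind="linear",
        response=config.response,
        posterior=posterior,
        diagnostics=diag,
        diagnostics_failed=failed,
        config=config,
        data=d,
        t_ref=t_ref,
    )


def _log_window_integral_density(y, mu0, beta0, t0, t1, s):
    """Stable log marginal density of y with t integrated over its window."""
    width = t1 - t0
    flat = (np.abs(beta0) * width) < (1e-6 * s)
    g0 = (y - mu0 - beta0 * np.where(flat, 0.0, t0)) / s
    g1 = (y - mu0 - beta0 * np.where(flat, 0.0, t1)) / s
    hi, lo = np.maximum(g0, g1), np.minimum(g0, g1)
    with np.errstate(divide="ignore", invalid="ignore"):
        upper = np.where(lo > 0, special.log_ndtr(-lo), special.log_ndtr(hi))
        lower = np.where(lo > 0, special.log_ndtr(-hi), special.log_ndtr(lo))
        diff = np.exp(np.clip(lower - upper, None, 0.0))
        logdiff = upper + np.log1p(-np.minimum(diff, 1 - 1e-300))
        denom = np.where(flat, 1.0, np.abs(beta0) * width)
        out = logdiff - np.log(denom)
    mid = (t0 + t1) / 2
    gm = (y - mu0 - beta0 * mid) / s
    out_flat = -0.5 * gm**2 - np.log(s * np.sqrt(2 * np.pi))
    return np.where(flat, out_flat, out)


def _draw_latent_times(rng, y, alpha, beta0, beta1, sigma, eta, zbar, sz, t0, t1):
    """Exact conditional draws of latent times (truncated normal on window)."""
    ndraw, n = len(alpha), len(y)
    v = sigma[:, None] ** 2 + eta[None, :] ** 2 + (beta1[:, None] * sz[None, :]) ** 2
    s = np.sqrt(v)
    width = (t1 - t0)[None, :]
    u = rng.random((ndraw, n))
    b0 = beta0[:, None]
    flat = np.abs(b0) * width < 1e-6 * s
    safe_b0 = np.where(np.abs(b0) > 0, b0, 1.0)
    loc = (y[None, :] - alpha[:, None] - beta1[:, None] * zbar[None, :]) / safe_b0
    scl = s / np.abs(safe_b0)
    lo = (t0[None, :] - loc) / scl
    hi = (t1[None, :] - loc) / scl
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    Flo, Fhi = special.ndtr(lo), special.ndtr(hi)
    mass = Fhi - Flo
    degenerate = flat | (mass < 1e-12) | (width == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = special.ndtri(Flo + u * mass)
        t = loc + scl * q
    t_uniform = t0[None, :] + u * width
    t = np.where(degenerate, t_uniform, t)
    return np.clip(t, t0[None, :], t1[None, :])


# ---------------------------------------------------------------------------
# derived quantities


def refine_dating(fit: ModelFit) -> pd.DataFrame:
    """Posterior dating summaries per specimen from a linear EIV fit.

    The sharpening ratio divides the posterior sd of the latent date by
    the prior (uniform-window) sd ``(t1 - t0) / sqrt(12)``; ratios below 1
    mean the trend carried usable chronological information.
    """
    if "t" not in fit.posterior:
        raise ValueError("fit has no latent time draws (need fit_linear_eiv)")
    t = fit.posterior["t"]
    d = fit.data
    prior_sd = (d.t1 - d.t0) / np.sqrt(12.0)
    post_sd = t.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(prior_sd > 0, post_sd / prior_sd, 1.0)
    out = pd.DataFrame(
        {
            "t0": d.t0,
            "t1": d.t1,
            "t_post_mean": t.mean(axis=0),
            "t_post_sd": post_sd,
            "t_q2_5": np.quantile(t, 0.025, axis=0),
            "t_q97_5": np.quantile(t, 0.975, axis=0),
            "prior_sd": prior_sd,
            "sharpening": ratio,
        },
        index=d.index,
    )
    if "specimen_id" in d.records.columns:
        out.insert(0, "specimen_id", d.records["specimen_id"].to_numpy())
    return out


def tp_transform(
    response_draws,
    pp_offset: float = PP_OFFSET,
    tef_mean: float = TEF_PRIOR_MEAN,
    tef_sd: float = TEF_PRIOR_SD,
    rng: np.random.Generator | int | None = None,
    response: str | None = None,
    tef_draws=None,
) -> np.ndarray:
    """Transform trophic-minus-source draws to trophic-position draws.

    ``TP = (Y - pp_offset) / TEF + 1`` with one TEF draw per posterior
    draw; TEF draws come from the configured normal prior truncated at
    zero (``tef_draws`` can supply fixed values instead). When the source
    ``response`` name is given it must be an offset proxy — applying the
    transform to a pure source or bulk response is refused.
    """
    if response is not None and response not in OFFSET_PROXIES:
        raise ValueError(
            f"response {response!r} is not a trophic-source offset proxy; "
            f"TP transform applies only to {OFFSET_PROXIES}"
        )
    y = np.asarray(response_draws, dtype=float)
    ndraw = y.shape[0]
    if tef_draws is None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        # truncated-normal draws via inverse CDF, truncation at zero
        lo = special.ndtr(-tef_mean / tef_sd)
        u = lo + rng.random(ndraw) * (1 - lo)
        tef = tef_mean + tef_sd * special.ndtri(u)
    else:
        tef = np.broadcast_to(np.asarray(tef_draws, dtype=float), (ndraw,))
        if (tef <= 0).any():
            raise ValueError("TEF draws must be positive")
    shape = (ndraw,) + (1,) * (y.ndim - 1)
    return (y - pp_offset) / tef.reshape(shape) + 1.0


@dataclass
class TrendPrediction:
    """Posterior trend of a response (and TP where applicable) on a grid."""

    times: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    fixed_size: float
    extrapolated: np.ndarray
    tp_mean: np.ndarray | None = None
    tp_lower: np.ndarray | None = None
    tp_upper: np.ndarray | None = None

    @property
    def frame(self) -> pd.DataFrame:
        d = {
            "t": self.times,
            "mean": self.mean,
            "q2_5": self.lower,
            "q97_5": self.upper,
            "extrapolated": self.extrapolated,
        }
        if self.tp_mean is not None:
            d.update(tp_mean=self.tp_mean, tp_q2_5=self.tp_lower, tp_q97_5=self.tp_upper)
        return pd.DataFrame(d)


def predict_trend(
    fit: ModelFit, times, fixed_size: float | None = None
) -> TrendPrediction:
    """Posterior trend on a time grid at a fixed fish size.

    Evaluates ``s(t) + beta1 * size`` per posterior draw and summarizes
    (mean, 2.5%, 97.5%). ``fixed_size`` defaults to the sample mean ETL.
    When the response is a trophic-source offset, trophic-position
    summaries via :func:`tp_transform` are attached (one TEF draw per
    posterior draw). Grid points beyond the observed span are flagged.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty prediction grid")
    lo, hi = fit.time_span
    extrapolated = (t < lo) | (t > hi)
    if fixed_size is None:
        z_fixed = 0.0
        fixed_size = fit.data.size_center
    else:
        z_fixed = (fixed_size - fit.data.size_center) / fit.data.size_scale
    draws = fit.curve_draws(t) + np.outer(fit.posterior["beta1_std"], np.full(t.size, z_fixed))
    pred = TrendPrediction(
        times=t,
        mean=draws.mean(axis=0),
        lower=np.quantile(draws, 0.025, axis=0),
        upper=np.quantile(draws, 0.975, axis=0),
        fixed_size=float(fixed_size),
        extrapolated=extrapolated,
    )
    if fit.response in OFFSET_PROXIES:
        cfg = fit.config
        tp = tp_transform(
            draws,
            pp_offset=cfg.pp_offset,
            tef_mean=cfg.tef_mean,
            tef_sd=cfg.tef_sd,
            rng=np.random.default_rng((cfg.seed + 50021) % (2**31)),
        )
        pred.tp_mean = tp.mean(axis=0)
        pred.tp_lower = np.quantile(tp, 0.025, axis=0)
        pred.tp_upper = np.quantile(tp, 0.975, axis=0)
    return pred


@dataclass
class SensitivityResult:
    """Comparison of trend fits across time-imputation strategies."""

    table: pd.DataFrame          # strategy, t, mean, q2_5, q97_5
    divergent: bool              # any pair of mean curves separated beyond band
    max_gap_ratio: float         # worst |mean_a - mean_b| / pooled half-width
    fits: dict[str, ModelFit] = field(default_factory=dict, repr=False)


def sensitivity_over_time_imputations(
    records: pd.DataFrame,
    config: TrendConfig,
    n_random: int = 5,
    grid: np.ndarray | None = None,
    strategies: Sequence[str] | None = None,
) -> SensitivityResult:
    """Refit the smooth trend under different point imputations of time.

    Default strategies: window midpoint, early edge (t0), late edge (t1),
    and ``n_random`` independent uniform draws per window. The divergence
    flag is raised when two strategies' posterior mean curves differ, at
    any grid point, by more than the pooled 95% credible half-width —
    i.e. when dating uncertainty alone can move the trend beyond its own
    uncertainty band.
    """
    if strategies is None:
        strategies = ["midpoint", "t0", "t1"] + [f"random:{i}" for i in range(n_random)]
    if not strategies:
        raise ValueError("strategy list is empty")
    fits: dict[str, ModelFit] = {}
    for strat in strategies:
        fits[strat] = fit_trend_gam(records, replace(config, imputation=strat))
    if grid is None:
        lo = min(f.time_span[0] for f in fits.values())
        hi = max(f.time_span[1] for f in fits.values())
        grid = np.linspace(lo, hi, 50)
    blocks, means, halfw = [], {}, []
    for strat, f in fits.items():
        pred = predict_trend(f, grid)
        blocks.append(
            pd.DataFrame(
                {
                    "strategy": strat,
                    "t": grid,
                    "mean": pred.mean,
                    "q2_5": pred.lower,
                    "q97_5": pred.upper,
                }
            )
        )
        means[strat] = pred.mean
        halfw.append((pred.upper - pred.lower) / 2)
    pooled = np.mean(halfw, axis=0)
    max_ratio = 0.0
    names = list(means)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.abs(means[a] - means[b]) / pooled
            max_ratio = max(max_ratio, float(np.nanmax(ratio)))
    return SensitivityResult(
        table=pd.concat(blocks, ignore_index=True),
        divergent=max_ratio > 1.0,
        max_gap_ratio=max_ratio,
        fits=fits,
    )
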