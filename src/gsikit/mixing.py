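"""Haul-level binomial models of mixing proportions.

Five nested models of the eastern-fish count ``East_ip ~ Binomial(pi_ip,
N_ip)`` with ``logit(pi_ip)`` built from standardized salinity, oxygen
and temperature plus, per model:

* M0 -- covariates only
* M1 -- + Area factor (west/east of the 13 deg E assessment split)
* M2 -- + Juvenile factor
* M3 -- + shared second-order random-walk smoother over longitude knots
* M4 -- + life-stage-specific second-order random-walk smoothers

All models carry an exchangeable Gaussian random intercept per haul --
a deliberate simplification of a period-replicated Matern spatial field
-- and are fitted in a Bayesian framework by a nested Laplace
approximation: for fixed hyperparameters (smoother precision, random-
intercept scale) the latent field (fixed effects, knot values, random
intercepts) has a concave log posterior whose mode is found by Newton
iteration with an analytic Hessian; the hyperparameters are then
optimized over the Laplace-approximate marginal posterior, and the
final posterior is represented by Gaussian draws of the latent field
taken at a small set of hyperparameter nodes weighted by the marginal
density (a coarse central-composite integration, INLA-like).  The
joint mode over latents *and* log-scales is deliberately avoided: it
does not exist (the well-known funnel -- the joint density is unbounded
as the random-effect scale goes to zero).  WAIC is computed from the
stored draws.  Smoothers use a second-order difference penalty and a
soft sum-to-zero constraint (joint across the two stage smoothers in
M4, which leaves the stage offset identifiable through the smoothers
themselves).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp
from statsmodels.stats.proportion import proportion_confint

log = logging.getLogger(__name__)

__all__ = [
    "MODELS",
    "HaulObservation",
    "StandardizedCovariate",
    "MixingConfig",
    "MixingModelFit",
    "standardize",
    "aggregate_hauls",
    "fit_mixing_model",
    "compute_waic",
    "compare_models",
    "predict_longitude_profile",
    "before_after_comparison",
]

MODELS = ("M0", "M1", "M2", "M3", "M4")
COVARIATES = ("salinity", "oxygen", "temperature")
STAGES = ("adult", "juvenile")
AREA_WEST = "west_of_13E"
AREA_EAST = "east_of_13E"


@dataclass
class HaulObservation:
    haul_id: str
    period_id: str
    east_count: int
    n_fish: int
    utm_x: float
    area: str
    life_stage: str
    salinity: float
    oxygen: float
    temperature: float

    def __post_init__(self) -> None:
        if self.n_fish < 1:
            raise ValueError(f"haul {self.haul_id}: n_fish must be >= 1")
        if not (0 <= self.east_count <= self.n_fish):
            raise ValueError(f"haul {self.haul_id}: need 0 <= east_count <= n_fish")
        if not self.period_id:
            raise ValueError(f"haul {self.haul_id}: empty period_id")
        if self.life_stage not in STAGES:
            raise ValueError(f"haul {self.haul_id}: unknown life stage {self.life_stage!r}")


def hauls_to_frame(data: Sequence[HaulObservation] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data.reset_index(drop=True).copy()
    return pd.DataFrame([vars(h) for h in data])


@dataclass
class StandardizedCovariate:
    values: np.ndarray
    original_mean: float
    original_sd: float


def standardize(x: Iterable[float]) -> StandardizedCovariate:
    """(x - mean) / sd with the sample (ddof=1) standard deviation.

    The mean and sd are retained so that predictions made at
    standardized values can be mapped back to data units."""
    arr = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values to standardize")
    if not np.all(np.isfinite(arr)):
        raise ValueError("covariate contains non-finite values")
    mu = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0:
        raise ValueError("constant covariate cannot be standardized")
    return StandardizedCovariate((arr - mu) / sd, mu, sd)


# ---------------------------------------------------------------------
# haul aggregation
# ---------------------------------------------------------------------


def aggregate_hauls(
    assignments,
    metadata: pd.DataFrame,
    east_label: str = "east",
    juvenile_length_cm: float = 20.0,
    area_split: float = 13.0,
) -> list[HaulObservation]:
    """Build per-(haul, life stage) binomial observations from individual
    assignments plus per-individual metadata.

    Ambiguous/unusable assignments are excluded.  Life stage comes from
    an explicit ``life_stage`` column when present, then a ``maturity``
    record, then the length rule (fish shorter than ``juvenile_length_cm``
    are juveniles).  Hauls with zero usable fish are dropped with a log
    entry."""
    meta = metadata.set_index("individual_id")
    assigned = {a.individual_id: a.assigned for a in assignments}
    missing = [i for i in assigned if i not in meta.index]
    if missing:
        raise KeyError(f"individuals missing metadata: {missing[:5]}")

    rows = []
    for ind, lab in assigned.items():
        if lab in ("ambiguous", "unusable"):
            continue
        m = meta.loc[ind]
        stage = None
        if "life_stage" in meta.columns and isinstance(m.get("life_stage"), str) and m["life_stage"]:
            stage = m["life_stage"]
        elif "maturity" in meta.columns and isinstance(m.get("maturity"), str) and m["maturity"]:
            stage = "adult" if m["maturity"] in ("mature", "spawning", "adult") else "juvenile"
        elif "length_cm" in meta.columns and np.isfinite(m.get("length_cm", np.nan)):
            stage = "juvenile" if m["length_cm"] < juvenile_length_cm else "adult"
        if stage not in STAGES:
            raise ValueError(f"cannot determine life stage for individual {ind}")
        rows.append(
            {
                "haul_id": str(m["haul_id"]),
                "period_id": str(m["period_id"]),
                "utm_x": float(m["utm_x"]),
                "life_stage": stage,
                "east": int(lab == east_label),
                "salinity": float(m["salinity"]),
                "oxygen": float(m["oxygen"]),
                "temperature": float(m["temperature"]),
                "area": m["area"]
                if "area" in meta.columns and isinstance(m.get("area"), str)
                else (AREA_WEST if float(m["utm_x"]) < area_split else AREA_EAST),
            }
        )
    if not rows:
        log.warning("no usable assigned fish; returning empty haul list")
        return []
    df = pd.DataFrame(rows)
    out = []
    for (haul, stage), grp in df.groupby(["haul_id", "life_stage"], sort=True):
        out.append(
            HaulObservation(
                haul_id=haul,
                period_id=grp["period_id"].iloc[0],
                east_count=int(grp["east"].sum()),
                n_fish=int(len(grp)),
                utm_x=float(grp["utm_x"].iloc[0]),
                area=grp["area"].iloc[0],
                life_stage=stage,
                salinity=float(grp["salinity"].iloc[0]),
                oxygen=float(grp["oxygen"].iloc[0]),
                temperature=float(grp["temperature"].iloc[0]),
            )
        )
    return out


# ---------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------


@dataclass
class MixingConfig:
    n_knots: int = 20
    n_draws: int = 1000
    beta_prior_sd: float = 10.0
    log_sigma_u_prior: tuple[float, float] = (math.log(0.5), 1.0)
    log_tau_prior: tuple[float, float] = (0.0, 3.0)
    constraint_weight: float = 1e6
    ridge: float = 1e-6
    seed: int = 0
    max_iter: int = 2000
    strict: bool = False


@dataclass
class _ModelSpec:
    model_id: str
    y: np.ndarray
    n: np.ndarray
    X: np.ndarray
    beta_names: list[str]
    haul_idx: np.ndarray
    n_hauls: int
    kfull: np.ndarray | None  # per-obs smoother coefficient index, or None
    n_knots: int
    n_smoothers: int
    knot_x: np.ndarray | None
    cov_stats: dict[str, tuple[float, float]]

    @property
    def dim(self) -> int:
        p = self.X.shape[1] + self.n_smoothers * self.n_knots + self.n_hauls + 1
        if self.n_smoothers:
            p += 1  # log tau
        return p

    def unpack(self, theta: np.ndarray):
        p = self.X.shape[1]
        nf = self.n_smoothers * self.n_knots
        beta = theta[:p]
        f = theta[p : p + nf]
        u = theta[p + nf : p + nf + self.n_hauls]
        rest = theta[p + nf + self.n_hauls :]
        lt = rest[0] if self.n_smoothers else None
        ls = rest[-1]
        return beta, f, u, lt, ls

    def eta(self, theta: np.ndarray, include_u: bool = True) -> np.ndarray:
        beta, f, u, _, _ = self.unpack(theta)
        eta = self.X @ beta
        if self.n_smoothers:
            eta = eta + f[self.kfull]
        if include_u:
            eta = eta + u[self.haul_idx]
        return eta


def _build_spec(df: pd.DataFrame, model_id: str, config: MixingConfig) -> _ModelSpec:
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}")
    if df["haul_id"].nunique() < 2:
        raise ValueError("need at least two hauls")
    cov_stats: dict[str, tuple[float, float]] = {}
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for c in COVARIATES:
        s = standardize(df[c].to_numpy())
        cov_stats[c] = (s.original_mean, s.original_sd)
        cols.append(s.values)
        names.append(c)
    if model_id == "M1":
        areas = set(df["area"])
        if not {AREA_WEST, AREA_EAST} <= areas:
            raise ValueError("M1 requires observations in both areas")
        cols.append((df["area"] == AREA_EAST).to_numpy(float))
        names.append("area_east")
    if model_id in ("M2", "M4"):
        stages = set(df["life_stage"])
        if not set(STAGES) <= stages:
            raise ValueError(f"{model_id} requires both life stages")
    if model_id == "M2":
        cols.append((df["life_stage"] == "juvenile").to_numpy(float))
        names.append("juvenile")
    X = np.column_stack(cols)

    haul_codes, haul_idx = np.unique(df["haul_id"], return_inverse=True)

    kfull = None
    knot_x = None
    n_smoothers = 0
    K = config.n_knots
    if model_id in ("M3", "M4"):
        x = df["utm_x"].to_numpy(float)
        lo, hi = x.min(), x.max()
        if hi <= lo:
            raise ValueError("utm_x must vary to fit a longitudinal smoother")
        edges = np.linspace(lo, hi, K + 1)
        k = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, K - 1)
        knot_x = 0.5 * (edges[:-1] + edges[1:])
        if model_id == "M3":
            n_smoothers = 1
            kfull = k
        else:
            n_smoothers = 2
            stage_idx = (df["life_stage"] == "juvenile").to_numpy(int)
            kfull = k + K * stage_idx
    return _ModelSpec(
        model_id=model_id,
        y=df["east_count"].to_numpy(float),
        n=df["n_fish"].to_numpy(float),
        X=X,
        beta_names=names,
        haul_idx=haul_idx,
        n_hauls=len(haul_codes),
        kfull=kfull,
        n_knots=K if n_smoothers else 0,
        n_smoothers=n_smoothers,
        knot_x=knot_x,
        cov_stats=cov_stats,
    )


def _rw2_penalty(K: int) -> np.ndarray:
    """Q = D2' D2 for a second-order random walk on K ordered knots."""
    D = np.zeros((K - 2, K))
    for i in range(K - 2):
        D[i, i] = 1.0
        D[i, i + 1] = -2.0
        D[i, i + 2] = 1.0
    return D.T @ D


def _latent_design(spec: _ModelSpec) -> np.ndarray:
    """Dense design of the latent field: eta = Z @ [beta, f, u]."""
    n_obs = spec.y.size
    p = spec.X.shape[1]
    nf = spec.n_smoothers * spec.n_knots
    Z = np.zeros((n_obs, p + nf + spec.n_hauls))
    Z[:, :p] = spec.X
    if nf:
        Z[np.arange(n_obs), p + spec.kfull] = 1.0
    Z[np.arange(n_obs), p + nf + spec.haul_idx] += 1.0
    return Z


def _prior_precision(
    spec: _ModelSpec, config: MixingConfig, Q: np.ndarray | None, phi: np.ndarray
) -> np.ndarray:
    """Gaussian prior precision of the latent field at hyperparameters
    phi = (log tau?, log sigma_u).  The soft sum-to-zero constraint is a
    rank-one precision term joint across all smoother coefficients."""
    p = spec.X.shape[1]
    nf = spec.n_smoothers * spec.n_knots
    dz = p + nf + spec.n_hauls
    P = np.zeros((dz, dz))
    P[np.arange(p), np.arange(p)] = 1.0 / config.beta_prior_sd**2
    if nf:
        tau = math.exp(phi[0])
        K = spec.n_knots
        for s in range(spec.n_smoothers):
            sl = slice(p + s * K, p + (s + 1) * K)
            P[sl, sl] += tau * Q
        P[p : p + nf, p : p + nf] += config.constraint_weight
        P[p + np.arange(nf), p + np.arange(nf)] += config.ridge
    ls = phi[-1]
    iu = p + nf + np.arange(spec.n_hauls)
    P[iu, iu] = math.exp(-2.0 * ls)
    return P


def _latent_objective(spec: _ModelSpec, Z: np.ndarray, P: np.ndarray, z: np.ndarray) -> float:
    eta = Z @ z
    nll = float(np.sum(spec.n * np.logaddexp(0.0, eta) - spec.y * eta))
    return nll + 0.5 * float(z @ (P @ z))


def _inner_newton(
    spec: _ModelSpec, Z: np.ndarray, P: np.ndarray, z0: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Mode of the (concave) latent log posterior given hyperparameters.
    Returns (mode, Hessian-at-mode, converged)."""
    z = z0.copy()
    converged = False
    H = P
    for _ in range(100):
        eta = Z @ z
        pi = expit(eta)
        g = Z.T @ (spec.n * pi - spec.y) + P @ z
        W = spec.n * pi * (1.0 - pi)
        H = (Z * W[:, None]).T @ Z + P
        if float(np.max(np.abs(g))) < 1e-8 * (1.0 + float(np.max(np.abs(spec.y)))):
            converged = True
            break
        c = cho_factor(H, lower=True)
        step = cho_solve(c, g)
        f0 = _latent_objective(spec, Z, P, z)
        t = 1.0
        z_new = z - step
        while _latent_objective(spec, Z, P, z_new) > f0 and t > 1e-6:
            t *= 0.5
            z_new = z - t * step
        if float(np.max(np.abs(z_new - z))) < 1e-12:
            converged = True
            z = z_new
            break
        z = z_new
    return z, H, converged


def _neg_log_marginal(
    phi: np.ndarray,
    spec: _ModelSpec,
    config: MixingConfig,
    Q: np.ndarray | None,
    Z: np.ndarray,
    cache: dict,
) -> float:
    """Laplace-approximate negative log marginal posterior of the
    hyperparameters: -[loglik(zhat) + logprior(zhat|phi)
    + 0.5 log|P| - 0.5 log|H|] - log hyperprior(phi)."""
    key = tuple(np.round(phi, 10))
    if key in cache:
        return cache[key][0]
    P = _prior_precision(spec, config, Q, phi)
    z0 = cache.get("warm")
    if z0 is None:
        z0 = np.zeros(P.shape[0])
        pooled = (spec.y.sum() + 0.5) / (spec.n.sum() + 1.0)
        z0[0] = math.log(pooled / (1.0 - pooled))
    zhat, H, ok = _inner_newton(spec, Z, P, z0)
    cache["warm"] = zhat
    obj = _latent_objective(spec, Z, P, zhat)
    _, ld_P = np.linalg.slogdet(P)
    _, ld_H = np.linalg.slogdet(H)
    val = obj - 0.5 * ld_P + 0.5 * ld_H
    if spec.n_smoothers:
        m, s_ = config.log_tau_prior
        val += 0.5 * ((phi[0] - m) / s_) ** 2
    m, s_ = config.log_sigma_u_prior
    val += 0.5 * ((phi[-1] - m) / s_) ** 2
    cache[key] = (val, zhat, H, ok)
    return val


@dataclass
class MixingModelFit:
    model_id: str
    config: MixingConfig
    spec: _ModelSpec
    mode: np.ndarray
    draws: np.ndarray  # (n_draws, dim)
    beta_summary: pd.DataFrame
    sigma_u_mean: float
    waic: float = float("nan")
    p_waic: float = float("nan")
    diagnostics: pd.DataFrame | None = None
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    @property
    def smoother_summary(self) -> pd.DataFrame | None:
        """Posterior summaries of the RW2 knot values, per smoother."""
        if not self.spec.n_smoothers:
            return None
        p = self.spec.X.shape[1]
        K = self.spec.n_knots
        rows = []
        stages = [None] if self.spec.n_smoothers == 1 else list(STAGES)
        for s, stage in enumerate(stages):
            block = self.draws[:, p + s * K : p + (s + 1) * K]
            rows.append(
                pd.DataFrame(
                    {
                        "life_stage": stage if stage else "all",
                        "utm_x": self.spec.knot_x,
                        "mean": block.mean(axis=0),
                        "q2.5": np.quantile(block, 0.025, axis=0),
                        "q97.5": np.quantile(block, 0.975, axis=0),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def fit_mixing_model(
    data: Sequence[HaulObservation] | pd.DataFrame,
    model_id: str,
    config: MixingConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MixingModelFit:
    """Fit one of M0-M4 by Laplace approximation (see module docs).

    Continuous covariates are standardized internally; means/sds are
    retained on the fit for prediction.  The returned fit carries
    posterior draws, fixed-effect summaries, WAIC, and population-level
    Pearson residuals (random intercepts excluded)."""
    config = config or MixingConfig()
    df = hauls_to_frame(data)
    spec = _build_spec(df, model_id, config)
    Q = _rw2_penalty(spec.n_knots) if spec.n_smoothers else None
    Z = _latent_design(spec)
    dz = Z.shape[1]
    warnings_: list[str] = []

    # --- outer optimization of the hyperparameters over the Laplace
    # marginal (1 dim without a smoother, 2 dims with one)
    cache: dict = {}
    if spec.n_smoothers:
        phi0 = np.array([config.log_tau_prior[0], config.log_sigma_u_prior[0]])
    else:
        phi0 = np.array([config.log_sigma_u_prior[0]])
    res = minimize(
        _neg_log_marginal,
        phi0,
        args=(spec, config, Q, Z, cache),
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-8, "maxiter": config.max_iter},
    )
    phi_hat = res.x
    converged = bool(res.success)
    if not converged:
        warnings_.append(f"hyperparameter optimization did not converge: {res.message}")
        if config.strict:
            raise RuntimeError(f"{model_id} fit failed to converge: {res.message}")

    # --- curvature of the marginal in phi (finite differences)
    d = phi_hat.size
    step = 0.05
    Hphi = np.zeros((d, d))
    f0 = _neg_log_marginal(phi_hat, spec, config, Q, Z, cache)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ei[i] = step
            ej = np.zeros(d)
            ej[j] = step
            fpp = _neg_log_marginal(phi_hat + ei + ej, spec, config, Q, Z, cache)
            fpm = _neg_log_marginal(phi_hat + ei - ej, spec, config, Q, Z, cache)
            fmp = _neg_log_marginal(phi_hat - ei + ej, spec, config, Q, Z, cache)
            fmm = _neg_log_marginal(phi_hat - ei - ej, spec, config, Q, Z, cache)
            Hphi[i, j] = Hphi[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step * step)
    try:
        cov_phi = np.linalg.inv(Hphi)
        sd_phi = np.sqrt(np.clip(np.diag(cov_phi), 1e-6, None))
    except np.linalg.LinAlgError:
        sd_phi = np.full(d, 0.5)
        warnings_.append("singular hyperparameter curvature; unit-scale nodes used")

    # --- hyperparameter nodes: mode plus +/- 1 sd per axis, weighted by
    # the marginal density (coarse central-composite integration)
    nodes = [phi_hat]
    for i in range(d):
        e = np.zeros(d)
        e[i] = sd_phi[i]
        nodes.append(phi_hat + e)
        nodes.append(phi_hat - e)
    neg_lm = np.array([_neg_log_marginal(nd, spec, config, Q, Z, cache) for nd in nodes])
    w = np.exp(-(neg_lm - neg_lm.min()))
    w /= w.sum()

    # deterministic proportional allocation of draws across nodes
    alloc = np.floor(w * config.n_draws).astype(int)
    rem = config.n_draws - alloc.sum()
    for i in np.argsort(-(w * config.n_draws - alloc))[:rem]:
        alloc[i] += 1

    if rng is None:
        rng = np.random.default_rng([config.seed, MODELS.index(model_id)])
    draws = np.empty((config.n_draws, spec.dim))
    pos = 0
    node_ok = True
    for nd, nk in zip(nodes, alloc):
        if nk == 0:
            continue
        key = tuple(np.round(nd, 10))
        _, zhat, H, ok = cache[key]
        node_ok &= ok
        L = np.linalg.cholesky(H)
        eps = rng.standard_normal((dz, nk))
        zdraw = zhat[:, None] + solve_triangular(L, eps, lower=True, trans="T")
        draws[pos : pos + nk, :dz] = zdraw.T
        draws[pos : pos + nk, dz:] = nd
        pos += nk
    if not node_ok:
        warnings_.append("inner Newton did not fully converge at some nodes")
        converged = False
        if config.strict:
            raise RuntimeError(f"{model_id}: latent mode search failed at some nodes")

    key = tuple(np.round(phi_hat, 10))
    mode = np.concatenate([cache[key][1], phi_hat])

    p = spec.X.shape[1]
    bd = draws[:, :p]
    beta_summary = pd.DataFrame(
        {
            "term": spec.beta_names,
            "mean": bd.mean(axis=0),
            "sd": bd.std(axis=0, ddof=1),
            "q2.5": np.quantile(bd, 0.025, axis=0),
            "q50": np.quantile(bd, 0.5, axis=0),
            "q97.5": np.quantile(bd, 0.975, axis=0),
        }
    )
    sigma_u_mean = float(np.exp(draws[:, -1]).mean())

    fit = MixingModelFit(
        model_id=model_id,
        config=config,
        spec=spec,
        mode=mode,
        draws=draws,
        beta_summary=beta_summary,
        sigma_u_mean=sigma_u_mean,
        converged=converged,
        warnings=warnings_,
    )
    fit.waic = compute_waic(fit)
    fit.diagnostics = _pearson_residuals(fit)
    return fit


def _loglik_draws(fit: MixingModelFit) -> np.ndarray:
    """(n_draws, n_obs) binomial log-pmf including the random intercept."""
    spec = fit.spec
    # eta for all draws at once
    p = spec.X.shape[1]
    nf = spec.n_smoothers * spec.n_knots
    eta = fit.draws[:, :p] @ spec.X.T
    if spec.n_smoothers:
        eta = eta + fit.draws[:, p : p + nf][:, spec.kfull]
    eta = eta + fit.draws[:, p + nf : p + nf + spec.n_hauls][:, spec.haul_idx]
    y, n = spec.y, spec.n
    logc = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return logc[None, :] + y[None, :] * eta - n[None, :] * np.logaddexp(0.0, eta)


def compute_waic(fit: MixingModelFit, data=None) -> float:
    """WAIC = -2 * sum_i [ log mean_s p(y_i | theta_s) - var_s log p(y_i | theta_s) ].

    Per-observation likelihood is binomial at the draw's pi including
    the haul random intercept."""
    if fit.draws.shape[0] < 2:
        raise ValueError("need at least 2 posterior draws for WAIC")
    ll = _loglik_draws(fit)
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - math.log(S)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    fit.p_waic = p_waic
    return -2.0 * (lppd - p_waic)


def _pearson_residuals(fit: MixingModelFit) -> pd.DataFrame:
    """Population-level Pearson residuals (random intercepts excluded)."""
    spec = fit.spec
    p = spec.X.shape[1]
    nf = spec.n_smoothers * spec.n_knots
    eta = fit.draws[:, :p] @ spec.X.T
    if spec.n_smoothers:
        eta = eta + fit.draws[:, p : p + nf][:, spec.kfull]
    pi = expit(eta).mean(axis=0)
    resid = (spec.y - spec.n * pi) / np.sqrt(spec.n * pi * (1.0 - pi))
    return pd.DataFrame({"fitted_pi": pi, "pearson_residual": resid})


def compare_models(
    data: Sequence[HaulObservation] | pd.DataFrame,
    model_ids: Sequence[str] = MODELS,
    config: MixingConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, MixingModelFit]]:
    """Fit the listed models and tabulate WAIC with differences to the
    best (minimum-WAIC) model.  Deterministic given the config seed."""
    config = config or MixingConfig()
    fits: dict[str, MixingModelFit] = {}
    for mid in model_ids:
        fits[mid] = fit_mixing_model(data, mid, config)
    tab = pd.DataFrame(
        {
            "model": list(fits),
            "waic": [fits[m].waic for m in fits],
            "p_waic": [fits[m].p_waic for m in fits],
        }
    ).sort_values("waic", kind="stable", ignore_index=True)
    tab["delta_waic"] = tab["waic"] - tab["waic"].min()
    return tab, fits


@dataclass
class LongitudeProfile:
    curve: pd.DataFrame  # utm_x, median, q2.5, q97.5
    crossing_utm_x: float | None  # longitude where the median crosses pi = 0.5


def predict_longitude_profile(
    fit: MixingModelFit,
    life_stage: str | None = None,
    covariate_values: dict[str, float] | None = None,
) -> LongitudeProfile:
    """Posterior median and equal-tailed 95% band of pi over the smoother
    knots, at fixed covariates (default: their means), excluding the
    haul-level random intercept."""
    spec = fit.spec
    if not spec.n_smoothers:
        raise ValueError(f"{fit.model_id} has no longitudinal smoother")
    if spec.model_id == "M3":
        if life_stage is not None:
            raise ValueError("M3 has no life-stage-specific smoother")
        block = 0
    else:
        if life_stage not in STAGES:
            raise ValueError(f"life_stage must be one of {STAGES} for M4")
        block = STAGES.index(life_stage)

    p = spec.X.shape[1]
    K = spec.n_knots
    eta0 = fit.draws[:, 0].copy()  # intercept
    for j, name in enumerate(spec.beta_names[1:], start=1):
        if name in COVARIATES:
            mu, sd = spec.cov_stats[name]
            raw = (covariate_values or {}).get(name, mu)
            eta0 += fit.draws[:, j] * ((raw - mu) / sd)
        elif name == "juvenile" and life_stage == "juvenile":
            eta0 += fit.draws[:, j]
    fblock = fit.draws[:, p + block * K : p + (block + 1) * K]
    pi = expit(eta0[:, None] + fblock)
    med = np.median(pi, axis=0)
    lo = np.quantile(pi, 0.025, axis=0)
    hi = np.quantile(pi, 0.975, axis=0)
    curve = pd.DataFrame({"utm_x": spec.knot_x, "median": med, "q2.5": lo, "q97.5": hi})

    crossing = None
    x = spec.knot_x
    d = med - 0.5
    for i in range(len(d) - 1):
        if d[i] == 0.0:
            crossing = float(x[i])
            break
        if d[i] * d[i + 1] < 0:
            crossing = float(x[i] + (x[i + 1] - x[i]) * (-d[i]) / (d[i + 1] - d[i]))
            break
    else:
        if d[-1] == 0.0:
            crossing = float(x[-1])
    return LongitudeProfile(curve, crossing)


def before_after_comparison(
    data: Sequence[HaulObservation] | pd.DataFrame,
    split_period: str,
) -> pd.DataFrame:
    """Pooled eastern proportions with Wilson 95% CIs before vs after a
    split period (periods sorting strictly below ``split_period`` count
    as 'before').  Descriptive only; also broken down by area."""
    df = hauls_to_frame(data)
    df["phase"] = np.where(df["period_id"].astype(str) < split_period, "before", "after")
    if df["phase"].nunique() < 2:
        raise ValueError("both the before and after period must contain observations")
    rows = []
    for (phase, area), grp in df.groupby(["phase", "area"]):
        rows.append((phase, area, grp["east_count"].sum(), grp["n_fish"].sum()))
    for phase, grp in df.groupby("phase"):
        rows.append((phase, "all", grp["east_count"].sum(), grp["n_fish"].sum()))
    out = []
    for phase, area, e, n in rows:
        lo, hi = proportion_confint(e, n, alpha=0.05, method="wilson")
        out.append(
            {
                "phase": phase,
                "area": area,
                "east_count": int(e),
                "n_fish": int(n),
                "proportion_east": e / n,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return (
        pd.DataFrame(out)
        .sort_values(["phase", "area"], ignore_index=True)
    )
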