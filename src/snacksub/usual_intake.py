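"""Usual-intake estimation from repeated 24-h recalls (NCI-style).

A single recall day is a noisy measurement of a person's long-run usual
intake: day-to-day (within-person) variation inflates the apparent spread
of the population distribution.  The model here follows the National
Cancer Institute approach: recall amounts are Box-Cox transformed to
approximate normality and modeled with a linear mixed model

    g(Y_ij; lambda) = x_ij' beta + u_i + eps_ij,
    u_i ~ N(0, sigma_u^2),  eps_ij ~ N(0, sigma_e^2)

with covariates for weekend vs weekday and recall sequence (first vs
second recall, which also absorbs interview-mode effects).  The usual
intake of a person with random effect u is the within-person expectation
of the back-transformed amount, taken over eps by Gauss-Hermite quadrature
and over a 5/7 weekday + 2/7 weekend mixture at first-recall covariates.
Episodically consumed items add a mixed logistic model for the probability
of consumption on a day; usual intake is then usual probability times the
usual consumption-day amount (parts fitted independently).

Survey weights enter the likelihood as frequency-type weights.  The
Box-Cox exponent is selected by profile likelihood over a grid.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit

logger = logging.getLogger(__name__)

#: default Box-Cox grid: {0, 0.05, ..., 1}
LAMBDA_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 2)

COVARIATES = ["intercept", "weekend", "sequence"]


def boxcox(y: np.ndarray, lam: float) -> np.ndarray:
    """Box-Cox transform; natural log at lambda = 0."""
    y = np.asarray(y, dtype=float)
    if lam == 0:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def inv_boxcox(z: np.ndarray, lam: float) -> np.ndarray:
    """Inverse Box-Cox; arguments outside the domain truncate to 0."""
    z = np.asarray(z, dtype=float)
    if lam == 0:
        return np.exp(z)
    base = 1.0 + lam * z
    return np.where(base > 0, np.power(np.clip(base, 0, None), 1.0 / lam), 0.0)


@dataclass(frozen=True)
class UsualIntakeModel:
    """Fitted amount (and optionally consumption-probability) model."""
    nutrient: str
    mode: str  # "ubiquitous" or "episodic"
    lam: float
    beta: dict[str, float]
    sigma_u: float
    sigma_e: float
    loglik: float
    # episodic part (consumption-probability model), None for ubiquitous
    prob_beta: dict[str, float] | None = None
    prob_sigma_u: float | None = None

    def __post_init__(self):
        if self.sigma_u < 0 or self.sigma_e <= 0:
            raise ValueError("sigma_u must be >=0 and sigma_e > 0")
        if self.mode not in ("ubiquitous", "episodic"):
            raise ValueError("mode must be ubiquitous or episodic")


@dataclass(frozen=True)
class UsualIntakeDistribution:
    nutrient: str
    mean: float
    se: float | None
    sd: float = 0.0  # SD of the usual-intake distribution
    percentiles: np.ndarray = None  # percentiles 1..99
    pct_below: dict[float, float] = field(default_factory=dict)
    pct_above: dict[float, float] = field(default_factory=dict)
    n_truncated: int = 0

    def __post_init__(self):
        if np.any(np.diff(self.percentiles) < -1e-9):
            raise ValueError("percentiles must be nondecreasing")


def _design(df: pd.DataFrame) -> np.ndarray:
    X = np.column_stack([
        np.ones(len(df)),
        df["weekend"].to_numpy(dtype=float),
        df["sequence"].to_numpy(dtype=float),
    ])
    return X


def _person_arrays(df: pd.DataFrame):
    """Sorted-by-person arrays plus person index codes and weights.

    Weights are person-level, normalized to mean 1 across persons so the
    weighted likelihood is on the scale of the actual sample size.
    """
    df = df.sort_values("person_id", kind="stable").reset_index(drop=True)
    codes, uniques = pd.factorize(df["person_id"], sort=False)
    w_person = df.groupby(codes, sort=True)["weight"].first().to_numpy(dtype=float)
    w_person = w_person / w_person.mean()
    n_i = np.bincount(codes)
    return df, codes, w_person, n_i


def _profile_loglik(z, X, codes, w_person, n_i, log_a, log_e):
    """Weighted profile log-likelihood of the random-intercept model.

    beta is profiled out by weighted GLS; the compound-symmetric person
    blocks are inverted in closed form (Sherman-Morrison).
    Returns (loglik, beta).
    """
    a, e = np.exp(log_a), np.exp(log_e)
    denom = e + n_i * a  # per person
    w_obs = w_person[codes]
    p = X.shape[1]
    # per-person column sums of X and of z
    SX = np.column_stack([np.bincount(codes, weights=X[:, j]) for j in range(p)])
    Sz = np.bincount(codes, weights=z)
    c = w_person * a / (e * denom)  # correction factor per person
    A = (X.T * w_obs) @ X / e - (SX.T * c) @ SX
    b = X.T @ (w_obs * z) / e - (SX.T * c) @ Sz
    beta = np.linalg.solve(A, b)
    r = z - X @ beta
    Sr = np.bincount(codes, weights=r)
    quad = np.sum(w_obs * r * r) / e - np.sum(w_person * a / (e * denom) * Sr * Sr)
    logdet = np.sum(w_person * ((n_i - 1) * np.log(e) + np.log(denom)))
    n_eff = np.sum(w_person * n_i)
    ll = -0.5 * (n_eff * np.log(2 * np.pi) + logdet + quad)
    return ll, beta


def _fit_mixed(z, X, codes, w_person, n_i):
    """Maximize over (sigma_u^2, sigma_e^2) on the log scale."""
    # moment start: within from 2-recall person differences, rest between
    var_tot = max(np.var(z), 1e-6)
    two = n_i == 2
    if two.any():
        # crude: use half mean squared diff among persons with 2 obs
        order = np.argsort(codes, kind="stable")
        zs = z[order]
        starts = np.concatenate([[0], np.cumsum(n_i)])[:-1]
        d = [zs[s + 1] - zs[s] for s, n in zip(starts, n_i) if n == 2]
        var_e0 = max(0.5 * np.mean(np.square(d)), 1e-6) if d else var_tot / 2
    else:
        var_e0 = var_tot / 2
    var_u0 = max(var_tot - var_e0, 1e-6)

    def neg(theta):
        ll, _ = _profile_loglik(z, X, codes, w_person, n_i, theta[0], theta[1])
        return -ll

    res = minimize(neg, x0=[np.log(var_u0), np.log(var_e0)],
                   method="L-BFGS-B",
                   bounds=[(-30, 10), (-15, 10)])
    ll, beta = _profile_loglik(z, X, codes, w_person, n_i, res.x[0], res.x[1])
    return ll, beta, np.sqrt(np.exp(res.x[0])), np.sqrt(np.exp(res.x[1]))


def fit_amount_model(df: pd.DataFrame, nutrient: str = "",
                     lambda_grid: np.ndarray = LAMBDA_GRID) -> UsualIntakeModel:
    """Fit the Box-Cox random-intercept amount model by weighted ML.

    ``df`` needs columns person_id, intake (>0 for the amount part),
    weekend (0/1), sequence (0 first recall / 1 second), weight.  The
    Box-Cox exponent is chosen by profile likelihood over ``lambda_grid``
    (the Jacobian term makes likelihoods comparable across exponents).
    """
    if (df["intake"] < 0).any():
        raise ValueError("negative intakes")
    if (df["intake"] <= 0).any():
        raise ValueError("amount model requires positive intakes "
                         "(use fit_episodic_model for zero-inflated items)")
    df, codes, w_person, n_i = _person_arrays(df)
    if (n_i < 2).all():
        raise ValueError("sigma_u unidentifiable: no person has >=2 recalls")
    y = df["intake"].to_numpy(dtype=float)
    X = _design(df)
    w_obs = (w_person / 1.0)[codes]
    logy_sum = np.sum(w_obs * np.log(y))

    best = None
    for lam in np.asarray(lambda_grid, dtype=float):
        z = boxcox(y, lam)
        ll, beta, su, se_ = _fit_mixed(z, X, codes, w_person, n_i)
        ll_total = ll + (lam - 1.0) * logy_sum  # Box-Cox Jacobian
        if best is None or ll_total > best[0]:
            best = (ll_total, lam, beta, su, se_)
    ll_total, lam, beta, su, se_ = best
    return UsualIntakeModel(
        nutrient=nutrient, mode="ubiquitous", lam=float(lam),
        beta=dict(zip(COVARIATES, map(float, beta))),
        sigma_u=float(su), sigma_e=float(max(se_, 1e-8)),
        loglik=float(ll_total))


def _logistic_loglik(params, Y, X, codes, w_person, n_i, nodes, wts):
    """Weighted marginal log-likelihood of the mixed logit, GH quadrature."""
    gamma, log_t = params[:-1], params[-1]
    tau = np.exp(0.5 * log_t)
    eta = X @ gamma  # (n_obs,)
    # per person x per node: sum over obs of log Bernoulli at eta + tau*node
    ll_p = np.zeros((len(n_i), len(nodes)))
    for k, node in enumerate(nodes):
        lin = eta + tau * node
        logp = np.where(Y == 1, -np.logaddexp(0, -lin), -np.logaddexp(0, lin))
        ll_p[:, k] = np.bincount(codes, weights=logp)
    m = ll_p.max(axis=1, keepdims=True)
    lik = np.log(np.exp(ll_p - m) @ wts) + m[:, 0]
    return np.sum(w_person * lik)


def fit_episodic_model(df: pd.DataFrame, nutrient: str = "",
                       lambda_grid: np.ndarray = LAMBDA_GRID,
                       quad_points: int = 21) -> UsualIntakeModel:
    """Two-part model for episodically consumed items.

    Part 1 is a mixed logistic model for the probability of consumption on
    a recall day (person random intercept, Gauss-Hermite marginal
    likelihood); part 2 is the Box-Cox amount model fitted to
    consumption days only.  The parts are fitted independently.
    """
    pos = df["intake"] > 0
    if pos.all():
        raise ValueError("no zero-consumption days: use fit_amount_model "
                         "(ubiquitous mode)")
    if not pos.any():
        raise ValueError("no positive-consumption days")
    dfs, codes, w_person, n_i = _person_arrays(df)
    Y = (dfs["intake"] > 0).to_numpy(dtype=float)
    X = _design(dfs)
    nodes, wts = hermegauss(quad_points)
    wts = wts / np.sqrt(2 * np.pi)

    def neg(params):
        return -_logistic_loglik(params, Y, X, codes, w_person, n_i, nodes, wts)

    p_bar = Y.mean()
    x0 = np.array([np.log(p_bar / (1 - p_bar)), 0.0, 0.0, np.log(0.5)])
    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-5, "fatol": 1e-7})
    gamma, log_t = res.x[:-1], res.x[-1]

    amount = fit_amount_model(df[pos], nutrient=nutrient,
                              lambda_grid=lambda_grid)
    return UsualIntakeModel(
        nutrient=nutrient, mode="episodic", lam=amount.lam,
        beta=amount.beta, sigma_u=amount.sigma_u, sigma_e=amount.sigma_e,
        loglik=float(amount.loglik - res.fun),
        prob_beta=dict(zip(COVARIATES, map(float, gamma))),
        prob_sigma_u=float(np.exp(0.5 * log_t)))


def expected_backtransform(z: np.ndarray, lam: float, sigma_e: float,
                           quad_points: int = 9):
    """E over eps~N(0, sigma_e^2) of inv_boxcox(z + eps), by Gauss-Hermite.

    Vectorized over z.  Returns (values, n_truncated) where n_truncated
    counts (z, node) pairs whose back-transform argument fell outside the
    domain and was truncated to 0.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    nodes, wts = hermegauss(quad_points)
    wts = wts / np.sqrt(2 * np.pi)
    args = z[:, None] + sigma_e * nodes[None, :]
    vals = inv_boxcox(args, lam)
    n_trunc = 0
    if lam > 0:
        n_trunc = int(np.sum(1.0 + lam * args <= 0))
    return vals @ wts, n_trunc


# prediction reference: 5/7 weekday + 2/7 weekend, first recall
WEEKEND_SHARE = 2.0 / 7.0


def usual_amounts(model: UsualIntakeModel, u: np.ndarray,
                  quad_points: int = 9):
    """Usual consumption-day amount T(u) at the reference covariates."""
    b = model.beta
    z_wd = b["intercept"] + u
    z_we = b["intercept"] + b["weekend"] + u
    t_wd, k1 = expected_backtransform(z_wd, model.lam, model.sigma_e, quad_points)
    t_we, k2 = expected_backtransform(z_we, model.lam, model.sigma_e, quad_points)
    return (1 - WEEKEND_SHARE) * t_wd + WEEKEND_SHARE * t_we, k1 + k2


def usual_probabilities(model: UsualIntakeModel, u: np.ndarray) -> np.ndarray:
    """Usual probability of consumption at the reference covariates."""
    g = model.prob_beta
    p_wd = expit(g["intercept"] + u)
    p_we = expit(g["intercept"] + g["weekend"] + u)
    return (1 - WEEKEND_SHARE) * p_wd + WEEKEND_SHARE * p_we


def usual_distribution(model: UsualIntakeModel, n_draws: int = 50_000,
                       seed: int = 0, thresholds_below=(), thresholds_above=(),
                       quad_points: int = 9) -> UsualIntakeDistribution:
    """Monte-Carlo population distribution of usual intake.

    Person random effects are drawn from their fitted normal law; for each
    draw the usual intake is the quadrature expectation of the
    back-transformed amount (times the usual consumption probability in
    episodic mode, with an independent probability random effect).
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, model.sigma_u, size=n_draws)
    t, n_trunc = usual_amounts(model, u, quad_points)
    if model.mode == "episodic":
        up = rng.normal(0.0, model.prob_sigma_u, size=n_draws)
        t = usual_probabilities(model, up) * t
    if n_trunc:
        logger.info("usual_distribution: %d truncated back-transform nodes",
                    n_trunc)
    pcts = np.percentile(t, np.arange(1, 100))
    return UsualIntakeDistribution(
        nutrient=model.nutrient, mean=float(t.mean()), se=None,
        sd=float(t.std()), percentiles=pcts,
        pct_below={float(c): float(100.0 * np.mean(t < c))
                   for c in thresholds_below},
        pct_above={float(c): float(100.0 * np.mean(t > c))
                   for c in thresholds_above},
        n_truncated=n_trunc)


def population_mean(day_intakes: pd.DataFrame, persons: pd.DataFrame,
                    scheme=None):
    """Survey-weighted population mean daily intake, with optional BRR SE.

    ``day_intakes`` has columns person_id and intake (one row per recall
    day); each person's recalls are averaged first, then averaged over
    persons with survey weights.  If a ReplicateScheme is given, the SE is
    estimated from the Fay replicate weights; otherwise SE is None.
    """
    per_person = (day_intakes.groupby("person_id")["intake"].mean()
                  .reindex(persons["person_id"]).to_numpy())
    if np.isnan(per_person).any():
        raise ValueError("persons without any recall day in day_intakes")

    def estimator(weights: np.ndarray) -> float:
        return float(np.average(per_person, weights=weights))

    est = estimator(persons["survey_weight"].to_numpy(dtype=float))
    if scheme is None:
        return est, None
    from .inference import brr_variance
    _, se = brr_variance(estimator, scheme)
    return est, se
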