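"""Allele-specific expression arm of the GxE test.

The response for sample *i* at transcribed SNP *s* is the folded alternate
read count ``min(y, n - y)``, modeled as

    min(y, n - y) ~ Binomial(n, sigmoid(e*g_e + h*g_h + e*h*b + mu + cov + eps))

with ``eps ~ N(0, v)`` a per-observation random effect capturing
overdispersion and ``v`` given an inverse-gamma prior IG(a, b) learned
empirically across tSNPs.  The random effect is integrated out by adaptive
Gauss-Hermite quadrature centered at each observation's conditional mode;
parameters are fitted by maximizing the resulting MAP objective, and the
interaction coefficient is tested with a 1-df likelihood-ratio test.

The likelihood is evaluated, as written above, as the binomial pmf at the
folded count with an unconstrained logistic mean.  The alternative
``likelihood="mixture"`` evaluates the exact two-term folded distribution
P(min(Y, n-Y) = m) instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, special, stats

__all__ = [
    "IGPrior",
    "AseGxeDesign",
    "AseGxeFit",
    "fold_count",
    "marginal_loglik",
    "fit_ase_model",
    "ase_lrt",
    "fit_ase_gxe",
    "fit_tsnp_variance",
    "estimate_ig_prior",
]

_GTOL = 1e-6
_MAX_NEWTON = 60


@dataclass(frozen=True)
class IGPrior:
    """Inverse-gamma prior IG(a, b) on the random-effect variance."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("IGPrior requires a > 0 and b > 0")

    @property
    def mode(self) -> float:
        return self.b / (self.a + 1.0)

    def logpdf(self, v: float) -> float:
        return float(stats.invgamma.logpdf(v, self.a, scale=self.b))


@dataclass
class AseGxeDesign:
    """Per-observation data for one candidate regulatory SNP x tSNP x trait.

    All arrays are aligned over observations (samples heterozygous at the
    tSNP).  ``h`` indicates heterozygosity at the candidate regulatory SNP.
    """

    n: np.ndarray
    y: np.ndarray
    e: np.ndarray
    h: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.e = np.asarray(self.e, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if not (self.n.shape == self.y.shape == self.e.shape == self.h.shape):
            raise ValueError("design arrays must share one shape")
        if (self.y < 0).any() or (self.y > self.n).any():
            raise ValueError("require 0 <= y <= n per observation")
        if not np.isin(self.h, [0.0, 1.0]).all():
            raise ValueError("h must be a 0/1 indicator")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.n.shape[0]:
                raise ValueError("covariate rows must align with observations")

    @property
    def n_obs(self) -> int:
        return int(self.n.shape[0])

    @property
    def folded(self) -> np.ndarray:
        return np.minimum(self.y, self.n - self.y)

    def matrix(self, include_interaction: bool) -> np.ndarray:
        """Design matrix: intercept, e, h, [e*h], covariates."""
        cols = [np.ones(self.n_obs), self.e, self.h]
        if include_interaction:
            cols.append(self.e * self.h)
        X = np.column_stack(cols)
        if self.covariates is not None:
            X = np.hstack([X, self.covariates])
        return X


@dataclass
class AseGxeFit:
    mu: float
    gamma_se: float
    gamma_sh: float
    beta_seh: float | None
    cov_effects: np.ndarray
    v: float
    loglik: float
    converged: bool
    n_obs: int
    p_value: float | None = None
    params: np.ndarray = field(default=None, repr=False)


def fold_count(y: int, n: int) -> int:
    """Folded (minor) allele count ``min(y, n - y)``."""
    if not 0 <= y <= n:
        raise ValueError(f"require 0 <= y <= n, got y={y}, n={n}")
    return min(y, n - y)


def _log_binom_pmf(m, n, eta, log_coef, likelihood):
    """log P(folded count = m) at logit-scale mean eta (broadcasting)."""
    lp = special.log_expit(eta)
    lq = special.log_expit(-eta)
    lead = log_coef + m * lp + (n - m) * lq
    if likelihood == "folded":
        return lead
    # exact folded distribution: add the reflected term unless m == n - m
    refl = log_coef + (n - m) * lp + m * lq
    out = np.logaddexp(lead, refl)
    mid = m == (n - m)
    return np.where(mid, lead, out)


def _obs_loglik(m, n, log_coef, eta, v, n_nodes, likelihood):
    """Vector of per-observation marginal log-likelihoods.

    ``eta`` may be (n_obs,) or (n_obs, K) for K parameter columns with
    matching ``v`` of shape () or (K,); the random effect is integrated by
    Gauss-Hermite quadrature after shifting to each observation's
    conditional mode and rescaling by the local curvature.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor")
    squeeze = eta.ndim == 1
    if squeeze:
        eta = eta[:, None]
    K = eta.shape[1]
    v = np.broadcast_to(np.asarray(v, dtype=float), (K,))
    m = m[:, None]
    n = n[:, None]
    log_coef = log_coef[:, None]

    out = np.empty(eta.shape)
    zero = v <= 0.0
    if zero.any():
        out[:, zero] = _log_binom_pmf(m, n, eta[:, zero], log_coef, likelihood)
    pos = ~zero
    if pos.any():
        et, vv = eta[:, pos], v[pos]
        # Newton for the mode of log Binom(m; n, sigmoid(eta+eps)) - eps^2/(2v)
        eps = np.zeros_like(et)
        for _ in range(_MAX_NEWTON):
            p = special.expit(et + eps)
            g1 = m - n * p - eps / vv
            g2 = -n * p * (1.0 - p) - 1.0 / vv
            step = g1 / g2
            np.clip(step, -10.0, 10.0, out=step)
            eps -= step
            if np.max(np.abs(g1)) < 1e-10:
                break
        p = special.expit(et + eps)
        sigma = 1.0 / np.sqrt(n * p * (1.0 - p) + 1.0 / vv)

        x, w = hermegauss(n_nodes)  # weight exp(-x^2/2)
        nodes = eps[..., None] + sigma[..., None] * x  # (n_obs, K, n_nodes)
        lf = (
            _log_binom_pmf(m[..., None], n[..., None], et[..., None] + nodes, log_coef[..., None], likelihood)
            - 0.5 * nodes**2 / vv[None, :, None]
            - 0.5 * np.log(2.0 * np.pi * vv)[None, :, None]
        )
        log_integrand = lf + 0.5 * x**2 + np.log(w) + np.log(sigma[..., None])
        out[:, pos] = special.logsumexp(log_integrand, axis=-1)
    return out[:, 0] if squeeze else out


def marginal_loglik(
    params,
    design: AseGxeDesign,
    *,
    include_interaction: bool = True,
    prior: IGPrior | None = None,
    n_nodes: int = 20,
    likelihood: str = "folded",
) -> float:
    """Marginal log-likelihood (plus log prior of v when given) at ``params``.

    ``params`` is the packed vector ``[mu, gamma_se, gamma_sh, (beta_seh),
    cov..., v]`` with the variance on the natural scale as the last entry.
    With ``v = 0`` this reduces exactly to the fixed-effect binomial
    log-likelihood on folded counts.
    """
    params = np.asarray(params, dtype=float)
    v = params[-1]
    if v < 0:
        raise ValueError("random-effect variance must be >= 0")
    X = design.matrix(include_interaction)
    if params.size != X.shape[1] + 1:
        raise ValueError(f"expected {X.shape[1] + 1} parameters, got {params.size}")
    m = design.folded
    log_coef = special.gammaln(design.n + 1) - special.gammaln(m + 1) - special.gammaln(design.n - m + 1)
    ll = float(np.sum(_obs_loglik(m, design.n, log_coef, X @ params[:-1], v, n_nodes, likelihood)))
    if prior is not None:
        ll += prior.logpdf(v)
    return ll


def _neg_objective_factory(design, include_interaction, prior, n_nodes, likelihood):
    X = design.matrix(include_interaction)
    m = design.folded
    n = design.n
    log_coef = special.gammaln(n + 1) - special.gammaln(m + 1) - special.gammaln(n - m + 1)

    def value_many(theta_cols):
        """Objective at many packed [beta..., log v] columns at once."""
        beta = theta_cols[:-1, :]
        v = np.exp(theta_cols[-1, :])
        ll = _obs_loglik(m, n, log_coef, X @ beta, v, n_nodes, likelihood).sum(axis=0)
        if prior is not None:
            ll = ll + stats.invgamma.logpdf(v, prior.a, scale=prior.b)
        return -ll

    def fun(theta):
        return float(value_many(theta[:, None])[0])

    def jac(theta):
        p = theta.size
        hstep = 1e-5 * np.maximum(1.0, np.abs(theta))
        cols = np.tile(theta[:, None], (1, 2 * p))
        for j in range(p):
            cols[j, 2 * j] += hstep[j]
            cols[j, 2 * j + 1] -= hstep[j]
        vals = value_many(cols)
        return (vals[0::2] - vals[1::2]) / (2.0 * hstep)

    return fun, jac


def fit_ase_model(
    design: AseGxeDesign,
    prior: IGPrior | None = None,
    include_interaction: bool = True,
    *,
    n_nodes: int = 20,
    likelihood: str = "folded",
    start: np.ndarray | None = None,
    require_double_het: bool = True,
    n_restarts: int = 0,
    restart_seed: int = 0,
) -> AseGxeFit:
    """Fit the ASE GxE model by MAP over ``(effects, log v)``.

    Starts from zeros with ``v`` at the prior mode (a deterministic start)
    and optimizes with L-BFGS-B to gradient tolerance 1e-6.  The null model
    is obtained with ``include_interaction=False``.  ``n_restarts`` adds
    seeded random restarts (off by default) and keeps the best solution.
    """
    if design.n_obs == 0:
        raise ValueError("empty design")
    if require_double_het and not (design.h > 0).any():
        raise ValueError("untestable: no double heterozygotes")
    if np.ptp(design.e) == 0:
        raise ValueError("zero-variance environment")

    X = design.matrix(include_interaction)
    p = X.shape[1]
    if start is None:
        v0 = prior.mode if prior is not None else 0.01
        start = np.concatenate([np.zeros(p), [np.log(v0)]])
    else:
        start = np.asarray(start, dtype=float)
        if start.size != p + 1:
            raise ValueError("bad start vector length")

    fun, jac = _neg_objective_factory(design, include_interaction, prior, n_nodes, likelihood)
    bounds = [(-40.0, 40.0)] * p + [(-30.0, 5.0)]  # last entry is log v
    starts = [start]
    if n_restarts:
        rs = np.random.default_rng(restart_seed)
        starts += [start + rs.normal(0.0, 0.5, start.size) for _ in range(n_restarts)]
    res = None
    for s0 in starts:
        cand = optimize.minimize(
            fun,
            s0,
            jac=jac,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-13, "gtol": _GTOL},
        )
        if res is None or cand.fun < res.fun:
            res = cand
    theta = res.x
    beta = theta[:-1]
    v = float(np.exp(theta[-1]))
    k = 4 if include_interaction else 3
    return AseGxeFit(
        mu=float(beta[0]),
        gamma_se=float(beta[1]),
        gamma_sh=float(beta[2]),
        beta_seh=float(beta[3]) if include_interaction else None,
        cov_effects=beta[k:].copy(),
        v=v,
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_obs=design.n_obs,
        params=theta.copy(),
    )


def ase_lrt(full: AseGxeFit, null: AseGxeFit, tol: float = 1e-6) -> float:
    """1-df likelihood-ratio p-value for the interaction coefficient."""
    lam = 2.0 * (full.loglik - null.loglik)
    if lam < -tol:
        raise ValueError(f"null fit exceeds full fit (lambda={lam:.3g}); refit required")
    return float(stats.chi2.sf(max(lam, 0.0), df=1))


def fit_ase_gxe(
    design: AseGxeDesign,
    prior: IGPrior | None = None,
    *,
    n_nodes: int = 20,
    likelihood: str = "folded",
) -> tuple[AseGxeFit, AseGxeFit]:
    """Fit full and null models and attach the LRT p-value to the full fit.

    If the null objective beats the full one (optimizer failure), the null
    solution seeds a full refit and, failing that, the null is refit from
    the full solution with the interaction removed.
    """
    full = fit_ase_model(design, prior, True, n_nodes=n_nodes, likelihood=likelihood)
    null = fit_ase_model(design, prior, False, n_nodes=n_nodes, likelihood=likelihood)
    if full.loglik < null.loglik - 1e-6:
        start = np.insert(null.params, 3, 0.0)
        refit = fit_ase_model(
            design, prior, True, n_nodes=n_nodes, likelihood=likelihood, start=start
        )
        if refit.loglik > full.loglik:
            full = refit
    full.p_value = ase_lrt(full, null)
    return full, null


def fit_tsnp_variance(
    n: np.ndarray, y: np.ndarray, *, n_nodes: int = 20, likelihood: str = "folded"
) -> tuple[float, float]:
    """Intercept-only ML fit of (mu, v) for one tSNP; returns ``(mu, v)``.

    Used to collect per-tSNP variance estimates for empirical-Bayes prior
    learning; no prior enters this fit.
    """
    n = np.asarray(n, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    m = np.minimum(y, n - y)
    log_coef = special.gammaln(n + 1) - special.gammaln(m + 1) - special.gammaln(n - m + 1)
    X = np.ones((n.size, 1))

    def value_many(theta_cols):
        mu = theta_cols[0:1, :]
        v = np.exp(theta_cols[1, :])
        return -_obs_loglik(m, n, log_coef, X @ mu, v, n_nodes, likelihood).sum(axis=0)

    def fun(theta):
        return float(value_many(theta[:, None])[0])

    def jac(theta):
        hstep = 1e-5 * np.maximum(1.0, np.abs(theta))
        cols = np.tile(theta[:, None], (1, 4))
        cols[0, 0] += hstep[0]
        cols[0, 1] -= hstep[0]
        cols[1, 2] += hstep[1]
        cols[1, 3] -= hstep[1]
        vals = value_many(cols)
        return np.array([(vals[0] - vals[1]) / (2 * hstep[0]), (vals[2] - vals[3]) / (2 * hstep[1])])

    res = optimize.minimize(
        fun, np.array([0.0, np.log(0.01)]), jac=jac, method="L-BFGS-B",
        bounds=[(-40.0, 40.0), (-30.0, 5.0)],
        options={"maxiter": 300, "ftol": 1e-13, "gtol": _GTOL},
    )
    return float(res.x[0]), float(np.exp(res.x[1]))


def estimate_ig_prior(vhat, min_estimates: int = 50) -> IGPrior:
    """Maximum-likelihood inverse-gamma fit to per-tSNP variance estimates.

    Non-positive estimates are excluded with a warning; fewer than
    ``min_estimates`` survivors, or a degenerate (constant) sample, is an
    error.
    """
    v = np.asarray(vhat, dtype=float)
    bad = ~(v > 0)
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} non-positive variance estimates")
        v = v[~bad]
    if v.size < min_estimates:
        raise ValueError(f"need >= {min_estimates} positive variance estimates, have {v.size}")
    if np.ptp(v) == 0:
        raise ValueError("degenerate variance sample (all equal)")
    a, _, b = stats.invgamma.fit(v, floc=0)
    return IGPrior(a=float(a), b=float(b))
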