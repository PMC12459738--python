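"""Estimation and diagnostics for the latent growth curve model.

Two routes target the same FIML likelihood:

* :func:`fit_ml` — bounded quasi-Newton (L-BFGS-B) maximisation of the
  observed-data log-likelihood, with Wald z tests and 95% CIs for the fixed
  effects from the numerical Hessian.
* :func:`sample_posterior` — an adaptive random-walk Metropolis sampler over
  prior x exp(loglik), recording the pointwise per-participant log-likelihood
  at every retained draw so predictive-fit criteria can be computed.

Model fit diagnostics follow the standard definitions: split-chain
Gelman-Rubin R-hat (:func:`gelman_rubin`), WAIC from the pointwise
log-likelihood matrix (:func:`waic`), and importance-sampling LOO with
truncated weights (:func:`loo`).  Both criteria are reported on the elpd scale
and on the deviance scale (-2 * elpd); a bare signed number is never emitted
because the two conventions differ in sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .lgcm import (
    DEFAULT_JITTER,
    FIXED_EFFECT_NAMES,
    Covariates,
    FimlData,
    LGCMParams,
)
from .measures import TimeBasis

__all__ = [
    "ModelSpec",
    "FitResult",
    "PosteriorResult",
    "fit_ml",
    "wald_test",
    "sample_posterior",
    "gelman_rubin",
    "waic",
    "loo",
    "WaicResult",
    "LooResult",
]

Z_95 = 1.959964  # two-sided 95% normal quantile
_VAR_FLOOR = 1e-8
_CORR_BOUND = 0.999


@dataclass(frozen=True)
class ModelSpec:
    """Which terms of the growth model are estimated.

    ``fixed`` maps parameter names to values held constant during estimation
    (e.g. ``{"b1exp": 0.0}`` for the no-intervention-effect null, or
    ``{"cov_e01": 0.0}`` to force independent intercepts and slopes).
    ``arm_effect`` / ``gender_effect`` drop the corresponding covariate terms
    entirely when False.
    """

    arm_effect: bool = True
    gender_effect: bool = True
    free_cov: bool = True
    fixed: dict = field(default_factory=dict)

    def fixed_values(self) -> dict:
        out = dict(self.fixed)
        if not self.arm_effect:
            out.setdefault("b0exp", 0.0)
            out.setdefault("b1exp", 0.0)
        if not self.gender_effect:
            out.setdefault("b0female", 0.0)
            out.setdefault("b1female", 0.0)
        if not self.free_cov:
            out.setdefault("cov_e01", 0.0)
        return out


# internal optimisation vector: fixed effects, variances, and the
# intercept-slope *correlation* (keeps Psi PSD inside box bounds)
_OPT_NAMES = (
    "b00", "b0exp", "b0female", "b10", "b1exp", "b1female",
    "var_e0", "var_e1", "corr_e01", "var_e2",
)


def _vec_to_params(vec: dict) -> LGCMParams:
    corr = vec["corr_e01"]
    cov = corr * np.sqrt(vec["var_e0"] * vec["var_e1"])
    kw = {k: v for k, v in vec.items() if k != "corr_e01"}
    kw["cov_e01"] = cov
    return LGCMParams(**kw)


class WaldTest(NamedTuple):
    z: float
    pvalue: float
    ci95: tuple[float, float]


def wald_test(estimate: float, se: float) -> WaldTest:
    """Wald z statistic, two-sided p value and 95% CI for one coefficient."""
    if not se > 0:
        raise ValueError(f"standard error must be positive, got {se}")
    z = estimate / se
    p = 2.0 * stats.norm.sf(abs(z))
    half = Z_95 * se
    return WaldTest(z=float(z), pvalue=float(p), ci95=(estimate - half, estimate + half))


@dataclass
class FitResult:
    """Maximum-likelihood fit: estimates, Wald inference and convergence state."""

    params: LGCMParams
    se: dict
    wald: dict
    pvalue: dict
    ci95: dict
    loglik: float
    converged: bool
    n_iter: int
    n_participants: int
    message: str = ""

    def summary_rows(self) -> list[dict]:
        """Table-style rows (beta, 95% limits, Wald, p) for each free fixed effect."""
        rows = []
        for name in FIXED_EFFECT_NAMES:
            if name not in self.se:
                continue
            lo, hi = self.ci95[name]
            rows.append(
                {
                    "term": name,
                    "beta": getattr(self.params, name),
                    "ll95": lo,
                    "ul95": hi,
                    "wald": self.wald[name],
                    "pvalue": self.pvalue[name],
                }
            )
        return rows


def _prepare(y, covariates, basis: TimeBasis):
    ya = np.asarray(y, dtype=float)
    if ya.ndim == 1:
        ya = ya[None, :]
    if isinstance(covariates, Covariates):
        cov = np.tile([covariates.g_exp, covariates.g_female], (ya.shape[0], 1)).astype(float)
    else:
        cov = np.asarray(covariates, dtype=float)
    obs_per_wave = (~np.isnan(ya)).sum(axis=0)
    if (obs_per_wave == 0).any():
        waves = np.nonzero(obs_per_wave == 0)[0] + 1
        raise ValueError(f"outcome has no observed values at wave(s) {list(waves)}")
    if len(set(basis.loadings)) < 2:
        raise ValueError("slope is unidentifiable: need >= 2 distinct time loadings")
    return ya, cov


def fit_ml(
    y,
    covariates,
    basis: TimeBasis,
    spec: ModelSpec | None = None,
    *,
    jitter: float = DEFAULT_JITTER,
    maxiter: int = 500,
    tol: float = 1e-11,
) -> FitResult:
    """Maximise the FIML log-likelihood by bounded L-BFGS-B.

    Fixed effects are unbounded; variance components are bounded below at
    1e-8.  Initial values: the intercept grand mean at the mean of observed
    baseline values, slope terms at 0, the observed outcome variance split
    equally across the three variance components, covariance at 0.  A second
    start with a moment-based variance split guards against a boundary local
    maximum at zero slope variance; the better optimum is kept.  Standard
    errors come from the inverse of the negative numerical Hessian at the
    optimum (central differences, variances on the log scale; pseudo-inverse
    fallback with the 1e-4 jitter rule if the Hessian is singular).

    Non-convergence is reported via ``converged=False`` on the result, not an
    exception.
    """
    spec = spec or ModelSpec()
    ya, cov = _prepare(y, covariates, basis)
    fixed = spec.fixed_values()
    if "cov_e01" in fixed:
        if fixed["cov_e01"] != 0.0:
            raise ValueError("only cov_e01 = 0 can be held fixed")
        fixed = {**{k: v for k, v in fixed.items() if k != "cov_e01"}, "corr_e01": 0.0}

    base_y = ya[:, 0]
    grand_mean = float(np.nanmean(base_y)) if np.isfinite(np.nanmean(base_y)) else 0.0
    total_var = float(np.nanvar(ya, ddof=1))
    if not np.isfinite(total_var) or total_var <= 0:
        total_var = 1.0
    init = {
        "b00": grand_mean, "b0exp": 0.0, "b0female": 0.0,
        "b10": 0.0, "b1exp": 0.0, "b1female": 0.0,
        "var_e0": total_var / 3.0, "var_e1": total_var / 3.0,
        "corr_e01": 0.0, "var_e2": total_var / 3.0,
    }
    # second start from crude moments: the equal split grossly overstates the
    # slope variance, which can strand L-BFGS-B on the var_e1 = 0 boundary
    f = basis.loading_array()
    dfl = f[-1] - f[0]
    base_var = float(np.nanvar(base_y, ddof=1))
    if not np.isfinite(base_var) or base_var <= 0:
        base_var = total_var
    change = ya[:, -1] - ya[:, 0]
    change_var = float(np.nanvar(change, ddof=1))
    if not np.isfinite(change_var) or change_var <= 0:
        change_var = total_var
    v2_m = base_var / 3.0
    init_moment = dict(init)
    init_moment.update({
        "var_e0": max(base_var - v2_m, _VAR_FLOOR),
        "var_e1": max((change_var - 2.0 * v2_m) / dfl**2, base_var / 100.0),
        "var_e2": v2_m,
    })
    free = [n for n in _OPT_NAMES if n not in fixed]
    starts = [np.array([ini[n] for n in free]) for ini in (init, init_moment)]
    bounds = []
    for n in free:
        if n.startswith("var_"):
            bounds.append((_VAR_FLOOR, None))
        elif n == "corr_e01":
            bounds.append((-_CORR_BOUND, _CORR_BOUND))
        else:
            bounds.append((None, None))

    data = FimlData(ya, cov, basis)

    def negll(x: np.ndarray) -> float:
        vec = dict(fixed)
        vec.update(zip(free, x))
        try:
            params = _vec_to_params(vec)
        except ValueError:
            return 1e12
        ll = data.loglik(params, jitter=jitter, validate=False)
        return -ll if np.isfinite(ll) else 1e12

    opts = {"maxiter": maxiter, "ftol": tol, "gtol": 1e-7}
    res = None
    n_iter_total = 0
    for x0 in starts:
        cand = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds, options=opts)
        n_iter_total += int(cand.nit)
        if res is None or cand.fun < res.fun:
            res = cand
    # restart from the solution: resets the quasi-Newton curvature estimate and
    # recovers the occasional early stop on a flat ridge
    for _ in range(2):
        res2 = optimize.minimize(negll, res.x, method="L-BFGS-B", bounds=bounds, options=opts)
        n_iter_total += int(res2.nit)
        improved = res2.fun < res.fun - 1e-9 * max(1.0, abs(res.fun))
        if res2.fun <= res.fun:
            res = res2
        if not improved:
            break
    vec = dict(fixed)
    vec.update(zip(free, res.x))
    params = _vec_to_params(vec)
    loglik = -float(res.fun)

    se, wald, pvalue, ci95 = _wald_block(negll, res.x, free, fixed, jitter)
    return FitResult(
        params=params, se=se, wald=wald, pvalue=pvalue, ci95=ci95,
        loglik=loglik, converged=bool(res.success and np.isfinite(loglik)),
        n_iter=n_iter_total, n_participants=ya.shape[0], message=str(res.message),
    )


def _wald_block(negll, xopt, free, fixed, jitter):
    """SEs for the free fixed effects from the numerical observed information.

    The Hessian is taken with variance components on the log scale for
    stability; fixed-effect SEs are invariant to that reparameterisation.
    """
    logvar = [n.startswith("var_") for n in free]

    def neg_t(phi: np.ndarray) -> float:
        x = np.where(logvar, np.exp(phi), phi)
        return negll(x)

    phi0 = np.where(logvar, np.log(np.maximum(xopt, _VAR_FLOOR)), xopt)
    p = len(phi0)
    h = 1e-4 * (1.0 + np.abs(phi0))
    hess = np.empty((p, p))
    f0 = neg_t(phi0)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        hess[i, i] = (neg_t(phi0 + ei) - 2 * f0 + neg_t(phi0 - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(p); ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                neg_t(phi0 + ei + ej) - neg_t(phi0 + ei - ej)
                - neg_t(phi0 - ei + ej) + neg_t(phi0 - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess + jitter * np.eye(p))
    variances = np.diag(cov)

    se, wald, pvalue, ci95 = {}, {}, {}, {}
    xopt_map = dict(zip(free, xopt))
    for i, name in enumerate(free):
        if name not in FIXED_EFFECT_NAMES:
            continue
        v = variances[i]
        if not np.isfinite(v) or v <= 0:
            se[name] = float("nan")
            wald[name] = float("nan")
            pvalue[name] = float("nan")
            ci95[name] = (float("nan"), float("nan"))
            continue
        s = float(np.sqrt(v))
        wt = wald_test(xopt_map[name], s)
        se[name], wald[name], pvalue[name], ci95[name] = s, wt.z, wt.pvalue, wt.ci95
    return se, wald, pvalue, ci95


# ---------------------------------------------------------------------------
# Bayesian route: adaptive random-walk Metropolis + diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Priors:
    """Default weakly-informative priors, scaled by the observed outcome SD.

    Fixed effects: Normal(0, fixed_scale * sd_y).  SD-scale variance
    parameters: half-Normal(0, sd_scale * sd_y).  Intercept-slope correlation:
    Uniform(-1, 1).  The intercept grand mean is centred at the observed
    baseline mean rather than 0 so chains start in a sensible region.
    """

    fixed_scale: float = 10.0
    sd_scale: float = 5.0


@dataclass
class PosteriorResult:
    """Retained draws, convergence diagnostics and the pointwise log-likelihood."""

    draws: np.ndarray           # (n_chains, n_draws, n_params)
    param_names: tuple
    pointwise_loglik: np.ndarray  # (n_chains * n_draws, n_participants)
    rhat: dict
    accept_rate: float
    seed: int

    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def params_at(self, chain: int, draw: int, fixed: dict) -> LGCMParams:
        vec = dict(fixed)
        vec.update(zip(self.param_names, self.draws[chain, draw]))
        return _sampler_vec_to_params(vec)

    def waic(self) -> "WaicResult":
        return waic(self.pointwise_loglik)

    def loo(self) -> "LooResult":
        return loo(self.pointwise_loglik)


# sampler parameterisation: fixed effects raw, variances as SDs, correlation raw
_SAMPLER_ALL = (
    "b00", "b0exp", "b0female", "b10", "b1exp", "b1female",
    "sd_e0", "sd_e1", "corr_e01", "sd_e2",
)


def _sampler_vec_to_params(vec: dict) -> LGCMParams:
    cov = vec["corr_e01"] * vec["sd_e0"] * vec["sd_e1"]
    return LGCMParams(
        b00=vec["b00"], b0exp=vec["b0exp"], b0female=vec["b0female"],
        b10=vec["b10"], b1exp=vec["b1exp"], b1female=vec["b1female"],
        var_e0=vec["sd_e0"] ** 2, var_e1=vec["sd_e1"] ** 2,
        cov_e01=cov, var_e2=vec["sd_e2"] ** 2,
    )


def sample_posterior(
    y,
    covariates,
    basis: TimeBasis,
    *,
    priors: Priors | None = None,
    n_chains: int = 2,
    n_iter: int = 2000,
    n_warmup: int | None = None,
    seed: int = 0,
    spec: ModelSpec | None = None,
    jitter: float = DEFAULT_JITTER,
) -> PosteriorResult:
    """Adaptive random-walk Metropolis over prior x exp(FIML log-likelihood).

    ``n_iter`` draws per chain are retained after ``n_warmup`` adaptation
    iterations (default: equal to ``n_iter``).  During warmup the proposal is
    a scaled empirical-covariance Gaussian (Haario-style) with the global
    scale tuned toward a 0.234 acceptance rate; adaptation is frozen
    afterwards so the retained chain is a valid Markov chain.  The chains are
    split deterministically from ``seed``; reruns are bit-reproducible.
    """
    if n_chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")
    priors = priors or Priors()
    spec = spec or ModelSpec()
    ya, cov = _prepare(y, covariates, basis)
    n_warmup = n_iter if n_warmup is None else n_warmup

    fixed_in = spec.fixed_values()
    fixed = {}
    for k, v in fixed_in.items():
        if k == "cov_e01":
            if v != 0.0:
                raise ValueError("only cov_e01 = 0 can be held fixed")
            fixed["corr_e01"] = 0.0
        elif k.startswith("var_"):
            fixed["sd_e" + k[-1]] = float(np.sqrt(v))
        else:
            fixed[k] = v
    free = [n for n in _SAMPLER_ALL if n not in fixed]
    p = len(free)

    sd_y = float(np.nanstd(ya, ddof=1))
    sd_y = sd_y if np.isfinite(sd_y) and sd_y > 0 else 1.0
    mean_y = float(np.nanmean(ya))
    f_scale = priors.fixed_scale * sd_y
    s_scale = priors.sd_scale * sd_y

    is_sd = np.array([n.startswith("sd_") for n in free])
    is_corr = np.array([n == "corr_e01" for n in free])
    is_b00 = np.array([n == "b00" for n in free])

    def log_prior(x: np.ndarray) -> float:
        if np.any(x[is_sd] < 0) or np.any(np.abs(x[is_corr]) >= 1):
            return -np.inf
        lp = 0.0
        fe = ~(is_sd | is_corr)
        centred = np.where(is_b00[fe], x[fe] - mean_y, x[fe])
        lp += float(-0.5 * np.sum((centred / f_scale) ** 2))
        lp += float(-0.5 * np.sum((x[is_sd] / s_scale) ** 2))
        return lp

    data = FimlData(ya, cov, basis)

    def log_post(x: np.ndarray):
        lp = log_prior(x)
        if not np.isfinite(lp):
            return -np.inf, None
        vec = dict(fixed)
        vec.update(zip(free, x))
        ll, per = data.loglik(_sampler_vec_to_params(vec), jitter=jitter,
                              pointwise=True, validate=False)
        if not np.isfinite(ll):
            return -np.inf, None
        return lp + ll, per

    init = {
        "b00": mean_y, "b0exp": 0.0, "b0female": 0.0,
        "b10": 0.0, "b1exp": 0.0, "b1female": 0.0,
        "sd_e0": sd_y / np.sqrt(3), "sd_e1": sd_y / np.sqrt(3),
        "corr_e01": 0.0, "sd_e2": sd_y / np.sqrt(3),
    }
    x_init = np.array([init[n] for n in free])
    init_scale = np.where(is_sd | is_corr, 0.1, 0.5) * np.maximum(np.abs(x_init), sd_y / 10)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_chains)
    n_pts = ya.shape[0]
    draws = np.empty((n_chains, n_iter, p))
    pls = np.empty((n_chains, n_iter, n_pts))
    n_acc = 0

    for c, child in enumerate(children):
        rng = np.random.default_rng(child)
        x = x_init + 0.01 * init_scale * rng.standard_normal(p)
        lp_cur, per_cur = log_post(x)
        tries = 0
        while not np.isfinite(lp_cur):
            x = x_init + 0.01 * init_scale * rng.standard_normal(p)
            lp_cur, per_cur = log_post(x)
            tries += 1
            if tries > 100:
                raise RuntimeError(
                    "could not find a finite starting posterior density near the "
                    f"initial point {dict(zip(free, x_init))}"
                )
        log_s = np.log(2.38 / np.sqrt(p))
        chol = np.diag(init_scale)
        hist = np.empty((n_warmup, p))
        for it in range(n_warmup + n_iter):
            prop = x + np.exp(log_s) * (chol @ rng.standard_normal(p))
            lp_prop, per_prop = log_post(prop)
            diff = lp_prop - lp_cur
            alpha = float(np.exp(min(0.0, diff))) if np.isfinite(lp_prop) else 0.0
            accept = np.log(rng.uniform()) < diff
            if accept:
                x, lp_cur, per_cur = prop, lp_prop, per_prop
            if it < n_warmup:
                hist[it] = x
                log_s += (alpha - 0.234) / (1 + it) ** 0.6
                if it >= 99 and (it + 1) % 100 == 0:
                    emp = np.cov(hist[max(0, it - 499): it + 1].T) + 1e-10 * np.eye(p)
                    try:
                        chol = np.linalg.cholesky(emp)
                    except np.linalg.LinAlgError:
                        pass
            else:
                keep = it - n_warmup
                draws[c, keep] = x
                pls[c, keep] = per_cur
                n_acc += int(accept)

    if not np.all(np.isfinite(pls)):
        raise RuntimeError("non-finite pointwise log-likelihood among retained draws")
    rhat_vals = gelman_rubin(draws)
    return PosteriorResult(
        draws=draws,
        param_names=tuple(free),
        pointwise_loglik=pls.reshape(-1, n_pts),
        rhat=dict(zip(free, rhat_vals)),
        accept_rate=n_acc / (n_chains * n_iter),
        seed=seed,
    )


def gelman_rubin(draws) -> np.ndarray:
    """Split-chain Gelman-Rubin R-hat per parameter.

    ``draws`` has shape ``(n_chains, n_iter, n_params)`` (a 2-D array is
    treated as one parameter).  Each chain is split in half; with chain length
    n, within-chain variance W and between-chain variance B,
    R-hat = sqrt(((n-1)/n * W + B/n) / W).  If W = 0 while chains disagree the
    statistic is +inf; identical constant chains give 1.
    """
    arr = np.asarray(draws, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    m, n, p = arr.shape
    if m < 2 or n < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    half = n // 2
    split = np.concatenate([arr[:, :half], arr[:, half: 2 * half]], axis=0)
    n = half
    means = split.mean(axis=1)                    # (2m, p)
    variances = split.var(axis=1, ddof=1)         # (2m, p)
    w = variances.mean(axis=0)
    b = n * means.var(axis=0, ddof=1)
    out = np.empty(p)
    for j in range(p):
        if w[j] > 0:
            out[j] = np.sqrt(((n - 1) / n * w[j] + b[j] / n) / w[j])
        else:
            out[j] = 1.0 if b[j] == 0 else np.inf
    return out


class WaicResult(NamedTuple):
    elpd_waic: float
    p_waic: float
    deviance: float
    elpd_i: np.ndarray
    se: float


class LooResult(NamedTuple):
    elpd_loo: float
    p_loo: float
    deviance: float
    elpd_i: np.ndarray
    se: float
    unstable: np.ndarray  # participants whose importance weights concentrate


def _check_ll(pointwise_loglik) -> np.ndarray:
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.size == 0:
        raise ValueError("pointwise log-likelihood must be a non-empty (draws x units) matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihood contains non-finite entries")
    return ll


def waic(pointwise_loglik) -> WaicResult:
    """Widely applicable information criterion from a (draws x units) matrix.

    elpd_waic = sum_i [ log mean_s exp(ll_si) - var_s(ll_si) ]; the deviance
    scale is -2 * elpd_waic.  A single draw has zero penalty by convention.
    """
    ll = _check_ll(pointwise_loglik)
    s = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(s)
    p_i = ll.var(axis=0, ddof=1) if s > 1 else np.zeros(ll.shape[1])
    elpd_i = lppd_i - p_i
    elpd = float(elpd_i.sum())
    se = float(np.sqrt(ll.shape[1] * elpd_i.var(ddof=1))) if ll.shape[1] > 1 else 0.0
    return WaicResult(elpd, float(p_i.sum()), -2.0 * elpd, elpd_i, se)


def loo(pointwise_loglik, *, weight_warn: float = 0.5) -> LooResult:
    """Importance-sampling leave-one-out cross-validation with truncated weights.

    Raw per-draw weights for unit i are 1/exp(ll_si); following standard
    truncated importance sampling they are capped at mean-weight * S^(3/4)
    before forming elpd_loo_i = log( sum_s w_si exp(ll_si) / sum_s w_si ).
    Units whose largest normalised weight exceeds ``weight_warn`` are flagged
    as unstable.  The deviance scale is -2 * elpd_loo.
    """
    ll = _check_ll(pointwise_loglik)
    s = ll.shape[0]
    lw_raw = -ll                                   # log raw weights
    cap = (logsumexp(lw_raw, axis=0) - np.log(s)) + 0.75 * np.log(s)
    lw = np.minimum(lw_raw, cap[None, :])
    norm = logsumexp(lw, axis=0)
    elpd_i = logsumexp(lw + ll, axis=0) - norm
    max_w = np.exp(lw.max(axis=0) - norm)
    lppd_i = logsumexp(ll, axis=0) - np.log(s)
    elpd = float(elpd_i.sum())
    se = float(np.sqrt(ll.shape[1] * elpd_i.var(ddof=1))) if ll.shape[1] > 1 else 0.0
    return LooResult(
        elpd, float((lppd_i - elpd_i).sum()), -2.0 * elpd, elpd_i, se,
        unstable=max_w > weight_warn,
    )
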