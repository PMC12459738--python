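"""Latent growth curve model: implied moments and the FIML observed-data likelihood.

The model gives participant *i* at wave *t* the outcome

    Y[it] = B0[i] + B1[i] * F[t] + E2[it]
    B0[i] = b00 + b0exp * Gexp[i] + b0female * Gfemale[i] + E0[i]
    B1[i] = b10 + b1exp * Gexp[i] + b1female * Gfemale[i] + E1[i]

with (E0, E1) bivariate normal with covariance Psi and E2 iid N(0, var_e2).
Stacking the waves, Y_i ~ N(mu_i, Lambda Psi Lambda' + var_e2 I) where row t of
Lambda is (1, F[t]).  Missing waves are handled by full-information maximum
likelihood (FIML): each participant contributes the normal density of their
*observed* sub-vector, so incomplete cases are never discarded.

Numerical conventions: a jitter of 1e-4 is added to the diagonal of each
observed sub-matrix immediately before inversion to keep it positive definite;
if the jittered matrix is still singular a pseudo-inverse is used together
with a pseudo-log-determinant (product of eigenvalues above 1e-12).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .measures import TimeBasis

__all__ = [
    "LGCMParams",
    "Covariates",
    "PARAM_NAMES",
    "FIXED_EFFECT_NAMES",
    "VARIANCE_NAMES",
    "DEFAULT_JITTER",
    "implied_moments",
    "fiml_loglik",
    "FimlData",
]

DEFAULT_JITTER = 1e-4
_PSEUDO_DET_TOL = 1e-12

FIXED_EFFECT_NAMES = ("b00", "b0exp", "b0female", "b10", "b1exp", "b1female")
VARIANCE_NAMES = ("var_e0", "var_e1", "cov_e01", "var_e2")
PARAM_NAMES = FIXED_EFFECT_NAMES + VARIANCE_NAMES


@dataclass(frozen=True)
class LGCMParams:
    """Fixed effects and variance components of the growth model.

    Intercept terms are in outcome units; slope terms are outcome units per
    unit of the time loading F.  ``var_e0``/``var_e1``/``cov_e01`` parameterise
    the random intercept-slope covariance Psi; ``var_e2`` is the residual
    (wave-level) variance, shared across waves.
    """

    b00: float = 0.0
    b0exp: float = 0.0
    b0female: float = 0.0
    b10: float = 0.0
    b1exp: float = 0.0
    b1female: float = 0.0
    var_e0: float = 0.0
    var_e1: float = 0.0
    cov_e01: float = 0.0
    var_e2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("var_e0", "var_e1", "var_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def psi(self) -> np.ndarray:
        """The 2x2 random-effect covariance matrix [[var_e0, cov], [cov, var_e1]]."""
        return np.array(
            [[self.var_e0, self.cov_e01], [self.cov_e01, self.var_e1]], dtype=float
        )

    def validate_psd(self, tol: float = 1e-10) -> None:
        """Raise if the random-effect covariance is not positive semidefinite."""
        if np.linalg.eigvalsh(self.psi).min() < -tol:
            raise ValueError(
                "random-effect matrix is not positive semidefinite: "
                f"cov_e01^2 = {self.cov_e01 ** 2:.6g} exceeds "
                f"var_e0*var_e1 = {self.var_e0 * self.var_e1:.6g}"
            )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "LGCMParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, arr))))

    def replace(self, **kw) -> "LGCMParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class Covariates:
    """Arm and gender indicators: g_exp = 1 for the experimental arm, g_female = 1 for women."""

    g_exp: int = 0
    g_female: int = 0

    def __post_init__(self) -> None:
        if self.g_exp not in (0, 1) or self.g_female not in (0, 1):
            raise ValueError("covariate indicators must be 0 or 1")


def _mean_vector(params: LGCMParams, g_exp: float, g_female: float, f: np.ndarray) -> np.ndarray:
    b0 = params.b00 + params.b0exp * g_exp + params.b0female * g_female
    b1 = params.b10 + params.b1exp * g_exp + params.b1female * g_female
    return b0 + b1 * f


def implied_moments(
    params: LGCMParams, cov: Covariates, basis: TimeBasis
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix over the waves.

    mean[t] = (b00 + b0exp g_exp + b0female g_female)
              + (b10 + b1exp g_exp + b1female g_female) * F[t]
    cov     = Lambda Psi Lambda' + var_e2 * I,  Lambda[t] = (1, F[t])

    The returned covariance is exactly symmetric and positive semidefinite.
    """
    params.validate_psd()
    f = basis.loading_array()
    lam = np.column_stack([np.ones_like(f), f])
    sigma = lam @ params.psi @ lam.T + params.var_e2 * np.eye(len(f))
    sigma = 0.5 * (sigma + sigma.T)
    return _mean_vector(params, cov.g_exp, cov.g_female, f), sigma


def _logdet_and_solve(sigma: np.ndarray, resid: np.ndarray) -> tuple[float, np.ndarray]:
    """Log-determinant of ``sigma`` and quadratic forms r' sigma^{-1} r per row of resid.

    Cholesky when possible; otherwise the pseudo-inverse / pseudo-determinant
    branch (eigenvalues above 1e-12 retained, null directions dropped).
    """
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(sigma)
        keep = w > _PSEUDO_DET_TOL
        if not keep.any():
            return 0.0, np.zeros(resid.shape[0])
        logdet = float(np.log(w[keep]).sum())
        proj = resid @ v[:, keep]
        quad = np.einsum("ij,ij->i", proj / w[keep], proj)
        return logdet, quad
    logdet = 2.0 * float(np.log(np.diag(chol)).sum())
    z = np.linalg.solve(chol, resid.T)
    return logdet, np.einsum("ji,ji->i", z, z)


def _as_matrix_inputs(y, covariates, n_waves: int) -> tuple[np.ndarray, np.ndarray]:
    ya = np.asarray(y, dtype=float)
    if ya.ndim == 1:
        ya = ya[None, :]
    if ya.shape[1] != n_waves:
        raise ValueError(
            f"outcome matrix has {ya.shape[1]} waves but the time basis has {n_waves}"
        )
    if isinstance(covariates, Covariates):
        cov = np.tile([covariates.g_exp, covariates.g_female], (ya.shape[0], 1)).astype(float)
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape == (1, 2) and ya.shape[0] > 1:
            cov = np.tile(cov, (ya.shape[0], 1))
    if cov.shape != (ya.shape[0], 2):
        raise ValueError(
            f"covariates shape {cov.shape} does not match {ya.shape[0]} participants x 2"
        )
    return ya, cov


class FimlData:
    """A dataset pre-grouped for repeated FIML likelihood evaluation.

    Rows sharing a missingness pattern and covariate combination share their
    implied mean and covariance, so the likelihood reduces to one Cholesky
    solve per group.  Build once, evaluate :meth:`loglik` many times (this is
    what the optimiser and the sampler do).
    """

    def __init__(self, y, covariates, basis: TimeBasis):
        f = basis.loading_array()
        ya, cov = _as_matrix_inputs(y, covariates, len(f))
        self.n = ya.shape[0]
        self.f = f
        self.lam = np.column_stack([np.ones_like(f), f])
        obs = ~np.isnan(ya)
        keys = np.column_stack([obs.astype(np.int8), cov.astype(np.int8)])
        _, inverse = np.unique(keys, axis=0, return_inverse=True)
        self.groups = []
        for gid in np.unique(inverse):
            rows = np.nonzero(inverse == gid)[0]
            mask = obs[rows[0]]
            if not mask.any():
                continue
            cols = np.nonzero(mask)[0]
            self.groups.append(
                (rows, mask, float(cov[rows[0], 0]), float(cov[rows[0], 1]),
                 ya[np.ix_(rows, cols)])
            )

    def loglik(self, params: LGCMParams, *, jitter: float = DEFAULT_JITTER,
               pointwise: bool = False, validate: bool = True):
        if validate:
            params.validate_psd()
        sigma_full = self.lam @ params.psi @ self.lam.T + params.var_e2 * np.eye(len(self.f))
        sigma_full = 0.5 * (sigma_full + sigma_full.T)
        per = np.zeros(self.n)
        log2pi = np.log(2.0 * np.pi)
        for rows, mask, g_exp, g_female, ysub in self.groups:
            k = ysub.shape[1]
            mu = _mean_vector(params, g_exp, g_female, self.f)[mask]
            sig = sigma_full[np.ix_(mask, mask)] + jitter * np.eye(k)
            logdet, quad = _logdet_and_solve(sig, ysub - mu)
            per[rows] = -0.5 * (k * log2pi + logdet + quad)
        total = float(per.sum())
        return (total, per) if pointwise else total


def fiml_loglik(
    y,
    covariates,
    params: LGCMParams,
    basis: TimeBasis,
    *,
    jitter: float = DEFAULT_JITTER,
    pointwise: bool = False,
):
    """Observed-data (FIML) log-likelihood of the growth model.

    Parameters
    ----------
    y
        ``(n, T)`` outcome matrix with NaN marking missing waves (a single
        participant may be passed as a length-``T`` vector).
    covariates
        ``(n, 2)`` array of ``(g_exp, g_female)`` indicators, or a single
        :class:`Covariates` shared by all rows.
    jitter
        Added to the diagonal of each observed sub-matrix immediately before
        inversion (default 1e-4) so the covariance stays positive.
    pointwise
        Also return the length-``n`` vector of per-participant contributions.

    Participants with no observed waves contribute exactly 0.  Evaluation is
    vectorised over groups sharing a missingness pattern and covariate values
    (see :class:`FimlData` for the reusable pre-grouped form).
    """
    return FimlData(y, covariates, basis).loglik(
        params, jitter=jitter, pointwise=pointwise
    )
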