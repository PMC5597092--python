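"""Linear latent growth model estimated by maximum likelihood.

The model for subject i at wave t is

    y_it = I_i + lambda_t * S_i + eps_it

with latent means (mu_I, mu_S), latent covariance Psi = [[psi_II, psi_IS],
[psi_IS, psi_SS]] and residual variances theta_t.  The implied moments over
waves are mean_t = mu_I + lambda_t mu_S and
cov_ts = psi_II + lambda_t lambda_s psi_SS + (lambda_t + lambda_s) psi_IS
+ [t = s] theta_t.

Estimation routes: listwise deletion (complete cases only), full-information
maximum likelihood over every subject's observed sub-vector, and FIML with
saturated-correlates auxiliary variables (joint normal model with a free
auxiliary block).  All routes share one quasi-Newton fitter operating on
pattern-grouped sufficient statistics, with observed-information standard
errors from a finite-difference Hessian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataio import WideDataset, ConfigurationError

logger = logging.getLogger("lgmsens")

__all__ = [
    "GrowthSpec",
    "GrowthEstimates",
    "implied_moments",
    "fiml_loglik",
    "fit_lgm_listwise",
    "fit_lgm_fiml",
    "fit_lgm_fiml_aux",
    "wald_summary",
]

_PENALTY = 1e12
_VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class GrowthSpec:
    """Skeleton of the growth model: loadings and which parameters are free.

    ``wave_times`` are the slope loadings (intercept loadings are fixed at 1);
    the first must be 0 and they must increase.  ``residual`` chooses
    per-wave-free or homogeneous residual variances.  ``cov_IS_free`` /
    ``slope_var_free`` free or fix (at zero) the latent covariance and the
    slope variance.
    """

    wave_times: tuple
    residual: str = "free"  # "free" | "homogeneous"
    cov_IS_free: bool = True
    slope_var_free: bool = True

    def __post_init__(self):
        lam = np.asarray(self.wave_times, dtype=float)
        object.__setattr__(self, "wave_times", tuple(lam))
        if lam[0] != 0:
            raise ValueError("first slope loading must be 0")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("slope loadings must be strictly increasing")
        if self.residual not in {"free", "homogeneous"}:
            raise ValueError("residual must be 'free' or 'homogeneous'")

    @property
    def n_waves(self) -> int:
        return len(self.wave_times)

    @property
    def lam(self) -> np.ndarray:
        return np.asarray(self.wave_times, dtype=float)

    def param_names(self) -> list[str]:
        names = ["mu_I", "mu_S", "psi_II"]
        if self.slope_var_free:
            names.append("psi_SS")
            if self.cov_IS_free:
                names.append("psi_IS")
        if self.residual == "free":
            names += [f"theta{t + 1}" for t in range(self.n_waves)]
        else:
            names.append("theta")
        # sanity: at least as many observed moments as free parameters
        T = self.n_waves
        if len(names) > T + T * (T + 1) // 2:
            raise ValueError("more free parameters than observed moments")
        return names

    def bounds(self) -> list[tuple]:
        bnds = []
        for name in self.param_names():
            if name.startswith(("psi_II", "psi_SS", "theta")):
                bnds.append((_VAR_FLOOR, None))
            elif name == "psi_IS":
                bnds.append((None, None))
            else:
                bnds.append((None, None))
        return bnds

    def unpack(self, vec: np.ndarray) -> dict:
        d = dict(zip(self.param_names(), np.asarray(vec, dtype=float)))
        d.setdefault("psi_SS", 0.0)
        d.setdefault("psi_IS", 0.0)
        if self.residual == "homogeneous":
            for t in range(self.n_waves):
                d[f"theta{t + 1}"] = d["theta"]
        return d


def implied_moments(params: dict, spec: GrowthSpec) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix over waves.

    ``params`` maps parameter names (``mu_I``, ``mu_S``, ``psi_II``,
    ``psi_SS``, ``psi_IS``, ``theta1..T`` or ``theta``) to values; parameters
    the spec fixes may be omitted (treated as 0).
    """
    lam = spec.lam
    T = spec.n_waves
    mu_I = params["mu_I"]
    mu_S = params["mu_S"]
    psi_II = params.get("psi_II", 0.0)
    psi_SS = params.get("psi_SS", 0.0) if spec.slope_var_free else 0.0
    psi_IS = params.get("psi_IS", 0.0) if (spec.slope_var_free and spec.cov_IS_free) else 0.0
    if spec.residual == "homogeneous":
        theta = np.full(T, params.get("theta", 0.0))
    else:
        theta = np.array([params.get(f"theta{t + 1}", params.get("theta", 0.0)) for t in range(T)])
    mean = mu_I + lam * mu_S
    cov = psi_II + np.outer(lam, lam) * psi_SS + (lam[:, None] + lam[None, :]) * psi_IS
    cov = cov + np.diag(theta)
    return mean, cov


# ---------------------------------------------------------------------------
# pattern-grouped sufficient statistics and the normal log-likelihood
# ---------------------------------------------------------------------------

def suffstats(Y: np.ndarray) -> list[tuple]:
    """Group rows of an (n, p) matrix with NaNs by missingness pattern.

    Returns a list of (observed-column index, n_j, mean_j, scatter_j); rows
    with no observed entry are rejected.
    """
    Y = np.asarray(Y, dtype=float)
    mask = ~np.isnan(Y)
    if not mask.any(axis=1).all():
        raise ValueError("every subject must have >= 1 observed value")
    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    out = []
    for j, pat in enumerate(patterns):
        rows = inverse == j
        obs = np.flatnonzero(pat)
        yo = Y[np.ix_(rows, obs)]
        ybar = yo.mean(axis=0)
        dev = yo - ybar
        out.append((obs, yo.shape[0], ybar, dev.T @ dev))
    return out


def normal_loglik(stats_list: list[tuple], mu: np.ndarray, sigma: np.ndarray) -> float:
    """Observed-data multivariate-normal log-likelihood from suffstats.

    Returns -inf when an observed submatrix is not positive definite.
    """
    ll = 0.0
    for obs, nj, ybar, scatter in stats_list:
        so = sigma[np.ix_(obs, obs)]
        try:
            L = np.linalg.cholesky(so)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.log(np.diag(L)).sum()
        inv = np.linalg.inv(so)
        d = ybar - mu[obs]
        ll += -0.5 * (
            nj * len(obs) * np.log(2 * np.pi)
            + nj * logdet
            + float(np.trace(inv @ scatter))
            + nj * float(d @ inv @ d)
        )
    return ll


def fiml_loglik(params: dict, spec: GrowthSpec, ds: WideDataset) -> float:
    """Full-information log-likelihood of the growth model on the dataset.

    Each subject contributes the normal log-density of its observed
    sub-vector under the implied moments' corresponding sub-mean and
    sub-matrix; contributions are summed over subjects.
    """
    mu, sigma = implied_moments(params, spec)
    return normal_loglik(suffstats(ds.y), mu, sigma)


# ---------------------------------------------------------------------------
# generic fitter
# ---------------------------------------------------------------------------

@dataclass
class GrowthEstimates:
    """One technique's fitted growth parameters with inference."""

    technique: str
    params: dict
    se: dict
    loglik: float
    n_used: int
    converged: bool
    spec: GrowthSpec = field(repr=False, default=None)
    cov: pd.DataFrame = field(repr=False, default=None)
    n_iter: int = 0
    grad_norm: float = np.nan
    extra: dict = field(default_factory=dict, repr=False)  # aux/nuisance block

    @property
    def z(self) -> dict:
        return {
            k: (self.params[k] / self.se[k]) if self.se.get(k, 0) else np.nan
            for k in self.params
        }

    @property
    def p(self) -> dict:
        return {
            k: 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            for k, z in self.z.items()
        }


def _fd_hessian(f, x: np.ndarray) -> np.ndarray:
    """Central finite-difference Hessian with step 1e-5 * max(|x_i|, 1)."""
    k = len(x)
    h = 1e-5 * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


# deterministic multiplicative jitters for the restarts (no RNG involved)
_RESTART_JITTER = (1.0, 0.85, 1.2)


def fit_normal_model(
    objective_stats: list,
    moments_fn,
    start: np.ndarray,
    bounds: list[tuple],
    names: list[str],
    technique: str,
    n_used: int,
    spec: GrowthSpec | None = None,
    restarts: int = 3,
) -> GrowthEstimates:
    """Maximize a pattern-grouped normal likelihood by L-BFGS-B.

    ``objective_stats`` is a list of per-group suffstats lists and
    ``moments_fn(vec)`` must return the matching list of (mu, sigma) pairs.
    Three deterministic restarts from jittered starts; best log-likelihood
    wins, ties broken by the first.
    """

    def negloglik(vec):
        ll = 0.0
        for stats_g, (mu, sigma) in zip(objective_stats, moments_fn(vec)):
            lg = normal_loglik(stats_g, mu, sigma)
            if not np.isfinite(lg):
                return _PENALTY
            ll += lg
        return -ll

    best = None
    for r in range(restarts):
        x0 = np.array(start, dtype=float)
        scale = _RESTART_JITTER[r % len(_RESTART_JITTER)]
        if r > 0:
            x0 = np.where(np.abs(x0) > 1e-6, x0 * scale, x0 + 0.01 * (scale - 1.0))
        x0 = np.clip(
            x0,
            [b[0] if b[0] is not None else -np.inf for b in bounds],
            [b[1] if b[1] is not None else np.inf for b in bounds],
        )
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    converged = bool(best.success) and best.fun < _PENALTY / 2
    if not converged:
        logger.warning(
            "%s fit did not converge cleanly (status %s, |grad| %.3g)",
            technique, best.message, np.max(np.abs(best.jac)),
        )
    xhat = best.x
    H = _fd_hessian(negloglik, xhat)
    se = np.full(len(xhat), np.nan)
    cov = None
    try:
        covm = np.linalg.inv(H)
        diag = np.diag(covm).copy()
        bad = diag <= 0
        if bad.any():
            covm = np.linalg.pinv(H)
            diag = np.diag(covm).copy()
        se = np.sqrt(np.where(diag > 0, diag, np.nan))
        cov = pd.DataFrame(covm, index=names, columns=names)
    except np.linalg.LinAlgError:
        logger.warning("%s: singular observed information; SEs unavailable", technique)
    return GrowthEstimates(
        technique=technique,
        params=dict(zip(names, xhat)),
        se=dict(zip(names, se)),
        loglik=-best.fun,
        n_used=n_used,
        converged=converged,
        spec=spec,
        cov=cov,
        n_iter=int(best.nit),
        grad_norm=float(np.max(np.abs(best.jac))),
    )


def _moment_start(ds: WideDataset, spec: GrowthSpec) -> np.ndarray:
    """Moment-based starting values from available-case statistics."""
    lam = spec.lam
    with np.errstate(invalid="ignore"):
        means = np.nanmean(ds.y, axis=0)
        vars_ = np.nanvar(ds.y, axis=0)
    means = np.nan_to_num(means, nan=float(np.nanmean(ds.y)))
    vars_ = np.where(np.isnan(vars_) | (vars_ <= 0), 0.5, vars_)
    # OLS of wave means on loadings for the latent means
    X = np.column_stack([np.ones_like(lam), lam])
    beta, *_ = np.linalg.lstsq(X, means, rcond=None)
    start = {
        "mu_I": beta[0],
        "mu_S": beta[1],
        "psi_II": max(0.5 * vars_[0], _VAR_FLOOR),
        "psi_SS": 0.01,
        "psi_IS": 0.0,
    }
    values = []
    for name in spec.param_names():
        if name.startswith("theta"):
            t = int(name[5:]) - 1 if name != "theta" else None
            values.append(max(0.5 * (vars_[t] if t is not None else vars_.mean()), _VAR_FLOOR))
        else:
            values.append(start[name])
    return np.array(values)


def _fit_lgm(ds: WideDataset, spec: GrowthSpec, technique: str) -> GrowthEstimates:
    names = spec.param_names()
    stats_list = suffstats(ds.y)

    def moments(vec):
        return [implied_moments(spec.unpack(vec), spec)]

    return fit_normal_model(
        [stats_list], moments, _moment_start(ds, spec), spec.bounds(), names,
        technique, n_used=ds.n, spec=spec,
    )


def fit_lgm_listwise(ds: WideDataset, spec: GrowthSpec) -> GrowthEstimates:
    """ML growth fit on complete cases only (listwise deletion)."""
    cc = ds.complete_cases()
    k = len(spec.param_names())
    if cc.n <= k:
        raise ValueError(f"only {cc.n} complete cases for {k} free parameters")
    est = _fit_lgm(cc, spec, "LD")
    return est


def fit_lgm_fiml(ds: WideDataset, spec: GrowthSpec) -> GrowthEstimates:
    """FIML growth fit on all subjects with >= 1 observed wave."""
    return _fit_lgm(ds, spec, "ML")


def wald_summary(est: GrowthEstimates, alphas=(0.05, 0.01, 0.001)) -> pd.DataFrame:
    """Per-parameter z, p, significance stars and symmetric 95% CI."""
    rows = []
    zcrit = stats.norm.ppf(0.975)
    for name, value in est.params.items():
        se = est.se.get(name, np.nan)
        z = value / se if se and np.isfinite(se) and se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        stars = ""
        if np.isfinite(p):
            for a, s in zip(sorted(alphas), ("***", "**", "*")):
                if p < a:
                    stars = s
                    break
        rows.append(
            {
                "parameter": name,
                "estimate": value,
                "se": se,
                "z": z,
                "p": p,
                "stars": stars,
                "ci_low": value - zcrit * se if np.isfinite(se) else np.nan,
                "ci_high": value + zcrit * se if np.isfinite(se) else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FIML with saturated-correlates auxiliary variables
# ---------------------------------------------------------------------------

def _aux_matrix(ds: WideDataset, aux_columns: list[str] | None) -> tuple[np.ndarray, list[str]]:
    if ds.aux is None or ds.aux.shape[1] == 0:
        raise ConfigurationError("dataset has no auxiliary variables")
    cols = list(aux_columns) if aux_columns else list(ds.aux.columns)
    sub = ds.aux[cols]
    num = sub.select_dtypes(include=[np.number])
    cat = sub.drop(columns=num.columns)
    parts = [num]
    if len(cat.columns):
        parts.append(pd.get_dummies(cat, drop_first=True, dtype=float))
    X = pd.concat(parts, axis=1)
    for c in X.columns:
        v = X[c].to_numpy(dtype=float)
        if np.nanstd(v) == 0:
            raise ConfigurationError(f"auxiliary {c!r} has zero variance")
    return X.to_numpy(dtype=float), list(X.columns)


def fit_lgm_fiml_aux(
    ds: WideDataset, spec: GrowthSpec, aux_columns: list[str] | None = None
) -> GrowthEstimates:
    """FIML with auxiliary variables via the saturated-correlates device.

    The joint vector (y, aux) is modelled as multivariate normal: the outcome
    block keeps the growth structure, while the auxiliary means, the
    auxiliary covariance block and the auxiliary-outcome cross-covariances
    are all free (saturated).  Growth parameters and their standard errors
    are reported; the saturated block is nuisance.
    """
    A, aux_names = _aux_matrix(ds, aux_columns)
    T = spec.n_waves
    K = A.shape[1]
    n_complete = int(ds.mask.all(axis=1).sum())
    if K > max(n_complete, 1) / 3:
        logger.warning(
            "%d auxiliary variables exceeds 1/3 of the %d complete cases; "
            "estimates may be unstable", K, n_complete,
        )
    J = np.column_stack([ds.y, A])
    # joint rows must keep >= 1 observed entry; outcome already guarantees it
    stats_list = suffstats(J)

    growth_names = spec.param_names()
    names = list(growth_names)
    names += [f"aux_mean[{c}]" for c in aux_names]
    chol_idx = [(i, j) for i in range(K) for j in range(i + 1)]
    names += [f"aux_chol[{i},{j}]" for i, j in chol_idx]
    names += [f"cross[{w},{c}]" for w in range(T) for c in aux_names]

    bounds = spec.bounds()
    bounds += [(None, None)] * K
    bounds += [(_VAR_FLOOR, None) if i == j else (None, None) for i, j in chol_idx]
    bounds += [(None, None)] * (T * K)

    ng = len(growth_names)

    def moments(vec):
        d = spec.unpack(vec[:ng])
        mu_y, sig_y = implied_moments(d, spec)
        pos = ng
        mu_a = vec[pos:pos + K]
        pos += K
        L = np.zeros((K, K))
        for (i, j), v in zip(chol_idx, vec[pos:pos + len(chol_idx)]):
            L[i, j] = v
        pos += len(chol_idx)
        sig_a = L @ L.T
        cross = vec[pos:pos + T * K].reshape(T, K)
        mu = np.concatenate([mu_y, mu_a])
        sigma = np.block([[sig_y, cross], [cross.T, sig_a]])
        return [(mu, sigma)]

    # starting values: growth moments + available-case aux moments
    start = list(_moment_start(ds, spec))
    with np.errstate(invalid="ignore"):
        mu_a0 = np.nanmean(A, axis=0)
        cov_a0 = np.zeros((K, K))
        for i in range(K):
            for j in range(K):
                ok = ~np.isnan(A[:, i]) & ~np.isnan(A[:, j])
                if ok.sum() > 2:
                    cov_a0[i, j] = np.cov(A[ok, i], A[ok, j], ddof=0)[0, 1]
        cov_a0 += np.eye(K) * 1e-3
    L0 = np.linalg.cholesky(cov_a0)
    start += list(np.nan_to_num(mu_a0))
    start += [L0[i, j] for i, j in chol_idx]
    start += [0.0] * (T * K)

    est = fit_normal_model(
        [stats_list], moments, np.array(start), bounds, names,
        "MLaux", n_used=ds.n, spec=spec,
    )
    # split growth parameters from the saturated nuisance block
    est.extra = {k: v for k, v in est.params.items() if k not in growth_names}
    est.params = {k: est.params[k] for k in growth_names}
    est.se = {k: est.se[k] for k in growth_names}
    return est
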