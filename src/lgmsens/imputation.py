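"""Joint multivariate-normal multiple imputation and Rubin's-rules pooling.

Missing cells are drawn with a data-augmentation (I-step / P-step) Gibbs
sampler under a joint normal model for the outcome waves (optionally joined
by auxiliary variables) with a Jeffreys-style noninformative prior: the
I-step draws each missing sub-vector from its conditional normal given the
observed cells and the current (mu, Sigma); the P-step draws Sigma from an
inverse-Wishart posterior and mu from its conditional normal.  One completed
dataset is kept every ``thin`` iterations after ``burn_in``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import WideDataset
from .diagnostics import em_mvn
from .growth import GrowthSpec, GrowthEstimates, fit_lgm_fiml

logger = logging.getLogger("lgmsens")

__all__ = [
    "ImputationSet",
    "PooledEstimates",
    "mvn_impute",
    "fit_growth_on_imputations",
    "pool_rubin",
]


@dataclass
class ImputationSet:
    """m completed datasets plus the sampler settings that produced them."""

    datasets: list  # of WideDataset, complete on the outcome waves
    variables: list[str]
    m: int
    burn_in: int
    thin: int
    seed: int | None
    include_aux: bool
    source_mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")


@dataclass
class PooledEstimates:
    """Rubin-pooled parameters over m imputations."""

    technique: str
    m: int
    qbar: dict  # pooled estimate per parameter
    W: dict  # within-imputation variance
    B: dict  # between-imputation variance
    T: dict  # total variance
    se: dict
    df: dict  # Rubin's nu
    p: dict

    @property
    def params(self) -> dict:
        return self.qbar


def _conditional_draw(rng, y_obs, obs, mis, mu, sigma):
    """Draw the missing block given the observed block under N(mu, sigma)."""
    soo = sigma[np.ix_(obs, obs)]
    B = np.linalg.solve(soo, sigma[np.ix_(obs, mis)]).T  # (|mis|, |obs|)
    cond_mu = mu[mis] + (y_obs - mu[obs]) @ B.T
    cond_cov = sigma[np.ix_(mis, mis)] - B @ sigma[np.ix_(obs, mis)]
    cond_cov = (cond_cov + cond_cov.T) / 2
    w, V = np.linalg.eigh(cond_cov)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    return cond_mu + rng.standard_normal(cond_mu.shape) @ root.T


def mvn_impute(
    ds: WideDataset,
    m: int = 100,
    include_aux: bool = False,
    burn_in: int = 500,
    thin: int = 100,
    seed: int | None = None,
    max_retries: int = 20,
) -> ImputationSet:
    """Generate m completed datasets by normal data augmentation.

    With ``include_aux`` the (dummy-coded, numeric) auxiliary columns join
    the imputation model; the analysis model downstream never changes.
    Observed cells are never altered.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    rng = np.random.default_rng(seed)
    Y = ds.y.copy()
    variables = list(ds.wave_names)
    n_waves = ds.n_waves
    if include_aux:
        if ds.aux is None or ds.aux.shape[1] == 0:
            raise ValueError("include_aux requested but dataset has no auxiliaries")
        num = ds.aux.select_dtypes(include=[np.number])
        cat = ds.aux.drop(columns=num.columns)
        parts = [num]
        if len(cat.columns):
            parts.append(pd.get_dummies(cat, drop_first=True, dtype=float))
        A = pd.concat(parts, axis=1)
        Y = np.column_stack([Y, A.to_numpy(dtype=float)])
        variables += list(A.columns)
    n, p = Y.shape
    if n <= p + 1:
        raise ValueError("too few subjects for the imputation model")
    mask = ~np.isnan(Y)
    if not mask.any(axis=1).all():
        raise ValueError("every subject must have >= 1 observed value")

    no_missing = mask.all()
    if no_missing:
        out = [ds.with_y(ds.y.copy()) for _ in range(m)]
        return ImputationSet(out, variables, m, burn_in, thin, seed, include_aux, mask)

    # group rows by pattern once; the I-step draws block-wise per pattern
    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    groups = [(np.flatnonzero(inverse == j), pat) for j, pat in enumerate(patterns)]

    em = em_mvn(_as_plain(Y, ds))
    mu, sigma = em.mu, em.sigma
    completed = Y.copy()
    # initial fill at the conditional means
    for rows, pat in groups:
        mis = np.flatnonzero(~pat)
        if not len(mis):
            continue
        obs = np.flatnonzero(pat)
        B = np.linalg.solve(sigma[np.ix_(obs, obs)], sigma[np.ix_(obs, mis)]).T
        completed[np.ix_(rows, mis)] = mu[mis] + (Y[np.ix_(rows, obs)] - mu[obs]) @ B.T

    kept: list[WideDataset] = []
    total_iter = burn_in + m * thin
    it = 0
    while len(kept) < m:
        it += 1
        # I-step
        for rows, pat in groups:
            mis = np.flatnonzero(~pat)
            if not len(mis):
                continue
            obs = np.flatnonzero(pat)
            completed[np.ix_(rows, mis)] = _conditional_draw(
                rng, Y[np.ix_(rows, obs)], obs, mis, mu, sigma
            )
        # P-step: Jeffreys prior -> Sigma | Y ~ IW(n-1, S), mu | Sigma ~ N(ybar, Sigma/n)
        ybar = completed.mean(axis=0)
        dev = completed - ybar
        S = dev.T @ dev
        for attempt in range(max_retries + 1):
            try:
                sigma = stats.invwishart.rvs(df=n - 1, scale=S, random_state=rng)
                sigma = np.atleast_2d(sigma)
                np.linalg.cholesky(sigma)
                break
            except np.linalg.LinAlgError:
                S = S + np.eye(p) * 1e-8 * np.trace(S) / p
                if attempt == max_retries:
                    raise RuntimeError("imputation P-step diverged: non-PD draws persisted")
        mu = ybar + np.linalg.cholesky(sigma / n) @ rng.standard_normal(p)
        if it > burn_in and (it - burn_in) % thin == 0:
            y_new = completed[:, :n_waves].copy()
            y_new[ds.mask] = ds.y[ds.mask]  # observed outcome cells are sacrosanct
            kept.append(ds.with_y(y_new))
        if it > total_iter + thin:  # pragma: no cover - safety
            raise RuntimeError("sampler failed to produce the requested datasets")
    return ImputationSet(kept, variables, m, burn_in, thin, seed, include_aux, mask)


def _as_plain(Y: np.ndarray, ds: WideDataset) -> WideDataset:
    """Wrap a (possibly aux-joined) matrix so em_mvn can digest it."""
    p = Y.shape[1]
    times = np.arange(p, dtype=float)
    return WideDataset(y=Y, wave_times=times)


def fit_growth_on_imputations(
    imp: ImputationSet, spec: GrowthSpec
) -> list[GrowthEstimates]:
    """Complete-data ML growth fit on each imputed dataset, order preserved.

    Non-convergent fits are excluded from downstream pooling with a warning.
    """
    fits = []
    n_failed = 0
    for k, d in enumerate(imp.datasets):
        est = fit_lgm_fiml(d, spec)
        est.technique = "MI"
        if not est.converged:
            n_failed += 1
            logger.warning("imputation %d: growth fit did not converge; excluded", k)
            continue
        fits.append(est)
    if n_failed:
        logger.warning("%d of %d imputation fits excluded", n_failed, imp.m)
    return fits


def pool_rubin(fits: list[GrowthEstimates], technique: str = "MI") -> PooledEstimates:
    """Rubin's rules over m analysis results.

    Qbar = mean estimate; W = mean squared SE; B = sample variance of the
    estimates (ddof 1); T = W + (1 + 1/m) B; nu = (m-1)(1 + W/((1+1/m)B))^2;
    p from the t distribution with nu degrees of freedom.
    """
    m = len(fits)
    if m < 2:
        raise ValueError("pooling needs >= 2 analysis results (B undefined)")
    names = list(fits[0].params.keys())
    qbar, W, B, T, se, df, p = {}, {}, {}, {}, {}, {}, {}
    for name in names:
        q = np.array([f.params[name] for f in fits])
        u = np.array([f.se[name] ** 2 for f in fits])
        qbar[name] = float(q.mean())
        W[name] = float(u.mean())
        B[name] = float(q.var(ddof=1))
        T[name] = W[name] + (1 + 1 / m) * B[name]
        se[name] = float(np.sqrt(T[name]))
        if B[name] > 0:
            nu = (m - 1) * (1 + W[name] / ((1 + 1 / m) * B[name])) ** 2
        else:
            nu = np.inf
        df[name] = float(nu)
        tstat = qbar[name] / se[name] if se[name] > 0 else np.nan
        if np.isfinite(nu):
            p[name] = float(2 * stats.t.sf(abs(tstat), nu)) if np.isfinite(tstat) else np.nan
        else:
            p[name] = float(2 * stats.norm.sf(abs(tstat))) if np.isfinite(tstat) else np.nan
    return PooledEstimates(
        technique=technique, m=m, qbar=qbar, W=W, B=B, T=T, se=se, df=df, p=p
    )
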