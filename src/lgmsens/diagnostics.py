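"""Pre-analysis diagnostics: EM for the incomplete multivariate normal,
Little's MCAR test, dropout-group ANOVA, and auxiliary-variable screening."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .dataio import WideDataset, missingness_pattern_table

logger = logging.getLogger("lgmsens")

__all__ = [
    "MvnEstimates",
    "LittleTestResult",
    "AnovaResult",
    "AuxScreenReport",
    "em_mvn",
    "little_mcar_test",
    "dropout_group_anova",
    "screen_auxiliaries",
    "mcar_t_tests",
    "nagelkerke_r2",
]


@dataclass
class MvnEstimates:
    """ML mean/covariance of an incomplete multivariate normal (via EM)."""

    mu: np.ndarray
    sigma: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(default=None, repr=False)


@dataclass
class LittleTestResult:
    chi2: float
    df: int
    p: float
    contributions: pd.DataFrame  # per-pattern n_j, p_j, chi2 contribution
    em: MvnEstimates = field(repr=False, default=None)


def _pattern_stats(ds: WideDataset):
    """Per-pattern sufficient statistics: (obs index, n_j, mean, scatter)."""
    table = missingness_pattern_table(ds)
    mask = ds.mask
    out = []
    for pat in table.patterns:
        rows = (mask == pat).all(axis=1)
        obs = np.flatnonzero(pat)
        yo = ds.y[np.ix_(rows, obs)]
        nj = yo.shape[0]
        ybar = yo.mean(axis=0)
        dev = yo - ybar
        out.append((obs, nj, ybar, dev.T @ dev))
    return out


def _obs_loglik(stats_list, mu, sigma) -> float:
    """Observed-data normal log-likelihood from pattern sufficient statistics."""
    ll = 0.0
    for obs, nj, ybar, scatter in stats_list:
        so = sigma[np.ix_(obs, obs)]
        sign, logdet = np.linalg.slogdet(so)
        if sign <= 0:
            return -np.inf
        inv = np.linalg.inv(so)
        d = ybar - mu[obs]
        ll += -0.5 * (
            nj * len(obs) * np.log(2 * np.pi)
            + nj * logdet
            + np.trace(inv @ scatter)
            + nj * float(d @ inv @ d)
        )
    return ll


def _start_moments(ds: WideDataset) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic EM start: complete-case moments, falling back to
    available-case means and variances with zero covariances."""
    T = ds.n_waves
    complete = ds.mask.all(axis=1)
    if complete.sum() > T + 1:
        yc = ds.y[complete]
        mu = yc.mean(axis=0)
        dev = yc - mu
        sigma = dev.T @ dev / len(yc)
        if np.linalg.matrix_rank(sigma) == T:
            return mu, sigma
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(ds.y, axis=0)
        var = np.nanvar(ds.y, axis=0)
    mu = np.nan_to_num(mu)
    var = np.where(np.isnan(var) | (var <= 0), 1.0, var)
    return mu, np.diag(var)


def em_mvn(
    ds: WideDataset,
    tol: float = 1e-10,
    max_iter: int = 5000,
    start: tuple | None = None,
) -> MvnEstimates:
    """EM estimates of the unstructured mean and covariance under MAR.

    Iterates until the relative log-likelihood change drops below ``tol``;
    non-convergence is flagged on the result, never silent.  The
    log-likelihood trace (one value per iteration) is retained so its
    monotonicity can be asserted.  ``start`` overrides the deterministic
    complete-case starting moments (useful for checking that the optimum is
    initialization-independent).
    """
    if ds.n_waves < 2:
        raise ValueError("need >= 2 waves")
    stats_list = _pattern_stats(ds)
    n = ds.n
    T = ds.n_waves
    if start is None:
        mu, sigma = _start_moments(ds)
    else:
        mu = np.asarray(start[0], dtype=float)
        sigma = np.asarray(start[1], dtype=float)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: expected sufficient statistics given (mu, sigma)
        sum_y = np.zeros(T)
        sum_yy = np.zeros((T, T))
        for obs, nj, ybar, scatter in stats_list:
            mis = np.setdiff1d(np.arange(T), obs)
            so = sigma[np.ix_(obs, obs)]
            try:
                inv = np.linalg.inv(so)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    f"singular within-pattern covariance for pattern with observed waves {obs.tolist()}"
                )
            d = ybar - mu[obs]
            Eyy = np.zeros((T, T))
            Ey = np.zeros(T)
            Ey[obs] = nj * ybar
            Eyy[np.ix_(obs, obs)] = scatter + nj * np.outer(ybar, ybar)
            if len(mis):
                B = sigma[np.ix_(mis, obs)] @ inv  # regression of missing on observed
                mhat = mu[mis] + B @ d  # conditional mean at the pattern mean
                C = sigma[np.ix_(mis, mis)] - B @ sigma[np.ix_(obs, mis)]
                # per-subject conditional means: mu_m + B (y_o - mu_o)
                Ey[mis] = nj * mhat
                # E[y_m y_o'] summed over subjects
                cross = nj * np.outer(mhat, ybar) + B @ scatter
                Eyy[np.ix_(mis, obs)] = cross
                Eyy[np.ix_(obs, mis)] = cross.T
                Eyy[np.ix_(mis, mis)] = (
                    nj * C
                    + nj * np.outer(mhat, mhat)
                    + B @ scatter @ B.T
                )
            sum_y += Ey
            sum_yy += Eyy
        mu = sum_y / n
        sigma = sum_yy / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2
        ll = _obs_loglik(stats_list, mu, sigma)
        trace.append(ll)
        if it > 1 and abs(ll - trace[-2]) <= tol * (abs(trace[-2]) + 1e-12):
            converged = True
            break
    if not converged:
        logger.warning("em_mvn did not converge in %d iterations", max_iter)
    return MvnEstimates(
        mu=mu, sigma=sigma, loglik=trace[-1], n_iter=it, converged=converged,
        loglik_trace=np.array(trace),
    )


def little_mcar_test(ds: WideDataset, em: MvnEstimates | None = None) -> LittleTestResult:
    """Little's chi-square test of the MCAR assumption.

    Compares each missingness pattern's observed means with the EM grand
    means, scaled by the EM covariance:
    chi2 = sum_j n_j (ybar_j - mu_[obs j])' Sigma_[obs j]^-1 (ybar_j - mu_[obs j]),
    df = sum_j p_j - p over patterns with at least one observed variable.
    """
    if em is None:
        em = em_mvn(ds)
    stats_list = _pattern_stats(ds)
    T = ds.n_waves
    chi2 = 0.0
    rows = []
    for obs, nj, ybar, _ in stats_list:
        so = em.sigma[np.ix_(obs, obs)]
        d = ybar - em.mu[obs]
        try:
            contrib = nj * float(d @ np.linalg.solve(so, d))
        except np.linalg.LinAlgError:
            logger.warning(
                "singular covariance submatrix for pattern %s; using pseudo-inverse", obs.tolist()
            )
            contrib = nj * float(d @ np.linalg.pinv(so) @ d)
        chi2 += contrib
        rows.append({"observed_waves": tuple(obs.tolist()), "n": nj,
                     "p_j": len(obs), "chi2": contrib})
    df = int(sum(r["p_j"] for r in rows) - T)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else (1.0 if chi2 <= 1e-10 else 0.0)
    return LittleTestResult(chi2=float(chi2), df=df, p=p,
                            contributions=pd.DataFrame(rows), em=em)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_stats: pd.DataFrame  # group, n, mean, sd
    pairwise: pd.DataFrame | None  # Tukey HSD table


def dropout_group_anova(
    ds: WideDataset,
    wave: int,
    groups: np.ndarray | None = None,
) -> AnovaResult:
    """One-way ANOVA of the wave's observed scores across dropout groups.

    Pairwise follow-up uses Tukey's HSD.  Groups with fewer than two observed
    values at the wave are excluded with a warning.
    """
    if groups is None:
        groups = ds.dropout_group
    if groups is None:
        raise ValueError("no group labels supplied and dataset has none")
    groups = np.asarray(groups)
    obs = ds.mask[:, wave]
    y = ds.y[obs, wave]
    g = groups[obs]
    labels = [lab for lab in pd.unique(g) if (g == lab).sum() >= 2]
    dropped = set(pd.unique(g)) - set(labels)
    if dropped:
        logger.warning("excluding groups with < 2 observed values at wave %d: %s", wave, sorted(dropped))
        keep = np.isin(g, labels)
        y, g = y[keep], g[keep]
    if len(labels) < 2:
        raise ValueError("need >= 2 groups with >= 2 observed values each")
    samples = [y[g == lab] for lab in sorted(labels)]
    F, p = stats.f_oneway(*samples)
    gstats = pd.DataFrame(
        {
            "group": sorted(labels),
            "n": [len(s) for s in samples],
            "mean": [s.mean() for s in samples],
            "sd": [s.std(ddof=1) for s in samples],
        }
    )
    pairwise = None
    if len(labels) >= 2:
        tk = pairwise_tukeyhsd(y, g)
        pairwise = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return AnovaResult(
        F=float(F),
        df_between=len(labels) - 1,
        df_within=len(y) - len(labels),
        p=float(p),
        group_stats=gstats,
        pairwise=pairwise,
    )


def nagelkerke_r2(ll_null: float, ll_full: float, n: int) -> float:
    """Nagelkerke's normalized likelihood-ratio pseudo R-squared."""
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll_null - ll_full))
    max_r2 = 1.0 - np.exp((2.0 / n) * ll_null)
    if max_r2 <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_r2, 0.0, 1.0))


@dataclass
class AuxScreenReport:
    """Per-wave screening of auxiliary variables (Table-4 style)."""

    table: pd.DataFrame  # wave, r2_missingness (Nagelkerke), r2_outcome, n_corr_ge_10, separation flag
    correlations: pd.DataFrame  # aux x wave correlation with the outcome
    n_used: int
    aux_names: list[str]


def _design_matrix(aux: pd.DataFrame) -> pd.DataFrame:
    """Numeric design: categorical/text columns dummy-coded (first level dropped)."""
    num = aux.select_dtypes(include=[np.number])
    cat = aux.drop(columns=num.columns)
    parts = [num]
    if len(cat.columns):
        parts.append(pd.get_dummies(cat, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1)


def screen_auxiliaries(ds: WideDataset, aux: pd.DataFrame | None = None) -> AuxScreenReport:
    """Screen auxiliary variables for their value in missing-data handling.

    Per wave: (a) Nagelkerke R2 of a logistic regression of the missingness
    indicator on all auxiliaries; (b) linear-regression R2 for the observed
    outcome; (c) the count of auxiliaries correlated |r| >= .10 with the
    outcome.  Rows with missing auxiliaries are dropped listwise within the
    screen (logged).  Perfect separation is flagged and R2 reported at its
    upper limit.
    """
    if aux is None:
        aux = ds.aux
    if aux is None or aux.shape[1] == 0:
        raise ValueError("no auxiliary variables supplied")
    X = _design_matrix(aux)
    ok = X.notna().all(axis=1).to_numpy()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("aux screen: dropping %d rows with missing auxiliaries", n_dropped)
    Xo = X.loc[ok]
    if any(Xo[c].std() == 0 for c in Xo.columns):
        raise ValueError("zero-variance auxiliary in the screen")
    Xc = sm.add_constant(Xo.to_numpy(dtype=float))
    rows = []
    corr_rows = {}
    for t in range(ds.n_waves):
        miss = (~ds.mask[:, t])[ok].astype(float)
        separation = False
        if miss.std() == 0:
            r2_miss = 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                try:
                    fit = sm.Logit(miss, Xc).fit(disp=0, maxiter=200)
                    r2_miss = nagelkerke_r2(fit.llnull, fit.llf, len(miss))
                    if not fit.mle_retvals.get("converged", True):
                        separation = True
                except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
                    separation = True
                    r2_miss = 1.0
        yobs = ds.mask[:, t] & ok
        yw = ds.y[yobs, t]
        Xw = sm.add_constant(X.loc[yobs].to_numpy(dtype=float))
        r2_out = float(sm.OLS(yw, Xw).fit().rsquared) if len(yw) > Xw.shape[1] else np.nan
        corr = {}
        for c in X.columns:
            xv = X.loc[yobs, c].to_numpy(dtype=float)
            corr[c] = (
                float(np.corrcoef(xv, yw)[0, 1])
                if xv.std() > 0 and yw.std() > 0 and len(yw) > 2 else 0.0
            )
        corr_rows[ds.wave_names[t]] = corr
        rows.append(
            {
                "wave": ds.wave_names[t],
                "r2_missingness": r2_miss,
                "r2_outcome": r2_out,
                "n_corr_ge_10": int(sum(abs(v) >= 0.10 for v in corr.values())),
                "separation": separation,
            }
        )
        if separation:
            logger.warning("aux screen: separation in logistic fit at wave %d", t)
    return AuxScreenReport(
        table=pd.DataFrame(rows),
        correlations=pd.DataFrame(corr_rows),
        n_used=int(ok.sum()),
        aux_names=list(X.columns),
    )


def mcar_t_tests(ds: WideDataset) -> pd.DataFrame:
    """Per-variable t-test screen for MCAR.

    For each pair of waves (s != t), compares the observed scores at wave s
    between subjects missing vs observed at wave t (Welch's t).  Reported for
    inspection; Little's test is the gating diagnostic.
    """
    rows = []
    for t in range(ds.n_waves):
        miss_t = ~ds.mask[:, t]
        for s in range(ds.n_waves):
            if s == t:
                continue
            obs_s = ds.mask[:, s]
            a = ds.y[obs_s & miss_t, s]
            b = ds.y[obs_s & ~miss_t, s]
            if len(a) >= 2 and len(b) >= 2:
                tt = stats.ttest_ind(a, b, equal_var=False)
                rows.append(
                    {
                        "indicator_wave": ds.wave_names[t],
                        "outcome_wave": ds.wave_names[s],
                        "n_missing": len(a),
                        "n_observed": len(b),
                        "mean_missing": a.mean(),
                        "mean_observed": b.mean(),
                        "t": float(tt.statistic),
                        "p": float(tt.pvalue),
                    }
                )
    return pd.DataFrame(rows)
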