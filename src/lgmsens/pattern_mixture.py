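"""Pattern-mixture models for MNAR sensitivity analysis.

Subjects are stratified by dropout pattern, the growth model is fitted per
stratum with the latent covariance matrix Psi and the residual variances
Theta shared across strata (the under-identified strata borrow them), and
population parameters are the stratum-proportion-weighted averages with
delta-method standard errors.

Two families:

* the two-group shared-variance model (completers vs non-completers) with
  group-specific latent means;
* the three-group models in which the last group is observed essentially
  only at wave 1, so its mean slope is fixed by an identifying restriction:
  complete-case (borrow group 1's slope), neighbouring-case (borrow group
  2's), or available-case (the size-weighted average of groups 1 and 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import WideDataset
from .growth import (
    GrowthSpec,
    GrowthEstimates,
    implied_moments,
    suffstats,
    fit_normal_model,
    _moment_start,
    _VAR_FLOOR,
)

logger = logging.getLogger("lgmsens")

__all__ = [
    "DropoutGrouping",
    "PatternMixtureResult",
    "assign_dropout_groups",
    "fit_two_group_pm",
    "fit_restriction_pm",
    "pool_pattern_mixture",
]

RESTRICTIONS = ("complete-case", "neighbouring-case", "available-case")


@dataclass
class DropoutGrouping:
    """Group label (1..k) per subject with sizes and proportions."""

    labels: np.ndarray
    k: int
    mode: str

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        for g in range(1, self.k + 1):
            if not np.any(self.labels == g):
                raise ValueError(f"dropout group {g} is empty")
        if set(np.unique(self.labels)) - set(range(1, self.k + 1)):
            raise ValueError("labels must lie in 1..k")

    @property
    def sizes(self) -> np.ndarray:
        return np.array([(self.labels == g).sum() for g in range(1, self.k + 1)])

    @property
    def proportions(self) -> np.ndarray:
        return self.sizes / self.sizes.sum()


def assign_dropout_groups(
    ds: WideDataset, mode: str = "auto", k: int = 3
) -> DropoutGrouping:
    """Stratify subjects by dropout pattern.

    ``administrative`` uses the dataset's dropout_group column (labels are
    ranked so 1 is the least-dropout group).  ``last-observed-wave`` derives
    the strata from the response pattern: with k = 2, complete trajectories
    vs the rest; with k = 3, last observed at the final wave / an
    intermediate wave / wave 1.  ``auto`` prefers administrative labels when
    present.  When both sources exist their cross-tabulation is logged,
    since wave non-response and attrition need not coincide.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    if mode == "auto":
        mode = "administrative" if ds.dropout_group is not None else "last-observed-wave"
    if mode == "administrative":
        if ds.dropout_group is None:
            raise ValueError("administrative mode requires a dropout_group column")
        raw = np.asarray(ds.dropout_group)
        uniq = np.unique(raw)
        if k == 3:
            if len(uniq) != 3:
                raise ValueError(f"administrative labels have {len(uniq)} levels; need 3")
            labels = np.searchsorted(uniq, raw) + 1
        else:
            labels = np.where(raw == uniq[0], 1, 2)
        grouping = DropoutGrouping(labels=labels, k=k, mode=mode)
        derived = _pattern_labels(ds, k)
        ct = pd.crosstab(pd.Series(labels, name="administrative"),
                         pd.Series(derived, name="response-pattern"))
        logger.info("administrative vs response-pattern cross-tabulation:\n%s", ct)
        return grouping
    if mode == "last-observed-wave":
        return DropoutGrouping(labels=_pattern_labels(ds, k), k=k, mode=mode)
    raise ValueError(f"unknown mode {mode!r}")


def _pattern_labels(ds: WideDataset, k: int) -> np.ndarray:
    mask = ds.mask
    if k == 2:
        return np.where(mask.all(axis=1), 1, 2)
    T = ds.n_waves
    last = np.array([np.flatnonzero(row)[-1] for row in mask])
    labels = np.full(ds.n, 2)
    labels[last == T - 1] = 1
    labels[last == 0] = 3
    return labels


@dataclass
class PatternMixtureResult:
    """Per-group estimates, shared variances, and pooled parameters."""

    technique: str
    restriction: str | None
    group_means: pd.DataFrame  # group, n, pi, mu_I, mu_S, se_mu_I, se_mu_S
    params: dict  # pooled/shared parameters in growth naming
    se: dict
    loglik: float
    n_used: int
    converged: bool
    weights: np.ndarray
    cov: pd.DataFrame = field(repr=False, default=None)
    raw: GrowthEstimates = field(repr=False, default=None)


def pool_pattern_mixture(
    estimates: np.ndarray,
    variances: np.ndarray,
    weights: np.ndarray,
    N: int,
    cov: np.ndarray | None = None,
    include_weight_variance: bool = True,
) -> tuple[float, float]:
    """Weighted-average pooling of per-group estimates with delta-method SE.

    pooled = sum_g pi_g theta_g.  Its variance has a parameter part
    (w' V w, with V the covariance of the group estimates; diagonal
    ``variances`` when ``cov`` is not given) and, when
    ``include_weight_variance``, a weight part sum_gh theta_g theta_h C_gh
    with C the multinomial covariance of the proportions
    (C_gg = pi_g (1 - pi_g) / N, C_gh = -pi_g pi_h / N).
    """
    theta = np.asarray(estimates, dtype=float)
    pi = np.asarray(weights, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError("weights must sum to 1")
    V = np.diag(np.asarray(variances, dtype=float)) if cov is None else np.asarray(cov)
    pooled = float(pi @ theta)
    var = float(pi @ V @ pi)
    if include_weight_variance:
        C = (np.diag(pi) - np.outer(pi, pi)) / N
        var += float(theta @ C @ theta)
    return pooled, float(np.sqrt(max(var, 0.0)))


def _multigroup_fit(
    ds: WideDataset,
    grouping: DropoutGrouping,
    spec: GrowthSpec,
    technique: str,
    slope_expr=None,
) -> tuple[GrowthEstimates, list[str]]:
    """Shared-variance multigroup FIML with group-specific latent means.

    ``slope_expr``: None, or a function mapping the free slope means
    (mu_S of groups 1..k-1) and group sizes to the last group's slope mean
    (the identifying restriction, implemented by reparameterization).
    """
    k = grouping.k
    shared = [n for n in spec.param_names() if n not in ("mu_I", "mu_S")]
    names = []
    for g in range(1, k + 1):
        names.append(f"mu_I[{g}]")
        if slope_expr is None or g < k:
            names.append(f"mu_S[{g}]")
    names += shared
    bounds = []
    for n in names:
        if n.startswith(("psi_II", "psi_SS", "theta")):
            bounds.append((_VAR_FLOOR, None))
        else:
            bounds.append((None, None))

    group_rows = [grouping.labels == g for g in range(1, k + 1)]
    # a group whose subjects never reach a second wave cannot free its slope
    for g, rows in enumerate(group_rows, start=1):
        multi = (ds.mask[rows].sum(axis=1) >= 2).any()
        frees_slope = slope_expr is None or g < k
        if frees_slope and not multi:
            raise ValueError(
                f"group {g} has no subject observed at >= 2 waves; "
                "its mean slope is inestimable without a restriction"
            )
    stats_groups = [suffstats(ds.y[rows]) for rows in group_rows]
    sizes = grouping.sizes

    n_mean = len(names) - len(shared)

    def unpack_means(vec):
        mus = []
        pos = 0
        for g in range(1, k + 1):
            mu_I = vec[pos]; pos += 1
            if slope_expr is None or g < k:
                mu_S = vec[pos]; pos += 1
            else:
                mu_S = None
            mus.append([mu_I, mu_S])
        if slope_expr is not None:
            free_slopes = np.array([m[1] for m in mus[:-1]])
            mus[-1][1] = slope_expr(free_slopes, sizes)
        return mus

    def moments(vec):
        mus = unpack_means(vec)
        shared_vals = dict(zip(shared, vec[n_mean:]))
        out = []
        for mu_I, mu_S in mus:
            d = dict(shared_vals)
            d["mu_I"], d["mu_S"] = mu_I, mu_S
            out.append(implied_moments(d, spec))
        return out

    base = _moment_start(ds, spec)
    base_d = dict(zip(spec.param_names(), base))
    start = []
    for g in range(1, k + 1):
        start.append(base_d["mu_I"])
        if slope_expr is None or g < k:
            start.append(base_d["mu_S"])
    start += [base_d[n] for n in shared]

    est = fit_normal_model(
        stats_groups, moments, np.array(start), bounds, names, technique,
        n_used=ds.n, spec=spec,
    )
    return est, shared


def _assemble_pm_result(
    est: GrowthEstimates,
    shared: list[str],
    grouping: DropoutGrouping,
    technique: str,
    restriction: str | None,
    spec: GrowthSpec,
    slope_expr=None,
) -> PatternMixtureResult:
    k = grouping.k
    pi = grouping.proportions
    sizes = grouping.sizes
    N = int(sizes.sum())
    names = list(est.params.keys())
    vec = np.array([est.params[n] for n in names])
    covm = est.cov.to_numpy() if est.cov is not None else np.zeros((len(names), len(names)))

    # group means, with the restricted slope reconstructed plus its gradient
    mu_I = np.array([est.params[f"mu_I[{g}]"] for g in range(1, k + 1)])
    mu_S = np.zeros(k)
    grad_S = np.zeros((k, len(names)))  # d mu_S_g / d free params
    grad_I = np.zeros((k, len(names)))
    for g in range(1, k + 1):
        grad_I[g - 1, names.index(f"mu_I[{g}]")] = 1.0
        if slope_expr is None or g < k:
            mu_S[g - 1] = est.params[f"mu_S[{g}]"]
            grad_S[g - 1, names.index(f"mu_S[{g}]")] = 1.0
    if slope_expr is not None:
        free = np.array([est.params[f"mu_S[{g}]"] for g in range(1, k)])
        mu_S[k - 1] = slope_expr(free, sizes)
        # numeric gradient of the restriction (it is linear in the free slopes)
        for g in range(1, k):
            e = np.zeros(k - 1)
            e[g - 1] = 1.0
            grad_S[k - 1, names.index(f"mu_S[{g}]")] = slope_expr(free + e, sizes) - slope_expr(free, sizes)

    se_I = np.sqrt(np.einsum("ij,jk,ik->i", grad_I, covm, grad_I))
    se_S = np.sqrt(np.einsum("ij,jk,ik->i", grad_S, covm, grad_S))
    group_means = pd.DataFrame(
        {
            "group": np.arange(1, k + 1),
            "n": sizes,
            "pi": pi,
            "mu_I": mu_I,
            "se_mu_I": se_I,
            "mu_S": mu_S,
            "se_mu_S": se_S,
        }
    )

    # pooled means: pi-weighted averages; delta-method SE combines the full
    # parameter covariance (via the gradients) with the multinomial weight part
    params: dict = {}
    se: dict = {}
    for label, vals, grads in (("mu_I", mu_I, grad_I), ("mu_S", mu_S, grad_S)):
        g_pooled = pi @ grads
        pooled = float(pi @ vals)
        var = float(g_pooled @ covm @ g_pooled)
        C = (np.diag(pi) - np.outer(pi, pi)) / N
        var += float(vals @ C @ vals)
        params[label] = pooled
        se[label] = float(np.sqrt(max(var, 0.0)))
    for nshared in shared:
        params[nshared] = est.params[nshared]
        se[nshared] = est.se[nshared]
    return PatternMixtureResult(
        technique=technique,
        restriction=restriction,
        group_means=group_means,
        params=params,
        se=se,
        loglik=est.loglik,
        n_used=est.n_used,
        converged=est.converged,
        weights=pi,
        cov=est.cov,
        raw=est,
    )


def fit_two_group_pm(
    ds: WideDataset, grouping: DropoutGrouping, spec: GrowthSpec
) -> PatternMixtureResult:
    """Two-group shared-variance pattern-mixture model (completers vs rest).

    Group-specific latent means; Psi and Theta equated across groups and
    identified by the complete group; pooled means are proportion-weighted
    averages with delta-method SEs.
    """
    if grouping.k != 2:
        raise ValueError("two-group model needs a k = 2 grouping")
    est, shared = _multigroup_fit(ds, grouping, spec, "H&G")
    return _assemble_pm_result(est, shared, grouping, "H&G", None, spec)


def _restriction_expr(restriction: str):
    if restriction == "complete-case":
        return lambda free, sizes: free[0]
    if restriction == "neighbouring-case":
        return lambda free, sizes: free[-1]
    if restriction == "available-case":
        return lambda free, sizes: float(
            (sizes[:-1] @ free) / sizes[:-1].sum()
        )
    raise ValueError(f"unknown restriction {restriction!r}")


def fit_restriction_pm(
    ds: WideDataset,
    grouping: DropoutGrouping,
    spec: GrowthSpec,
    restriction: str,
    allow_complete_case: bool = False,
) -> PatternMixtureResult:
    """Three-group pattern-mixture model under an identifying restriction.

    The last group's mean slope is substituted inside the likelihood by its
    restriction expression (reparameterization, so the constraint holds
    exactly): group 1's slope (complete-case), group 2's
    (neighbouring-case), or the size-weighted average of groups 1-2
    (available-case).  The complete-case restriction runs only behind
    ``allow_complete_case`` since borrowing growth from completers is rarely
    defensible for early dropouts.
    """
    if restriction not in RESTRICTIONS:
        raise ValueError(f"restriction must be one of {RESTRICTIONS}")
    if restriction == "complete-case" and not allow_complete_case:
        raise ValueError(
            "the complete-case restriction is disabled by default; "
            "pass allow_complete_case=True to opt in"
        )
    if grouping.k != 3:
        raise ValueError("restriction models need a k = 3 grouping")
    label = {"complete-case": "Complete", "neighbouring-case": "Neighbouring",
             "available-case": "Available"}[restriction]
    est, shared = _multigroup_fit(
        ds, grouping, spec, label, slope_expr=_restriction_expr(restriction)
    )
    return _assemble_pm_result(
        est, shared, grouping, label, restriction, spec,
        slope_expr=_restriction_expr(restriction),
    )
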