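"""Orchestration: run the eight missing-data techniques on one dataset,
assemble the comparison table, and classify cross-technique agreement.

Technique labels: LD (listwise deletion, assumes MCAR); ML, MI, MLaux,
MIaux (assume MAR); H&G, Neighbouring, Available, and the opt-in Complete
(pattern-mixture models, assume MNAR).  Agreement per parameter is judged
on significance concordance at a chosen alpha, with 95%-CI overlap as the
secondary magnitude check, and mapped onto three reporting options:

1. MAR-class and MNAR-class disagree -> present both, choose cautiously.
2. The classes agree -> report MAR in detail, note MNAR concurs.
3. ML disagrees with MI/MLaux/MIaux and the MNAR class -> prefer the latter.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import WideDataset
from .growth import (
    GrowthSpec,
    fit_lgm_listwise,
    fit_lgm_fiml,
    fit_lgm_fiml_aux,
    wald_summary,
)
from .imputation import mvn_impute, fit_growth_on_imputations, pool_rubin
from .pattern_mixture import (
    assign_dropout_groups,
    fit_two_group_pm,
    fit_restriction_pm,
)

logger = logging.getLogger("lgmsens")

__all__ = [
    "SensitivityConfig",
    "SensitivitySummary",
    "run_sensitivity",
    "classify_agreement",
    "render_report",
    "MCAR_CLASS",
    "MAR_CLASS",
    "MNAR_CLASS",
    "GUIDELINE_TEXT",
]

MCAR_CLASS = ("LD",)
MAR_CLASS = ("ML", "MI", "MLaux", "MIaux")
MNAR_CLASS = ("H&G", "Neighbouring", "Available", "Complete")

# map internal parameter names onto the report's row labels
REPORT_PARAMS = {
    "mu_I": "mean_intercept",
    "mu_S": "mean_slope",
    "psi_II": "intercept_variance",
    "psi_SS": "slope_variance",
    "psi_IS": "covariance",
}

GUIDELINE_TEXT = {
    1: "Present MAR and MNAR; Cautiously choose; Present findings cautiously.",
    2: "MAR models in detail; Add: Not contradicted by MNAR.",
    3: "Present MAR & MNAR models; Opt for the MI, MLaux, MIaux & MNAR results.",
}


@dataclass
class SensitivityConfig:
    """Run settings for the full sensitivity analysis."""

    m: int = 100
    burn_in: int = 500
    thin: int = 100
    alpha: float = 0.05
    seed: int | None = None
    include_complete_case: bool = False
    grouping_mode: str = "auto"


@dataclass
class SensitivitySummary:
    """The assembled comparison table plus classification and metadata."""

    table: pd.DataFrame  # technique, parameter, estimate, se, z, p, stars, ci_low, ci_high
    classification: pd.DataFrame | None
    metadata: dict
    warnings: list = field(default_factory=list)

    @property
    def techniques(self) -> list[str]:
        return list(pd.unique(self.table["technique"]))


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for a, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
        if p < a:
            return s
    return ""


def _rows_from_params(technique, params, se, p=None, zvals=None) -> list[dict]:
    rows = []
    zcrit = stats.norm.ppf(0.975)
    for name, label in REPORT_PARAMS.items():
        if name not in params:
            continue
        est = params[name]
        s = se.get(name, np.nan)
        z = zvals[name] if zvals and name in zvals else (est / s if s and np.isfinite(s) and s > 0 else np.nan)
        pv = p[name] if p and name in p else (2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan)
        rows.append(
            {
                "technique": technique,
                "parameter": label,
                "estimate": est,
                "se": s,
                "z": z,
                "p": pv,
                "stars": _stars(pv),
                "ci_low": est - zcrit * s if np.isfinite(s) else np.nan,
                "ci_high": est + zcrit * s if np.isfinite(s) else np.nan,
            }
        )
    return rows


def _dataset_hash(ds: WideDataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(ds.y).tobytes())
    h.update(np.ascontiguousarray(ds.wave_times).tobytes())
    return h.hexdigest()[:16]


def run_sensitivity(
    ds: WideDataset,
    spec: GrowthSpec,
    aux_columns: list[str] | None = None,
    grouping=None,
    config: SensitivityConfig | None = None,
) -> SensitivitySummary:
    """Run every applicable missing-data technique and assemble the table.

    Techniques whose prerequisites are missing (no auxiliaries, no viable
    dropout grouping) are skipped with a warning; any technique failure is
    isolated and recorded without aborting the rest.
    """
    config = config or SensitivityConfig()
    rows: list[dict] = []
    warns: list[str] = []

    def attempt(label, fn):
        try:
            rows.extend(fn())
        except Exception as exc:  # isolate per-technique failures
            msg = f"{label}: {type(exc).__name__}: {exc}"
            warns.append(msg)
            logger.warning("technique failed - %s", msg)

    has_aux = ds.aux is not None and ds.aux.shape[1] > 0
    if aux_columns is None and has_aux:
        aux_columns = list(ds.aux.columns)

    attempt("LD", lambda: _rows_from_est(fit_lgm_listwise(ds, spec)))
    attempt("ML", lambda: _rows_from_est(fit_lgm_fiml(ds, spec)))
    if has_aux:
        attempt("MLaux", lambda: _rows_from_est(fit_lgm_fiml_aux(ds, spec, aux_columns)))
    else:
        warns.append("MLaux: skipped, no auxiliary variables")
        logger.warning("MLaux skipped: no auxiliary variables")

    def run_mi(include_aux, label):
        imp = mvn_impute(
            ds, m=config.m, include_aux=include_aux,
            burn_in=config.burn_in, thin=config.thin,
            seed=None if config.seed is None else config.seed + (1 if include_aux else 0),
        )
        fits = fit_growth_on_imputations(imp, spec)
        pooled = pool_rubin(fits, technique=label)
        return _rows_from_params(label, pooled.qbar, pooled.se, p=pooled.p)

    attempt("MI", lambda: run_mi(False, "MI"))
    if has_aux:
        attempt("MIaux", lambda: run_mi(True, "MIaux"))
    else:
        warns.append("MIaux: skipped, no auxiliary variables")

    try:
        g2 = (grouping if grouping is not None and grouping.k == 2
              else assign_dropout_groups(ds, config.grouping_mode, k=2))
        attempt("H&G", lambda: _rows_from_pm(fit_two_group_pm(ds, g2, spec)))
    except Exception as exc:
        warns.append(f"H&G: {type(exc).__name__}: {exc}")
    try:
        g3 = (grouping if grouping is not None and grouping.k == 3
              else assign_dropout_groups(ds, config.grouping_mode, k=3))
        attempt("Neighbouring", lambda: _rows_from_pm(
            fit_restriction_pm(ds, g3, spec, "neighbouring-case")))
        attempt("Available", lambda: _rows_from_pm(
            fit_restriction_pm(ds, g3, spec, "available-case")))
        if config.include_complete_case:
            attempt("Complete", lambda: _rows_from_pm(
                fit_restriction_pm(ds, g3, spec, "complete-case", allow_complete_case=True)))
    except Exception as exc:
        warns.append(f"restriction models: {type(exc).__name__}: {exc}")

    table = pd.DataFrame(rows)
    summary = SensitivitySummary(
        table=table,
        classification=None,
        metadata={
            "seed": config.seed,
            "alpha": config.alpha,
            "m": config.m,
            "dataset_hash": _dataset_hash(ds),
            "wave_times": list(spec.wave_times),
            "residual": spec.residual,
            "cov_IS_free": spec.cov_IS_free,
            "n": ds.n,
        },
        warnings=warns,
    )
    if not table.empty:
        try:
            summary.classification = classify_agreement(summary, alpha=config.alpha)
        except ValueError as exc:
            warns.append(f"classification: {exc}")
            logger.warning("classification skipped: %s", exc)
    return summary


def _rows_from_est(est) -> list[dict]:
    tab = wald_summary(est)
    tab = tab[tab["parameter"].isin(REPORT_PARAMS)]
    tab = tab.assign(parameter=tab["parameter"].map(REPORT_PARAMS), technique=est.technique)
    return tab[
        ["technique", "parameter", "estimate", "se", "z", "p", "stars", "ci_low", "ci_high"]
    ].to_dict("records")


def _rows_from_pm(res) -> list[dict]:
    return _rows_from_params(res.technique, res.params, res.se)


def classify_agreement(summary: SensitivitySummary, alpha: float = 0.05) -> pd.DataFrame:
    """Classify cross-technique agreement per parameter.

    Pure function of the (estimate, se, p) table; never re-estimates.
    Significance is judged at ``alpha``; p in [alpha, 0.10] is flagged as
    borderline ("at the verge") but counted as not significant.  The LD row
    is additionally flagged when its 95% CI excludes the ML estimate.
    """
    t = summary.table
    present = set(t["technique"])
    mar = [x for x in MAR_CLASS if x in present]
    mnar = [x for x in MNAR_CLASS if x in present]
    if not mar or not mnar:
        raise ValueError("classification needs >= 1 MAR-class and >= 1 MNAR-class technique")
    out = []
    for param in pd.unique(t["parameter"]):
        sub = t[t["parameter"] == param].set_index("technique")
        sig = {k: bool(sub.loc[k, "p"] < alpha) for k in sub.index if np.isfinite(sub.loc[k, "p"])}
        borderline = sorted(
            k for k in sub.index
            if np.isfinite(sub.loc[k, "p"]) and alpha <= sub.loc[k, "p"] <= 0.10
        )
        sig_names = sorted(k for k, v in sig.items() if v)
        nonsig_names = sorted(k for k, v in sig.items() if not v)
        pattern = f"Significant: {', '.join(sig_names) or 'none'}; Not significant: {', '.join(nonsig_names) or 'none'}."

        # option 3: ML alone against the other MAR techniques plus MNAR
        option = None
        others = [x for x in mar if x != "ML"] + mnar
        if "ML" in sig and others and all(x in sig for x in others):
            s_others = {sig[x] for x in others}
            if len(s_others) == 1 and sig["ML"] not in s_others:
                option = 3
        if option is None:
            s_mar = {sig[x] for x in mar if x in sig}
            s_mnar = {sig[x] for x in mnar if x in sig}
            if len(s_mar) == 1 and len(s_mnar) == 1 and s_mar != s_mnar:
                option = 1
            else:
                option = 2

        # "=": every technique (including LD) concordant and all CIs overlap
        all_agree = len({v for v in sig.values()}) == 1
        cis = sub[["ci_low", "ci_high"]].dropna()
        overlap = True
        for a in cis.index:
            for b in cis.index:
                if a < b:
                    if cis.loc[a, "ci_low"] > cis.loc[b, "ci_high"] or cis.loc[b, "ci_low"] > cis.loc[a, "ci_high"]:
                        overlap = False
        category = "=" if (all_agree and overlap and option == 2) else pattern

        ld_flag = False
        if "LD" in sub.index and "ML" in sub.index:
            ml_est = sub.loc["ML", "estimate"]
            ld_flag = bool(
                np.isfinite(sub.loc["LD", "ci_low"])
                and not (sub.loc["LD", "ci_low"] <= ml_est <= sub.loc["LD", "ci_high"])
            )
        out.append(
            {
                "parameter": param,
                "category": category,
                "significance_pattern": pattern,
                "guideline_option": option,
                "guideline_text": GUIDELINE_TEXT[option],
                "ld_differs_from_ml": ld_flag,
                "borderline": ", ".join(borderline),
            }
        )
    return pd.DataFrame(out)


def render_report(summary: SensitivitySummary, fmt: str = "text") -> str:
    """Render the summary deterministically as CSV or aligned text.

    Identical summaries render to identical bytes.
    """
    if fmt == "csv":
        parts = [summary.table.to_csv(index=False, float_format="%.6g")]
        if summary.classification is not None:
            parts.append(summary.classification.to_csv(index=False))
        return "\n".join(parts)
    if fmt != "text":
        raise ValueError("format must be 'csv' or 'text'")
    lines = ["Sensitivity analysis: growth estimates by missing-data technique", ""]
    wide = summary.table.copy()
    wide["cell"] = wide.apply(
        lambda r: f"{r.estimate:.3f} ({r.se:.3f}){r.stars}" if np.isfinite(r.se) else f"{r.estimate:.3f}",
        axis=1,
    )
    pivot = wide.pivot(index="technique", columns="parameter", values="cell")
    order = [c for c in ("mean_intercept", "mean_slope", "intercept_variance",
                         "slope_variance", "covariance") if c in pivot.columns]
    tech_order = [x for x in ("LD", *MAR_CLASS, *MNAR_CLASS) if x in pivot.index]
    lines.append(pivot.loc[tech_order, order].to_string())
    lines.append("")
    if summary.classification is not None and len(summary.techniques) > 1:
        lines.append("Agreement classification")
        for _, row in summary.classification.iterrows():
            lines.append(f"  {row['parameter']}: {row['category']}")
            lines.append(f"    option {row['guideline_option']}: {row['guideline_text']}")
            if row["ld_differs_from_ml"]:
                lines.append("    note: LD interval excludes the ML estimate")
            if row["borderline"]:
                lines.append(f"    at the verge of significance: {row['borderline']}")
    meta = summary.metadata
    lines.append("")
    lines.append(
        f"n = {meta.get('n')}, alpha = {meta.get('alpha')}, m = {meta.get('m')}, "
        f"seed = {meta.get('seed')}, data hash = {meta.get('dataset_hash')}"
    )
    for w in summary.warnings:
        lines.append(f"warning: {w}")
    return "\n".join(lines) + "\n"
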