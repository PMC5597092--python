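"""Synthetic three-wave (or T-wave) growth data with controllable missingness.

The generative model is the linear latent growth curve

    y_it = I_i + lambda_t * S_i + eps_it,
    (I_i, S_i) ~ N((mu_I, mu_S), Psi),   eps_it ~ N(0, theta_t),

with subject-level intercept I and slope S.  Missingness is imposed on top of
the complete data as a per-wave logistic dropout hazard (monotone attrition)
plus an independent Bernoulli wave non-response overlay, optionally driven by
observed prior scores (MAR), by the subject's latent slope or the value being
deleted (MNAR), or by an auxiliary covariate.

The latent intercepts/slopes and the deletion log are returned on separate
channels from the data handed to estimators, so oracle checks can use them
without the estimators ever seeing them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .dataio import WideDataset, ConfigurationError

__all__ = [
    "GrowthParams",
    "MissingnessScenario",
    "simulate_growth",
    "impose_missingness",
    "generate_auxiliaries",
    "study_emulation_preset",
    "STUDY_WAVE_TIMES",
    "STUDY_N",
]

# Loadings for a 3-wave design with a 14-month and then a 12-month gap,
# expressed in units of 12 months: 0, 14/12, 14/12 + 1.
STUDY_WAVE_TIMES = np.array([0.0, round(14 / 12, 2), round(14 / 12, 2) + 1.0])
STUDY_N = 1072


@dataclass(frozen=True)
class GrowthParams:
    """Population parameters of the linear latent growth model.

    mu_I / mu_S are the mean intercept (score units) and mean slope (score
    units per year); psi_II, psi_SS, psi_IS the latent covariance matrix; and
    theta the residual variance, a scalar (homogeneous) or one value per wave.
    """

    mu_I: float
    mu_S: float
    psi_II: float
    psi_SS: float
    psi_IS: float = 0.0
    theta: float | tuple = 0.25

    def __post_init__(self):
        if self.psi_II < 0 or self.psi_SS < 0:
            raise ValueError("latent variances must be non-negative")
        bound = math.sqrt(self.psi_II * self.psi_SS)
        if abs(self.psi_IS) > bound + 1e-12:
            raise ValueError("|psi_IS| exceeds sqrt(psi_II * psi_SS); latent covariance not PSD")
        if np.any(np.asarray(self.theta, dtype=float) < 0):
            raise ValueError("residual variances must be non-negative")

    def theta_per_wave(self, n_waves: int) -> np.ndarray:
        th = np.asarray(self.theta, dtype=float)
        if th.ndim == 0:
            return np.full(n_waves, float(th))
        if len(th) != n_waves:
            raise ValueError("theta length must match number of waves")
        return th

    def psi(self) -> np.ndarray:
        return np.array([[self.psi_II, self.psi_IS], [self.psi_IS, self.psi_SS]])

    def implied_mean(self, wave_times: np.ndarray) -> np.ndarray:
        lam = np.asarray(wave_times, dtype=float)
        return self.mu_I + lam * self.mu_S

    def implied_cov(self, wave_times: np.ndarray) -> np.ndarray:
        lam = np.asarray(wave_times, dtype=float)
        Lam = np.column_stack([np.ones_like(lam), lam])
        return Lam @ self.psi() @ Lam.T + np.diag(self.theta_per_wave(len(lam)))


@dataclass(frozen=True)
class MissingnessScenario:
    """How missingness is imposed on a complete dataset.

    ``dropout_hazard[t]`` is the marginal per-wave probability (at the
    predictor's mean) of permanently dropping out at wave t, given survival to
    it; index 0 is ignored (wave 1 is never removed by attrition).
    ``intermittent_rate[t]`` is an independent wave non-response probability
    for subjects still enrolled.  ``wave1_nonresponse`` removes wave 1 only
    for subjects observed at a later wave, so every subject keeps >= 1
    observed value.  ``coef`` shifts the dropout log-odds per SD of the
    mechanism's predictor: the last observed earlier score (MAR,
    ``predictor="previous_score"``), the latent slope or the value being
    deleted (MNAR), or an auxiliary column (``predictor="aux:<name>"``).
    """

    mechanism: str  # MCAR | MAR | MNAR
    form: str = "mixed"  # monotone | intermittent | mixed
    dropout_hazard: tuple = (0.0, 0.0, 0.0)
    intermittent_rate: tuple = (0.0, 0.0, 0.0)
    wave1_nonresponse: float = 0.0
    coef: float = 0.0
    predictor: str = "previous_score"
    seed: int | None = None

    def __post_init__(self):
        if self.mechanism not in {"MCAR", "MAR", "MNAR"}:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.form not in {"monotone", "intermittent", "mixed"}:
            raise ValueError(f"unknown form {self.form!r}")
        for p in (*self.dropout_hazard, *self.intermittent_rate, self.wave1_nonresponse):
            if not 0.0 <= p <= 1.0:
                raise ValueError("missingness probabilities must lie in [0, 1]")
        if self.mechanism == "MCAR" and self.coef != 0.0:
            raise ValueError("MCAR requires coef = 0 (missingness unrelated to data)")
        if self.mechanism == "MNAR" and self.predictor not in {"latent_slope", "current_score"}:
            raise ValueError("MNAR predictor must be 'latent_slope' or 'current_score'")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_growth(
    n: int,
    wave_times: np.ndarray,
    params: GrowthParams,
    seed: int | np.random.Generator | None = None,
) -> tuple[WideDataset, pd.DataFrame]:
    """Draw a complete dataset from the growth model.

    Returns the dataset and, separately, the latent record (one row per
    subject with its intercept and slope) for oracle use only.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    lam = np.asarray(wave_times, dtype=float)
    T = len(lam)
    psi = params.psi()
    # guard: frozen dataclass already validated PSD, cholesky via eigh for psd edge
    w, V = np.linalg.eigh(psi)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    latent = np.column_stack([params.mu_I, params.mu_S]) + rng.standard_normal((n, 2)) @ root.T
    eps = rng.standard_normal((n, T)) * np.sqrt(params.theta_per_wave(T))
    y = latent[:, [0]] + np.outer(latent[:, 1], lam) + eps
    ds = WideDataset(y=y, wave_times=lam)
    record = pd.DataFrame({"intercept": latent[:, 0], "slope": latent[:, 1]})
    return ds, record


def _predictor_z(
    ds: WideDataset,
    scenario: MissingnessScenario,
    wave: int,
    observed_so_far: np.ndarray,
    latent: pd.DataFrame | None,
) -> np.ndarray:
    """Standardized linear-predictor values for dropout at ``wave``."""
    n = ds.n
    if scenario.coef == 0.0:
        return np.zeros(n)
    pred = scenario.predictor
    if pred.startswith("aux:"):
        name = pred[4:]
        if ds.aux is None or name not in ds.aux.columns:
            raise ConfigurationError(f"auxiliary predictor {name!r} not present")
        x = pd.to_numeric(ds.aux[name]).to_numpy(dtype=float)
    elif pred == "previous_score":
        # last score observed before this wave, in the current masked state
        x = np.full(n, np.nan)
        for t in range(wave - 1, -1, -1):
            take = np.isnan(x) & observed_so_far[:, t]
            x[take] = ds.y[take, t]
        if np.isnan(x).any():
            raise ConfigurationError(
                "MAR scenario needs an observed earlier score for every subject; "
                "supply an auxiliary predictor for subjects missing all prior waves"
            )
    elif pred == "latent_slope":
        if latent is None:
            raise ConfigurationError("MNAR on the latent slope needs the latent record")
        x = latent["slope"].to_numpy(dtype=float)
    elif pred == "current_score":
        x = ds.y[:, wave].copy()
    else:  # pragma: no cover - guarded in __post_init__
        raise ConfigurationError(f"unknown predictor {pred!r}")
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros(n)


def impose_missingness(
    ds: WideDataset,
    scenario: MissingnessScenario,
    latent: pd.DataFrame | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[WideDataset, pd.DataFrame]:
    """Mask a complete dataset according to the scenario.

    Returns the masked dataset and a deletion log with one row per removed
    cell (subject row index, wave, cause, linear predictor value).
    """
    rng = _rng(scenario.seed if seed is None else seed)
    n, T = ds.y.shape
    observed = ds.mask.copy()
    if scenario.mechanism == "MAR" and scenario.predictor == "previous_score" and not observed[:, 0].all():
        raise ConfigurationError(
            "MAR on the previous score requires wave 1 observed for all subjects "
            "(or an auxiliary predictor)"
        )
    log_rows: list[dict] = []
    dropped = np.zeros(n, dtype=bool)

    use_dropout = scenario.form in {"monotone", "mixed"}
    use_intermittent = scenario.form in {"intermittent", "mixed"}

    for t in range(1, T):
        if use_dropout and scenario.dropout_hazard[t] > 0:
            z = _predictor_z(ds, scenario, t, observed, latent)
            base = scenario.dropout_hazard[t]
            lin = (logit(np.clip(base, 1e-12, 1 - 1e-12)) + scenario.coef * z) if 0 < base < 1 else None
            p = expit(lin) if lin is not None else np.full(n, float(base))
            new_drop = ~dropped & (rng.random(n) < p)
            for i in np.flatnonzero(new_drop):
                for s in range(t, T):
                    if observed[i, s]:
                        log_rows.append(
                            {"subject": i, "wave": s, "cause": "dropout",
                             "lin_pred": float(lin[i]) if lin is not None else float(logit(np.clip(base, 1e-12, 1 - 1e-12)))}
                        )
                observed[i, t:] = False
            dropped |= new_drop
        if use_intermittent and scenario.intermittent_rate[t] > 0:
            hit = ~dropped & observed[:, t] & (rng.random(n) < scenario.intermittent_rate[t])
            for i in np.flatnonzero(hit):
                log_rows.append({"subject": i, "wave": t, "cause": "intermittent", "lin_pred": 0.0})
            observed[hit, t] = False

    if scenario.wave1_nonresponse > 0:
        later = observed[:, 1:].any(axis=1)
        hit = later & observed[:, 0] & (rng.random(n) < scenario.wave1_nonresponse)
        for i in np.flatnonzero(hit):
            log_rows.append({"subject": i, "wave": 0, "cause": "wave1_nonresponse", "lin_pred": 0.0})
        observed[hit, 0] = False

    y = ds.y.copy()
    y[~observed] = np.nan
    out = ds.with_y(y)
    log = pd.DataFrame(log_rows, columns=["subject", "wave", "cause", "lin_pred"])
    return out, log


def generate_auxiliaries(
    latent: pd.DataFrame,
    names: list[str],
    rho_intercept: float = 0.3,
    rho_slope: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Standard-normal auxiliary covariates correlated with the latent factors.

    Each auxiliary x satisfies corr(x, I) = rho_intercept and
    corr(x, S) = rho_slope (given uncorrelated I and S); the residual part is
    independent noise, so auxiliaries are exchangeable and mutually
    independent given the factors.
    """
    if rho_intercept**2 + rho_slope**2 > 1:
        raise ValueError("rho_intercept^2 + rho_slope^2 must be <= 1")
    rng = _rng(seed)
    zI = (latent["intercept"] - latent["intercept"].mean()).to_numpy()
    zS = (latent["slope"] - latent["slope"].mean()).to_numpy()
    sI, sS = zI.std(), zS.std()
    zI = zI / sI if sI > 0 else zI
    zS = zS / sS if sS > 0 else zS
    resid_sd = math.sqrt(max(1.0 - rho_intercept**2 - rho_slope**2, 0.0))
    cols = {}
    for name in names:
        cols[name] = rho_intercept * zI + rho_slope * zS + resid_sd * rng.standard_normal(len(zI))
    return pd.DataFrame(cols)


def study_emulation_preset() -> tuple[GrowthParams, MissingnessScenario, int, np.ndarray]:
    """Configuration emulating the tutorial cohort's shape.

    N = 1072 students, loadings (0, 1.17, 2.17), growth parameters near the
    memorizing-scale ML solution, and MCAR mixed attrition/non-response rates
    solved from the observed per-wave response margins (1029/442/278 of 1072)
    and the 225 complete trajectories; see docs/methods.md for the algebra.
    """
    params = GrowthParams(
        mu_I=3.28, mu_S=-0.06, psi_II=0.41, psi_SS=0.02, psi_IS=0.0, theta=0.27
    )
    scenario = MissingnessScenario(
        mechanism="MCAR",
        form="mixed",
        dropout_hazard=(0.0, 0.552, 0.371),
        intermittent_rate=(0.0, 0.08, 0.08),
        wave1_nonresponse=0.093,
    )
    return params, scenario, STUDY_N, STUDY_WAVE_TIMES.copy()
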