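"""Synthetic adolescent cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
bifactor (general + specific internalizing/externalizing) latent structure
behind 8 psychopathology facets each reported by two raters; person-level
sleep means and log residual variances that depend linearly on the latent
factors and demographic covariates; nightly sleep outcomes with a linear
night trend, a weekend shift, and person-specific residual variance; and
age-dependent wear-night missingness with a minority of persons having
too few nights to count as valid.

The default configuration encodes the generating values the package's
recovery experiments target: standardized loadings for the aggregated
indicators, between-person regression coefficients, outcome-level means
and spreads, and intraclass correlations of 0.17 / 0.42 / 0.29 for
duration, bedtime and waketime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sleep_records import FACETS, NIGHT_COLUMNS, PERSON_COLUMNS

#: Between-level outcome labels, fixed order.
OUTCOMES6: tuple[str, ...] = (
    "alpha_duration",
    "alpha_bedtime",
    "alpha_waketime",
    "omega_duration",
    "omega_bedtime",
    "omega_waketime",
)

#: Between-level predictor labels (after the intercept), fixed order.
PREDICTORS7: tuple[str, ...] = ("g", "s_int", "s_ext", "age", "sex", "medu", "inr")

#: Internalizing / externalizing facet membership.
INT_FACETS: tuple[str, ...] = ("ad", "wd", "som")
EXT_FACETS: tuple[str, ...] = ("odd", "cd", "hyp", "at")

# Standardized loadings of the aggregated indicators (general factor order
# follows FACETS; specific loadings keyed by facet).
_LAMBDA_GENERAL = {
    "ad": 0.641, "wd": 0.573, "som": 0.569, "odd": 0.719,
    "cd": 0.509, "hyp": 0.558, "at": 0.727, "eri": 0.918,
}
_LAMBDA_SPECIFIC = {
    "ad": 0.641, "wd": 0.584, "som": 0.459,
    "odd": 0.590, "cd": 0.611, "hyp": 0.428, "at": 0.246,
}

# Between-level coefficients, rows = OUTCOMES6, cols = PREDICTORS7.
# Covariate columns apply to z-scored age/medu/inr and binary sex.
_B_DEFAULT = np.array([
    [3.434, -4.389, -3.371, -4.770, -27.798, 1.762, 1.399],
    [6.603, 7.973, -9.731, 14.436, 39.890, -2.784, -6.372],
    [3.633, 3.490, -10.355, 8.131, 17.699, -1.901, -2.755],
    [0.121, 0.051, -0.005, 0.015, -0.020, -0.085, -0.019],
    [0.058, 0.125, 0.098, 0.014, 0.328, -0.055, -0.064],
    [0.127, 0.123, -0.037, 0.071, 0.157, -0.032, -0.064],
])

#: Target cohort-level sleep means (duration, bedtime, waketime; minutes).
ALPHA_MEANS = (389.54, -3.83, 463.07)
#: Target mean within-person nightly SDs (minutes).
WITHIN_SDS = (79.10, 74.22, 91.92)
#: Target intraclass correlations (duration, bedtime, waketime).
ICC_TARGETS = (0.17, 0.42, 0.29)

_P_FEMALE = 0.534
_MEDU_VALUES = (10.0, 12.0, 14.0, 16.0)
_MEDU_PROBS = (0.0294, 0.0798, 0.4412, 0.4500)
_AGE_LOW, _AGE_HIGH = 14.0, 18.0
_INR_MEAN, _INR_SD = 2.53, 1.84


def _population_scales() -> dict[str, tuple[float, float]]:
    """Generating (mean, sd) of each covariate, used for z-scoring truth."""
    p = np.asarray(_MEDU_PROBS) / np.sum(_MEDU_PROBS)
    v = np.asarray(_MEDU_VALUES)
    medu_mean = float(p @ v)
    medu_sd = float(np.sqrt(p @ (v - medu_mean) ** 2))
    age_mean = (_AGE_LOW + _AGE_HIGH) / 2
    age_sd = (_AGE_HIGH - _AGE_LOW) / np.sqrt(12.0)
    return {
        "age": (age_mean, age_sd),
        "medu": (medu_mean, medu_sd),
        "inr": (_INR_MEAN, _INR_SD),
    }


@dataclass
class CohortConfig:
    """Generating parameters for one synthetic cohort."""

    n_persons: int = 238
    n_nights: int = 14
    seed: int = 0
    lambda_general: dict[str, float] = field(
        default_factory=lambda: dict(_LAMBDA_GENERAL))
    lambda_specific: dict[str, float] = field(
        default_factory=lambda: dict(_LAMBDA_SPECIFIC))
    rater_reliability: float = 0.8
    B: np.ndarray = field(default_factory=lambda: _B_DEFAULT.copy())
    Psi: np.ndarray | None = None
    alpha_mean: tuple[float, float, float] = ALPHA_MEANS
    within_sd: tuple[float, float, float] = WITHIN_SDS
    omega_var: tuple[float, float, float] = (0.4, 0.4, 0.4)
    gamma_night: tuple[float, float, float] = (-0.8, 1.0, 0.5)
    gamma_weekend: tuple[float, float, float] = (15.0, 45.0, 60.0)
    icc_targets: tuple[float, float, float] = ICC_TARGETS
    miss_intercept: float = -1.87
    miss_age_slope: float = -0.30
    invalid_fraction: float = 34.0 / 238.0

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.B.shape != (6, 7):
            raise ValueError("B must be 6x7 (OUTCOMES6 x PREDICTORS7)")
        if not (0.0 < self.rater_reliability <= 1.0):
            raise ValueError("rater_reliability must lie in (0, 1]")
        if any(not 0.0 < t < 1.0 for t in self.icc_targets):
            raise ValueError("icc_targets must lie in (0, 1)")
        k2 = (1.0 + self.rater_reliability) / (2.0 * self.rater_reliability)
        for f in FACETS:
            lam2 = self.lambda_general[f] ** 2 + self.lambda_specific.get(f, 0.0) ** 2
            if k2 * lam2 >= 1.0:
                raise ValueError(
                    f"facet {f!r}: disattenuated communality {k2 * lam2:.3f} >= 1; "
                    "raise rater_reliability or lower loadings")
        if self.Psi is None:
            self.Psi = build_psi(self)
        self.Psi = np.asarray(self.Psi, dtype=float)
        if self.Psi.shape != (6, 6) or not np.allclose(self.Psi, self.Psi.T):
            raise ValueError("Psi must be symmetric 6x6")
        if np.linalg.eigvalsh(self.Psi)[0] <= 0.0:
            raise ValueError("Psi is not positive definite")

    @property
    def omega_mean(self) -> np.ndarray:
        """Generating mean of log residual variance: exp(omega/2) = within SD."""
        return 2.0 * np.log(np.asarray(self.within_sd))


# Residual correlations among the six between-level outcomes (order OUTCOMES6).
_PSI_CORR = np.array([
    [1.00, -0.35, 0.25, 0.15, 0.00, 0.00],
    [-0.35, 1.00, 0.50, 0.00, 0.15, 0.00],
    [0.25, 0.50, 1.00, 0.00, 0.00, 0.15],
    [0.15, 0.00, 0.00, 1.00, 0.30, 0.30],
    [0.00, 0.15, 0.00, 0.30, 1.00, 0.30],
    [0.00, 0.00, 0.15, 0.30, 0.30, 1.00],
])

#: Generating variances of the 7 between-level predictors (sex is Bernoulli).
_VAR_X = np.array([1, 1, 1, 1, _P_FEMALE * (1 - _P_FEMALE), 1, 1], dtype=float)


def build_psi(config: CohortConfig) -> np.ndarray:
    """Residual covariance of the six between-level outcomes.

    Diagonal entries for the three intercepts are chosen so the *total*
    between-person variance (regression-explained + residual) divides the
    total outcome variance in the icc_targets proportions, given the mean
    within-night variance implied by ``within_sd`` and ``omega_var``.
    Log-variance residuals get ``omega_var`` total spread.  Off-diagonal
    structure applies fixed modest correlations (later bedtime pairs with
    later waketime and slightly shorter duration; variabilities co-vary).
    """
    B = np.asarray(config.B, dtype=float)
    explained = (B ** 2) @ _VAR_X
    om_mean = 2.0 * np.log(np.asarray(config.within_sd))
    v_om = np.asarray(config.omega_var, dtype=float)
    # E[exp(omega)] under a normal omega
    v_within = np.exp(om_mean + v_om / 2.0)
    icc = np.asarray(config.icc_targets)
    v_between_total = icc / (1.0 - icc) * v_within
    diag = np.empty(6)
    diag[:3] = np.maximum(v_between_total - explained[:3], 0.15 * v_between_total)
    diag[3:] = np.maximum(v_om - explained[3:], 0.15 * v_om)
    d = np.sqrt(diag)
    return _PSI_CORR * np.outer(d, d)


def default_config(n_persons: int = 238, seed: int = 0, **overrides) -> CohortConfig:
    """The reference cohort configuration (all published anchors)."""
    return CohortConfig(n_persons=n_persons, seed=seed, **overrides)


def _draw_demographics(rng: np.random.Generator, n: int) -> pd.DataFrame:
    age = rng.uniform(_AGE_LOW, _AGE_HIGH, size=n)
    sex = rng.binomial(1, _P_FEMALE, size=n).astype(float)
    p = np.asarray(_MEDU_PROBS) / np.sum(_MEDU_PROBS)
    medu = rng.choice(_MEDU_VALUES, size=n, p=p)
    sigma2 = np.log(1.0 + (_INR_SD / _INR_MEAN) ** 2)
    mu = np.log(_INR_MEAN) - sigma2 / 2.0
    inr = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    return pd.DataFrame(
        {"age": age, "sex": sex, "maternal_education": medu, "income_to_needs": inr}
    )


def _covariate_design(demo: pd.DataFrame) -> np.ndarray:
    """Columns [age_z, sex, medu_z, inr_z] on the generating scale."""
    scales = _population_scales()
    return np.column_stack([
        (demo["age"].to_numpy() - scales["age"][0]) / scales["age"][1],
        demo["sex"].to_numpy(),
        (demo["maternal_education"].to_numpy() - scales["medu"][0]) / scales["medu"][1],
        (demo["income_to_needs"].to_numpy() - scales["inr"][0]) / scales["inr"][1],
    ])


def generate_cohort(
    config: CohortConfig, return_latents: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame] | tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; deterministic given ``config.seed``.

    Returns ``(persons, nights)`` data frames in the on-disk column layout,
    plus a per-person latent-truth frame when ``return_latents`` is set.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    ids = [f"p{i:04d}" for i in range(n)]

    demo = _draw_demographics(rng, n)
    latent = rng.standard_normal((n, 3))  # g, s_int, s_ext; orthogonal
    x = np.column_stack([latent, _covariate_design(demo)])  # (n, 7)

    # --- psychopathology facet scores, two raters each -------------------
    rel = config.rater_reliability
    k = np.sqrt((1.0 + rel) / (2.0 * rel))  # disattenuation for aggregation
    noise_sd = np.sqrt((1.0 - rel) / rel)
    persons = pd.DataFrame({"person_id": ids})
    persons = pd.concat([persons, demo], axis=1)
    for j, f in enumerate(FACETS):
        lg = k * config.lambda_general[f]
        ls = k * config.lambda_specific.get(f, 0.0)
        dom = latent[:, 1] if f in INT_FACETS else latent[:, 2]
        if f == "eri":
            dom = np.zeros(n)
        resid_sd = np.sqrt(max(1.0 - lg ** 2 - ls ** 2, 1e-12))
        signal = lg * latent[:, 0] + ls * dom + resid_sd * rng.standard_normal(n)
        for r in ("cg", "yr"):
            raw = signal + noise_sd * rng.standard_normal(n)
            # cosmetic T-score-like scale; aggregation re-standardizes anyway
            persons[f"{f}_{r}"] = 50.0 + 10.0 * np.sqrt(rel) * raw

    # --- between-person sleep effects ------------------------------------
    gam_n = np.asarray(config.gamma_night)
    gam_w = np.asarray(config.gamma_weekend)
    # intercepts: keep marginal cohort means at their targets given the
    # expected contribution of sex (only non-centered predictor), the
    # night trend midpoint and the expected weekend share (2 of 7).
    alpha0 = (np.asarray(config.alpha_mean)
              - config.B[:3, 4] * _P_FEMALE
              - gam_n * (config.n_nights - 1) / 2.0
              - gam_w * (2.0 / 7.0))
    omega0 = config.omega_mean - config.B[3:, 4] * _P_FEMALE
    mu_b = np.concatenate([alpha0, omega0]) + x @ config.B.T  # (n, 6)
    b = mu_b + rng.multivariate_normal(np.zeros(6), config.Psi, size=n,
                                       method="cholesky")
    alpha, omega = b[:, :3], b[:, 3:]

    # --- nightly outcomes with wear missingness ---------------------------
    age_z = x[:, 3]
    p_miss = 1.0 / (1.0 + np.exp(-(config.miss_intercept
                                   + config.miss_age_slope * age_z)))
    w_invalid = 1.0 / (1.0 + np.exp(0.5 * age_z))
    p_invalid = np.clip(
        config.invalid_fraction * w_invalid / max(w_invalid.mean(), 1e-12), 0, 1)
    invalid = rng.random(n) < p_invalid

    start_dow = rng.integers(0, 7, size=n)
    rows = []
    for i in range(n):
        t_idx = np.arange(config.n_nights)
        if invalid[i]:
            n_obs = rng.integers(0, 3)  # 0, 1 or 2 wear nights
            worn = np.zeros(config.n_nights, dtype=bool)
            worn[rng.choice(config.n_nights, size=n_obs, replace=False)] = True
        else:
            worn = rng.random(config.n_nights) >= p_miss[i]
        dow = (start_dow[i] + t_idx) % 7
        wkd = np.isin(dow, (4, 5)).astype(int)  # Fri/Sat night starts
        eps = rng.standard_normal((config.n_nights, 3)) * np.exp(omega[i] / 2.0)
        y = alpha[i] + np.outer(t_idx, gam_n) + np.outer(wkd, gam_w) + eps
        y[:, 0] = np.clip(y[:, 0], 0.0, 1440.0)
        for t in np.flatnonzero(worn):
            rows.append((ids[i], int(t), int(wkd[t]), y[t, 0], y[t, 1], y[t, 2]))

    nights = pd.DataFrame(rows, columns=list(NIGHT_COLUMNS))
    persons = persons[list(PERSON_COLUMNS)]

    if return_latents:
        truth = pd.DataFrame(
            {"person_id": ids, "g": latent[:, 0], "s_int": latent[:, 1],
             "s_ext": latent[:, 2]})
        for j, name in enumerate(OUTCOMES6):
            truth[name] = b[:, j]
        return persons, nights, truth
    return persons, nights


def truth_table(config: CohortConfig) -> pd.DataFrame:
    """Flat listing of every free generating parameter, one labeled row each.

    Labels follow the fitted-model naming (``outcome~predictor``) so
    recovery reports can join on label.
    """
    rows: list[tuple[str, str, str, float]] = []
    for i, out in enumerate(OUTCOMES6):
        for j, pred in enumerate(PREDICTORS7):
            rows.append((f"{out}~{pred}", out, pred, float(config.B[i, j])))
    for s, out in enumerate(("duration", "bedtime", "waketime")):
        rows.append((f"gamma_night[{out}]", out, "night", float(config.gamma_night[s])))
        rows.append((f"gamma_weekend[{out}]", out, "weekend",
                     float(config.gamma_weekend[s])))
        rows.append((f"alpha_mean[{out}]", out, "intercept",
                     float(config.alpha_mean[s])))
        rows.append((f"omega_mean[{out}]", out, "intercept",
                     float(config.omega_mean[s])))
    for i in range(6):
        for j in range(i, 6):
            rows.append((f"psi[{OUTCOMES6[i]},{OUTCOMES6[j]}]", OUTCOMES6[i],
                         OUTCOMES6[j], float(config.Psi[i, j])))
    for f in FACETS:
        rows.append((f"lambda_g[{f}]", f, "general", float(config.lambda_general[f])))
    for f, v in config.lambda_specific.items():
        rows.append((f"lambda_s[{f}]", f, "specific", float(v)))
    rows.append(("rater_reliability", "raters", "reliability",
                 float(config.rater_reliability)))
    rows.append(("miss_intercept", "missingness", "intercept",
                 float(config.miss_intercept)))
    rows.append(("miss_age_slope", "missingness", "age", float(config.miss_age_slope)))
    rows.append(("invalid_fraction", "missingness", "invalid",
                 float(config.invalid_fraction)))
    df = pd.DataFrame(rows, columns=["label", "outcome", "predictor", "value"])
    if df["label"].duplicated().any():
        raise AssertionError("truth_table labels must be unique")
    return df
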