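"""End-to-end orchestration: measurement model -> factor scores -> MELSM.

Provides the primary analysis (six sleep outcomes regressed on general /
specific psychopathology factor scores plus covariates), the demographic
moderation model, the correlated-factors supplement, and seeded
parameter-recovery experiments against the synthetic generator's truth
table.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bifactor, melsm, sleep_records, synthetic_cohort
from .melsm import McmcConfig, MelsmSpec
from .sleep_records import SLEEP_METRICS
from .synthetic_cohort import CohortConfig, PREDICTORS7

log = logging.getLogger("nightvar")

#: Table layout order: variabilities first, then means.
SUMMARY_OUTCOMES = (
    "omega_duration", "omega_bedtime", "omega_waketime",
    "alpha_duration", "alpha_bedtime", "alpha_waketime",
)


@dataclass
class AnalysisConfig:
    """Which models to run, with shared MCMC settings."""

    seed: int
    models: tuple[str, ...] = ("primary",)
    n_iter: int = 2000
    n_chains: int = 2
    min_nights: int = 3
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("select at least one model")


def _zscore(x: pd.Series) -> pd.Series:
    return (x - x.mean()) / x.std(ddof=1)


def prepare_covariates(persons: pd.DataFrame,
                       scores: pd.DataFrame) -> pd.DataFrame:
    """Between-level predictor table: factor scores + z-scored demographics.

    Age, maternal education and income-to-needs are z-scored over the
    sample; sex stays binary.  Missing covariates are mean-imputed with a
    logged count (age enters every model, addressing age-related
    missingness in the sleep series).
    """
    df = persons.set_index("person_id")
    cov = pd.DataFrame(index=df.index)
    cov["g"] = scores["g"]
    cov["s_int"] = scores.iloc[:, 1]
    cov["s_ext"] = scores.iloc[:, 2]
    cov["age"] = _zscore(df["age"])
    cov["sex"] = df["sex"]
    cov["medu"] = _zscore(df["maternal_education"])
    cov["inr"] = _zscore(df["income_to_needs"])
    n_missing = int(cov.isna().sum().sum())
    if n_missing:
        log.info("mean-imputing %d missing covariate cells", n_missing)
        cov = cov.fillna(cov.mean())
    return cov[list(PREDICTORS7)]


def _filtered_series(nights: pd.DataFrame, persons: pd.DataFrame,
                     min_nights: int = 3) -> list[sleep_records.NightlySeries]:
    ids = persons["person_id"].astype(str).tolist()
    series = sleep_records._series_from_frame(nights, ids)
    return [sleep_records.apply_validity_filter(s, min_nights) for s in series]


def summarize_table(posterior: melsm.MelsmPosterior,
                    level: float = 0.95) -> pd.DataFrame:
    """Coefficient table: outcome blocks x predictor rows, plus
    standardized betas for the psychopathology effects."""
    summ = posterior.summary(level)
    std = melsm.standardize_effects(posterior)
    rows = []
    outs = [f"alpha_{o}" for o in posterior.data.outcome_labels] + \
           [f"omega_{o}" for o in posterior.data.outcome_labels]
    order = [o for o in SUMMARY_OUTCOMES if o in outs] + \
            [o for o in outs if o not in SUMMARY_OUTCOMES]
    for out in order:
        for p in posterior.data.predictor_labels:
            if p == "intercept":
                continue
            lab = f"{out}~{p}"
            r = summ.loc[lab]
            srow = std[(std["outcome"] == out) & (std["predictor"] == p)]
            rows.append({
                "outcome": out, "predictor": p, "estimate": r["mean"],
                "posterior_sd": r["sd"], "ci_lower": r["ci_lower"],
                "ci_upper": r["ci_upper"], "significant": bool(r["significant"]),
                "beta": float(srow["beta_median"].iloc[0]) if len(srow) else np.nan,
                "beta_lower": float(srow["beta_lower"].iloc[0]) if len(srow) else np.nan,
                "beta_upper": float(srow["beta_upper"].iloc[0]) if len(srow) else np.nan,
            })
    return pd.DataFrame(rows)


@dataclass
class PrimaryResult:
    fit: bifactor.FactorFit
    indices: dict[str, float]
    scores: pd.DataFrame
    posterior: melsm.MelsmPosterior
    table: pd.DataFrame


def run_primary(persons: pd.DataFrame, nights: pd.DataFrame,
                config: AnalysisConfig,
                extra_covariates=None) -> PrimaryResult:
    """Measurement model -> scores -> MELSM on all three sleep outcomes."""
    t0 = time.time()
    panel = bifactor.aggregate_raters(persons)
    fit = bifactor.fit_bifactor_s1(panel, seed=config.seed)
    indices = bifactor.fit_indices(fit)
    scores = bifactor.factor_scores(fit, panel)
    log.info("stage=cfa wall=%.1fs cfi=%.3f", time.time() - t0, indices["cfi"])

    cov = prepare_covariates(persons, scores)
    if extra_covariates is not None:
        cov = pd.concat([cov, extra_covariates], axis=1)
    series = _filtered_series(nights, persons, config.min_nights)
    t0 = time.time()
    posterior = melsm.fit_melsm(
        series, cov, MelsmSpec(outcomes=SLEEP_METRICS),
        McmcConfig(n_chains=config.n_chains, n_iter=config.n_iter,
                   seed=config.seed))
    log.info("stage=melsm wall=%.1fs max_psr=%.3f", time.time() - t0,
             float(posterior.psr_vector().max()))
    return PrimaryResult(fit=fit, indices=indices, scores=scores,
                         posterior=posterior, table=summarize_table(posterior))


def run_moderation(persons: pd.DataFrame, nights: pd.DataFrame,
                   config: AnalysisConfig) -> PrimaryResult:
    """Primary model plus four simultaneous GF-DP x demographic interactions.

    The general factor score and the four demographics are z-scored first
    and the products are formed from the z-scores (product of z-scores,
    not z-score of products).
    """
    panel = bifactor.aggregate_raters(persons)
    fit = bifactor.fit_bifactor_s1(panel, seed=config.seed)
    scores = bifactor.factor_scores(fit, panel)
    cov = prepare_covariates(persons, scores)
    zg = _zscore(cov["g"])
    inter = pd.DataFrame(index=cov.index)
    for d in ("age", "sex", "medu", "inr"):
        inter[f"g_x_{d}"] = zg * _zscore(cov[d])
    series = _filtered_series(nights, persons, config.min_nights)
    posterior = melsm.fit_melsm(
        series, pd.concat([cov, inter], axis=1),
        MelsmSpec(outcomes=SLEEP_METRICS),
        McmcConfig(n_chains=config.n_chains, n_iter=config.n_iter,
                   seed=config.seed))
    return PrimaryResult(fit=fit, indices=bifactor.fit_indices(fit),
                         scores=scores, posterior=posterior,
                         table=summarize_table(posterior))


def run_correlated_supplement(persons: pd.DataFrame, nights: pd.DataFrame,
                              config: AnalysisConfig) -> dict[str, PrimaryResult]:
    """Correlated internalizing/externalizing/dysregulation factors in
    place of the general + specific factors; separate models for sleep
    duration and for bedtime + waketime."""
    panel = bifactor.aggregate_raters(persons)
    fit = bifactor.fit_factor_model(panel, bifactor.correlated_spec(),
                                    seed=config.seed)
    scores = bifactor.factor_scores(fit, panel)
    scores = scores.rename(columns={"s_int_corr": "g", "s_ext_corr": "s_int",
                                    "dys": "s_ext"})
    # predictor roles: int, ext, dysregulation (names fixed for the design)
    cov = prepare_covariates(persons, scores)
    cov = cov.rename(columns={"g": "int", "s_int": "ext", "s_ext": "dys"})
    series = _filtered_series(nights, persons, config.min_nights)
    out: dict[str, PrimaryResult] = {}
    for name, metrics in (("duration", ("duration_min",)),
                          ("bedtime_waketime", ("bedtime_min", "waketime_min"))):
        posterior = melsm.fit_melsm(
            series, cov, MelsmSpec(outcomes=metrics),
            McmcConfig(n_chains=config.n_chains, n_iter=config.n_iter,
                       seed=config.seed))
        out[name] = PrimaryResult(fit=fit, indices=bifactor.fit_indices(fit),
                                  scores=scores, posterior=posterior,
                                  table=summarize_table(posterior))
    return out


# ---------------------------------------------------------------------------
# Recovery experiments

def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds below 2**31."""
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def run_recovery(cohort_config: CohortConfig, n_replicates: int,
                 seed: int, n_iter: int = 1200,
                 labels: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Generate -> fit -> compare against the generating truth.

    Per tracked between-level coefficient: generating value, mean posterior
    mean across replicates, count of replicates whose 95% interval covers
    the truth, and the replicate count.  Failures of individual replicates
    are recorded (``n_failed``), not fatal.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    truth = synthetic_cohort.truth_table(cohort_config)
    track = list(labels) if labels else [
        f"{o}~{p}" for o in synthetic_cohort.OUTCOMES6 for p in PREDICTORS7]
    seeds = replicate_seeds(seed, n_replicates)
    est: dict[str, list[float]] = {t: [] for t in track}
    cover: dict[str, int] = {t: 0 for t in track}
    n_failed = 0
    for r, s in enumerate(seeds):
        cfg = CohortConfig(**{**cohort_config.__dict__, "seed": s})
        persons, nights = synthetic_cohort.generate_cohort(cfg)
        try:
            res = run_primary(persons, nights,
                              AnalysisConfig(seed=s, n_iter=n_iter))
        except Exception as exc:  # recorded, not fatal
            log.warning("replicate %d failed: %s", r, exc)
            n_failed += 1
            continue
        summ = res.posterior.summary()
        for t in track:
            row = summ.loc[t]
            est[t].append(float(row["mean"]))
            tv = float(truth.loc[truth["label"] == t, "value"].iloc[0])
            if row["ci_lower"] <= tv <= row["ci_upper"]:
                cover[t] += 1
    rows = []
    for t in track:
        tv = float(truth.loc[truth["label"] == t, "value"].iloc[0])
        rows.append({
            "label": t, "truth": tv,
            "mean_estimate": float(np.mean(est[t])) if est[t] else np.nan,
            "coverage": cover[t], "n_replicates": len(est[t]),
            "n_failed": n_failed,
        })
    return pd.DataFrame(rows)


def write_outputs(result: PrimaryResult, out_dir: str | Path) -> None:
    """Persist scores.csv, summary.csv and convergence.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores = result.scores.copy()
    scores.index.name = "person_id"
    scores.to_csv(out / "scores.csv")
    result.table.to_csv(out / "summary.csv", index=False)
    conv = {
        "max_psr": float(result.posterior.psr_vector().max()),
        "psr": {k: float(v) for k, v in result.posterior.psr_vector().items()},
        "cfa_fit": result.indices,
    }
    (out / "convergence.json").write_text(json.dumps(conv, indent=2))
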