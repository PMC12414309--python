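"""Bifactor S-1 measurement model of adolescent psychopathology.

Eight facet indicators (anxious/depressed, withdrawn/depressed, somatic,
oppositional defiance, conduct, hyperactivity, inattention, emotion
dysregulation) load on a general factor of dysregulation and
psychopathology; the first three additionally load on a specific
internalizing factor and the next four on a specific externalizing
factor.  Emotion dysregulation is the reference indicator: it loads on
the general factor only, anchoring its interpretation.  The standard
specification frees two residual covariances (hyperactivity-inattention,
withdrawn-hyperactivity) and one factor-residual covariance
(externalizing with the anxious/depressed residual).

Estimation is full-information (casewise) Gaussian maximum likelihood, so
persons with arbitrarily missing indicators contribute through their
observed subset.  Model chi-square is computed against a saturated
mean/covariance model (EM-estimated under missingness); CFI uses an
independence baseline with free means and variances.  Factor scores are
regression-method (posterior mean) scores, computed per missingness
pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .sleep_records import FACETS, RATERS, PersonProfile, persons_to_frame
from .synthetic_cohort import EXT_FACETS, INT_FACETS

FREE = None  # sentinel for a freely estimated parameter


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the best log-likelihood found."""

    def __init__(self, message: str, best_loglik: float = np.nan):
        super().__init__(message)
        self.best_loglik = best_loglik


# ---------------------------------------------------------------------------
# Rater aggregation

def aggregate_raters(profiles) -> pd.DataFrame:
    """Z-score each rater column, average available raters per facet,
    re-standardize; returns a person x facet indicator panel.

    A facet with zero non-missing values in both raters is an error.
    """
    if isinstance(profiles, pd.DataFrame):
        df = profiles
    else:
        df = persons_to_frame(profiles)
    if len(df) < 2:
        raise ValueError("need at least 2 persons to standardize indicators")
    panel = pd.DataFrame(index=df.index)
    for f in FACETS:
        zs = []
        for r in RATERS:
            col = df[f"{f}_{r}"]
            if col.notna().any():
                zs.append((col - col.mean()) / col.std(ddof=1))
        if not zs:
            raise ValueError(f"facet {f!r} has no non-missing rater scores")
        agg = pd.concat(zs, axis=1).mean(axis=1)  # available-case mean
        if agg.notna().sum() == 0:
            raise ValueError(f"facet {f!r} has no non-missing rater scores")
        panel[f] = (agg - agg.mean()) / agg.std(ddof=1)
    panel.index = df["person_id"].astype(str).values
    panel.index.name = "person_id"
    return panel


# ---------------------------------------------------------------------------
# Model specification

@dataclass
class FactorModelSpec:
    """Pattern specification of a linear-Gaussian factor model.

    ``loadings[(indicator, factor)]`` is ``FREE`` or a fixed value;
    pairs not listed are fixed at zero.  ``factor_cov`` overrides the
    default (variances fixed 1, covariances fixed 0).  ``resid_cov``
    lists free residual covariances, ``factor_resid_cov`` free
    factor-residual covariances.  Residual variances are free unless
    fixed in ``resid_var_fixed``.
    """

    indicators: tuple[str, ...]
    factors: tuple[str, ...]
    loadings: dict[tuple[str, str], float | None]
    factor_cov: dict[tuple[str, str], float | None] = field(default_factory=dict)
    resid_cov: tuple[tuple[str, str], ...] = ()
    factor_resid_cov: tuple[tuple[str, str], ...] = ()
    resid_var_fixed: dict[str, float] = field(default_factory=dict)

    # -- bookkeeping ---------------------------------------------------
    def free_labels(self) -> list[str]:
        labels = []
        for (i, f), v in self.loadings.items():
            if v is FREE:
                labels.append(f"lambda[{i},{f}]")
        for i in self.indicators:
            if i not in self.resid_var_fixed:
                labels.append(f"theta[{i}]")
        for a, b in self.resid_cov:
            labels.append(f"theta[{a},{b}]")
        for f, i in self.factor_resid_cov:
            labels.append(f"kappa[{f},{i}]")
        for (a, b), v in self.factor_cov.items():
            if v is FREE:
                labels.append(f"phi[{a},{b}]")
        return labels

    @property
    def n_free_sigma(self) -> int:
        return len(self.free_labels())

    def build(self, params: np.ndarray):
        """Assemble (Lambda, Phi, Theta, K) from the free-parameter vector."""
        p, q = len(self.indicators), len(self.factors)
        iidx = {n: i for i, n in enumerate(self.indicators)}
        fidx = {n: i for i, n in enumerate(self.factors)}
        Lam = np.zeros((p, q))
        Phi = np.eye(q)
        Theta = np.zeros((p, p))
        K = np.zeros((q, p))
        pos = 0
        for (i, f), v in self.loadings.items():
            if v is FREE:
                Lam[iidx[i], fidx[f]] = params[pos]
                pos += 1
            else:
                Lam[iidx[i], fidx[f]] = v
        for i in self.indicators:
            if i in self.resid_var_fixed:
                Theta[iidx[i], iidx[i]] = self.resid_var_fixed[i]
            else:
                Theta[iidx[i], iidx[i]] = params[pos]
                pos += 1
        for a, b in self.resid_cov:
            Theta[iidx[a], iidx[b]] = Theta[iidx[b], iidx[a]] = params[pos]
            pos += 1
        for f, i in self.factor_resid_cov:
            K[fidx[f], iidx[i]] = params[pos]
            pos += 1
        for (a, b), v in self.factor_cov.items():
            val = params[pos] if v is FREE else v
            if v is FREE:
                pos += 1
            Phi[fidx[a], fidx[b]] = Phi[fidx[b], fidx[a]] = val
        assert pos == len(params)
        return Lam, Phi, Theta, K

    def start_values(self) -> np.ndarray:
        start = []
        for (i, f), v in self.loadings.items():
            if v is FREE:
                start.append(0.5)
        for i in self.indicators:
            if i not in self.resid_var_fixed:
                start.append(0.5)
        start.extend(0.0 for _ in self.resid_cov)
        start.extend(0.0 for _ in self.factor_resid_cov)
        for (a, b), v in self.factor_cov.items():
            if v is FREE:
                start.append(0.3 if a != b else 1.0)
        return np.asarray(start, dtype=float)


def bifactor_spec() -> FactorModelSpec:
    """The bifactor S-1 specification with its three covariance modifications."""
    loadings: dict[tuple[str, str], float | None] = {
        (f, "g"): FREE for f in FACETS}
    loadings.update({(f, "s_int"): FREE for f in INT_FACETS})
    loadings.update({(f, "s_ext"): FREE for f in EXT_FACETS})
    return FactorModelSpec(
        indicators=FACETS,
        factors=("g", "s_int", "s_ext"),
        loadings=loadings,
        resid_cov=(("hyp", "at"), ("wd", "hyp")),
        factor_resid_cov=(("s_ext", "ad"),),
    )


def correlated_spec(eri_resid_var: float = 0.05) -> FactorModelSpec:
    """Correlated internalizing / externalizing / dysregulation factors.

    Dysregulation is a single-indicator factor: the emotion dysregulation
    loading is fixed at 1 and its residual variance fixed at a small share
    of the (unit) indicator variance; the factor variance is free.
    """
    loadings: dict[tuple[str, str], float | None] = {}
    loadings.update({(f, "int"): FREE for f in INT_FACETS})
    loadings.update({(f, "ext"): FREE for f in EXT_FACETS})
    loadings[("eri", "dys")] = 1.0
    return FactorModelSpec(
        indicators=FACETS,
        factors=("int", "ext", "dys"),
        loadings=loadings,
        factor_cov={
            ("int", "ext"): FREE, ("int", "dys"): FREE, ("ext", "dys"): FREE,
            ("dys", "dys"): FREE,
        },
        resid_var_fixed={"eri": eri_resid_var},
    )


def model_df(spec: FactorModelSpec) -> int:
    """Covariance-structure degrees of freedom: p(p+1)/2 minus free
    covariance-side parameters (the mean structure is saturated)."""
    p = len(spec.indicators)
    df = p * (p + 1) // 2 - spec.n_free_sigma
    if df < 0:
        raise ValueError(f"over-parameterized specification (df = {df})")
    return df


# ---------------------------------------------------------------------------
# FIML machinery

def _pattern_stats(X: np.ndarray):
    """Group rows by missingness pattern; per-pattern sufficient stats."""
    isobs = ~np.isnan(X)
    keys = {}
    out = []
    for i in range(X.shape[0]):
        key = isobs[i].tobytes()
        keys.setdefault(key, []).append(i)
    for key, idx in keys.items():
        obs = np.frombuffer(key, dtype=bool)
        if not obs.any():
            continue
        sub = X[np.ix_(idx, np.flatnonzero(obs))]
        n_p = sub.shape[0]
        ybar = sub.mean(axis=0)
        dev = sub - ybar
        S = dev.T @ dev / n_p
        out.append((np.flatnonzero(obs), n_p, ybar, S))
    return out


_LOG2PI = np.log(2.0 * np.pi)


def _fiml_loglik(mu: np.ndarray, Sigma: np.ndarray, patterns) -> float:
    ll = 0.0
    for obs, n_p, ybar, S in patterns:
        So = Sigma[np.ix_(obs, obs)]
        sign, logdet = np.linalg.slogdet(So)
        if sign <= 0:
            return -np.inf
        Si = np.linalg.inv(So)
        d = ybar - mu[obs]
        k = len(obs)
        ll += -0.5 * n_p * (k * _LOG2PI + logdet + np.trace(S @ Si) + d @ Si @ d)
    return ll


def saturated_loglik(X: np.ndarray, max_iter: int = 500, tol: float = 1e-9):
    """ML mean/covariance of a saturated multivariate normal under
    arbitrary missingness, via EM; returns (loglik, mu, Sigma)."""
    patterns = _pattern_stats(X)
    p = X.shape[1]
    col_mean = np.nanmean(X, axis=0)
    col_var = np.nanvar(X, axis=0)
    mu = col_mean.copy()
    Sigma = np.diag(np.maximum(col_var, 1e-6))
    if all(len(obs) == p for obs, *_ in patterns):  # complete data
        n = sum(n_p for _, n_p, _, _ in patterns)
        Xc = X[~np.isnan(X).any(axis=1)]
        mu = Xc.mean(axis=0)
        dev = Xc - mu
        Sigma = dev.T @ dev / n
        return _fiml_loglik(mu, Sigma, patterns), mu, Sigma
    ll_old = -np.inf
    n_tot = sum(n_p for _, n_p, _, _ in patterns)
    for _ in range(max_iter):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        for obs, n_p, ybar, S in patterns:
            mis = np.setdiff1d(np.arange(p), obs)
            Soo = Sigma[np.ix_(obs, obs)]
            Soi = np.linalg.inv(Soo)
            d = ybar - mu[obs]
            if len(mis):
                Smo = Sigma[np.ix_(mis, obs)]
                A = Smo @ Soi
                m_mis = mu[mis] + A @ d
                C = Sigma[np.ix_(mis, mis)] - A @ Smo.T
            Eyy = np.zeros((p, p))
            Ey = np.zeros(p)
            Ey[obs] = ybar
            Eyy[np.ix_(obs, obs)] = S + np.outer(ybar, ybar)
            if len(mis):
                Ey[mis] = m_mis
                # E[y_mis y_obs'] = m_mis ybar' + A S
                Eyy[np.ix_(mis, obs)] = np.outer(m_mis, ybar) + A @ S
                Eyy[np.ix_(obs, mis)] = Eyy[np.ix_(mis, obs)].T
                Eyy[np.ix_(mis, mis)] = (C + A @ S @ A.T
                                         + np.outer(m_mis, m_mis))
            T1 += n_p * Ey
            T2 += n_p * Eyy
        mu = T1 / n_tot
        Sigma = T2 / n_tot - np.outer(mu, mu)
        Sigma = (Sigma + Sigma.T) / 2.0
        ll = _fiml_loglik(mu, Sigma, patterns)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            break
        ll_old = ll
    return ll, mu, Sigma


def independence_loglik(X: np.ndarray) -> tuple[float, int]:
    """Baseline model: free means and variances, zero covariances.

    The likelihood factorizes per variable, so the ML solution is closed
    form over available cases.  Returns (loglik, free parameter count of
    the covariance side = p).
    """
    ll = 0.0
    for j in range(X.shape[1]):
        x = X[:, j]
        x = x[~np.isnan(x)]
        nj = len(x)
        v = max(x.var(), 1e-12)  # ML variance
        ll += -0.5 * nj * (_LOG2PI + np.log(v) + 1.0)
    return ll, X.shape[1]


# ---------------------------------------------------------------------------
# Fitting

@dataclass
class FactorFit:
    """Fitted measurement model: estimates, implied moments, fit statistics."""

    spec: FactorModelSpec
    mu: np.ndarray
    Lambda: np.ndarray
    Phi: np.ndarray
    Theta: np.ndarray
    K: np.ndarray
    Sigma: np.ndarray
    loglik: float
    loglik_saturated: float
    loglik_baseline: float
    df_baseline: int
    n: int
    converged: bool
    heywood: bool
    sample_cov: np.ndarray

    @property
    def df(self) -> int:
        return model_df(self.spec)

    @property
    def chi2(self) -> float:
        return max(2.0 * (self.loglik_saturated - self.loglik), 0.0)

    @property
    def chi2_baseline(self) -> float:
        return max(2.0 * (self.loglik_saturated - self.loglik_baseline), 0.0)

    @property
    def std_loadings(self) -> pd.DataFrame:
        sd_y = np.sqrt(np.diag(self.Sigma))
        sd_f = np.sqrt(np.diag(self.Phi))
        L = self.Lambda * sd_f[None, :] / sd_y[:, None]
        return pd.DataFrame(L, index=self.spec.indicators, columns=self.spec.factors)

    def loadings_table(self) -> pd.DataFrame:
        """Standardized loadings, zero-pattern cells left missing."""
        L = self.std_loadings.copy()
        for i in self.spec.indicators:
            for f in self.spec.factors:
                if (i, f) not in self.spec.loadings:
                    L.loc[i, f] = np.nan
        return L


def _sigma_of(spec: FactorModelSpec, params: np.ndarray) -> np.ndarray:
    Lam, Phi, Theta, K = spec.build(params)
    LK = Lam @ K
    return Lam @ Phi @ Lam.T + LK + LK.T + Theta


def fit_factor_model(
    panel: pd.DataFrame,
    spec: FactorModelSpec,
    n_starts: int = 1,
    seed: int = 0,
    max_iter: int = 2000,
) -> FactorFit:
    """Full-information ML fit of ``spec`` to a (standardized) indicator panel.

    Persons with every indicator missing contribute nothing to the
    likelihood but are retained for scoring.  Raises
    :class:`ConvergenceError` after all starts fail; a Heywood case
    (negative residual variance at the solution) is flagged with a
    warning, never silently.
    """
    X = panel[list(spec.indicators)].to_numpy(dtype=float)
    n = int((~np.isnan(X)).any(axis=1).sum())
    if n < spec.n_free_sigma:
        raise ValueError("fewer persons than free parameters")
    patterns = _pattern_stats(X)
    complete = all(len(obs) == X.shape[1] for obs, *_ in patterns)

    ll_sat, mu_sat, Sigma_sat = saturated_loglik(X)
    ll_base, _ = independence_loglik(X)

    p = X.shape[1]
    mu_free = not complete

    def unpack(theta):
        if mu_free:
            return theta[:p], theta[p:]
        return mu_sat, theta

    def negloglik(theta):
        mu, sig_params = unpack(theta)
        Sigma = _sigma_of(spec, sig_params)
        w = np.linalg.eigvalsh(Sigma)[0]
        if w < 1e-8:
            return 1e8 * (1e-8 - w) + 1e6
        ll = _fiml_loglik(mu, Sigma, patterns)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, n_starts)):
        sig0 = spec.start_values()
        if s > 0:
            sig0 = sig0 + 0.2 * rng.standard_normal(sig0.shape)
        theta0 = np.concatenate([mu_sat, sig0]) if mu_free else sig0
        res = optimize.minimize(
            negloglik, theta0, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("factor model failed to converge",
                               best_loglik=-best.fun if best else np.nan)
    converged = bool(best.success or best.fun < 1e6)
    if not converged:
        raise ConvergenceError(
            f"factor model did not converge: {best.message}", best_loglik=-best.fun)

    mu_hat, sig_hat = unpack(best.x)
    Lam, Phi, Theta, K = spec.build(sig_hat)
    # sign convention: dominant loading of each factor positive
    for j in range(Lam.shape[1]):
        col = Lam[:, j]
        if len(col[np.abs(col) > 0]) and col[np.argmax(np.abs(col))] < 0:
            Lam[:, j] *= -1
            K[j, :] *= -1
            Phi[j, :] *= -1
            Phi[:, j] *= -1  # diagonal flips twice, staying positive
    heywood = bool((np.diag(Theta) < 0).any())
    if heywood:
        warnings.warn("Heywood case: negative residual variance at solution",
                      stacklevel=2)
    LK = Lam @ K
    Sigma = Lam @ Phi @ Lam.T + LK + LK.T + Theta
    return FactorFit(
        spec=spec, mu=np.asarray(mu_hat), Lambda=Lam, Phi=Phi, Theta=Theta, K=K,
        Sigma=Sigma, loglik=-best.fun, loglik_saturated=ll_sat,
        loglik_baseline=ll_base, df_baseline=p * (p + 1) // 2 - p, n=n,
        converged=converged, heywood=heywood, sample_cov=Sigma_sat)


def fit_bifactor_s1(panel: pd.DataFrame, **kwargs) -> FactorFit:
    """Fit the bifactor S-1 model (convenience wrapper)."""
    return fit_factor_model(panel, bifactor_spec(), **kwargs)


# ---------------------------------------------------------------------------
# Fit indices

def indices_from_chi2(chi2_m: float, df_m: int, chi2_b: float, df_b: int,
                      n: int) -> tuple[float, float]:
    """CFI and RMSEA from model and baseline chi-square statistics.

    CFI = 1 - max(chi2_M - df_M, 0) / max(chi2_B - df_B, chi2_M - df_M, 0);
    RMSEA = sqrt(max(chi2_M - df_M, 0) / (df_M * n)).
    """
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    if df_m == 0:
        if chi2_m > 1e-8:
            raise ZeroDivisionError("RMSEA undefined: df = 0 with chi2 > 0")
        rmsea = 0.0
    else:
        rmsea = float(np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * n)))
    return float(cfi), rmsea


def fit_indices(fit: FactorFit) -> dict[str, float]:
    """CFI, RMSEA and SRMR from the model and independence-baseline fits."""
    chi2_m, df_m = fit.chi2, fit.df
    cfi, rmsea = indices_from_chi2(chi2_m, df_m, fit.chi2_baseline,
                                   fit.df_baseline, fit.n)
    S, Sig = fit.sample_cov, fit.Sigma
    sd = np.sqrt(np.diag(S))
    resid = (S - Sig) / np.outer(sd, sd)
    iu = np.triu_indices_from(resid)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return {"cfi": float(cfi), "rmsea": rmsea, "srmr": srmr,
            "chi2": float(chi2_m), "df": df_m}


# ---------------------------------------------------------------------------
# Factor scores

def factor_scores(fit: FactorFit, panel: pd.DataFrame) -> pd.DataFrame:
    """Regression-method (posterior mean) factor scores per person.

    Computed per missingness pattern from the observed indicator subset;
    persons with all indicators missing get missing scores but keep their
    row.
    """
    X = panel[list(fit.spec.indicators)].to_numpy(dtype=float)
    q = len(fit.spec.factors)
    Cfy = fit.Phi @ fit.Lambda.T + fit.K  # Cov(factors, indicators)
    out = np.full((X.shape[0], q), np.nan)
    isobs = ~np.isnan(X)
    for key in {row.tobytes() for row in isobs}:
        obs = np.frombuffer(key, dtype=bool)
        if not obs.any():
            continue
        rows = np.flatnonzero((isobs == obs).all(axis=1))
        oi = np.flatnonzero(obs)
        A = Cfy[:, oi] @ np.linalg.inv(fit.Sigma[np.ix_(oi, oi)])
        out[rows] = (X[np.ix_(rows, oi)] - fit.mu[oi]) @ A.T
    cols = {"g": "g", "s_int": "s_int", "s_ext": "s_ext",
            "int": "s_int_corr", "ext": "s_ext_corr", "dys": "dys"}
    names = [cols.get(f, f) for f in fit.spec.factors]
    return pd.DataFrame(out, index=panel.index, columns=names)
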