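"""Bayesian mixed-effects location-scale model (MELSM) for nightly sleep.

For person ``i``, outcome ``s`` (sleep duration, bedtime, waketime) and
observed night ``t``::

    y_sit = alpha_si + gamma_night_s * night_it + gamma_weekend_s * weekend_it
            + eps_sit,        eps_sit ~ Normal(0, exp(omega_si))

The person-level intercepts ``alpha_i`` and log residual variances
``omega_i`` (2S latent outcomes for S observed outcomes) are jointly
multivariate normal with mean ``B x_i`` — a linear regression on
psychopathology factor scores and demographic covariates — and residual
covariance ``Psi``.  Night-to-night variability is therefore modeled as a
person-specific residual variance, net of the linear night trend and the
weekend shift.

Estimation is MCMC: conjugate Gibbs updates for ``alpha``, the
within-level fixed effects, ``B`` and ``Psi`` (inverse-Wishart), and an
adaptive Metropolis-within-Gibbs step for each log-variance ``omega``
(whose full conditional is non-conjugate).  Two chains from dispersed
starts are run by default; convergence is monitored through the
Gelman-Rubin potential scale reduction (PSR) of every model-level
parameter, and the convergence protocol re-runs with doubled iterations
once PSR falls under the threshold.  Persons with no observed nights are
retained and contribute through the between-level model alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sleep_records import SLEEP_METRICS, NightlySeries, nights_to_frame

OUTCOME_NAMES = {"duration_min": "duration", "bedtime_min": "bedtime",
                 "waketime_min": "waketime"}


class McmcError(RuntimeError):
    """Convergence failure; carries the names of the worst parameters."""

    def __init__(self, message: str, worst: list[str] | None = None):
        super().__init__(message)
        self.worst = worst or []


# ---------------------------------------------------------------------------
# Potential scale reduction

def psr(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction for one parameter.

    ``chains`` is (n_chains, L) of retained draws.  PSR =
    sqrt(((L-1)/L * W + B/L) / W) with W the mean within-chain variance
    and B = L * variance of the chain means.  Identical constant chains
    return 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal retained length >= 2")
    L = chains.shape[1]
    W = chains.var(axis=1, ddof=1).mean()
    Bv = L * chains.mean(axis=1).var(ddof=1)
    if W <= 0.0:
        return 1.0 if Bv <= 0.0 else math.inf
    return float(np.sqrt(((L - 1) / L * W + Bv / L) / W))


# ---------------------------------------------------------------------------
# Model specification and data container

@dataclass
class MelsmSpec:
    """Model layout: outcomes, priors, convergence threshold."""

    outcomes: tuple[str, ...] = SLEEP_METRICS
    coef_prior_var: float = 1e6
    psi_prior_scale: float = 1.0      # identity scale multiplier
    psi_prior_df_extra: float = 1.0   # df = dimension + extra
    psr_threshold: float = 1.05


@dataclass
class McmcConfig:
    n_chains: int = 2
    n_iter: int = 2000        # total per chain; first half discarded
    seed: int = 0
    max_iter: int = 64000     # cap for the convergence protocol


@dataclass
class MelsmData:
    """Padded per-person arrays for the sampler."""

    Y: np.ndarray         # (N, T, S), NaN = missing
    night: np.ndarray     # (N, T)
    weekend: np.ndarray   # (N, T)
    X: np.ndarray         # (N, P) between-level design, column 0 = intercept
    person_ids: list[str]
    outcome_labels: tuple[str, ...]
    predictor_labels: tuple[str, ...]

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.Y)


def build_design(
    series: list[NightlySeries],
    covariates: pd.DataFrame,
    outcomes: tuple[str, ...] = SLEEP_METRICS,
) -> MelsmData:
    """Assemble padded arrays from nightly series plus a person-level table.

    ``covariates`` must be indexed by person_id and contain every
    predictor column (factor scores and demographics); an intercept is
    prepended.  Rows of ``covariates`` and ``series`` are matched by id.
    """
    ids = [s.person_id for s in series]
    cov = covariates.loc[ids]
    T = max((len(s.records) for s in series), default=0)
    T = max(T, 1)
    N, S = len(series), len(outcomes)
    Y = np.full((N, T, S), np.nan)
    night = np.zeros((N, T))
    weekend = np.zeros((N, T))
    for i, s in enumerate(series):
        df = nights_to_frame([s])
        for t in range(len(df)):
            night[i, t] = df["night_index"].iloc[t]
            weekend[i, t] = df["weekend"].iloc[t]
            for j, m in enumerate(outcomes):
                Y[i, t, j] = df[m].iloc[t]
    # Center the within-level predictors at their pooled observed means.
    # A global constant shift only re-bases the person intercepts (alpha
    # then refers to a night at the protocol midpoint with the average
    # weekend share); every slope, Psi and gamma is unchanged, while the
    # posterior correlation between intercepts and slopes — which cripples
    # one-at-a-time Gibbs mixing — largely disappears.
    anyobs = ~np.isnan(Y).all(axis=2)
    if anyobs.any():
        night = night - night[anyobs].mean()
        weekend = weekend - weekend[anyobs].mean()
    X = np.column_stack([np.ones(N), cov.to_numpy(dtype=float)])
    labels = tuple(OUTCOME_NAMES.get(m, m) for m in outcomes)
    return MelsmData(Y=Y, night=night, weekend=weekend, X=X, person_ids=ids,
                     outcome_labels=labels,
                     predictor_labels=("intercept",) + tuple(cov.columns))


def parameter_labels(data: MelsmData) -> list[str]:
    """Stored-parameter labels: B entries, within-level slopes, Psi."""
    outs = [f"alpha_{o}" for o in data.outcome_labels] + \
           [f"omega_{o}" for o in data.outcome_labels]
    labels = [f"{o}~{p}" for o in outs for p in data.predictor_labels]
    for o in data.outcome_labels:
        labels.append(f"gamma_night[{o}]")
        labels.append(f"gamma_weekend[{o}]")
    D = len(outs)
    for i in range(D):
        for j in range(i, D):
            labels.append(f"psi[{outs[i]},{outs[j]}]")
    return labels


# ---------------------------------------------------------------------------
# The sampler

def _init_state(data: MelsmData, rng: np.random.Generator, disperse: float):
    M = data.mask
    N, T, S = data.Y.shape
    import warnings as _w
    with np.errstate(invalid="ignore"), _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        pm = np.nanmean(data.Y, axis=1)           # (N, S)
        pv = np.nanvar(data.Y, axis=1)
        grand_m = np.nanmean(pm, axis=0)
        grand_v = np.nanmean(np.where(pv > 0, pv, np.nan), axis=0)
    grand_m = np.where(np.isfinite(grand_m), grand_m, 0.0)
    grand_v = np.where(np.isfinite(grand_v) & (grand_v > 0), grand_v, 1.0)
    alpha = np.where(np.isnan(pm), grand_m, pm)
    lv = np.log(np.where((pv > 0) & M.sum(1).astype(bool), pv, grand_v))
    omega = np.where(np.isfinite(lv), lv, np.log(grand_v))
    alpha = alpha + disperse * np.sqrt(grand_v) * rng.standard_normal((N, S)) * 0.3
    omega = omega + disperse * rng.standard_normal((N, S)) * 0.3
    gamma = disperse * 0.1 * rng.standard_normal((S, 2))
    D, P = 2 * S, data.X.shape[1]
    B = np.zeros((D, P))
    B[:S, 0] = grand_m
    B[S:, 0] = np.log(grand_v)
    Psi = np.diag(np.concatenate([np.maximum(grand_v / 4.0, 1.0),
                                  np.full(S, 0.5)]))
    return alpha, omega, gamma, B, Psi


def _run_chain(data: MelsmData, spec: MelsmSpec, n_iter: int,
               rng: np.random.Generator, disperse: float) -> np.ndarray:
    M = data.mask
    Mf = M.astype(float)
    N, T, S = data.Y.shape
    D, P = 2 * S, data.X.shape[1]
    X = data.X
    XtX = X.T @ X
    Y0 = np.nan_to_num(data.Y)
    n_si = M.sum(axis=1)                                   # (N, S)
    C = np.stack([data.night, data.weekend], axis=2)       # (N, T, 2)

    alpha, omega, gamma, B, Psi = _init_state(data, rng, disperse)
    nu0 = D + spec.psi_prior_df_extra
    S0 = spec.psi_prior_scale * np.eye(D)
    prior_prec = 1.0 / spec.coef_prior_var
    step = np.full(S, 0.4)                                  # MH step sizes
    step_B = np.full((S, P), 0.1)                           # NC B_omega steps
    burn = n_iter // 2

    n_store = D * P + 2 * S + D * (D + 1) // 2
    draws = np.empty((n_iter, n_store))
    eyeS = np.eye(S)
    iu = np.triu_indices(D)

    for it in range(n_iter):
        # --- within-level fixed-effect means, residuals -------------------
        fixed = C[..., 0:1] * gamma[:, 0] + C[..., 1:2] * gamma[:, 1]  # (N,T,S)
        r = np.where(M, data.Y - fixed, 0.0)
        sum_r = r.sum(axis=1)                              # (N, S)

        # --- alpha | rest (blocked MVN per person) ------------------------
        mu_b = X @ B.T                                     # (N, D)
        Paa, Pao, Poo = Psi[:S, :S], Psi[:S, S:], Psi[S:, S:]
        Poo_inv = np.linalg.inv(Poo)
        W = Pao @ Poo_inv
        Vc = Paa - W @ Pao.T
        Vc_inv = np.linalg.inv(Vc)
        mc = mu_b[:, :S] + (omega - mu_b[:, S:]) @ W.T     # (N, S)
        d = n_si * np.exp(-omega)                          # (N, S)
        prec = Vc_inv[None, :, :] + d[:, :, None] * eyeS[None, :, :]
        V = np.linalg.inv(prec)
        rhs = mc @ Vc_inv.T + np.exp(-omega) * sum_r
        m = np.einsum("nij,nj->ni", V, rhs)
        Lc = np.linalg.cholesky(V)
        alpha = m + np.einsum("nij,nj->ni", Lc, rng.standard_normal((N, S)))

        # --- omega | rest (adaptive MH per outcome) -----------------------
        dev = np.where(M, data.Y - fixed - alpha[:, None, :], 0.0)
        SSR = (dev * dev).sum(axis=1)                      # (N, S)
        b_cur = np.concatenate([alpha, omega], axis=1)     # (N, D)
        Q = np.linalg.inv(Psi)
        for s in range(S):
            j = S + s
            v = 1.0 / Q[j, j]
            resid_b = b_cur - mu_b
            other = resid_b @ Q[j] - Q[j, j] * resid_b[:, j]
            cm = mu_b[:, j] - v * other                    # conditional mean
            w_cur = omega[:, s]
            w_new = w_cur + step[s] * rng.standard_normal(N)

            def logt(w):
                return (-0.5 * n_si[:, s] * w - 0.5 * SSR[:, s] * np.exp(-w)
                        - 0.5 * (w - cm) ** 2 / v)

            acc = np.log(rng.random(N)) < logt(w_new) - logt(w_cur)
            omega[:, s] = np.where(acc, w_new, w_cur)
            b_cur[:, j] = omega[:, s]
            if it < burn:  # Robbins-Monro scale adaptation toward 0.44
                step[s] *= math.exp((acc.mean() - 0.44) / math.sqrt(1 + it / 10))

        # --- gamma | rest (weighted least squares per outcome) ------------
        wobs = Mf * np.exp(-omega)[:, None, :]             # (N, T, S)
        resp = Y0 - alpha[:, None, :]
        for s in range(S):
            w = wobs[:, :, s]
            cs = C                                          # (N, T, 2)
            XtXw = np.einsum("nt,nti,ntj->ij", w, cs, cs)
            Xtyw = np.einsum("nt,nti,nt->i", w, cs, np.where(M[:, :, s], resp[:, :, s], 0.0))
            A = XtXw + prior_prec * np.eye(2)
            mean = np.linalg.solve(A, Xtyw)
            Lg = np.linalg.cholesky(np.linalg.inv(A))
            gamma[s] = mean + Lg @ rng.standard_normal(2)

        # --- B | rest (matrix-normal regression) --------------------------
        b_cur = np.concatenate([alpha, omega], axis=1)
        Psi_inv = np.linalg.inv(Psi)
        Prec = np.kron(XtX, Psi_inv) + prior_prec * np.eye(D * P)
        lin = (Psi_inv @ (b_cur.T @ X)).flatten(order="F")
        Lp = np.linalg.cholesky(Prec)
        mean = np.linalg.solve(Prec, lin)
        z = rng.standard_normal(D * P)
        bvec = mean + np.linalg.solve(Lp.T, z)
        B = bvec.reshape((P, D)).T                         # undo column-major

        # --- interweaving (ASIS) redraw of the alpha-block rows of B ------
        # Holding the non-centered residuals u = alpha - B_a x fixed, alpha
        # is linear in B_a, so the data likelihood gives a second conjugate
        # Gaussian update.  Alternating the centered and non-centered
        # updates breaks the strong alpha/B/Psi autocorrelation that the
        # one-at-a-time Gibbs scan otherwise suffers at low ICC.
        fixed = C[..., 0:1] * gamma[:, 0] + C[..., 1:2] * gamma[:, 1]
        r = np.where(M, data.Y - fixed, 0.0)
        sum_r = r.sum(axis=1)
        u_a = alpha - X @ B[:S].T
        e_om = np.exp(-omega)
        for s in range(S):
            w_i = n_si[:, s] * e_om[:, s]
            prec = (X * w_i[:, None]).T @ X + prior_prec * np.eye(P)
            lin = X.T @ (e_om[:, s] * (sum_r[:, s] - n_si[:, s] * u_a[:, s]))
            La = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, lin)
            B[s] = mean + np.linalg.solve(La.T, rng.standard_normal(P))
        alpha = X @ B[:S].T + u_a

        # --- interweaving redraw of the omega-block rows of B -------------
        # Same ancillary parameterization for the log-variance equations:
        # with u_o = omega - B_o x fixed, each coefficient shifts every
        # person's omega, and the data likelihood is exp-linear in it, so
        # a scalar Metropolis step per coefficient mixes the scale
        # regressions far faster than the centered update alone.
        dev = np.where(M, data.Y - fixed - alpha[:, None, :], 0.0)
        SSR = (dev * dev).sum(axis=1)
        for s in range(S):
            for p_i in range(P):
                delta = step_B[s, p_i] * rng.standard_normal()
                d_om = delta * X[:, p_i]
                om_old = omega[:, s]
                om_new = om_old + d_om
                b_old, b_new = B[S + s, p_i], B[S + s, p_i] + delta
                dll = (-0.5 * np.sum(n_si[:, s] * d_om)
                       - 0.5 * np.sum(SSR[:, s] * (np.exp(-om_new)
                                                   - np.exp(-om_old)))
                       - 0.5 * prior_prec * (b_new ** 2 - b_old ** 2))
                acc_b = np.log(rng.random()) < dll
                if acc_b:
                    B[S + s, p_i] = b_new
                    omega[:, s] = om_new
                if it < burn:
                    step_B[s, p_i] *= math.exp(
                        ((1.0 if acc_b else 0.0) - 0.44)
                        / math.sqrt(1 + it / 10))
        b_cur = np.concatenate([alpha, omega], axis=1)

        # --- Psi | rest (inverse-Wishart) ---------------------------------
        E = b_cur - X @ B.T
        scale = S0 + E.T @ E
        Psi = stats.invwishart.rvs(df=nu0 + N, scale=scale, random_state=rng)
        Psi = (Psi + Psi.T) / 2.0

        draws[it] = np.concatenate(
            [B.flatten(), gamma.flatten(), Psi[iu]])
    return draws


@dataclass
class MelsmPosterior:
    """Retained draws (per chain) and posterior summaries."""

    labels: list[str]
    draws: np.ndarray          # (n_chains, L, n_params), post burn-in
    data: MelsmData
    spec: MelsmSpec
    config: McmcConfig

    def pooled(self, label: str) -> np.ndarray:
        j = self.labels.index(label)
        return self.draws[:, :, j].ravel()

    def psr_vector(self) -> pd.Series:
        vals = [psr(self.draws[:, :, j]) for j in range(len(self.labels))]
        return pd.Series(vals, index=self.labels)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        flat = self.draws.reshape(-1, len(self.labels))
        lo = np.quantile(flat, lo_q, axis=0)
        hi = np.quantile(flat, hi_q, axis=0)
        out = pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                "median": np.median(flat, axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "ci_lower": lo,
                "ci_upper": hi,
                "significant": (lo > 0) | (hi < 0),
                "psr": self.psr_vector().values,
            },
            index=self.labels,
        )
        return out


def fit_melsm(
    series: list[NightlySeries],
    covariates: pd.DataFrame,
    spec: MelsmSpec | None = None,
    mcmc: McmcConfig | None = None,
) -> MelsmPosterior:
    """Fit the location-scale model by MCMC (chains from dispersed starts).

    ``covariates`` holds factor scores and demographic predictors indexed
    by person_id.  Requires at least 2 persons with >= 2 observed nights.
    """
    spec = spec or MelsmSpec()
    mcmc = mcmc or McmcConfig()
    data = build_design(series, covariates, spec.outcomes)
    return _fit_melsm_data(data, spec, mcmc)


def _fit_melsm_data(data: MelsmData, spec: MelsmSpec,
                    mcmc: McmcConfig) -> MelsmPosterior:
    n_rich = int((data.mask.any(axis=2).sum(axis=1) >= 2).sum())
    if n_rich < 2:
        raise ValueError("need >= 2 persons with >= 2 observed nights")
    labels = parameter_labels(data)
    ss = np.random.SeedSequence(mcmc.seed)
    child = ss.spawn(mcmc.n_chains)
    kept = []
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(child[c])
        disperse = float(c)  # chain 0 at data-based start, others dispersed
        draws = _run_chain(data, spec, mcmc.n_iter, rng, disperse)
        kept.append(draws[mcmc.n_iter // 2:])
    return MelsmPosterior(labels=labels, draws=np.stack(kept), data=data,
                          spec=spec, config=mcmc)


def converge_and_double(fit, mcmc: McmcConfig, threshold: float = 1.05):
    """Run ``fit(n_iter)`` until max PSR < threshold, then re-run doubled.

    ``fit`` maps an iteration count to a :class:`MelsmPosterior`.  Returns
    ``(posterior, report)`` where the posterior comes from the doubled run
    and the report holds both PSR snapshots.  Raises :class:`McmcError`
    naming the worst parameters if the cap is reached.
    """
    n_iter = mcmc.n_iter
    while True:
        post = fit(n_iter)
        p1 = post.psr_vector()
        if float(p1.max()) < threshold:
            break
        n_iter *= 2
        if n_iter > mcmc.max_iter:
            worst = list(p1.sort_values(ascending=False).head(5).index)
            raise McmcError(
                f"PSR did not reach {threshold} at {mcmc.max_iter} iterations; "
                f"worst parameters: {worst}", worst=worst)
    post2 = fit(2 * n_iter)
    p2 = post2.psr_vector()
    report = {"iters_converged": n_iter, "iters_final": 2 * n_iter,
              "psr_first": p1, "psr_doubled": p2}
    return post2, report


def credibility_intervals(
    posterior: MelsmPosterior, level: float = 0.95
) -> pd.DataFrame:
    """Equal-tailed quantile intervals; significant = zero excluded."""
    flat = posterior.draws.reshape(-1, len(posterior.labels))
    if flat.shape[0] < 100:
        raise ValueError("need >= 100 pooled retained draws")
    lo = np.quantile(flat, (1 - level) / 2, axis=0)
    hi = np.quantile(flat, 1 - (1 - level) / 2, axis=0)
    return pd.DataFrame(
        {"lower": lo, "upper": hi, "significant": (lo > 0) | (hi < 0)},
        index=posterior.labels)


def standardize_effects(
    posterior: MelsmPosterior,
    predictors: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Standardized coefficients beta = b * SD(x) / SD(y), per draw.

    SD(y) for a between-level outcome is the model-implied total SD at
    that draw: sqrt(B_row' Cov(X) B_row + Psi_jj), with Cov(X) the sample
    covariance of the predictors.  Draws with non-positive outcome
    variance are dropped (count reported in the ``n_dropped`` column).
    """
    data = posterior.data
    S = len(data.outcome_labels)
    outs = [f"alpha_{o}" for o in data.outcome_labels] + \
           [f"omega_{o}" for o in data.outcome_labels]
    preds = predictors or tuple(p for p in data.predictor_labels
                                if p != "intercept")
    Xc = data.X - data.X.mean(axis=0)
    covX = Xc.T @ Xc / (len(data.X) - 1)        # intercept row/col ~ 0
    sd_x = {p: float(np.std(data.X[:, data.predictor_labels.index(p)], ddof=1))
            for p in preds}
    flat = posterior.draws.reshape(-1, len(posterior.labels))
    rows = []
    for j, out in enumerate(outs):
        bcols = [posterior.labels.index(f"{out}~{p}")
                 for p in data.predictor_labels]
        Brow = flat[:, bcols]                    # (n_draws, P)
        psi_j = flat[:, posterior.labels.index(f"psi[{out},{out}]")]
        var_y = np.einsum("np,pq,nq->n", Brow, covX, Brow) + psi_j
        ok = var_y > 0
        sd_y = np.sqrt(var_y[ok])
        for p in preds:
            b = flat[ok, posterior.labels.index(f"{out}~{p}")]
            beta = b * sd_x[p] / sd_y
            lo, hi = np.quantile(beta, [0.025, 0.975])
            rows.append({"outcome": out, "predictor": p,
                         "beta_median": float(np.median(beta)),
                         "beta_lower": float(lo), "beta_upper": float(hi),
                         "n_dropped": int((~ok).sum())})
    return pd.DataFrame(rows)


def icc(nights: pd.DataFrame | list[NightlySeries],
        outcome: str = "duration_min") -> float:
    """Intraclass correlation from an unconditional random-intercept model.

    Fraction of total variance at the between-person level, estimated by
    ML (statsmodels MixedLM).  Requires >= 2 persons with >= 2 nights of
    the outcome.
    """
    import statsmodels.api as sm

    if not isinstance(nights, pd.DataFrame):
        nights = nights_to_frame(nights)
    df = nights[["person_id", outcome]].dropna()
    counts = df.groupby("person_id").size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 persons with >= 2 observed nights")
    model = sm.MixedLM(df[outcome].to_numpy(),
                       np.ones((len(df), 1)),
                       groups=df["person_id"].to_numpy())
    fit = model.fit(reml=False)
    v_between = float(np.asarray(fit.cov_re)[0, 0])
    v_within = float(fit.scale)
    return v_between / (v_between + v_within)
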