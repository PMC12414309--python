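"""Independent covariance-based ML oracle for the bifactor model.

Used only by tests: fits the same structure as the package's FIML fitter
but through a different route — the Wishart ML discrepancy
F(theta) = log|Sigma| + tr(S Sigma^-1) - log|S| - p computed from the
complete-data sample covariance, with its own hard-coded parameter layout
and a different optimizer.  At the optimum (complete data, saturated
means) this is the same estimator, so agreement is a genuine cross-check
of the package's likelihood and optimization code.
"""

import numpy as np
from scipy import optimize

# parameter layout: 8 general loadings, 3 internalizing, 4 externalizing,
# 8 residual variances, theta(hyp,at), theta(wd,hyp), kappa(ext, ad)
N_PARAMS = 26
_INT = [0, 1, 2]          # ad, wd, som
_EXT = [3, 4, 5, 6]       # odd, cd, hyp, at
_HYP, _AT, _WD, _AD = 5, 6, 1, 0


def implied_cov(theta):
    lg = theta[:8]
    li = theta[8:11]
    le = theta[11:15]
    tv = theta[15:23]
    c_hyp_at, c_wd_hyp, kappa = theta[23], theta[24], theta[25]
    Lam = np.zeros((8, 3))
    Lam[:, 0] = lg
    Lam[_INT, 1] = li
    Lam[_EXT, 2] = le
    Th = np.diag(tv)
    Th[_HYP, _AT] = Th[_AT, _HYP] = c_hyp_at
    Th[_WD, _HYP] = Th[_HYP, _WD] = c_wd_hyp
    K = np.zeros((3, 8))
    K[2, _AD] = kappa
    LK = Lam @ K
    return Lam @ Lam.T + LK + LK.T + Th


def fit_ml_discrepancy(S, n, n_starts=5, seed=0):
    """Minimize the Wishart discrepancy; returns (theta, loglik, F)."""
    p = S.shape[0]
    sign, logdet_s = np.linalg.slogdet(S)

    def F(theta):
        Sig = implied_cov(theta)
        w = np.linalg.eigvalsh(Sig)[0]
        if w < 1e-8:
            return 1e4 + 1e6 * (1e-8 - w)
        s2, logdet = np.linalg.slogdet(Sig)
        return logdet + np.trace(S @ np.linalg.inv(Sig)) - logdet_s - p

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        x0 = np.concatenate([np.full(15, 0.5), np.full(8, 0.5), np.zeros(3)])
        if s > 0:
            x0 = x0 + 0.15 * rng.standard_normal(N_PARAMS)
        res = optimize.minimize(F, x0, method="BFGS",
                                options={"maxiter": 4000, "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    # flip signs to the positive-dominant convention per factor
    if theta[:8][np.argmax(np.abs(theta[:8]))] < 0:
        theta[:8] *= -1
    if theta[8:11][np.argmax(np.abs(theta[8:11]))] < 0:
        theta[8:11] *= -1
    if theta[11:15][np.argmax(np.abs(theta[11:15]))] < 0:
        theta[11:15] *= -1
        theta[25] *= -1
    loglik = -0.5 * n * (p * np.log(2 * np.pi) + best.fun + logdet_s + p)
    return theta, float(loglik), float(best.fun)
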