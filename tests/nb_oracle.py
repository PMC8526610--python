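"""Independent NB2 fitting oracle for cross-checking the main implementation.

Deliberately a different route: iteratively reweighted least squares for
the coefficients at fixed theta, alternated with 1-D profile maximisation
of theta, in the style of classic GLM software.  Shares no code with
railbat.count_models.
"""

import numpy as np
from scipy import optimize, special


def _irls_beta(X, y, theta, beta0, tol=1e-12, maxit=200):
    beta = beta0.copy()
    for _ in range(maxit):
        eta = X @ beta
        mu = np.exp(eta)
        w = mu * theta / (theta + mu)
        z = eta + (y - mu) / mu
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


def _profile_ltheta(X, y, beta):
    mu = np.exp(X @ beta)

    def negll(ltheta):
        th = np.exp(ltheta)
        return -np.sum(special.gammaln(y + th) - special.gammaln(th)
                       - special.gammaln(y + 1)
                       + th * np.log(th / (th + mu))
                       + y * np.log(mu / (th + mu)))

    res = optimize.minimize_scalar(negll, bounds=(-8, 16), method="bounded",
                                   options={"xatol": 1e-12})
    return res.x


def fit_nb_irls(X, y, maxit=100, tol=1e-11):
    """Joint MLE of (beta, theta) by alternating IRLS and profile steps."""
    # start from a log-linear least squares fit
    beta = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)[0]
    ltheta = 0.0
    for _ in range(maxit):
        beta_new = _irls_beta(X, y, np.exp(ltheta), beta)
        ltheta_new = _profile_ltheta(X, y, beta_new)
        done = (np.max(np.abs(beta_new - beta)) < tol
                and abs(ltheta_new - ltheta) < 1e-9)
        beta, ltheta = beta_new, ltheta_new
        if done:
            break
    theta = np.exp(ltheta)
    mu = np.exp(X @ beta)
    ll = float(np.sum(special.gammaln(y + theta) - special.gammaln(theta)
                      - special.gammaln(y + 1)
                      + theta * np.log(theta / (theta + mu))
                      + y * np.log(mu / (theta + mu))))
    return beta, theta, ll
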