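"""Three-variable path model: baseline cognition -> cluster -> outcome.

Estimates the mediation model

    M = a*X + e1
    Y = b*M + c'*X + e2

by maximum likelihood under trivariate normality.  With the
full-information missing-data policy, partially observed cases contribute
the marginal likelihood of their observed subset instead of being
dropped, which is how SEM software handles incomplete questionnaire and
task batteries.  All variables are z-scored internally so the reported
paths are standardized coefficients; the mediator (cluster label) enters
as an ordered numeric 1 < 2 < 3.

Standard errors come from the observed information matrix (numerical
Hessian of the log-likelihood at the optimum); the model is compared to
an independence baseline (means and variances of the observed variables
only) with a likelihood-ratio chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "PathEstimate",
    "MediationFit",
    "fit_mediation",
    "indirect_effect_test",
    "dummy_mediator_sensitivity",
]

_EPS = 1e-10


@dataclass
class PathEstimate:
    coef: float
    se: float

    @property
    def z(self) -> float:
        return self.coef / self.se if self.se > 0 else np.inf * np.sign(self.coef)

    @property
    def p(self) -> float:
        return float(2 * sps.norm.sf(abs(self.z)))

    def to_dict(self) -> dict:
        return {"coef": self.coef, "se": self.se, "z": self.z, "p": self.p}


@dataclass
class MediationFit:
    a: PathEstimate          # X -> M
    b: PathEstimate          # M -> Y
    c_prime: PathEstimate    # direct X -> Y
    indirect: PathEstimate   # a*b with delta-method SE
    chi2_vs_baseline: tuple[float, int, float]
    n_used: int
    loglik: float
    converged: bool
    missing_policy: str
    _data: np.ndarray | None = None  # standardized (n, 3) with NaN, for bootstrap

    def to_dict(self) -> dict:
        stat, df, p = self.chi2_vs_baseline
        return {
            "a": self.a.to_dict(),
            "b": self.b.to_dict(),
            "c_prime": self.c_prime.to_dict(),
            "indirect": self.indirect.to_dict(),
            "chi2_vs_baseline": {"stat": stat, "df": df, "p": p},
            "n_used": self.n_used,
            "loglik": self.loglik,
            "converged": self.converged,
            "missing_policy": self.missing_policy,
        }


def _implied_moments(theta: np.ndarray):
    mu_x, al1, al2, lvx, lv1, lv2, a, b, c = theta
    px, p1, p2 = np.exp(lvx), np.exp(lv1), np.exp(lv2)
    mu_m = al1 + a * mu_x
    mu_y = al2 + b * mu_m + c * mu_x
    sxx = px
    sxm = a * px
    smm = a * a * px + p1
    sxy = c * px + b * sxm
    smy = b * smm + c * sxm
    syy = b * b * smm + c * c * px + 2 * b * c * sxm + p2
    mu = np.array([mu_x, mu_m, mu_y])
    sigma = np.array([[sxx, sxm, sxy], [sxm, smm, smy], [sxy, smy, syy]])
    return mu, sigma


def _pattern_groups(data: np.ndarray):
    """Group case indices by missingness pattern (at least one observed)."""
    obs = ~np.isnan(data)
    groups: dict[tuple, np.ndarray] = {}
    keys = [tuple(row) for row in obs]
    for key in set(keys):
        if not any(key):
            continue
        idx = np.array([i for i, k in enumerate(keys) if k == key])
        groups[key] = idx
    return groups


def _fiml_loglik(theta: np.ndarray, groups, data: np.ndarray) -> float:
    mu, sigma = _implied_moments(theta)
    ll = 0.0
    for key, idx in groups.items():
        sel = np.flatnonzero(key)
        sub_mu = mu[sel]
        sub_sig = sigma[np.ix_(sel, sel)]
        rows = data[np.ix_(idx, sel)]
        try:
            chol = np.linalg.cholesky(sub_sig)
        except np.linalg.LinAlgError:
            return -np.inf
        dev = rows - sub_mu
        z = np.linalg.solve(chol, dev.T)
        logdet = 2 * np.log(np.diag(chol)).sum()
        ll += -0.5 * (
            rows.shape[0] * (len(sel) * np.log(2 * np.pi) + logdet)
            + np.sum(z * z)
        )
    return ll


def _baseline_loglik(data: np.ndarray) -> tuple[float, int]:
    """Independence model: per-variable ML mean and variance."""
    ll = 0.0
    n_par = 0
    for j in range(data.shape[1]):
        col = data[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        mu = col.mean()
        var = max(col.var(), _EPS)  # ML variance (ddof=0)
        ll += float(np.sum(sps.norm.logpdf(col, mu, np.sqrt(var))))
        n_par += 2
    return ll, n_par


def _num_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    p = x.size
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h
            ej[j] = h
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return H


def _standardize(col: np.ndarray) -> np.ndarray:
    obs = col[~np.isnan(col)]
    sd = obs.std(ddof=1)
    if obs.size < 2 or sd == 0.0:
        raise ValueError("zero variance in a mediation variable")
    return (col - obs.mean()) / sd


def fit_mediation(
    x,
    m,
    y,
    missing_policy: str = "fiml",
    min_cases: int = 10,
) -> MediationFit:
    """Fit the X -> M -> Y path model by (full-information) ML.

    Parameters
    ----------
    x, m, y : participant-keyed mappings/Series (or aligned arrays)
        Predictor, mediator (cluster label, ordered numeric) and outcome.
    missing_policy : {"fiml", "listwise"}
        "fiml" keeps partially observed cases; "listwise" drops them.

    Returns a :class:`MediationFit` with standardized paths a, b, c',
    the delta-method indirect effect, and a likelihood-ratio chi-square
    against the independence baseline model.
    """
    if missing_policy not in ("fiml", "listwise"):
        raise ValueError("missing_policy must be 'fiml' or 'listwise'")
    x = pd.Series(x, dtype=float)
    m = pd.Series(m, dtype=float)
    y = pd.Series(y, dtype=float)
    idx = x.index.union(m.index).union(y.index)
    data = np.column_stack(
        [x.reindex(idx).to_numpy(), m.reindex(idx).to_numpy(), y.reindex(idx).to_numpy()]
    )
    data = data[~np.isnan(data).all(axis=1)]
    if missing_policy == "listwise":
        data = data[~np.isnan(data).any(axis=1)]
    if data.shape[0] < min_cases:
        raise ValueError(f"need >= {min_cases} usable cases, have {data.shape[0]}")
    data = np.column_stack([_standardize(data[:, j]) for j in range(3)])

    groups = _pattern_groups(data)

    # moment-based start from pairwise covariances
    def _pair_cov(i, j):
        both = ~np.isnan(data[:, i]) & ~np.isnan(data[:, j])
        if both.sum() < 3:
            return 0.0
        return float(np.cov(data[both, i], data[both, j], ddof=0)[0, 1])

    a0 = _pair_cov(0, 1)
    resid = max(1.0 - a0 * a0, 0.1)
    sxy, smy = _pair_cov(0, 2), _pair_cov(1, 2)
    b0 = (smy - a0 * sxy) / resid
    c0 = sxy - b0 * a0
    theta0 = np.array(
        [0.0, 0.0, 0.0, 0.0, np.log(resid), np.log(0.5), a0, b0, c0]
    )

    nll = lambda th: -_fiml_loglik(th, groups, data)
    res = optimize.minimize(nll, theta0, method="BFGS", options={"maxiter": 500})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"mediation ML failed to converge: {res.message}")
    theta = res.x
    ll = -res.fun

    H = _num_hessian(nll, theta)
    try:
        cov = np.linalg.inv(H)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(theta.size, np.nan)
    a = PathEstimate(float(theta[6]), float(ses[6]))
    b = PathEstimate(float(theta[7]), float(ses[7]))
    c_prime = PathEstimate(float(theta[8]), float(ses[8]))
    ind_se = float(np.sqrt(a.coef**2 * b.se**2 + b.coef**2 * a.se**2))
    indirect = PathEstimate(a.coef * b.coef, ind_se)

    ll_base, base_par = _baseline_loglik(data)
    df = theta.size - base_par
    chi2 = max(2 * (ll - ll_base), 0.0)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else np.nan

    return MediationFit(
        a=a,
        b=b,
        c_prime=c_prime,
        indirect=indirect,
        chi2_vs_baseline=(float(chi2), int(df), p),
        n_used=int(data.shape[0]),
        loglik=float(ll),
        converged=bool(res.success or np.isfinite(res.fun)),
        missing_policy=missing_policy,
        _data=data,
    )


def indirect_effect_test(
    fit: MediationFit,
    method: str = "delta",
    n_boot: int = 1000,
    rng_seed: int = 0,
    level: float = 0.95,
):
    """Confidence interval for the indirect effect a*b.

    ``delta`` uses the first-order (Sobel) SE from the fit; ``bootstrap``
    resamples cases and refits, returning a percentile interval.
    """
    zcrit = sps.norm.ppf(0.5 + level / 2)
    if method == "delta":
        est, se = fit.indirect.coef, fit.indirect.se
        return est, (est - zcrit * se, est + zcrit * se)
    if method != "bootstrap":
        raise ValueError("method must be 'delta' or 'bootstrap'")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if fit._data is None:
        raise ValueError("bootstrap requires the fitted case-level data")
    data = fit._data
    rng = np.random.default_rng(rng_seed)
    estimates = []
    n = data.shape[0]
    for _ in range(n_boot):
        sample = data[rng.integers(0, n, size=n)]
        try:
            bf = fit_mediation(
                pd.Series(sample[:, 0]),
                pd.Series(sample[:, 1]),
                pd.Series(sample[:, 2]),
                missing_policy=fit.missing_policy,
            )
        except (ValueError, RuntimeError):
            continue
        estimates.append(bf.indirect.coef)
    lo, hi = np.percentile(estimates, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
    return fit.indirect.coef, (float(lo), float(hi))


def dummy_mediator_sensitivity(x, m, y) -> pd.DataFrame:
    """Sensitivity check: dummy-coded mediator, listwise OLS path model.

    The ordered-numeric treatment of the cluster mediator assumes equal
    spacing; this re-estimates both structural equations with the cluster
    entered as indicator variables (reference = cluster 1) on complete
    cases and reports the coefficient table.
    """
    import statsmodels.api as sm

    x = pd.Series(x, dtype=float)
    m = pd.Series(m)
    y = pd.Series(y, dtype=float)
    df = pd.DataFrame({"x": x, "m": m, "y": y}).dropna()
    if df.shape[0] < 10:
        raise ValueError("need >= 10 complete cases")
    df["x"] = (df["x"] - df["x"].mean()) / df["x"].std(ddof=1)
    df["y"] = (df["y"] - df["y"].mean()) / df["y"].std(ddof=1)
    dummies = pd.get_dummies(df["m"].astype(int), prefix="cluster", drop_first=True)
    dummies = dummies.astype(float)

    rows = []
    for col in dummies.columns:
        fit_m = sm.OLS(dummies[col], sm.add_constant(df[["x"]])).fit()
        rows.append(
            {
                "equation": f"{col} ~ x",
                "term": "x",
                "coef": fit_m.params["x"],
                "se": fit_m.bse["x"],
                "p": fit_m.pvalues["x"],
            }
        )
    X2 = sm.add_constant(pd.concat([dummies, df[["x"]]], axis=1))
    fit_y = sm.OLS(df["y"], X2).fit()
    for term in list(dummies.columns) + ["x"]:
        rows.append(
            {
                "equation": "y ~ clusters + x",
                "term": term,
                "coef": fit_y.params[term],
                "se": fit_y.bse[term],
                "p": fit_y.pvalues[term],
            }
        )
    return pd.DataFrame(rows)
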