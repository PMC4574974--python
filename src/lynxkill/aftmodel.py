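"""Right-censored accelerated failure time (AFT) regression of prey times.

The inter-kill (prey) time ``T`` of a lynx is modelled on the log scale,

    log T = x'beta + sigma * W,

with ``W`` a standard Gumbel-minimum variate (Weibull AFT) or standard
normal (log-normal AFT).  Right-censored rows (no subsequent kill accepted
as an event) contribute the survival term of the likelihood; events
contribute the density term.  Covariates are the categorical lynx status,
prey species, and season, with reference levels single adult female / red
deer / summer, so that a negative coefficient means a shorter time scale.

The fitter is a quasi-Newton maximizer on ``(beta, log sigma)`` with
analytic gradients; the covariance is the inverse observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

#: Reference levels fixing the sign convention of the coefficients.
DEFAULT_REFERENCES: dict[str, str] = {
    "status": "single_adult_female",
    "species": "red",
    "season": "summer",
}

DEFAULT_COVARIATES = ("status", "species", "season")


@dataclass
class AftSpec:
    """What to fit: which duration, which factors, which error family."""

    response: str = "prey_time"                  # prey_time | handling_time | searching_time
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    distribution: str = "weibull"                # weibull | lognormal
    references: dict[str, str] | None = None


def build_design(
    df: pd.DataFrame,
    covariates: tuple[str, ...],
    references: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix with an explicit intercept.

    Dummy columns are named ``{covariate}_{level}``; the reference level of
    each factor (from ``references``, else the alphabetically first level)
    is absorbed into the intercept.
    """
    references = {**DEFAULT_REFERENCES, **(references or {})}

    def factor_dummies(cov: str) -> list[tuple[str, np.ndarray]]:
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} not in data")
        values = df[cov].astype(str)
        levels = sorted(values.unique())
        ref = references.get(cov, levels[0])
        if ref in levels:
            levels.remove(ref)
        elif len(levels) > 1:
            levels = levels[1:]
        return [(f"{cov}_{lv}", (values == lv).to_numpy(float))
                for lv in levels]

    cols = [np.ones(len(df))]
    names = ["intercept"]
    for cov in covariates:
        if ":" in cov:  # interaction: products of the two factors' dummies
            left, right = cov.split(":", 1)
            for na, va in factor_dummies(left):
                for nb, vb in factor_dummies(right):
                    cols.append(va * vb)
                    names.append(f"{na}:{nb}")
        else:
            for name, col in factor_dummies(cov):
                cols.append(col)
                names.append(name)
    return np.column_stack(cols), names


def _loglik_terms(z: np.ndarray, event: np.ndarray, distribution: str):
    """Per-row log-likelihood and its derivatives w.r.t. z, at unit scale."""
    ll = np.empty_like(z)
    dz = np.empty_like(z)
    e = event
    c = ~event
    if distribution == "lognormal":
        ll[e] = stats.norm.logpdf(z[e])
        dz[e] = -z[e]
        ll[c] = stats.norm.logsf(z[c])
        # d/dz log Phi(-z) = -phi(z) / Phi(-z)
        dz[c] = -np.exp(stats.norm.logpdf(z[c]) - stats.norm.logsf(z[c]))
    elif distribution == "weibull":
        ez = np.exp(z)
        ll[e] = z[e] - ez[e]
        dz[e] = 1.0 - ez[e]
        ll[c] = -ez[c]
        dz[c] = -ez[c]
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return ll, dz


def _neg_loglik_and_grad(theta, X, logt, event, distribution):
    p = X.shape[1]
    beta, log_sigma = theta[:p], theta[p]
    sigma = np.exp(log_sigma)
    z = (logt - X @ beta) / sigma
    ll, dz = _loglik_terms(z, event, distribution)
    ll = ll - np.where(event, log_sigma, 0.0)
    # d/d eta = dz * (-1/sigma); d/d log sigma = dz * (-z) - 1{event}
    g_eta = -dz / sigma
    g_beta = X.T @ g_eta
    g_logsig = np.sum(dz * (-z)) - event.sum()
    grad = np.append(g_beta, g_logsig)
    return -np.sum(ll), -grad


def _numeric_hessian(fun_grad, theta, *args, eps=1e-5):
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        step = eps * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += step
        tm[j] -= step
        gp = fun_grad(tp, *args)[1]
        gm = fun_grad(tm, *args)[1]
        H[:, j] = (gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)


class AFTRegressor(BaseEstimator):
    """Scikit-learn style right-censored AFT regression.

    Parameters
    ----------
    distribution : {"weibull", "lognormal"}
        Error family of ``log T``.
    covariates : tuple of str
        Factor columns of the fitting frame.
    references : dict or None
        Reference level per factor (defaults fix single adult female /
        red deer / summer as baselines).
    tol, max_iter : float, int
        Convergence tolerance and iteration cap of the quasi-Newton
        optimizer on ``(beta, log sigma)``.

    Attributes (after ``fit``)
    --------------------------
    coef_ : pandas.Series  — coefficients on the log-days scale (incl. intercept)
    se_ : pandas.Series    — standard errors
    scale_ : float         — sigma
    vcov_ : pandas.DataFrame — coefficient covariance (beta block)
    loglik_ : float
    n_, n_censored_ : int
    """

    def __init__(self, distribution: str = "weibull",
                 covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                 references: dict[str, str] | None = None,
                 tol: float = 1e-8, max_iter: int = 500):
        self.distribution = distribution
        self.covariates = covariates
        self.references = references
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y, event=None):
        y = np.asarray(y, float)
        if np.any(y <= 0) or not np.all(np.isfinite(y)):
            raise ValueError("durations must be positive and finite")
        event = (np.ones(len(y), bool) if event is None
                 else np.asarray(event, bool))
        if event.sum() == 0:
            raise ValueError("need at least one event to fit")
        design, names = build_design(X, tuple(self.covariates),
                                     self.references)
        for name, col in zip(names[1:], design.T[1:]):
            n_events = event[col > 0].sum()
            if n_events < 2:
                warnings.warn(
                    f"level {name} has {n_events} events; "
                    "its coefficient is weakly identified", stacklevel=2)
        logt = np.log(y)

        beta0, *_ = np.linalg.lstsq(design, logt, rcond=None)
        resid = logt - design @ beta0
        sigma0 = max(float(resid.std()), 0.05)
        theta0 = np.append(beta0, np.log(sigma0))

        res = optimize.minimize(
            _neg_loglik_and_grad, theta0,
            args=(design, logt, event, self.distribution),
            jac=True, method="BFGS",
            options={"gtol": self.tol, "maxiter": self.max_iter},
        )
        theta = res.x
        H = _numeric_hessian(_neg_loglik_and_grad, theta, design, logt,
                             event, self.distribution)
        try:
            vcov_full = np.linalg.inv(H)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular information matrix: a factor level is likely "
                "separated into censored-only rows") from exc
        if not np.all(np.isfinite(vcov_full)) or np.any(np.diag(vcov_full) < 0):
            raise np.linalg.LinAlgError(
                "information matrix is not positive definite")

        p = design.shape[1]
        self.feature_names_ = names
        self.coef_ = pd.Series(theta[:p], index=names)
        self.scale_ = float(np.exp(theta[p]))
        self.scale_se_ = float(self.scale_
                               * np.sqrt(max(vcov_full[p, p], 0.0)))
        self.vcov_ = pd.DataFrame(vcov_full[:p, :p], index=names,
                                  columns=names)
        self.se_ = pd.Series(np.sqrt(np.diag(vcov_full[:p, :p])),
                             index=names)
        self.loglik_ = float(-res.fun)
        self.n_ = int(len(y))
        self.n_censored_ = int((~event).sum())
        self.converged_ = bool(res.success or res.status == 2)
        return self

    def _linear_predictor(self, setting: dict[str, str]) -> float:
        lp = self.coef_["intercept"]
        for cov in self.covariates:
            if cov not in setting:
                raise ValueError(f"setting must give a level for {cov!r}")
            name = f"{cov}_{setting[cov]}"
            if name in self.coef_.index:
                lp += self.coef_[name]
            else:
                ref = {**DEFAULT_REFERENCES, **(self.references or {})}.get(cov)
                levels = {n.split("_", 1)[1] for n in self.coef_.index
                          if n.startswith(f"{cov}_")}
                if setting[cov] != ref and setting[cov] not in levels:
                    raise ValueError(
                        f"unknown level {setting[cov]!r} for {cov!r}")
        return float(lp)

    def predict(self, settings, kind: str = "mean") -> np.ndarray:
        """Predicted duration (days) at covariate settings.

        ``kind="mean"`` gives the mean of the fitted distribution
        (log-normal: exp(mu + sigma^2/2); Weibull: exp(mu) * Gamma(1+sigma));
        ``kind="median"`` the median.
        """
        if isinstance(settings, dict):
            settings = [settings]
        if isinstance(settings, pd.DataFrame):
            settings = settings.to_dict("records")
        out = np.array([self._predict_one(s, kind) for s in settings])
        return out

    def _predict_one(self, setting, kind):
        mu = self._linear_predictor(setting)
        s = self.scale_
        if self.distribution == "lognormal":
            return np.exp(mu + 0.5 * s * s) if kind == "mean" else np.exp(mu)
        if kind == "mean":
            from scipy.special import gamma as gamma_fn
            return np.exp(mu) * gamma_fn(1.0 + s)
        return np.exp(mu) * np.log(2.0) ** s

    def sample(self, setting: dict[str, str], size: int,
               rng: np.random.Generator) -> np.ndarray:
        """Draw durations from the fitted distribution at one setting."""
        mu = self._linear_predictor(setting)
        if self.scale_ == 0.0:
            return np.full(size, np.exp(mu))
        if self.distribution == "lognormal":
            return np.exp(rng.normal(mu, self.scale_, size))
        # Weibull AFT: T = exp(mu) * E^sigma with E ~ Exp(1)
        return np.exp(mu) * rng.exponential(1.0, size) ** self.scale_


@dataclass
class AftFit:
    """Fitted AFT model: coefficient table plus the underlying estimator."""

    beta: pd.Series
    se: pd.Series
    scale: float
    vcov: pd.DataFrame
    loglik: float
    n: int
    n_censored: int
    distribution: str
    model: AFTRegressor

    def summary(self) -> pd.DataFrame:
        """Term / effect / SE / z / p table (z = effect / SE, normal p)."""
        z = self.beta / self.se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({
            "term": self.beta.index,
            "effect": self.beta.values,
            "se": self.se.values,
            "z": z.values,
            "p": p,
        })


def fit_aft(intervals: pd.DataFrame, spec: AftSpec | None = None) -> AftFit:
    """Fit the censored AFT regression described by ``spec`` to an
    intervals table (columns per :mod:`lynxkill.killseries`)."""
    spec = spec or AftSpec()
    est = AFTRegressor(distribution=spec.distribution,
                       covariates=spec.covariates,
                       references=spec.references)
    event = (intervals["event"].to_numpy(bool)
             if "event" in intervals.columns else None)
    est.fit(intervals, intervals[spec.response].to_numpy(float), event=event)
    return AftFit(beta=est.coef_, se=est.se_, scale=est.scale_,
                  vcov=est.vcov_, loglik=est.loglik_, n=est.n_,
                  n_censored=est.n_censored_,
                  distribution=spec.distribution, model=est)


def predict_mean_time(fit: AftFit, setting: dict[str, str],
                      kind: str = "mean") -> float:
    """Model-based duration (days) at one covariate setting."""
    return float(fit.model.predict(setting, kind=kind)[0])


@dataclass
class ContrastResult:
    """All-pair factor contrasts with single-step adjusted p-values."""

    pairs: list[tuple[str, str]]
    estimate: np.ndarray       # difference a - b on the log-days scale
    se: np.ndarray
    z: np.ndarray
    p_adjusted: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "level_a": [a for a, _ in self.pairs],
            "level_b": [b for _, b in self.pairs],
            "estimate": self.estimate,
            "se": self.se,
            "z": self.z,
            "p_adjusted": self.p_adjusted,
        })


def _max_abs_z_pvalues(z_obs: np.ndarray, corr: np.ndarray,
                       n_draws: int, seed: int) -> np.ndarray:
    """P(max_k |Z_k| >= |z_j|) under Z ~ MVN(0, corr), by Monte Carlo."""
    rng = np.random.default_rng(seed)
    jitter = 1e-10 * np.eye(len(corr))
    L = np.linalg.cholesky(corr + jitter)
    draws = rng.standard_normal((n_draws, len(corr))) @ L.T
    max_abs = np.abs(draws).max(axis=1)
    return np.array([(max_abs >= abs(zj)).mean() for zj in z_obs])


def tukey_contrasts(fit: AftFit, factor: str = "status",
                    n_draws: int = 200_000, seed: int = 0) -> ContrastResult:
    """Tukey-type all-pair comparisons of one factor's levels.

    Adjusted p-values are single-step: the distribution of the maximum
    absolute z over all pairwise contrasts under the joint normal
    approximation with the fit's contrast correlation, integrated by
    fixed-seed Monte Carlo.
    """
    names = list(fit.beta.index)
    dummy_names = [n for n in names if n.startswith(f"{factor}_")]
    if not dummy_names:
        raise ValueError(f"factor {factor!r} not in the fitted model")
    refs = {**DEFAULT_REFERENCES, **(fit.model.references or {})}
    levels = [refs.get(factor, "reference")] + [
        n.split("_", 1)[1] for n in dummy_names]
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs at least two levels")

    k = len(fit.beta)

    def level_vec(level):
        v = np.zeros(k)
        name = f"{factor}_{level}"
        if name in names:
            v[names.index(name)] = 1.0
        return v

    pairs, C = [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            pairs.append((levels[i], levels[j]))
            C.append(level_vec(levels[i]) - level_vec(levels[j]))
    C = np.array(C)
    est = C @ fit.beta.to_numpy()
    V = C @ fit.vcov.to_numpy() @ C.T
    se = np.sqrt(np.diag(V))
    z = est / se
    corr = V / np.outer(se, se)
    p_adj = _max_abs_z_pvalues(z, corr, n_draws, seed)
    return ContrastResult(pairs=pairs, estimate=est, se=se, z=z,
                          p_adjusted=p_adj)


def likelihood_ratio_test(full: AftFit, reduced: AftFit):
    """LRT of a reduced model nested in a full model fit on the same rows.

    Returns ``(statistic, df, p)`` with the chi-square reference.
    """
    if full.n != reduced.n or full.n_censored != reduced.n_censored:
        raise ValueError("models must be fitted on identical rows")
    df = len(full.beta) - len(reduced.beta)
    if df < 0 or not set(reduced.beta.index) <= set(full.beta.index):
        raise ValueError("reduced model is not nested in the full model")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p
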