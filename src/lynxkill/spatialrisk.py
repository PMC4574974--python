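"""Two-stage (hurdle) spatial model of kill risk on a quadrant grid.

Kill counts per 500×500 m quadrant are strongly zero-inflated, so risk is
modelled in two stages, per season:

1. a penalized logistic additive model of the probability that a quadrant
   holds at least one kill, with smooths of forest cover, altitude and
   distance to civilization plus a 2-D tensor-product smooth of the
   quadrant centroids (the spatial term);
2. a zero-truncated Poisson additive model of the conditional number of
   kills on the quadrants with at least one observed kill (distance to
   civilization enters stage 1 only).

The combined surface ``expected = p * E[N | N >= 1]`` is a unitless
relative risk index and should not be read as literal kill counts.  The
*partial* risk recomputes both stages with the spatial smooth's
contribution removed, isolating the covariate effects.

Smooths are cubic B-spline bases with second-difference penalties and
sum-to-zero constraints; smoothing parameters are chosen by GCV inside a
penalized IRLS loop.  These numerical choices are package defaults, all
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline
from scipy.linalg import null_space
from sklearn.base import BaseEstimator

from lynxkill.killseries import assign_season

_ETA_LIM = 12.0


# --------------------------------------------------------------------------
# spline machinery

def _knots(lo: float, hi: float, k: int) -> np.ndarray:
    pad = 1e-6 * max(hi - lo, 1e-12)
    lo, hi = lo - pad, hi + pad
    inner = np.linspace(lo, hi, k - 2)
    return np.concatenate([[lo] * 3, inner, [hi] * 3])


def _design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    x = np.clip(x, knots[3], knots[-4])
    return BSpline.design_matrix(x, knots, 3).toarray()


def _second_diff_penalty(k: int) -> np.ndarray:
    D = np.diff(np.eye(k), 2, axis=0)
    return D.T @ D


class _Smooth1D:
    """Centered univariate cubic B-spline smooth of one covariate."""

    def __init__(self, var: str, k: int = 10, name: str | None = None):
        self.var = var
        self.k = k
        self.name = name or var

    def setup(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.var].to_numpy(float)
        self.mu_, self.sd_ = float(x.mean()), float(x.std() or 1.0)
        xs = (x - self.mu_) / self.sd_
        self.knots_ = _knots(xs.min(), xs.max(), self.k)
        B = _design(xs, self.knots_)
        self.Z_ = null_space(B.sum(axis=0)[None, :])
        self.penalty_ = self.Z_.T @ _second_diff_penalty(self.k) @ self.Z_
        return B @ self.Z_

    def build(self, df: pd.DataFrame) -> np.ndarray:
        xs = (df[self.var].to_numpy(float) - self.mu_) / self.sd_
        return _design(xs, self.knots_) @ self.Z_


class _TensorSmooth2D:
    """Centered tensor product of two marginal cubic B-spline bases."""

    def __init__(self, vars: tuple[str, str] = ("cx_m", "cy_m"),
                 k: int = 6, name: str = "space"):
        self.vars = vars
        self.k = k
        self.name = name

    def _marginals(self, df: pd.DataFrame, setup: bool):
        out = []
        for i, var in enumerate(self.vars):
            x = df[var].to_numpy(float)
            if setup:
                mu, sd = float(x.mean()), float(x.std() or 1.0)
                xs = (x - mu) / sd
                knots = _knots(xs.min(), xs.max(), self.k)
                self._scales = getattr(self, "_scales", {})
                self._scales[i] = (mu, sd, knots)
            else:
                mu, sd, knots = self._scales[i]
                xs = (x - mu) / sd
            out.append(_design(xs, knots))
        return out

    def setup(self, df: pd.DataFrame) -> np.ndarray:
        B1, B2 = self._marginals(df, setup=True)
        T = np.einsum("ij,ik->ijk", B1, B2).reshape(len(df), -1)
        self.Z_ = null_space(T.sum(axis=0)[None, :])
        S1 = _second_diff_penalty(self.k)
        S = np.kron(S1, np.eye(self.k)) + np.kron(np.eye(self.k), S1)
        self.penalty_ = self.Z_.T @ S @ self.Z_
        return T @ self.Z_

    def build(self, df: pd.DataFrame) -> np.ndarray:
        B1, B2 = self._marginals(df, setup=False)
        T = np.einsum("ij,ik->ijk", B1, B2).reshape(len(df), -1)
        return T @ self.Z_


# --------------------------------------------------------------------------
# exponential-family plumbing for penalized IRLS

class _Bernoulli:
    name = "bernoulli"

    @staticmethod
    def init_eta(y):
        mu = (y + 0.5) / 2.0
        return np.log(mu / (1.0 - mu))

    @staticmethod
    def mean(eta):
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_LIM, _ETA_LIM)))

    @classmethod
    def weight(cls, eta):
        p = cls.mean(eta)
        return np.maximum(p * (1.0 - p), 1e-10)

    @classmethod
    def deviance(cls, y, eta):
        p = np.clip(cls.mean(eta), 1e-12, 1.0 - 1e-12)
        return -2.0 * np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


class _ZeroTruncPoisson:
    """Zero-truncated Poisson with log link on the untruncated rate lambda;
    the reported conditional mean is E[N | N >= 1] = lambda / (1 - e^-lambda)."""

    name = "ztpoisson"

    @staticmethod
    def init_eta(y):
        return np.full(len(y), np.log(max(float(np.mean(y)) - 0.9, 0.1)))

    @staticmethod
    def _lam(eta):
        return np.exp(np.clip(eta, -_ETA_LIM, _ETA_LIM))

    @classmethod
    def mean(cls, eta):
        lam = cls._lam(eta)
        return lam / -np.expm1(-lam)

    @classmethod
    def weight(cls, eta):
        lam = cls._lam(eta)
        denom = -np.expm1(-lam)
        dm_dlam = (denom - lam * np.exp(-lam)) / denom ** 2
        return np.maximum(lam * dm_dlam, 1e-10)

    @classmethod
    def deviance(cls, y, eta):
        lam = cls._lam(eta)
        ll = np.sum(y * np.log(lam) - lam - np.log(-np.expm1(-lam)))
        return -2.0 * ll


# --------------------------------------------------------------------------
# penalized additive model

class _PenalizedGAM(BaseEstimator):
    """Penalized-spline additive model fitted by IRLS, smoothing by GCV.

    Subclasses set ``_family`` and ``_term_spec`` (list of smooth factories).
    """

    _family = None

    def __init__(self, k_uni: int = 10, k_tensor: int = 6,
                 lambdas=None, max_iter: int = 100, tol: float = 1e-8):
        self.k_uni = k_uni
        self.k_tensor = k_tensor
        self.lambdas = lambdas
        self.max_iter = max_iter
        self.tol = tol

    def _make_terms(self) -> list:
        raise NotImplementedError

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, float)
        self.terms_ = self._make_terms()
        cols = [np.ones((len(X), 1))]
        slices, penalties = [slice(0, 1)], []
        pos = 1
        for term in self.terms_:
            block = term.setup(X)
            cols.append(block)
            slices.append(slice(pos, pos + block.shape[1]))
            penalties.append(term.penalty_)
            pos += block.shape[1]
        design = np.hstack(cols)
        self.X_, self.y_ = X, y
        self.design_ = design
        self.term_slices_ = dict(zip([t.name for t in self.terms_],
                                     slices[1:]))

        if self.lambdas is not None:
            lam = np.asarray(self.lambdas, float)
            self.coef_, self.edf_, self.term_edf_, self.deviance_ = \
                self._pirls(design, y, penalties, slices[1:], lam)
            self.lambda_ = lam
        else:
            def gcv(log_lam):
                lam = np.exp(np.clip(log_lam, -8.0, 12.0))
                _, edf, _, dev = self._pirls(design, y, penalties,
                                             slices[1:], lam)
                n = len(y)
                return n * dev / max(n - edf, 1.0) ** 2

            x0 = np.zeros(len(penalties))
            res = optimize.minimize(gcv, x0, method="Nelder-Mead",
                                    options={"xatol": 0.05, "fatol": 1e-7,
                                             "maxiter": 300})
            self.lambda_ = np.exp(np.clip(res.x, -8.0, 12.0))
            self.coef_, self.edf_, self.term_edf_, self.deviance_ = \
                self._pirls(design, y, penalties, slices[1:], self.lambda_)

        self.eta_ = design @ self.coef_
        self.fitted_ = self._family.mean(self.eta_)
        return self

    def _pirls(self, design, y, penalties, pen_slices, lam):
        p = design.shape[1]
        S = np.zeros((p, p))
        for lam_j, pen, sl in zip(lam, penalties, pen_slices):
            S[sl, sl] += lam_j * pen
        fam = self._family
        eta = fam.init_eta(y)
        dev = fam.deviance(y, eta)
        beta = None
        for _ in range(self.max_iter):
            w = fam.weight(eta)
            mu = fam.mean(eta)
            z = np.clip(eta, -_ETA_LIM, _ETA_LIM) + (y - mu) / w
            XtW = design.T * w
            A = XtW @ design + S + 1e-9 * np.eye(p)
            beta = np.linalg.solve(A, XtW @ z)
            eta = design @ beta
            new_dev = fam.deviance(y, eta)
            if abs(new_dev - dev) < self.tol * (abs(dev) + 0.1):
                dev = new_dev
                break
            dev = new_dev
        w = fam.weight(eta)
        XtW = design.T * w
        A = XtW @ design + S + 1e-9 * np.eye(p)
        H = np.linalg.solve(A, XtW @ design)     # influence (edf) matrix
        edf = float(np.trace(H))
        term_edf = {t.name: float(np.trace(H[sl, sl]))
                    for t, sl in zip(self.terms_, pen_slices)}
        return beta, edf, term_edf, dev

    def linear_predictor(self, X: pd.DataFrame | None = None,
                         exclude: tuple[str, ...] = ()) -> np.ndarray:
        """Linear predictor on the training grid or new covariates, with
        the named smooth terms' contributions set to zero."""
        unknown = set(exclude) - set(self.term_slices_)
        if unknown:
            raise ValueError(f"no such smooth terms: {sorted(unknown)}")
        if X is None:
            design = self.design_
        else:
            blocks = [np.ones((len(X), 1))]
            blocks += [t.build(X) for t in self.terms_]
            design = np.hstack(blocks)
        coef = self.coef_.copy()
        for name in exclude:
            coef[self.term_slices_[name]] = 0.0
        return design @ coef


class PresenceGAM(_PenalizedGAM):
    """Stage 1: penalized logistic additive model of P(at least one kill).

    Smooths: forest, altitude, distance to civilization, and a tensor
    product of the quadrant centroid coordinates.
    """

    _family = _Bernoulli

    def _make_terms(self):
        return [
            _Smooth1D("forest", self.k_uni),
            _Smooth1D("altitude_m", self.k_uni),
            _Smooth1D("dist_civ_m", self.k_uni),
            _TensorSmooth2D(("cx_m", "cy_m"), self.k_tensor, name="space"),
        ]

    def fit(self, X, y):
        y = np.asarray(y, float)
        if y.min() == y.max():
            raise ValueError(
                "presence model needs both presence and absence cells")
        return super().fit(X, y)

    def predict_proba(self, X=None, exclude=()):
        return _Bernoulli.mean(self.linear_predictor(X, exclude))


class TruncatedPoissonGAM(_PenalizedGAM):
    """Stage 2: zero-truncated Poisson additive model of positive counts.

    Smooths: forest, altitude, and the 2-D spatial tensor product
    (distance to civilization is a stage-1 covariate only).
    """

    _family = _ZeroTruncPoisson

    def _make_terms(self):
        return [
            _Smooth1D("forest", self.k_uni),
            _Smooth1D("altitude_m", self.k_uni),
            _TensorSmooth2D(("cx_m", "cy_m"), self.k_tensor, name="space"),
        ]

    def fit(self, X, y):
        y = np.asarray(y, float)
        if np.any(y < 1):
            raise ValueError("stage 2 takes cells with at least one kill")
        if len(y) < 10:
            raise ValueError("need at least 10 positive cells")
        return super().fit(X, y)

    def predict_conditional_mean(self, X=None, exclude=()):
        return _ZeroTruncPoisson.mean(self.linear_predictor(X, exclude))


# --------------------------------------------------------------------------
# spec-level operations

def rasterize_kills(kills: pd.DataFrame, grid: pd.DataFrame,
                    cell_size: float = 500.0):
    """Count kills per quadrant and season (half-open cell membership).

    Returns ``(grid_with_counts, n_outside)``: the grid gains
    ``kills_summer`` / ``kills_winter`` columns; kills falling outside the
    grid are counted in ``n_outside`` rather than silently dropped.
    """
    grid = grid.copy()
    x0 = grid["cx_m"].min() - cell_size / 2.0
    y0 = grid["cy_m"].min() - cell_size / 2.0
    nx = int(round((grid["cx_m"].max() - grid["cx_m"].min()) / cell_size)) + 1
    ny = int(round((grid["cy_m"].max() - grid["cy_m"].min()) / cell_size)) + 1

    counts = {"summer": np.zeros(nx * ny, int),
              "winter": np.zeros(nx * ny, int)}
    outside = 0
    for rec in kills.itertuples():
        ix = int(np.floor((rec.x_m - x0) / cell_size))
        iy = int(np.floor((rec.y_m - y0) / cell_size))
        if not (0 <= ix < nx and 0 <= iy < ny):
            outside += 1
            continue
        counts[assign_season(rec.kill_date)][ix * ny + iy] += 1

    gx = np.round((grid["cx_m"] - cell_size / 2.0 - x0) / cell_size).astype(int)
    gy = np.round((grid["cy_m"] - cell_size / 2.0 - y0) / cell_size).astype(int)
    flat = gx * ny + gy
    grid["kills_summer"] = counts["summer"][flat]
    grid["kills_winter"] = counts["winter"][flat]
    return grid, outside


def fit_presence(grid: pd.DataFrame, season: str, **kwargs) -> PresenceGAM:
    """Stage-1 fit for one season on a grid with kill-count columns."""
    y = (grid[f"kills_{season}"] >= 1).astype(float)
    return PresenceGAM(**kwargs).fit(grid, y)


def fit_conditional_count(grid: pd.DataFrame, season: str,
                          **kwargs) -> TruncatedPoissonGAM:
    """Stage-2 fit on the quadrants with at least one observed kill."""
    positive = grid[grid[f"kills_{season}"] >= 1]
    return TruncatedPoissonGAM(**kwargs).fit(
        positive, positive[f"kills_{season}"].astype(float))


@dataclass
class RiskSurface:
    """Per-quadrant risk: presence probability, conditional mean, and their
    product (the combined, unitless expectation)."""

    season: str
    table: pd.DataFrame     # quad_id, p, mu_cond, expected


def combine_hurdle(stage1: PresenceGAM, stage2: TruncatedPoissonGAM,
                   grid: pd.DataFrame, season: str = "",
                   exclude: tuple[str, ...] = ()) -> RiskSurface:
    """Combined expectation ``p * E[N | N >= 1]`` per quadrant."""
    if len(stage1.X_) != len(grid):
        raise ValueError("stage-1 fit and grid have different lengths")
    p = stage1.predict_proba(exclude=exclude)
    mu = stage2.predict_conditional_mean(grid, exclude=exclude)
    table = pd.DataFrame({
        "quad_id": grid["quad_id"].to_numpy(),
        "p": p,
        "mu_cond": mu,
        "expected": p * mu,
    })
    return RiskSurface(season=season, table=table)


def partial_risk(stage1: PresenceGAM, stage2: TruncatedPoissonGAM,
                 grid: pd.DataFrame, season: str = "") -> RiskSurface:
    """Combined risk with the spatial smooth excluded from both stages,
    isolating the effect of the biotic and abiotic covariates."""
    for fit in (stage1, stage2):
        if "space" not in fit.term_slices_:
            raise ValueError("fit has no spatial smooth to exclude")
    return combine_hurdle(stage1, stage2, grid, season=season,
                          exclude=("space",))


@dataclass
class ZoneComparison:
    """Zone (inside / outside the national park) summaries of a surface."""

    season: str
    table: pd.DataFrame          # zone, n, mean_p, se_p, mean_expected_km2, se_expected_km2
    altitude_correlation: float  # Pearson r of altitude vs expected risk


def compare_zones(surface: RiskSurface, grid: pd.DataFrame,
                  cell_area_km2: float = 0.25) -> ZoneComparison:
    """Compare mean kill probability and expected kills per km² inside vs
    outside the protected area, and correlate altitude with expected risk."""
    tab = surface.table
    rows = []
    for zone, flag in (("inside_np", 1), ("outside_np", 0)):
        mask = (grid["in_np"].to_numpy() == flag)
        if mask.sum() < 2:
            raise ValueError(f"zone {zone} has fewer than 2 quadrants")
        p = tab["p"].to_numpy()[mask]
        e = tab["expected"].to_numpy()[mask] / cell_area_km2
        rows.append({
            "zone": zone, "n": int(mask.sum()),
            "mean_p": p.mean(), "se_p": p.std(ddof=1) / np.sqrt(len(p)),
            "mean_expected_km2": e.mean(),
            "se_expected_km2": e.std(ddof=1) / np.sqrt(len(e)),
        })
    alt = grid["altitude_m"].to_numpy(float)
    exp_risk = tab["expected"].to_numpy(float)
    if np.std(exp_risk) == 0 or np.std(alt) == 0:
        corr = 0.0
    else:
        corr = float(stats.pearsonr(alt, exp_risk)[0])
    return ZoneComparison(season=surface.season,
                          table=pd.DataFrame(rows),
                          altitude_correlation=corr)
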