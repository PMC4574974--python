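"""Hurdle spatial model: rasterization, stage fits, combination, zones."""

import numpy as np
import pandas as pd
import pytest

from lynxkill import spatialrisk, synthio
from lynxkill.spatialrisk import (PresenceGAM, RiskSurface,
                                  TruncatedPoissonGAM, _ZeroTruncPoisson)


def _grid(n=20, seed=0):
    rng = np.random.default_rng(seed)
    ix, iy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ix, iy = ix.ravel(), iy.ravel()
    return pd.DataFrame({
        "quad_id": np.arange(n * n),
        "cx_m": (ix + 0.5) * 500.0,
        "cy_m": (iy + 0.5) * 500.0,
        "forest": rng.uniform(0.1, 0.9, n * n),
        "altitude_m": 600.0 + 700.0 * iy / (n - 1)
        + rng.normal(0, 10, n * n),
        "dist_civ_m": rng.uniform(0, 5000.0, n * n),
        "in_np": (iy >= n // 2).astype(int),
    })


def _sample_ztp(lam, rng):
    """Zero-truncated Poisson draws by conditional inversion."""
    u = rng.uniform(size=len(lam))
    # invert the truncated CDF cell by cell
    out = np.empty(len(lam), int)
    for i, (l, ui) in enumerate(zip(lam, u)):
        k, cdf, p = 1, 0.0, l * np.exp(-l) / -np.expm1(-l)
        while True:
            cdf += p
            if ui <= cdf or k > 200:
                out[i] = k
                break
            k += 1
            p *= l / k
    return out


def test_rasterize_kills_half_open_cells_and_outside_report():
    grid = _grid(4)
    kills = pd.DataFrame({
        "lynx_id": "L1",
        "kill_date": [pd.Timestamp("2011-07-01")] * 4
        + [pd.Timestamp("2011-12-01")],
        "x_m": [0.0, 10.0, 10.0, 10.0, -50.0],
        "y_m": [0.0, 10.0, 10.0, 10.0, 100.0],
    })
    counted, outside = spatialrisk.rasterize_kills(kills, grid)
    assert outside == 1
    # exact corner belongs to the cell whose origin it is
    assert counted.loc[0, "kills_summer"] == 4
    assert counted["kills_summer"].sum() == 4
    assert counted["kills_winter"].sum() == 0


def test_presence_fit_recovers_constant_rate_under_noise_covariates():
    grid = _grid(20, seed=1)
    rng = np.random.default_rng(2)
    y = (rng.uniform(size=len(grid)) < 0.3).astype(float)
    fit = PresenceGAM().fit(grid, y)
    # IRLS score equation: fitted probabilities average to the observed rate
    assert abs(fit.fitted_.mean() - y.mean()) < 1e-6
    assert abs(fit.fitted_.mean() - 0.3) < 3 * np.sqrt(0.3 * 0.7 / len(y))
    # GCV shrinks the univariate noise smooths to their 1-df (linear) null
    # space; the tensor smooth's unpenalized bilinear trend keeps 3 df, so
    # it can only shrink toward that floor.
    for name, edf in fit.term_edf_.items():
        assert edf < (7.0 if name == "space" else 2.0), fit.term_edf_
    assert np.percentile(fit.fitted_, 95) < 0.5  # no dramatic overfit


def test_presence_partial_effect_of_altitude_is_monotone():
    grid = _grid(22, seed=3)
    rng = np.random.default_rng(4)
    eta = 1.0 - 3.0 * (grid["altitude_m"] - 950.0) / 350.0
    y = (rng.uniform(size=len(grid)) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = PresenceGAM().fit(grid, y)
    term = fit.terms_[1]
    assert term.var == "altitude_m"
    sl = fit.term_slices_["altitude_m"]
    lo, hi = np.quantile(grid["altitude_m"], [0.1, 0.9])
    probe = pd.DataFrame({"altitude_m": np.linspace(lo, hi, 25)})
    effect = term.build(probe) @ fit.coef_[sl]
    drops = np.diff(effect)
    tol = 0.02 * (effect.max() - effect.min())
    assert np.all(drops <= tol)
    assert effect[0] > effect[-1]


def test_presence_requires_both_outcomes():
    grid = _grid(6)
    with pytest.raises(ValueError):
        PresenceGAM().fit(grid, np.ones(len(grid)))


def test_conditional_count_recovers_forest_effect():
    grid = _grid(20, seed=5)
    rng = np.random.default_rng(6)
    eta_true = -0.3 + 1.6 * (grid["forest"] - 0.5)
    y = _sample_ztp(np.exp(eta_true), rng)
    fit = TruncatedPoissonGAM().fit(grid, y)
    eta_hat = np.log(spatialrisk._ZeroTruncPoisson._lam(
        fit.linear_predictor()))
    slope = np.polyfit(eta_true, eta_hat, 1)[0]
    assert 0.6 < slope < 1.4
    assert np.corrcoef(eta_true, eta_hat)[0, 1] > 0.7


def test_conditional_count_boundary_and_validation():
    grid = _grid(8, seed=7)
    fit = TruncatedPoissonGAM().fit(grid, np.ones(len(grid)))
    mu = fit.predict_conditional_mean()
    assert np.all(mu >= 1.0) and np.all(mu < 1.1)

    with pytest.raises(ValueError):
        TruncatedPoissonGAM().fit(grid.head(20),
                                  np.r_[np.zeros(1), np.ones(19)])
    with pytest.raises(ValueError):
        TruncatedPoissonGAM().fit(grid.head(5), np.ones(5))


def _fit_hurdle(grid, y_presence, y_counts):
    s1 = PresenceGAM().fit(grid, y_presence)
    positive = grid[y_counts >= 1]
    s2 = TruncatedPoissonGAM().fit(positive, y_counts[y_counts >= 1])
    return s1, s2


def test_combined_surface_identity_and_bounds():
    grid = _grid(15, seed=8)
    rng = np.random.default_rng(9)
    p_true = 1 / (1 + np.exp(-(-1.0 + 2.0 * (grid["forest"] - 0.5))))
    present = rng.uniform(size=len(grid)) < p_true
    counts = np.where(present, _sample_ztp(
        np.full(len(grid), 1.2), rng), 0)
    s1, s2 = _fit_hurdle(grid, present.astype(float), counts)
    surface = spatialrisk.combine_hurdle(s1, s2, grid, season="summer")
    tab = surface.table
    np.testing.assert_allclose(tab["expected"], tab["p"] * tab["mu_cond"],
                               rtol=0, atol=1e-12)
    assert np.all(tab["expected"] <= tab["mu_cond"] + 1e-12)
    assert np.all((tab["p"] > 0) & (tab["p"] < 1))
    with pytest.raises(ValueError):
        spatialrisk.combine_hurdle(s1, s2, grid.head(10))


def test_hurdle_beats_intercept_only_baseline():
    grid = _grid(20, seed=10)
    rng = np.random.default_rng(11)
    p_true = 1 / (1 + np.exp(-(-0.8 + 2.5 * (grid["forest"] - 0.5)
                               - 1.5 * (grid["altitude_m"] - 950) / 350)))
    lam_true = np.exp(0.2 + 1.0 * (grid["forest"] - 0.5))
    truth = p_true * lam_true / -np.expm1(-lam_true)
    present = rng.uniform(size=len(grid)) < p_true
    counts = np.where(present, _sample_ztp(lam_true, rng), 0)

    s1, s2 = _fit_hurdle(grid, present.astype(float), counts)
    surface = spatialrisk.combine_hurdle(s1, s2, grid)
    mae = np.abs(surface.table["expected"] - truth).mean()
    baseline = present.mean() * counts[present].mean()
    mae_baseline = np.abs(baseline - truth).mean()
    assert mae < mae_baseline


def test_partial_risk_drops_exactly_the_spatial_columns():
    grid = _grid(15, seed=12)
    rng = np.random.default_rng(13)
    present = (rng.uniform(size=len(grid)) < 0.25).astype(float)
    counts = np.where(present > 0, 1 + rng.poisson(0.8, len(grid)), 0)
    s1, s2 = _fit_hurdle(grid, present, counts)

    # linear-algebra oracle: zero the spatial block of the coefficient vector
    coef = s1.coef_.copy()
    coef[s1.term_slices_["space"]] = 0.0
    manual = s1.design_ @ coef
    np.testing.assert_allclose(
        s1.linear_predictor(exclude=("space",)), manual, atol=1e-12)

    partial = spatialrisk.partial_risk(s1, s2, grid)
    full = spatialrisk.combine_hurdle(s1, s2, grid)
    # zero-weight spatial term -> partial equals full
    s1.coef_[s1.term_slices_["space"]] = 0.0
    s2.coef_[s2.term_slices_["space"]] = 0.0
    s1.eta_ = s1.design_ @ s1.coef_
    zeroed_full = spatialrisk.combine_hurdle(s1, s2, grid)
    zeroed_partial = spatialrisk.partial_risk(s1, s2, grid)
    np.testing.assert_allclose(zeroed_partial.table["expected"],
                               zeroed_full.table["expected"], atol=1e-12)
    # and with spatial weight present they differ somewhere
    assert not np.allclose(partial.table["expected"],
                           full.table["expected"])


def test_partial_risk_requires_spatial_term():
    grid = _grid(10, seed=20)
    rng = np.random.default_rng(21)
    present = (rng.uniform(size=len(grid)) < 0.3).astype(float)
    counts = np.where(present > 0, 1, 0)
    s1, s2 = _fit_hurdle(grid, present, counts)
    s1.term_slices_ = {k: v for k, v in s1.term_slices_.items()
                       if k != "space"}
    with pytest.raises(ValueError):
        spatialrisk.partial_risk(s1, s2, grid)


def test_compare_zones_uniform_and_perfectly_correlated_surfaces():
    grid = _grid(10, seed=14)
    uniform = RiskSurface(season="summer", table=pd.DataFrame({
        "quad_id": grid["quad_id"], "p": 0.2, "mu_cond": 1.5,
        "expected": 0.3}))
    zc = spatialrisk.compare_zones(uniform, grid)
    means = zc.table.set_index("zone")["mean_p"]
    assert np.isclose(means["inside_np"], means["outside_np"])
    assert zc.altitude_correlation == 0.0

    alt = grid["altitude_m"].to_numpy()
    scaled = (alt.max() - alt) / (alt.max() - alt.min())
    anti = RiskSurface(season="winter", table=pd.DataFrame({
        "quad_id": grid["quad_id"], "p": scaled, "mu_cond": 1.0,
        "expected": scaled}))
    zc = spatialrisk.compare_zones(anti, grid)
    assert zc.altitude_correlation < -0.99

    tiny = grid.copy()
    tiny["in_np"] = 0
    with pytest.raises(ValueError):
        spatialrisk.compare_zones(uniform, tiny)


def test_synthetic_seasonal_scenarios_reproduce_zone_pattern():
    """Winter kills pulled to low ground outside the park: outside mean kill
    probability exceeds inside and altitude correlates negatively with risk;
    the bias-free summer shows no zone difference beyond noise."""
    cfg = synthio.SimConfig(seed=17, monitoring_days=730, miss_rate=0.0,
                            n_lynx={"adult_male": 3, "family_group": 3,
                                    "single_adult_female": 3})
    landscape = synthio.make_landscape(cfg)
    kills = synthio.simulate_killseries(cfg, landscape)
    grid, _ = spatialrisk.rasterize_kills(kills, landscape.to_frame())

    results = {}
    for season in ("summer", "winter"):
        s1 = spatialrisk.fit_presence(grid, season)
        s2 = spatialrisk.fit_conditional_count(grid, season)
        surface = spatialrisk.combine_hurdle(s1, s2, grid, season=season)
        results[season] = spatialrisk.compare_zones(surface, grid)

    win = results["winter"].table.set_index("zone")
    assert (win.loc["outside_np", "mean_p"]
            > win.loc["inside_np", "mean_p"])
    assert results["winter"].altitude_correlation < 0

    summ = results["summer"].table.set_index("zone")
    diff = abs(summ.loc["outside_np", "mean_p"]
               - summ.loc["inside_np", "mean_p"])
    pooled = np.sqrt(summ.loc["outside_np", "se_p"] ** 2
                     + summ.loc["inside_np", "se_p"] ** 2)
    assert diff < 2 * pooled
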