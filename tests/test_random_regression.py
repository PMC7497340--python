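"""Thermal time, spline covariables, RR fitting and covariance reconstruction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vigblup as v
from vigblup.errors import (
    CoverageError,
    ExtrapolationError,
    IdentifiabilityError,
    ParameterError,
)
from vigblup.io import identity_grm


# ---------------------------------------------------------------------------
# growing degree days


@pytest.mark.parametrize(
    "tmax, tmin, expected",
    [
        (35.0, 5.0, 10.0),  # both clamps active: (30 + 10)/2 − 10
        (8.0, 4.0, 0.0),  # both floored to base
        (28.0, 16.0, 12.0),
        (30.0, 30.0, 20.0),  # maximum possible daily value
        (10.0, 10.0, 0.0),
    ],
)
def test_daily_gdd_with_clamps(tmax, tmin, expected):
    assert v.daily_gdd(tmax, tmin) == pytest.approx(expected)


def test_daily_gdd_rejects_inverted_temperatures():
    with pytest.raises(ParameterError):
        v.daily_gdd(10.0, 20.0)


def _weather(days, tmax=28.0, tmin=16.0, start="2016-05-10"):
    return pd.DataFrame(
        {
            "date": pd.date_range(start, periods=days, freq="D").date,
            "tmin": tmin,
            "tmax": tmax,
        }
    )


def test_cumulative_gdd_single_day_and_linearity():
    w = _weather(10)
    assert v.cumulative_gdd(w, "2016-05-10", "2016-05-10") == pytest.approx(12.0)
    assert v.cumulative_gdd(w, "2016-05-10", "2016-05-19") == pytest.approx(120.0)


def test_cumulative_gdd_invariant_to_day_order():
    rng = np.random.default_rng(4)
    w = _weather(15)
    w["tmax"] = rng.uniform(12, 35, 15)
    w["tmin"] = w["tmax"] - rng.uniform(0, 10, 15)
    total = v.cumulative_gdd(w, "2016-05-10", "2016-05-24")
    shuffled = w.sample(frac=1.0, random_state=1).reset_index(drop=True)
    assert v.cumulative_gdd(shuffled, "2016-05-10", "2016-05-24") == pytest.approx(total)


def test_cumulative_gdd_coverage_gap_raises():
    w = _weather(10).drop(index=4)
    with pytest.raises(CoverageError):
        v.cumulative_gdd(w, "2016-05-10", "2016-05-19")


# ---------------------------------------------------------------------------
# spline covariables

KNOTS = np.array([524.0, 816.0, 1501.0])


@pytest.mark.parametrize(
    "gdd, expected",
    [
        (816.0, (0.0, 1.0, 0.0)),  # exactly at a knot → indicator
        (670.0, (0.5, 0.5, 0.0)),  # midpoint of the first segment
        (759.0, ((816 - 759) / 292, 1 - (816 - 759) / 292, 0.0)),  # ≈ (0.19521, 0.80479, 0)
        (524.0, (1.0, 0.0, 0.0)),
        (1501.0, (0.0, 0.0, 1.0)),
    ],
)
def test_spline_covariables_values(gdd, expected):
    assert v.spline_covariables(gdd, KNOTS) == pytest.approx(np.array(expected), abs=1e-10)


def test_spline_covariables_reject_extrapolation_and_bad_knots():
    with pytest.raises(ExtrapolationError):
        v.spline_covariables(500.0, KNOTS)
    with pytest.raises(ExtrapolationError):
        v.spline_covariables(1502.0, KNOTS)
    with pytest.raises(ParameterError):
        v.spline_covariables(600.0, [816.0, 524.0])


@given(
    data=st.data(),
    knots=st.lists(
        st.floats(min_value=0.0, max_value=2000.0), min_size=2, max_size=6, unique=True
    ),
)
def test_spline_covariable_invariants(data, knots):
    knots = np.sort(np.asarray(knots))
    if np.min(np.diff(knots)) < 1e-6:
        return
    gdd = data.draw(st.floats(min_value=float(knots[0]), max_value=float(knots[-1])))
    z = v.spline_covariables(gdd, knots)
    assert np.all(z >= 0.0)
    assert np.sum(z) == pytest.approx(1.0, abs=1e-12)
    assert np.count_nonzero(z) <= 2
    nz = np.flatnonzero(z)
    if len(nz) == 2:  # the two nonzero entries must be adjacent knots
        assert nz[1] - nz[0] == 1


# ---------------------------------------------------------------------------
# covariance-function reconstruction


def test_reconstruct_identity_cases():
    eye = np.eye(3)
    assert v.reconstruct_covariance(eye, KNOTS, 816.0) == pytest.approx(1.0)
    assert v.reconstruct_covariance(eye, KNOTS, 670.0, 670.0) == pytest.approx(0.5)


def test_reconstruct_matches_dense_triple_product_oracle():
    rng = np.random.default_rng(3)
    a = rng.standard_normal((3, 3))
    sigma = a @ a.T
    for _ in range(50):
        t, s = rng.uniform(524.0, 1501.0, 2)
        zt = v.spline_covariables(t, KNOTS)
        zs = v.spline_covariables(s, KNOTS)
        oracle = (zt.reshape(1, -1) @ sigma @ zs.reshape(-1, 1)).item()
        assert v.reconstruct_covariance(sigma, KNOTS, t, s) == pytest.approx(oracle, abs=1e-12)


def test_reconstruct_returns_sigma_entries_exactly_at_knot_pairs():
    rng = np.random.default_rng(5)
    a = rng.standard_normal((3, 3))
    sigma = a @ a.T
    for i, t in enumerate(KNOTS):
        for j, s in enumerate(KNOTS):
            assert v.reconstruct_covariance(sigma, KNOTS, float(t), float(s)) == sigma[i, j]


def test_reconstructed_grid_is_symmetric_psd_with_unit_diagonal_correlation():
    rng = np.random.default_rng(6)
    a = rng.standard_normal((3, 3))
    sigma = a @ a.T
    grid = v.reconstruct_covariance_grid(sigma, KNOTS, np.linspace(524, 1501, 9))
    values = grid.to_numpy()
    assert np.allclose(values, values.T)
    assert np.linalg.eigvalsh(values)[0] > -1e-10
    d = np.sqrt(np.diag(values))
    corr = values / np.outer(d, d)
    assert np.allclose(np.diag(corr), 1.0)


def test_reconstruct_out_of_range_raises():
    with pytest.raises(ExtrapolationError):
        v.reconstruct_covariance(np.eye(3), KNOTS, 100.0)


# ---------------------------------------------------------------------------
# model fitting


@pytest.fixture(scope="module")
def rr_fit_small(request):
    cfg = v.SimulationConfig(n_hybrids=120, seed=77)
    hybrids = [f"H{i:04d}" for i in range(120)]
    layout = v.build_field_layout(hybrids, seed=3)
    grm = identity_grm(hybrids)
    long, coeffs = v.simulate_vi_trajectories(cfg, layout, grm)
    design = v.build_rr_design(long, np.asarray(cfg.knot_gdds), grm)
    fit = v.fit_random_regression(design, grm, tol=1e-6)
    return cfg, fit, coeffs


def test_rr_fit_recovers_structure_and_is_monotone(rr_fit_small):
    cfg, fit, coeffs = rr_fit_small
    assert fit.converged
    assert np.all(np.diff(fit.loglik_history) >= -1e-10)
    # coefficient BLUPs track the simulated truth at every knot
    for k in range(3):
        r = np.corrcoef(fit.a_hat[f"k{k}"], coeffs[f"k{k}"])[0, 1]
        assert r > 0.6
    # variance scale: reconstructed mid-season genetic variance near truth
    est = v.reconstruct_covariance(fit.Sigma_a, fit.knot_gdds, 816.0)
    truth = cfg.Sigma_a_true[1, 1]
    assert est == pytest.approx(truth, rel=0.75)
    assert (fit.resid_vars > 0).all()
    assert np.linalg.eigvalsh(fit.Sigma_a)[0] > -1e-12


def test_rr_design_validations(rr_fit_small):
    cfg, _, _ = rr_fit_small
    hybrids = [f"H{i}" for i in range(4)]
    layout = v.build_field_layout(hybrids, seed=1)
    grm = identity_grm(hybrids)
    long, _ = v.simulate_vi_trajectories(
        v.SimulationConfig(n_hybrids=4, seed=1), layout, grm
    )
    with pytest.raises(IdentifiabilityError):
        v.build_rr_design(long, np.linspace(524, 1501, 7), grm)
    with pytest.raises(ExtrapolationError):
        v.build_rr_design(long, np.array([600.0, 1501.0]), grm)  # first flight below knot 1


# ---------------------------------------------------------------------------
# genetic curves


def _fit_with_coeffs(coeffs: pd.DataFrame) -> v.RRFit:
    m = coeffs.shape[1]
    return v.RRFit(
        Sigma_a=np.eye(m),
        Sigma_pe=np.eye(m),
        resid_vars=pd.Series([1.0]),
        a_hat=coeffs,
        pe_hat=coeffs.iloc[:0],
        knot_gdds=KNOTS,
        loglik=0.0,
        loglik_history=[0.0],
        converged=True,
        n_iter=0,
    )


def test_curves_interpolate_coefficients():
    coeffs = pd.DataFrame(
        [[0.1, 0.3, 0.2], [0.0, -0.1, 0.4]], index=["H1", "H2"], columns=["k0", "k1", "k2"]
    )
    fit = _fit_with_coeffs(coeffs)
    out = v.genetic_curves(fit, KNOTS)
    at_knots = out.pivot(index="hybrid", columns="gdd", values="genetic_value")
    assert np.allclose(at_knots.loc["H1", KNOTS], coeffs.loc["H1"])
    # group of one hybrid equals that hybrid's curve
    grouped = v.genetic_curves(fit, [670.0], groups={"solo": ["H2"]})
    direct = 0.5 * (coeffs.loc["H2", "k0"] + coeffs.loc["H2", "k1"])
    assert grouped["genetic_value"].iloc[0] == pytest.approx(direct)


def test_group_curves_preserve_separation_everywhere():
    rng = np.random.default_rng(8)
    high = pd.DataFrame(1.0 + 0.1 * rng.random((5, 3)), columns=["k0", "k1", "k2"],
                        index=[f"hi{i}" for i in range(5)])
    low = pd.DataFrame(-1.0 - 0.1 * rng.random((5, 3)), columns=["k0", "k1", "k2"],
                       index=[f"lo{i}" for i in range(5)])
    fit = _fit_with_coeffs(pd.concat([high, low]))
    grid = np.linspace(524, 1501, 11)
    out = v.genetic_curves(fit, grid, groups={"high": list(high.index), "low": list(low.index)})
    wide = out.pivot(index="gdd", columns="group", values="genetic_value")
    assert (wide["high"] > wide["low"]).all()


def test_empty_group_raises():
    fit = _fit_with_coeffs(
        pd.DataFrame([[0.0, 0.0, 0.0]], index=["H1"], columns=["k0", "k1", "k2"])
    )
    with pytest.raises(ParameterError):
        v.genetic_curves(fit, [600.0], groups={"none": []})
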