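"""Statistical structure of the synthetic trial generator."""

import numpy as np
import pandas as pd
import pytest

import vigblup as v
from vigblup.errors import ParameterError
from vigblup.io import identity_grm
from vigblup.simulate import mean_vi_curve


# ---------------------------------------------------------------------------
# parents, hybrids, layout, weather


def test_parents_inbred_limit_has_no_heterozygotes():
    panel = v.simulate_parents(4, 10, (0.3, 0.5), seed=1, het_rate=0.0)
    assert np.isin(panel.calls, (0.0, 2.0)).all()


def test_parents_reproducible_and_distinct_by_seed():
    a = v.simulate_parents(20, 50, seed=3)
    b = v.simulate_parents(20, 50, seed=3)
    c = v.simulate_parents(20, 50, seed=4)
    assert np.array_equal(a.calls, b.calls)
    assert not np.array_equal(a.calls, c.calls)


def test_parents_realized_frequencies_track_maf_range():
    panel = v.simulate_parents(200, 2000, (0.05, 0.5), seed=7, het_rate=0.0)
    freq = panel.calls.mean(axis=0) / 2.0
    freq = np.minimum(freq, 1 - freq)
    se = np.sqrt(0.25 / 200)  # worst-case binomial sampling error per marker
    assert freq.max() <= 0.5
    assert freq.min() >= 0.05 - 4.5 * se
    # the bulk must sit inside the requested interval
    assert np.mean((freq >= 0.05) & (freq <= 0.5)) > 0.9


def test_parents_bad_maf_range_raises():
    with pytest.raises(ParameterError):
        v.simulate_parents(5, 5, (0.0, 0.6), seed=0)


def test_hybrids_exhaustive_cross_and_single_cross():
    mothers = v.simulate_parents(2, 5, seed=1, panel="maternal")
    fathers = v.simulate_parents(2, 5, seed=2, panel="paternal")
    ped = v.simulate_hybrids(mothers, fathers, 4, seed=0)
    crosses = set(zip(ped["mother_id"], ped["father_id"]))
    assert len(crosses) == 4  # all distinct crosses present
    single = v.simulate_hybrids(
        v.simulate_parents(1, 5, seed=1), v.simulate_parents(1, 5, seed=2), 1
    )
    assert len(single) == 1
    with pytest.raises(ParameterError):
        v.simulate_hybrids(mothers, fathers, 5, seed=0)


def test_hybrids_reproducible():
    mothers = v.simulate_parents(6, 5, seed=1, panel="maternal")
    fathers = v.simulate_parents(6, 5, seed=2, panel="paternal")
    a = v.simulate_hybrids(mothers, fathers, 10, seed=9)
    b = v.simulate_hybrids(mothers, fathers, 10, seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_layout_is_rcbd():
    layout = v.build_field_layout([f"H{i}" for i in range(10)], n_reps=2, seed=0)
    counts = layout.groupby(["replicate", "hybrid_id"]).size()
    assert (counts == 1).all()  # each hybrid exactly once per block
    assert layout["plot_id"].is_unique


def test_weather_constraints_and_temperature_extremes():
    weather = v.simulate_weather("2016-05-10", 120, seed=0)
    assert len(weather) == 120
    assert (weather["tmin"] <= weather["tmax"]).all()
    assert (weather["tmax"] > 30).any()  # exercises the 30 °C cap
    assert (weather["tmin"] < 10).any()  # exercises the 10 °C base


# ---------------------------------------------------------------------------
# VI trajectories


def _degenerate_config(resid=1e-12):
    m = 3
    return v.SimulationConfig(
        n_hybrids=6,
        Sigma_a_true=np.zeros((m, m)),
        Sigma_pe_true=np.zeros((m, m)),
        resid_vars_true=(resid,) * 5,
        seed=5,
    )


def test_trajectories_degenerate_to_the_mean_curve():
    cfg = _degenerate_config()
    hybrids = [f"H{i}" for i in range(6)]
    layout = v.build_field_layout(hybrids, seed=1)
    long, coeffs = v.simulate_vi_trajectories(cfg, layout, identity_grm(hybrids))
    expected = mean_vi_curve(long["gdd"].to_numpy(), cfg.flight_gdds)
    assert np.allclose(long["value"].to_numpy(), expected, atol=1e-5)
    assert np.allclose(coeffs.to_numpy(), 0.0)
    # mean curve itself stays inside the plausible VI band
    assert (expected > 0.2).all() and (expected < 0.95).all()


def test_replicates_differ_only_through_pe_and_residual_draws():
    cfg = _degenerate_config()
    cfg = v.SimulationConfig(
        n_hybrids=6,
        Sigma_a_true=cfg.Sigma_a_true,
        Sigma_pe_true=np.zeros((3, 3)),
        resid_vars_true=(1e-12,) * 5,
        seed=5,
    )
    hybrids = [f"H{i}" for i in range(6)]
    layout = v.build_field_layout(hybrids, seed=1)
    long, _ = v.simulate_vi_trajectories(cfg, layout, identity_grm(hybrids))
    wide = long.pivot_table(index="hybrid_id", columns=["replicate", "time_label"], values="value")
    # with pe = 0 and residuals ≈ 0 the two replicates of a hybrid coincide
    assert np.allclose(wide["rep1"].to_numpy(), wide["rep2"].to_numpy(), atol=1e-5)


def test_coefficient_covariance_converges_to_truth():
    cfg = v.SimulationConfig(n_hybrids=500, seed=11)
    hybrids = [f"H{i}" for i in range(500)]
    layout = v.build_field_layout(hybrids, seed=1)
    _, coeffs = v.simulate_vi_trajectories(cfg, layout, identity_grm(hybrids))
    sample_cov = np.cov(coeffs.to_numpy().T)
    truth = cfg.Sigma_a_true
    # Wishart sampling error: sd(S_ij) = sqrt((σ_ii σ_jj + σ_ij²)/n)
    for i in range(3):
        for j in range(3):
            se = np.sqrt((truth[i, i] * truth[j, j] + truth[i, j] ** 2) / 500)
            assert abs(sample_cov[i, j] - truth[i, j]) < 4 * se


def test_non_psd_sigma_rejected():
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues −1, 3
    with pytest.raises(ParameterError):
        v.SimulationConfig(knot_gdds=(524.0, 1501.0), Sigma_a_true=bad, Sigma_pe_true=np.eye(2))


# ---------------------------------------------------------------------------
# end-of-season traits


def _eos_setup(r_g, h2, n=400, seed=21):
    cfg = v.SimulationConfig(n_hybrids=n, r_g_eos=r_g, eos_h2=h2, seed=seed)
    hybrids = [f"H{i:04d}" for i in range(n)]
    layout = v.build_field_layout(hybrids, seed=2)
    grm = identity_grm(hybrids)
    _, coeffs = v.simulate_vi_trajectories(cfg, layout, grm)
    table, truth = v.simulate_end_of_season(cfg, coeffs, grm, layout)
    return cfg, table, truth


def test_eos_zero_correlation_gives_uncorrelated_genetic_values():
    _, _, truth = _eos_setup(r_g=0.0, h2=0.4)
    r = np.corrcoef(truth["true_genetic_value"], truth["true_vi_genetic_value"])[0, 1]
    assert abs(r) < 1e-8


def test_eos_perfect_correlation_and_heritability_is_affine_in_vi_genetics():
    cfg, table, truth = _eos_setup(r_g=1.0, h2=1.0, n=100)
    merged = table.merge(truth, on="hybrid_id")
    r = np.corrcoef(merged["yield"], merged["true_vi_genetic_value"])[0, 1]
    assert r == pytest.approx(1.0, abs=1e-8)


def test_eos_realized_heritability_matches_target():
    cfg, table, truth = _eos_setup(r_g=0.9, h2=0.4)
    g = truth.set_index("hybrid_id")["true_genetic_value"]
    plot_g = g.loc[table["hybrid_id"]].to_numpy()
    resid = table["yield"].to_numpy() - cfg.eos_mean - plot_g
    var_g = float(np.var(plot_g, ddof=1))
    var_e = float(np.var(resid, ddof=1))
    assert var_g / (var_g + var_e) == pytest.approx(0.4, abs=0.03)


def test_eos_invalid_correlation_rejected():
    with pytest.raises(ParameterError):
        v.SimulationConfig(r_g_eos=1.5)


# ---------------------------------------------------------------------------
# determinism of the full generator


def test_dataset_bit_reproducible():
    a = v.simulate_dataset(v.SimulationConfig(n_hybrids=20, n_maternal=6, n_paternal=6, n_markers=80, seed=42))
    b = v.simulate_dataset(v.SimulationConfig(n_hybrids=20, n_maternal=6, n_paternal=6, n_markers=80, seed=42))
    assert np.array_equal(a["maternal"].calls, b["maternal"].calls)
    pd.testing.assert_frame_equal(a["vi_long"], b["vi_long"])
    pd.testing.assert_frame_equal(a["eos"], b["eos"])
    c = v.simulate_dataset(v.SimulationConfig(n_hybrids=20, n_maternal=6, n_paternal=6, n_markers=80, seed=43))
    assert not np.allclose(a["vi_long"]["value"], c["vi_long"]["value"])
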