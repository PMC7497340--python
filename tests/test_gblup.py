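"""REML engine and GBLUP layer: oracle equivalence, recovery, predictions."""

import numpy as np
import pandas as pd
import pytest

import vigblup as v
from vigblup.errors import (
    IdentifiabilityError,
    ParameterError,
    PedigreeError,
    UndefinedValueError,
)
from vigblup.grm import RelationshipMatrix
from vigblup.io import identity_grm

from conftest import make_st_pheno


# ---------------------------------------------------------------------------
# heritability and correlation arithmetic


@pytest.mark.parametrize(
    "sigma_a, sigma_e, expected",
    [
        (607.70, 792.10, 0.43),  # grain yield, one site-year
        (308.84, 684.40, 0.31),  # grain yield, another site-year
        (4.89, 0.62, 0.89),  # grain moisture
        (0.0, 5.0, 0.0),
    ],
)
def test_heritability_ratio(sigma_a, sigma_e, expected):
    assert v.heritability(sigma_a, sigma_e) == pytest.approx(expected, abs=0.005)


def test_heritability_undefined_when_both_zero():
    with pytest.raises(UndefinedValueError):
        v.heritability(0.0, 0.0)


@pytest.mark.parametrize(
    "sigma, expected",
    [
        ([[4, 2], [2, 4]], 0.5),
        ([[1, 0], [0, 9]], 0.0),
        ([[2, -2], [-2, 2]], -1.0),
    ],
)
def test_genetic_correlation(sigma, expected):
    assert v.genetic_correlation(np.array(sigma, float)) == pytest.approx(expected)


def test_genetic_correlation_zero_diagonal_undefined():
    with pytest.raises(UndefinedValueError):
        v.genetic_correlation(np.array([[0.0, 0.0], [0.0, 1.0]]))


# ---------------------------------------------------------------------------
# BLUP solutions vs dense Henderson / GLS oracles at fixed components


def henderson_oracle(y, X, Z, G, sigma_a2, sigma_e2):
    """Dense mixed-model equations, solved directly."""
    k = sigma_e2 / sigma_a2
    Ginv = np.linalg.inv(G)
    top = np.hstack([X.T @ X, X.T @ Z])
    bottom = np.hstack([Z.T @ X, Z.T @ Z + k * Ginv])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[: X.shape[1]], sol[X.shape[1] :]


def gls_oracle(y, X, Z, G, sigma_a2, sigma_e2):
    """V-based generalized least squares and BLUP formulas."""
    Vm = sigma_a2 * Z @ G @ Z.T + sigma_e2 * np.eye(len(y))
    Vi = np.linalg.inv(Vm)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    a = sigma_a2 * G @ Z.T @ Vi @ (y - X @ b)
    return b, a


def _tiny_instances():
    rng = np.random.default_rng(99)
    instances = []
    for n_h, reps in [(3, 2), (4, 3), (6, 2)]:
        hybrids = [f"H{i}" for i in range(n_h)]
        a = rng.standard_normal((n_h, n_h))
        G = a @ a.T / n_h + np.eye(n_h)
        rows = []
        for r in range(reps):
            for i, h in enumerate(hybrids):
                rows.append(
                    {"plot_id": f"r{r}_{i}", "hybrid_id": h, "replicate": f"rep{r + 1}",
                     "y": rng.normal(50, 5)}
                )
        pheno = pd.DataFrame(rows)
        grm = RelationshipMatrix(ids=hybrids, values=0.5 * (G + G.T))
        instances.append((pheno, grm))
    return instances


def test_blup_equals_henderson_and_gls_oracles_on_tiny_instances():
    for pheno, grm in _tiny_instances():
        assert len(pheno) <= 18
        spec = v.build_st_spec(pheno, "y", grm)
        fit = v.solve_st_blup(spec, sigma_a2=2.0, sigma_e2=3.0)
        Z = spec.Z.toarray()
        b_h, a_h = henderson_oracle(spec.y, spec.X, Z, grm.values, 2.0, 3.0)
        b_g, a_g = gls_oracle(spec.y, spec.X, Z, grm.values, 2.0, 3.0)
        assert np.allclose(fit.a_hat.to_numpy(), a_h, atol=1e-8)
        assert np.allclose(fit.a_hat.to_numpy(), a_g, atol=1e-8)
        assert np.allclose(fit.b_hat, b_h, atol=1e-8)


# ---------------------------------------------------------------------------
# single-trait REML


def test_st_reml_matches_statsmodels_variance_components():
    statsmodels = pytest.importorskip("statsmodels.formula.api")
    pheno, hybrids, _ = make_st_pheno(80, sigma_a2=4.0, sigma_e2=6.0, seed=5)
    fit = v.fit_st_gblup(v.build_st_spec(pheno, "y", identity_grm(hybrids)))
    ref = statsmodels.mixedlm("y ~ C(replicate)", pheno, groups=pheno["hybrid_id"]).fit(reml=True)
    assert fit.sigma_a2 == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-4)
    assert fit.sigma_e2 == pytest.approx(float(ref.scale), rel=1e-3)


def test_st_loglik_monotone_and_h2_in_unit_interval():
    pheno, hybrids, _ = make_st_pheno(60, sigma_a2=3.0, sigma_e2=9.0, seed=8)
    fit = v.fit_st_gblup(v.build_st_spec(pheno, "y", identity_grm(hybrids)))
    diffs = np.diff(fit.loglik_history)
    assert np.all(diffs >= -1e-10)
    assert 0.0 <= fit.h2 <= 1.0
    assert fit.converged


def test_st_null_genetic_variance_stays_near_boundary():
    hits = 0
    for seed in range(20):
        pheno, hybrids, _ = make_st_pheno(400, sigma_a2=0.0, sigma_e2=10.0, seed=1000 + seed)
        fit = v.fit_st_gblup(v.build_st_spec(pheno, "y", identity_grm(hybrids)), tol=1e-6)
        if fit.sigma_a2 < 0.05 * (fit.sigma_a2 + fit.sigma_e2):
            hits += 1
    assert hits >= 18  # ≥90% of seeds at the boundary


def test_st_pure_em_mode_is_monotone():
    pheno, hybrids, _ = make_st_pheno(40, sigma_a2=5.0, sigma_e2=5.0, seed=3)
    fit = v.fit_st_gblup(
        v.build_st_spec(pheno, "y", identity_grm(hybrids)), method="em", tol=1e-6, max_iter=300
    )
    assert np.all(np.diff(fit.loglik_history) >= -1e-10)


# ---------------------------------------------------------------------------
# multi-trait REML


def test_mt_near_degenerate_secondary_trait_gives_correlation_near_one():
    rng = np.random.default_rng(17)
    pheno, hybrids, _ = make_st_pheno(120, sigma_a2=6.0, sigma_e2=4.0, seed=17)
    pheno["y2"] = pheno["y"] + rng.normal(0, 0.3, len(pheno))
    grm = identity_grm(hybrids)
    fit = v.fit_mt_gblup(
        v.build_st_spec(pheno, "y", grm), v.build_st_spec(pheno, "y2", grm), tol=1e-6
    )
    assert fit.r_g > 0.95
    assert np.all(np.diff(fit.loglik_history) >= -1e-10)


def test_mt_independent_second_trait_leaves_trait1_marginals_nearly_unchanged():
    pheno, hybrids, _ = make_st_pheno(120, sigma_a2=6.0, sigma_e2=4.0, seed=23)
    other, _, _ = make_st_pheno(120, sigma_a2=2.0, sigma_e2=8.0, seed=24)
    pheno["y2"] = other["y"].to_numpy()
    grm = identity_grm(hybrids)
    st = v.fit_st_gblup(v.build_st_spec(pheno, "y", grm))
    mt = v.fit_mt_gblup(
        v.build_st_spec(pheno, "y", grm), v.build_st_spec(pheno, "y2", grm), tol=1e-6
    )
    assert mt.Sigma_g[0, 0] == pytest.approx(st.sigma_a2, rel=0.05)
    assert mt.Sigma_e[0, 0] == pytest.approx(st.sigma_e2, rel=0.05)


def test_mt_requires_joint_plots():
    pheno, hybrids, _ = make_st_pheno(20, sigma_a2=4.0, sigma_e2=4.0, seed=2)
    half1 = pheno.iloc[:20].copy()
    half2 = pheno.iloc[20:].copy().rename(columns={"y": "y2"})
    grm = identity_grm(hybrids)
    with pytest.raises(IdentifiabilityError):
        v.fit_mt_gblup(
            v.build_st_spec(half1, "y", grm), v.build_st_spec(half2, "y2", grm)
        )


def test_mt_requires_shared_relationship_matrix():
    pheno, hybrids, _ = make_st_pheno(10, sigma_a2=4.0, sigma_e2=4.0, seed=2)
    pheno["y2"] = pheno["y"]
    other = RelationshipMatrix(ids=hybrids, values=2.0 * np.eye(10))
    with pytest.raises(ParameterError):
        v.fit_mt_gblup(
            v.build_st_spec(pheno, "y", identity_grm(hybrids)),
            v.build_st_spec(pheno, "y2", other),
        )


# ---------------------------------------------------------------------------
# genetic-value prediction


def test_predict_phenotyped_hybrid_returns_its_blup():
    pheno, hybrids, _ = make_st_pheno(30, sigma_a2=5.0, sigma_e2=5.0, seed=4)
    fit = v.fit_st_gblup(v.build_st_spec(pheno, "y", identity_grm(hybrids)))
    out = v.predict_genetic_values(fit, hybrids[:3])
    assert np.allclose(out["genetic_value"], fit.a_hat.loc[hybrids[:3]])
    with pytest.raises(PedigreeError):
        v.predict_genetic_values(fit, ["ghost"])


def test_predict_unrelated_unphenotyped_hybrid_shrinks_to_zero():
    pheno, hybrids, _ = make_st_pheno(20, sigma_a2=5.0, sigma_e2=5.0, seed=6)
    ids = hybrids + ["loner"]
    grm = identity_grm(ids)  # loner has zero off-diagonal relationships
    fit = v.fit_st_gblup(v.build_st_spec(pheno, "y", grm))
    pred = v.predict_genetic_values(fit, ["loner"])["genetic_value"].iloc[0]
    assert pred == pytest.approx(0.0, abs=1e-10)


def test_predict_clone_of_phenotyped_hybrid_matches_its_blup():
    # clone: G entry to its phenotyped twin equals both diagonals
    pheno, hybrids, _ = make_st_pheno(6, sigma_a2=5.0, sigma_e2=5.0, seed=7)
    ids = hybrids + ["clone"]
    values = np.eye(7)
    values[0, 6] = values[6, 0] = 1.0  # clone of hybrids[0]
    grm = RelationshipMatrix(ids=ids, values=values)
    spec = v.build_st_spec(pheno, "y", grm)
    fit = v.solve_st_blup(spec, sigma_a2=5.0, sigma_e2=5.0)
    assert fit.a_hat["clone"] == pytest.approx(fit.a_hat[hybrids[0]], abs=1e-8)
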