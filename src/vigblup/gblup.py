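"""Single- and multi-trait GBLUP with REML variance components.

The single-trait model is

    y = 1μ + X b + Z a + e,    a ~ N(0, σ²_a G),  e ~ N(0, σ²_e I),

with an intercept and replicate as the only fixed effects, hybrids as the
genetic levels structured by the hybrid relationship matrix G, and
narrow-sense heritability h² = σ²_a / (σ²_a + σ²_e).

The bivariate model stacks two such traits with unstructured 2 × 2 genetic
and residual covariances, [a₁ a₂] ~ N(0, Σ_g ⊗ G) and plot-wise residual
pairs ~ N(0, Σ_e). Record sets may differ between traits (a hybrid masked
for trait 1 can keep its trait-2 records), in which case the residual
covariance is informed only by the jointly recorded plots — the standard
unbalanced multi-trait treatment. Genetic effects are predicted for every
hybrid in G, including hybrids without records, which is what genomic
prediction of masked hybrids uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import (
    IdentifiabilityError,
    ParameterError,
    PedigreeError,
    SchemaError,
    UndefinedValueError,
)
from .grm import RelationshipMatrix
from .reml import MixedModelREML, RandomTerm, REMLResult

REQUIRED_PHENO_COLUMNS = ("plot_id", "hybrid_id", "replicate")


@dataclass
class STModelSpec:
    """Design for one trait: response, fixed design, hybrid incidence, G."""

    y: np.ndarray
    X: np.ndarray
    Z: sp.csr_matrix  # plots × hybrids (columns span every id in G)
    G: RelationshipMatrix
    plot_ids: list[str]
    trait: str

    def __post_init__(self) -> None:
        if not (len(self.y) == self.X.shape[0] == self.Z.shape[0] == len(self.plot_ids)):
            raise SchemaError("y, X, Z and plot_ids must agree in length")
        if self.Z.shape[1] != self.G.n:
            raise SchemaError("Z columns must match the relationship matrix dimension")


def build_st_spec(pheno: pd.DataFrame, trait: str, grm: RelationshipMatrix) -> STModelSpec:
    """Assemble an ST-GBLUP design from a tidy plot table.

    ``pheno`` needs columns ``plot_id, hybrid_id, replicate`` plus the trait
    column; rows with a missing trait value are dropped (masked records).
    The fixed design is an intercept plus replicate contrasts.
    """
    missing = [c for c in (*REQUIRED_PHENO_COLUMNS, trait) if c not in pheno.columns]
    if missing:
        raise SchemaError(f"phenotype table missing column(s) {missing}")
    data = pheno.loc[pheno[trait].notna()].copy()
    if data.empty:
        raise ParameterError(f"no records with observed {trait!r}")
    y = data[trait].to_numpy(float)
    reps = sorted(data["replicate"].astype(str).unique())
    X = np.ones((len(data), 1 + max(len(reps) - 1, 0)))
    for k, rep in enumerate(reps[1:]):
        X[:, 1 + k] = (data["replicate"].astype(str) == rep).to_numpy(float)
    hybrid_index = grm.index_of([str(h) for h in data["hybrid_id"]])
    Z = sp.csr_matrix(
        (np.ones(len(data)), (np.arange(len(data)), hybrid_index)),
        shape=(len(data), grm.n),
    )
    return STModelSpec(
        y=y,
        X=X,
        Z=Z,
        G=grm,
        plot_ids=[str(p) for p in data["plot_id"]],
        trait=trait,
    )


@dataclass
class STFit:
    sigma_a2: float
    sigma_e2: float
    h2: float
    a_hat: pd.Series
    b_hat: np.ndarray
    loglik: float
    loglik_history: list[float]
    converged: bool
    n_iter: int
    se: dict[str, float] | None


@dataclass
class MTFit:
    Sigma_g: np.ndarray
    Sigma_e: np.ndarray
    r_g: float
    r_e: float
    a_hat: pd.DataFrame  # hybrids × [trait1, trait2]
    b_hat: np.ndarray
    loglik: float
    loglik_history: list[float]
    converged: bool
    n_iter: int
    traits: tuple[str, str]


def heritability(sigma_a2: float, sigma_e2: float) -> float:
    """Narrow-sense heritability: σ²_a / (σ²_a + σ²_e)."""
    if sigma_a2 < 0 or sigma_e2 < 0:
        raise ParameterError("variance components must be nonnegative")
    total = sigma_a2 + sigma_e2
    if total == 0:
        raise UndefinedValueError("heritability undefined when both variances are zero")
    return sigma_a2 / total


def genetic_correlation(sigma: np.ndarray) -> float:
    """Correlation σ₁₂ / √(σ₁₁ σ₂₂) from a 2 × 2 covariance matrix."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (2, 2):
        raise ParameterError("expected a 2×2 covariance matrix")
    if sigma[0, 0] <= 0 or sigma[1, 1] <= 0:
        raise UndefinedValueError("correlation undefined with a zero diagonal variance")
    return float(sigma[0, 1] / np.sqrt(sigma[0, 0] * sigma[1, 1]))


def fit_st_gblup(
    spec: STModelSpec,
    tol: float = 1e-8,
    max_iter: int = 500,
    method: str = "ai",
) -> STFit:
    """REML fit of the single-trait GBLUP model.

    Variance components start at half the phenotypic variance each; the
    restricted log-likelihood history is monotone non-decreasing (EM steps
    with average-information acceleration accepted only when improving).
    Non-convergence is flagged on the result, not raised.
    """
    vary = float(np.var(spec.y, ddof=1))
    if vary <= 0:
        raise ParameterError("response has zero variance")
    terms = [
        RandomTerm("genetic", spec.Z, spec.G.values, dim=1, start=np.array([[vary / 2]])),
        RandomTerm("residual", sp.eye(len(spec.y), format="csr"), None, dim=1, start=np.array([[vary / 2]])),
    ]
    engine = MixedModelREML(
        spec.y, spec.X, terms, tol_loglik=tol, max_iter=max_iter, method=method
    )
    res = engine.fit()
    return _st_fit_from(res, spec)


def _st_fit_from(res: REMLResult, spec: STModelSpec) -> STFit:
    sigma_a2 = float(res.sigmas["genetic"][0, 0])
    sigma_e2 = float(res.sigmas["residual"][0, 0])
    se = None
    if res.param_se is not None:
        se = {
            "sigma_a2": float(res.param_se["genetic"][0, 0]),
            "sigma_e2": float(res.param_se["residual"][0, 0]),
        }
    return STFit(
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        h2=heritability(sigma_a2, sigma_e2),
        a_hat=pd.Series(res.blups["genetic"][:, 0], index=spec.G.ids, name=spec.trait),
        b_hat=res.beta,
        loglik=res.loglik,
        loglik_history=res.loglik_history,
        converged=res.converged,
        n_iter=res.n_iter,
        se=se,
    )


def solve_st_blup(spec: STModelSpec, sigma_a2: float, sigma_e2: float) -> STFit:
    """BLUP/GLS solutions at *fixed* variance components (no REML iteration)."""
    if sigma_a2 < 0 or sigma_e2 <= 0:
        raise ParameterError("need sigma_a2 >= 0 and sigma_e2 > 0")
    terms = [
        RandomTerm("genetic", spec.Z, spec.G.values, dim=1, start=np.array([[max(sigma_a2, 1e-300)]])),
        RandomTerm("residual", sp.eye(len(spec.y), format="csr"), None, dim=1, start=np.array([[sigma_e2]])),
    ]
    engine = MixedModelREML(spec.y, spec.X, terms)
    res = engine.evaluate([np.array([[sigma_a2]]), np.array([[sigma_e2]])])
    return _st_fit_from(res, spec)


def fit_mt_gblup(
    spec1: STModelSpec,
    spec2: STModelSpec,
    tol: float = 1e-8,
    max_iter: int = 500,
    method: str = "ai",
) -> MTFit:
    """REML fit of the bivariate GBLUP model with unstructured Σ_g and Σ_e.

    Both traits must reference the same relationship matrix. Residual
    covariance is carried by plots recorded for both traits; at least 3 such
    plots are required for it to be estimable. Interim non-PD covariance
    estimates are bent back to the PSD cone (eigenvalue flooring).
    """
    if spec1.G.ids != spec2.G.ids:
        raise ParameterError("both traits must reference the same relationship matrix")
    if not np.array_equal(spec1.G.values, spec2.G.values):
        raise ParameterError("both traits must reference the same relationship matrix")
    n1, n2 = len(spec1.y), len(spec2.y)
    joint = set(spec1.plot_ids) & set(spec2.plot_ids)
    if len(joint) < 3:
        raise IdentifiabilityError(
            f"only {len(joint)} jointly recorded plots; residual covariance is not estimable"
        )
    # fit on per-trait standardized scales so the two traits condition the
    # covariance blocks equally; back-transform the estimates afterwards
    sd1 = float(np.std(spec1.y, ddof=1)) or 1.0
    sd2 = float(np.std(spec2.y, ddof=1)) or 1.0
    y = np.concatenate([spec1.y / sd1, spec2.y / sd2])
    X = sp.block_diag([sp.csr_matrix(spec1.X), sp.csr_matrix(spec2.X)]).toarray()
    q = spec1.G.n
    z_gen = sp.bmat(
        [[spec1.Z, sp.csr_matrix((n1, q))], [sp.csr_matrix((n2, q)), spec2.Z]], format="csr"
    )
    # residual: one 2-block effect per plot; record (trait t, plot j) loads column t·P + j
    plots = sorted(set(spec1.plot_ids) | set(spec2.plot_ids))
    plot_index = {p: i for i, p in enumerate(plots)}
    n_plots = len(plots)
    rows = np.arange(n1 + n2)
    cols = np.concatenate(
        [
            [plot_index[p] for p in spec1.plot_ids],
            [n_plots + plot_index[p] for p in spec2.plot_ids],
        ]
    ).astype(int)
    z_res = sp.csr_matrix((np.ones(n1 + n2), (rows, cols)), shape=(n1 + n2, 2 * n_plots))
    start_cov = 0.5 * 0.5 * 0.1  # 0.5·√(σ11 σ22)·0.1 on the standardized scale
    start_g = np.array([[0.5, start_cov], [start_cov, 0.5]])
    start_e = start_g.copy()
    terms = [
        RandomTerm("genetic", z_gen, spec1.G.values, dim=2, start=start_g,
                   labels=[spec1.trait, spec2.trait]),
        RandomTerm("residual", z_res, None, dim=2, start=start_e,
                   labels=[spec1.trait, spec2.trait]),
    ]
    engine = MixedModelREML(y, X, terms, tol_loglik=tol, max_iter=max_iter, method=method)
    res = engine.fit()
    scale = np.diag([sd1, sd2])
    sigma_g = scale @ res.sigmas["genetic"] @ scale
    sigma_e = scale @ res.sigmas["residual"] @ scale
    a_hat = pd.DataFrame(
        res.blups["genetic"] * np.array([sd1, sd2]),
        index=spec1.G.ids,
        columns=[spec1.trait, spec2.trait],
    )
    beta = res.beta.copy()
    p1 = spec1.X.shape[1]
    beta[:p1] *= sd1
    beta[p1:] *= sd2
    return MTFit(
        Sigma_g=sigma_g,
        Sigma_e=sigma_e,
        r_g=genetic_correlation(sigma_g),
        r_e=genetic_correlation(sigma_e),
        a_hat=a_hat,
        b_hat=beta,
        loglik=res.loglik,
        loglik_history=res.loglik_history,
        converged=res.converged,
        n_iter=res.n_iter,
        traits=(spec1.trait, spec2.trait),
    )


def predict_genetic_values(fit: STFit | MTFit, hybrid_ids: list[str], trait: str | None = None) -> pd.DataFrame:
    """BLUP genetic values for the requested hybrids (phenotyped or not).

    Prediction for hybrids without records flows through the relationship
    matrix inside the mixed-model equations, so any id present in G at fit
    time has a solution.

    Raises
    ------
    PedigreeError
        For an id absent from the fitted relationship matrix.
    """
    if isinstance(fit, STFit):
        values = fit.a_hat
    else:
        col = trait if trait is not None else fit.traits[0]
        if col not in fit.a_hat.columns:
            raise ParameterError(f"trait {col!r} not in fit (has {list(fit.a_hat.columns)})")
        values = fit.a_hat[col]
    missing = [h for h in hybrid_ids if h not in values.index]
    if missing:
        raise PedigreeError(f"hybrid id(s) {missing[:5]} absent from the fitted relationship matrix")
    return pd.DataFrame(
        {"hybrid_id": list(hybrid_ids), "genetic_value": values.loc[list(hybrid_ids)].to_numpy()}
    )
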