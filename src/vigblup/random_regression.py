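"""Linear-spline random regression of VI growth curves on thermal time.

Time is measured in cumulative growing degree days (GDD) from planting,

    daily GDD = (Tmax + Tmin)/2 − Tbase,   Tbase = 10 °C,

with each daily temperature first floored at Tbase and capped at 30 °C, so
a day can never contribute negatively and hot days saturate.

A record observed at thermal time s between knots k and k+1 loads the two
flanking knots with

    z_k = (GDD_{k+1} − s) / (GDD_{k+1} − GDD_k),   z_{k+1} = 1 − z_k,

and every other knot with exactly zero, giving nonnegative covariables that
sum to one. The model

    y = X b + Z₁ a + Z₂ pe + e

carries one m-vector of genetic spline coefficients per hybrid
(a ~ N(0, Σ_a ⊗ G)), one m-vector of permanent-environment coefficients per
plot (pe ~ N(0, Σ_pe ⊗ I)) absorbing the within-plot correlation of
repeated records, a saturated replicate-by-time fixed mean, and residuals
independent with a separate variance per flight. The fitted Σ_a is a
covariance *function*: genetic covariance between any two thermal times t, s
inside the knot range is z(t)' Σ_a z(s).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import (
    CoverageError,
    ExtrapolationError,
    IdentifiabilityError,
    ParameterError,
    SchemaError,
)
from .grm import RelationshipMatrix
from .reml import MixedModelREML, RandomTerm

T_BASE = 10.0
T_CAP = 30.0


# ---------------------------------------------------------------------------
# thermal time


def daily_gdd(tmax: float, tmin: float) -> float:
    """Growing degree days for one day, base 10 °C, cap 30 °C.

    Raises
    ------
    ParameterError
        If tmin > tmax.
    """
    if tmin > tmax:
        raise ParameterError(f"tmin {tmin} exceeds tmax {tmax}")
    hi = min(max(float(tmax), T_BASE), T_CAP)
    lo = min(max(float(tmin), T_BASE), T_CAP)
    return (hi + lo) / 2.0 - T_BASE


def cumulative_gdd(
    weather: pd.DataFrame,
    planting_date: dt.date | str,
    target_date: dt.date | str,
) -> float:
    """Sum of daily GDD from planting through target date, both inclusive.

    ``weather`` must have columns ``date, tmin, tmax`` and cover every day
    of the span.

    Raises
    ------
    CoverageError
        If any day in the span is missing from the weather table.
    """
    for col in ("date", "tmin", "tmax"):
        if col not in weather.columns:
            raise SchemaError(f"weather table missing column {col!r}")
    planting = pd.Timestamp(planting_date).normalize()
    target = pd.Timestamp(target_date).normalize()
    if target < planting:
        raise ParameterError("target date precedes planting date")
    dates = pd.to_datetime(weather["date"]).dt.normalize()
    span = pd.date_range(planting, target, freq="D")
    table = weather.assign(_d=dates).set_index("_d")
    missing = span.difference(table.index)
    if len(missing):
        raise CoverageError(f"weather table missing {len(missing)} day(s), first: {missing[0].date()}")
    rows = table.loc[span]
    return float(sum(daily_gdd(tx, tn) for tx, tn in zip(rows["tmax"], rows["tmin"])))


# ---------------------------------------------------------------------------
# spline basis


def spline_covariables(gdd_s: float, knot_gdds: np.ndarray) -> np.ndarray:
    """Covariable vector z for one observation at thermal time ``gdd_s``.

    Nonnegative, sums to one, at most two nonzero (flanking) entries; an
    observation exactly at a knot yields that knot's indicator vector.

    Raises
    ------
    ExtrapolationError
        If ``gdd_s`` lies outside [first knot, last knot].
    ParameterError
        If the knots are not strictly increasing or fewer than two.
    """
    knots = np.asarray(knot_gdds, dtype=float)
    if knots.ndim != 1 or knots.size < 2 or not np.all(np.diff(knots) > 0):
        raise ParameterError("knots must be a strictly increasing vector of length >= 2")
    g = float(gdd_s)
    if g < knots[0] or g > knots[-1]:
        raise ExtrapolationError(
            f"time {g} outside knot range [{knots[0]}, {knots[-1]}]; no extrapolation"
        )
    z = np.zeros(knots.size)
    k = int(np.searchsorted(knots, g, side="right") - 1)
    if k == knots.size - 1:  # exactly at the last knot
        z[-1] = 1.0
        return z
    z[k] = (knots[k + 1] - g) / (knots[k + 1] - knots[k])
    z[k + 1] = 1.0 - z[k]
    return z


def spline_basis(gdds: np.ndarray, knot_gdds: np.ndarray) -> np.ndarray:
    """Stack covariable vectors for many observations (rows)."""
    return np.vstack([spline_covariables(g, knot_gdds) for g in np.asarray(gdds, float)])


# ---------------------------------------------------------------------------
# design and fit

LONG_COLUMNS = ("plot_id", "hybrid_id", "replicate", "time_label", "gdd", "value")


@dataclass
class RRDesign:
    """Assembled random-regression design over plot × time records."""

    y: np.ndarray
    X: np.ndarray
    Z_genetic: sp.csr_matrix  # n × (m · n_hybrids), knot-major blocks
    Z_pe: sp.csr_matrix  # n × (m · n_plots)
    knot_gdds: np.ndarray
    time_labels: list[str]  # distinct time points, in GDD order
    time_of_record: np.ndarray  # index into time_labels per record
    hybrid_ids: list[str]
    plot_ids: list[str]
    records: pd.DataFrame


def build_rr_design(
    data: pd.DataFrame,
    knot_gdds: np.ndarray,
    grm: RelationshipMatrix,
) -> RRDesign:
    """Build the design from a tidy longitudinal table.

    ``data`` columns: ``plot_id, hybrid_id, replicate, time_label, gdd,
    value``. The fixed design is saturated replicate × time cell means. The
    genetic design spans every hybrid in ``grm`` (knot-major column blocks),
    so hybrids without records still receive coefficient BLUPs.
    """
    missing = [c for c in LONG_COLUMNS if c not in data.columns]
    if missing:
        raise SchemaError(f"longitudinal table missing column(s) {missing}")
    knots = np.asarray(knot_gdds, dtype=float)
    data = data.loc[data["value"].notna()].copy()
    if data.empty:
        raise ParameterError("no observed records")
    times = (
        data[["time_label", "gdd"]]
        .drop_duplicates()
        .sort_values("gdd")
        .reset_index(drop=True)
    )
    if times["time_label"].duplicated().any():
        raise SchemaError("a time_label maps to more than one gdd value")
    m = knots.size
    if m > len(times):
        raise IdentifiabilityError(
            f"{m} knots exceed the {len(times)} distinct time points"
        )
    y = data["value"].to_numpy(float)
    n = len(data)
    # saturated replicate-by-time cells (cell-means coding, full rank, no intercept)
    cell = data["replicate"].astype(str) + "|" + data["time_label"].astype(str)
    cell_levels = sorted(cell.unique())
    cell_idx = pd.Categorical(cell, categories=cell_levels).codes
    X = np.zeros((n, len(cell_levels)))
    X[np.arange(n), cell_idx] = 1.0
    z_rows = spline_basis(data["gdd"].to_numpy(float), knots)  # n × m
    # basis invariants hold for every observation entering a fit
    if (z_rows < 0).any() or not np.allclose(z_rows.sum(axis=1), 1.0):
        raise ParameterError("spline covariables violate their invariants")
    if (np.count_nonzero(z_rows, axis=1) > 2).any():
        raise ParameterError("spline covariables have more than two nonzero entries")
    hybrid_idx = grm.index_of([str(h) for h in data["hybrid_id"]])
    q = grm.n
    plots = sorted(data["plot_id"].astype(str).unique())
    plot_lookup = {p: i for i, p in enumerate(plots)}
    plot_idx = np.array([plot_lookup[str(p)] for p in data["plot_id"]])
    rows = np.repeat(np.arange(n), m)
    zg_cols = (np.arange(m)[None, :] * q + hybrid_idx[:, None]).ravel()
    zp_cols = (np.arange(m)[None, :] * len(plots) + plot_idx[:, None]).ravel()
    vals = z_rows.ravel()
    keep = vals != 0.0
    z_gen = sp.csr_matrix((vals[keep], (rows[keep], zg_cols[keep])), shape=(n, m * q))
    z_pe = sp.csr_matrix((vals[keep], (rows[keep], zp_cols[keep])), shape=(n, m * len(plots)))
    time_lookup = {t: i for i, t in enumerate(times["time_label"])}
    time_of_record = np.array([time_lookup[t] for t in data["time_label"]])
    return RRDesign(
        y=y,
        X=X,
        Z_genetic=z_gen,
        Z_pe=z_pe,
        knot_gdds=knots,
        time_labels=list(times["time_label"]),
        time_of_record=time_of_record,
        hybrid_ids=list(grm.ids),
        plot_ids=plots,
        records=data.reset_index(drop=True),
    )


@dataclass
class RRFit:
    Sigma_a: np.ndarray  # m × m genetic covariance of spline coefficients
    Sigma_pe: np.ndarray  # m × m permanent-environment covariance
    resid_vars: pd.Series  # per time point
    a_hat: pd.DataFrame  # hybrids × m
    pe_hat: pd.DataFrame  # plots × m
    knot_gdds: np.ndarray
    loglik: float
    loglik_history: list[float]
    converged: bool
    n_iter: int


def fit_random_regression(
    design: RRDesign,
    grm: RelationshipMatrix,
    tol: float = 1e-8,
    max_iter: int = 500,
    method: str = "ai",
) -> RRFit:
    """REML fit of the spline random-regression model.

    Estimates Σ_a (genetic, structured by ⊗G), Σ_pe (permanent environment,
    ⊗I over plots) and one residual variance per flight, plus coefficient
    BLUPs. The restricted log-likelihood history is monotone; interim
    covariance estimates are bent to PSD when needed.
    """
    m = design.knot_gdds.size
    n = design.y.size
    if design.Z_genetic.shape[1] != m * grm.n:
        raise ParameterError("design was built against a different relationship matrix")
    vary = float(np.var(design.y, ddof=1))
    start_block = np.eye(m) * (vary / 3.0) + np.full((m, m), vary / 30.0)
    terms = [
        RandomTerm("genetic", design.Z_genetic, grm.values, dim=m, start=start_block.copy()),
        RandomTerm("pe", design.Z_pe, None, dim=m, start=start_block / 2.0),
    ]
    for ti, label in enumerate(design.time_labels):
        sel = np.flatnonzero(design.time_of_record == ti)
        z_t = sp.csr_matrix(
            (np.ones(sel.size), (sel, np.arange(sel.size))), shape=(n, sel.size)
        )
        terms.append(
            RandomTerm(f"resid:{label}", z_t, None, dim=1, start=np.array([[vary / 3.0]]))
        )
    engine = MixedModelREML(
        design.y, design.X, terms, tol_loglik=tol, max_iter=max_iter, method=method
    )
    res = engine.fit()
    resid = pd.Series(
        [float(res.sigmas[f"resid:{t}"][0, 0]) for t in design.time_labels],
        index=design.time_labels,
        name="residual_variance",
    )
    knot_cols = [f"k{j}" for j in range(m)]
    return RRFit(
        Sigma_a=res.sigmas["genetic"],
        Sigma_pe=res.sigmas["pe"],
        resid_vars=resid,
        a_hat=pd.DataFrame(res.blups["genetic"], index=design.hybrid_ids, columns=knot_cols),
        pe_hat=pd.DataFrame(res.blups["pe"], index=design.plot_ids, columns=knot_cols),
        knot_gdds=design.knot_gdds,
        loglik=res.loglik,
        loglik_history=res.loglik_history,
        converged=res.converged,
        n_iter=res.n_iter,
    )


# ---------------------------------------------------------------------------
# covariance function and curves


def reconstruct_covariance(
    sigma_a: np.ndarray, knot_gdds: np.ndarray, t: float, s: float | None = None
) -> float:
    """Genetic (co)variance between thermal times t and s: z(t)' Σ_a z(s).

    With ``s`` omitted (or equal to t) this is the genetic variance at t.
    Both times must lie inside the knot range.
    """
    sigma_a = np.asarray(sigma_a, dtype=float)
    knots = np.asarray(knot_gdds, dtype=float)
    if sigma_a.shape != (knots.size, knots.size):
        raise ParameterError("Sigma_a dimension must match the number of knots")
    z_t = spline_covariables(t, knots)
    z_s = z_t if s is None or s == t else spline_covariables(s, knots)
    return float(z_t @ sigma_a @ z_s)


def reconstruct_covariance_grid(
    sigma_a: np.ndarray, knot_gdds: np.ndarray, gdds: np.ndarray
) -> pd.DataFrame:
    """Full reconstructed (co)variance matrix over a set of thermal times."""
    gdds = np.asarray(gdds, dtype=float)
    basis = spline_basis(gdds, knot_gdds)
    values = basis @ np.asarray(sigma_a, float) @ basis.T
    return pd.DataFrame(0.5 * (values + values.T), index=gdds, columns=gdds)


def genetic_curves(
    fit: RRFit,
    gdd_grid: np.ndarray,
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Piecewise-linear genetic curves per hybrid, or means per named group.

    Evaluates Σ_k z_k(t)·â_k at each grid point; at a knot the curve equals
    that knot's coefficient. Returns long format with columns
    ``(hybrid | group), gdd, genetic_value``.

    Raises
    ------
    ParameterError
        For an empty group or a group member without coefficients.
    """
    grid = np.asarray(gdd_grid, dtype=float)
    basis = spline_basis(grid, fit.knot_gdds)  # len(grid) × m
    curves = fit.a_hat.to_numpy() @ basis.T  # hybrids × len(grid)
    if groups is None:
        frame = pd.DataFrame(curves, index=fit.a_hat.index, columns=grid)
        out = frame.reset_index(names="hybrid").melt(
            id_vars="hybrid", var_name="gdd", value_name="genetic_value"
        )
        return out.astype({"gdd": float})
    rows = []
    for name, members in groups.items():
        if not members:
            raise ParameterError(f"group {name!r} is empty")
        missing = [h for h in members if h not in fit.a_hat.index]
        if missing:
            raise ParameterError(f"group {name!r} members {missing[:5]} have no coefficients")
        member_curves = fit.a_hat.loc[list(members)].to_numpy() @ basis.T
        mean_curve = member_curves.mean(axis=0)
        rows.append(pd.DataFrame({"group": name, "gdd": grid, "genetic_value": mean_curve}))
    return pd.concat(rows, ignore_index=True)
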