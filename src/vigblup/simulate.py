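"""Synthetic trial generator with the statistical structure the models assume.

Emulates one site-year of a hybrid maize trial phenotyped by drone: two
unrelated parental inbred panels genotyped at independent biallelic SNPs,
single-cross hybrids laid out in a randomized complete block design (RCBD)
with two replicates, a daily weather series driving a growing-degree-day
axis, 4–6 flights per season yielding one VI value per plot per flight, and
end-of-season traits (yield- and moisture-like) genetically correlated with
the VI genetic value at a chosen flight.

VI trajectories follow exactly the linear-spline random-regression model:
hybrid spline coefficients a ~ N(0, Σ_a ⊗ G), plot permanent-environment
coefficients pe ~ N(0, Σ_pe), per-flight residual variances, on top of a
logistic mean curve in thermal time that saturates the way canopy NDVI
does. True coefficients and variance components are returned so recovery
tests can score the estimators.

All randomness flows from named substreams of a single master seed, so any
stage can be regenerated independently and bit-identically.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .grm import GenotypeMatrix, RelationshipMatrix

#: default flight schedule on the cumulative-GDD axis (five flights spanning
#: late vegetative through late reproductive stages of a temperate season)
DEFAULT_FLIGHT_GDDS = (524.0, 759.0, 816.0, 1157.0, 1501.0)
#: default knots: first, middle, last flight
DEFAULT_KNOT_GDDS = (524.0, 816.0, 1501.0)


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of a master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def _check_psd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    if not np.allclose(mat, mat.T):
        raise ParameterError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(mat)[0] < -1e-8 * max(1.0, float(np.trace(mat))):
        raise ParameterError(f"{name} must be positive semidefinite")
    return mat


def psd_sqrt(mat: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root; negative eigenvalues are floored at zero."""
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    eigval, eigvec = np.linalg.eigh(0.5 * (mat + mat.T))
    return (eigvec * np.sqrt(np.maximum(eigval, 0.0))) @ eigvec.T


def _default_sigma(variances: tuple[float, ...], corr: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.asarray(variances))
    return corr * np.outer(sd, sd)


_DEFAULT_CORR_A = np.array([[1.0, 0.7, 0.5], [0.7, 1.0, 0.8], [0.5, 0.8, 1.0]])


@dataclass
class SimulationConfig:
    """True parameters of one simulated site-year.

    Defaults describe a realistic temperate hybrid trial: VI genetic and
    permanent-environment (co)variances on the NDVI scale (phenotypic
    variance a few thousandths, per-flight heritability roughly 0.4–0.7 and
    rising through the season), an end-of-season trait on a grain-yield-like
    scale with heritability 0.3, and a strong (0.9) genetic correlation with
    the VI at the mid-season flight.
    """

    n_maternal: int = 30
    n_paternal: int = 30
    n_markers: int = 500
    n_hybrids: int = 200
    n_reps: int = 2
    flight_gdds: tuple[float, ...] = DEFAULT_FLIGHT_GDDS
    knot_gdds: tuple[float, ...] = DEFAULT_KNOT_GDDS
    Sigma_a_true: np.ndarray = field(
        default_factory=lambda: _default_sigma((0.002, 0.004, 0.005), _DEFAULT_CORR_A)
    )
    Sigma_pe_true: np.ndarray = field(
        default_factory=lambda: _default_sigma((0.0010, 0.0015, 0.0020), _DEFAULT_CORR_A)
    )
    resid_vars_true: tuple[float, ...] = (0.0010, 0.0012, 0.0012, 0.0015, 0.0015)
    eos_h2: float = 0.3
    r_g_eos: float = 0.9
    eos_vi_flight: int = 2  # flight index whose genetic value drives the trait
    eos_mean: float = 150.0
    eos_phen_var: float = 1650.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    site_year: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        m = len(self.knot_gdds)
        self.Sigma_a_true = _check_psd(self.Sigma_a_true, "Sigma_a_true")
        self.Sigma_pe_true = _check_psd(self.Sigma_pe_true, "Sigma_pe_true")
        if self.Sigma_a_true.shape != (m, m) or self.Sigma_pe_true.shape != (m, m):
            raise ParameterError("Sigma_a_true/Sigma_pe_true must be m×m for m knots")
        knots = np.asarray(self.knot_gdds, float)
        flights = np.asarray(self.flight_gdds, float)
        if not np.all(np.diff(knots) > 0):
            raise ParameterError("knot_gdds must be strictly increasing")
        if not set(np.round(knots, 6)).issubset(set(np.round(flights, 6))):
            raise ParameterError("knot_gdds must be a subset of flight_gdds")
        if knots[0] > flights.min() or knots[-1] < flights.max():
            raise ParameterError("first and last knots must flank every flight")
        if len(self.resid_vars_true) != len(self.flight_gdds):
            raise ParameterError("one residual variance per flight is required")
        if not all(v > 0 for v in self.resid_vars_true):
            raise ParameterError("resid_vars_true must be positive")
        if not 0.0 <= self.eos_h2 <= 1.0:
            raise ParameterError("eos_h2 must lie in [0, 1]")
        if abs(self.r_g_eos) > 1.0:
            raise ParameterError("|r_g_eos| must not exceed 1")
        if not (0 <= self.eos_vi_flight < len(self.flight_gdds)):
            raise ParameterError("eos_vi_flight must index a flight")


# ---------------------------------------------------------------------------
# genotypes, pedigree, layout, weather


def simulate_parents(
    n_individuals: int,
    n_markers: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    het_rate: float = 0.005,
    missing_rate: float = 0.0,
    panel: str = "unlabeled",
) -> GenotypeMatrix:
    """Near-homozygous inbred panel at independent biallelic markers.

    Allele frequencies are uniform on ``maf_range``; each line carries a
    single allele per marker (genotype 0 or 2) except for a small
    heterozygote rate (default below the 1% QC screen). Optional missingness
    is injected at random.

    Raises
    ------
    ParameterError
        If ``maf_range`` is not within (0, 0.5] or sizes are nonpositive.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ParameterError(f"maf_range {maf_range} must satisfy 0 < lo <= hi <= 0.5")
    if n_individuals < 1 or n_markers < 1:
        raise ParameterError("need at least one individual and one marker")
    if not 0.0 <= het_rate <= 1.0 or not 0.0 <= missing_rate < 1.0:
        raise ParameterError("het_rate/missing_rate out of range")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_markers)
    calls = 2.0 * (rng.random((n_individuals, n_markers)) < p)
    if het_rate > 0:
        calls[rng.random(calls.shape) < het_rate] = 1.0
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = np.nan
    prefix = {"maternal": "M", "paternal": "P"}.get(panel, "I")
    return GenotypeMatrix(
        individual_ids=[f"{prefix}{i:04d}" for i in range(n_individuals)],
        marker_ids=[f"snp{j:05d}" for j in range(n_markers)],
        calls=calls,
        panel=panel,
    )


def simulate_hybrids(
    maternal: GenotypeMatrix,
    paternal: GenotypeMatrix,
    n_hybrids: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Pedigree of single-cross hybrids: random (mother, father) pairs
    sampled without replacement from the full factorial.

    Raises
    ------
    ParameterError
        If more hybrids are requested than distinct crosses exist.
    """
    n_m, n_p = maternal.n_individuals, paternal.n_individuals
    if n_m == 0 or n_p == 0:
        raise ParameterError("both parental panels must be non-empty")
    if n_hybrids > n_m * n_p:
        raise ParameterError(f"{n_hybrids} hybrids requested but only {n_m * n_p} distinct crosses exist")
    rng = np.random.default_rng(seed)
    pair_codes = rng.choice(n_m * n_p, size=n_hybrids, replace=False)
    mothers = pair_codes // n_p
    fathers = pair_codes % n_p
    return pd.DataFrame(
        {
            "hybrid_id": [f"H{i:04d}" for i in range(n_hybrids)],
            "mother_id": [maternal.individual_ids[i] for i in mothers],
            "father_id": [paternal.individual_ids[j] for j in fathers],
        }
    )


def build_field_layout(
    hybrid_ids: list[str],
    n_reps: int = 2,
    site_year: str = "SIM",
    seed: int = 0,
) -> pd.DataFrame:
    """RCBD layout: every hybrid once per replicate, order randomized within block."""
    if n_reps < 1:
        raise ParameterError("need at least one replicate")
    rng = np.random.default_rng(seed)
    rows = []
    plot = 0
    for rep in range(1, n_reps + 1):
        order = rng.permutation(len(hybrid_ids))
        for k in order:
            rows.append(
                {
                    "plot_id": f"p{plot:05d}",
                    "hybrid_id": hybrid_ids[k],
                    "replicate": f"rep{rep}",
                    "site_year": site_year,
                }
            )
            plot += 1
    return pd.DataFrame(rows)


def simulate_weather(
    planting_date: dt.date | str,
    n_days: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily Tmin/Tmax (°C) for a temperate growing season.

    A sinusoidal seasonal mean (≈17 °C at planting, ≈25 °C mid-season) with
    ±7 °C diurnal spread and day-to-day noise, so cool early days dip below
    the 10 °C base temperature and midsummer days exceed the 30 °C cap —
    both GDD clamps are exercised. Tmin ≤ Tmax holds on every row.
    """
    if n_days < 1:
        raise ParameterError("n_days must be at least 1")
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(planting_date).normalize()
    days = np.arange(n_days)
    seasonal = 17.0 + 8.0 * np.sin(np.pi * np.minimum(days / 140.0, 1.0))
    spread = 7.0 + rng.normal(0.0, 1.0, n_days).clip(-3.0, 3.0)
    noise = rng.normal(0.0, 2.5, n_days)
    tmax = seasonal + spread + noise
    tmin = seasonal - spread + noise
    return pd.DataFrame(
        {
            "date": pd.date_range(start, periods=n_days, freq="D").date,
            "tmin": np.round(tmin, 2),
            "tmax": np.round(tmax, 2),
        }
    )


# ---------------------------------------------------------------------------
# longitudinal VI phenotypes


def mean_vi_curve(gdd: np.ndarray, flight_gdds: tuple[float, ...] = DEFAULT_FLIGHT_GDDS) -> np.ndarray:
    """Logistic mean curve in thermal time, saturating inside (0.2, 0.95).

    Mimics the way canopy NDVI rises through canopy closure and saturates;
    the center and scale are tied to the flight window so the curve sweeps
    its range over the observed season.
    """
    gdd = np.asarray(gdd, dtype=float)
    lo, hi = float(min(flight_gdds)), float(max(flight_gdds))
    center = 0.5 * (lo + hi)
    scale = max((hi - lo) / 8.0, 1.0)
    return 0.2 + 0.72 / (1.0 + np.exp(-(gdd - center) / scale))


def simulate_vi_trajectories(
    config: SimulationConfig,
    layout: pd.DataFrame,
    grm: RelationshipMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot × flight VI values under the spline random-regression model.

    Returns the tidy longitudinal table
    (``plot_id, hybrid_id, replicate, time_label, gdd, value``) and the true
    genetic spline coefficients (hybrids × knots) for recovery tests.
    Hybrid coefficient vectors have covariance Σ_a_true ⊗ G across hybrids;
    plot permanent-environment vectors are iid N(0, Σ_pe_true); residuals
    are independent with the per-flight true variances.
    """
    from .random_regression import spline_basis  # local import to avoid a cycle

    hybrids = list(grm.ids)
    missing = set(layout["hybrid_id"].astype(str)) - set(hybrids)
    if missing:
        raise ParameterError(f"layout hybrids {sorted(missing)[:5]} absent from the GRM")
    rng = substream(config.seed, "vi_trajectories")
    m = len(config.knot_gdds)
    q = len(hybrids)
    root_g = psd_sqrt(grm.values)
    root_a = psd_sqrt(config.Sigma_a_true)
    coeffs = root_g @ rng.standard_normal((q, m)) @ root_a.T  # rows: hybrids
    true_coeffs = pd.DataFrame(coeffs, index=hybrids, columns=[f"k{j}" for j in range(m)])
    root_pe = psd_sqrt(config.Sigma_pe_true)
    plots = layout["plot_id"].astype(str).tolist()
    pe = rng.standard_normal((len(plots), m)) @ root_pe.T
    flights = np.asarray(config.flight_gdds, float)
    basis = spline_basis(flights, np.asarray(config.knot_gdds, float))  # flights × m
    mean_curve = mean_vi_curve(flights, config.flight_gdds)
    hybrid_row = true_coeffs.loc[layout["hybrid_id"].astype(str)].to_numpy()  # plots × m
    records = []
    for t, gdd in enumerate(flights):
        z = basis[t]
        e = rng.normal(0.0, np.sqrt(config.resid_vars_true[t]), len(plots))
        value = mean_curve[t] + hybrid_row @ z + pe @ z + e
        records.append(
            pd.DataFrame(
                {
                    "plot_id": plots,
                    "hybrid_id": layout["hybrid_id"].astype(str).to_numpy(),
                    "replicate": layout["replicate"].astype(str).to_numpy(),
                    "site_year": layout["site_year"].astype(str).to_numpy()
                    if "site_year" in layout.columns
                    else config.site_year,
                    "time_label": f"t{t + 1}",
                    "gdd": gdd,
                    "value": value,
                }
            )
        )
    long = pd.concat(records, ignore_index=True)
    return long, true_coeffs


def simulate_end_of_season(
    config: SimulationConfig,
    true_coeffs: pd.DataFrame,
    grm: RelationshipMatrix,
    layout: pd.DataFrame,
    seed: int | None = None,
    trait: str = "yield",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-level end-of-season trait with known genetic link to the VI.

    The hybrid genetic value is r_g_eos times the standardized VI genetic
    value at the chosen flight plus √(1 − r²) times an independent
    G-structured deviate (orthogonalized in sample, so the realized genetic
    correlation hits the target); genetic and residual scales are set
    empirically so the realized heritability matches ``eos_h2`` on the
    ``eos_phen_var`` scale. Returns the plot table
    (``plot_id, hybrid_id, replicate, value``) and a per-hybrid truth table.
    """
    from .random_regression import spline_covariables

    rng = substream(config.seed if seed is None else seed, f"eos:{trait}")
    hybrids = list(grm.ids)
    z_star = spline_covariables(
        config.flight_gdds[config.eos_vi_flight], np.asarray(config.knot_gdds, float)
    )
    vi_genetic = true_coeffs.loc[hybrids].to_numpy() @ z_star
    v = _standardize(vi_genetic)
    u = psd_sqrt(grm.values) @ rng.standard_normal(len(hybrids))
    u = _standardize(u - v * float(v @ u) / float(v @ v))  # sample-orthogonal part
    r = config.r_g_eos
    g = r * v + np.sqrt(max(0.0, 1.0 - r * r)) * u
    sd_g = float(np.std(g, ddof=1))
    g = g / sd_g if sd_g > 0 else g
    genetic_sd = np.sqrt(config.eos_h2 * config.eos_phen_var)
    resid_sd = np.sqrt((1.0 - config.eos_h2) * config.eos_phen_var)
    g_scaled = pd.Series(g * genetic_sd, index=hybrids)
    e = rng.standard_normal(len(layout))
    e = _standardize(e) * resid_sd if resid_sd > 0 else np.zeros(len(layout))
    plot_genetic = g_scaled.loc[layout["hybrid_id"].astype(str)].to_numpy()
    table = pd.DataFrame(
        {
            "plot_id": layout["plot_id"].astype(str),
            "hybrid_id": layout["hybrid_id"].astype(str),
            "replicate": layout["replicate"].astype(str),
            "site_year": layout["site_year"].astype(str)
            if "site_year" in layout.columns
            else config.site_year,
            trait: config.eos_mean + plot_genetic + e,
        }
    )
    truth = pd.DataFrame(
        {
            "hybrid_id": hybrids,
            "true_genetic_value": g_scaled.to_numpy(),
            "true_vi_genetic_value": vi_genetic,
        }
    )
    truth.attrs["residuals"] = e
    return table, truth


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return x - float(np.mean(x))
    return (x - float(np.mean(x))) / sd


# ---------------------------------------------------------------------------
# bivariate plot traits (for multi-trait recovery studies)


def simulate_bivariate(
    n_hybrids: int,
    n_reps: int = 2,
    h2: tuple[float, float] = (0.3, 0.3),
    r_g: float = 0.8,
    r_e: float = 0.2,
    phen_var: tuple[float, float] = (1.0, 1.0),
    grm: RelationshipMatrix | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two plot-level traits with prescribed heritabilities and correlations.

    Genetic values are drawn with covariance Σ_g ⊗ G (G = identity when no
    GRM is given); plot residual pairs are iid with correlation ``r_e``.
    Returns the plot table (both trait columns) and the hybrid truth table.
    """
    if not all(0.0 <= h <= 1.0 for h in h2):
        raise ParameterError("heritabilities must lie in [0, 1]")
    if abs(r_g) > 1 or abs(r_e) > 1:
        raise ParameterError("correlations must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    if grm is None:
        hybrids = [f"H{i:04d}" for i in range(n_hybrids)]
        root_g = None
    else:
        if grm.n != n_hybrids:
            raise ParameterError("grm dimension must equal n_hybrids")
        hybrids = list(grm.ids)
        root_g = psd_sqrt(grm.values)
    g_sd = np.sqrt([h2[t] * phen_var[t] for t in (0, 1)])
    e_sd = np.sqrt([(1 - h2[t]) * phen_var[t] for t in (0, 1)])
    sigma_g = np.array([[1.0, r_g], [r_g, 1.0]])
    raw = rng.standard_normal((n_hybrids, 2)) @ psd_sqrt(sigma_g).T
    if root_g is not None:
        raw = root_g @ raw
    genetic = raw * g_sd
    sigma_e = np.array([[1.0, r_e], [r_e, 1.0]])
    layout = build_field_layout(hybrids, n_reps=n_reps, seed=seed + 1)
    resid = rng.standard_normal((len(layout), 2)) @ psd_sqrt(sigma_e).T * e_sd
    gmap = pd.DataFrame(genetic, index=hybrids, columns=["g1", "g2"])
    gg = gmap.loc[layout["hybrid_id"]].to_numpy()
    table = layout.copy()
    table["trait1"] = 10.0 + gg[:, 0] + resid[:, 0]
    table["trait2"] = 5.0 + gg[:, 1] + resid[:, 1]
    truth = gmap.reset_index(names="hybrid_id")
    return table, truth


# ---------------------------------------------------------------------------
# one-call dataset


def simulate_dataset(config: SimulationConfig) -> dict:
    """Generate a full site-year: genotypes → pedigree → GRM → layout →
    VI trajectories → end-of-season traits. Returns a dict of artifacts."""
    from .grm import hybrid_grm, impute_mode, qc_markers, vanraden_grm

    maternal = simulate_parents(
        config.n_maternal, config.n_markers, config.maf_range,
        seed=int(substream(config.seed, "maternal").integers(2**31)), panel="maternal",
    )
    paternal = simulate_parents(
        config.n_paternal, config.n_markers, config.maf_range,
        seed=int(substream(config.seed, "paternal").integers(2**31)), panel="paternal",
    )
    pedigree = simulate_hybrids(
        maternal, paternal, config.n_hybrids,
        seed=int(substream(config.seed, "pedigree").integers(2**31)),
    )
    qc_m, report_m = qc_markers(maternal)
    qc_p, report_p = qc_markers(paternal)
    grm_m = vanraden_grm(impute_mode(qc_m))
    grm_p = vanraden_grm(impute_mode(qc_p))
    grm_h = hybrid_grm(grm_m, grm_p, pedigree)
    layout = build_field_layout(
        pedigree["hybrid_id"].tolist(), n_reps=config.n_reps, site_year=config.site_year,
        seed=int(substream(config.seed, "layout").integers(2**31)),
    )
    vi_long, true_coeffs = simulate_vi_trajectories(config, layout, grm_h)
    eos, eos_truth = simulate_end_of_season(config, true_coeffs, grm_h, layout)
    weather = simulate_weather(
        "2016-05-10", 160, seed=int(substream(config.seed, "weather").integers(2**31))
    )
    return {
        "config": config,
        "maternal": maternal,
        "paternal": paternal,
        "pedigree": pedigree,
        "qc_reports": {"maternal": report_m, "paternal": report_p},
        "grm_maternal": grm_m,
        "grm_paternal": grm_p,
        "grm_hybrid": grm_h,
        "layout": layout,
        "vi_long": vi_long,
        "true_coeffs": true_coeffs,
        "eos": eos,
        "eos_truth": eos_truth,
        "weather": weather,
    }
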