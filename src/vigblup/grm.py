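"""Marker QC, mode imputation and genomic relationship matrices.

Parental inbred panels are handled separately (maternal and paternal lines
are assumed unrelated), each yielding a VanRaden method-1 additive GRM

    G = W W' / (2 Σ_j p_j (1 − p_j)),   W = M − 2p,

with allele frequencies p_j computed within the panel. Hybrid relationships
are then assembled from the two parental GRMs as

    r_ij = 0.5 (r_{m_i, m_j} + r_{p_i, p_j}),

including the diagonal (i = j uses the parental self-relationships). A small
ridge on the diagonal keeps every GRM positive definite for the mixed-model
equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LinearAlgebraError, ParameterError, PedigreeError, SchemaError


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """SNP calls for one panel: individuals × markers, 0/1/2 with NaN missing."""

    individual_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray  # float array, entries in {0,1,2} or NaN
    panel: str = "unlabeled"

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise SchemaError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals × {len(self.marker_ids)} markers"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise SchemaError("duplicate individual ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise SchemaError("duplicate marker ids")
        observed = self.calls[~np.isnan(self.calls)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise SchemaError("genotype calls must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.individual_ids, columns=self.marker_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, panel: str = "unlabeled") -> "GenotypeMatrix":
        return cls(
            individual_ids=[str(i) for i in frame.index],
            marker_ids=[str(c) for c in frame.columns],
            calls=frame.to_numpy(dtype=float),
            panel=panel,
        )


@dataclass
class QCReport:
    """Per-filter accounting of removed markers.

    Each removed marker is attributed to the *first* failing filter in the
    order missingness → MAF → heterozygosity.
    """

    n_input_markers: int
    removed_missing: list[str] = field(default_factory=list)
    removed_maf: list[str] = field(default_factory=list)
    removed_het: list[str] = field(default_factory=list)

    @property
    def n_removed_missing(self) -> int:
        return len(self.removed_missing)

    @property
    def n_removed_maf(self) -> int:
        return len(self.removed_maf)

    @property
    def n_removed_het(self) -> int:
        return len(self.removed_het)

    @property
    def n_retained(self) -> int:
        return self.n_input_markers - self.n_removed_missing - self.n_removed_maf - self.n_removed_het

    def summary(self) -> str:
        return (
            f"markers in: {self.n_input_markers}; removed missing>thr: {self.n_removed_missing}; "
            f"removed MAF<thr: {self.n_removed_maf}; removed het>thr: {self.n_removed_het}; "
            f"retained: {self.n_retained}"
        )


@dataclass
class RelationshipMatrix:
    """Symmetric additive relationship matrix with its regularization ridge."""

    ids: list[str]
    values: np.ndarray
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise SchemaError(f"relationship matrix shape {self.values.shape} != ({n}, {n})")
        if not np.array_equal(self.values, self.values.T):
            raise LinearAlgebraError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids: list[str]) -> np.ndarray:
        lookup = {k: i for i, k in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise PedigreeError(f"id {exc.args[0]!r} not present in relationship matrix") from exc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, epsilon: float = 0.0) -> "RelationshipMatrix":
        values = frame.to_numpy(dtype=float)
        # CSV round-trips can break exact symmetry in the last bit; resymmetrize.
        values = 0.5 * (values + values.T)
        return cls(ids=[str(i) for i in frame.index], values=values, epsilon=epsilon)


# ---------------------------------------------------------------------------
# marker QC and imputation


def _column_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (missing fraction, MAF, heterozygote rate) over non-missing calls."""
    n = calls.shape[0]
    missing = np.isnan(calls)
    n_obs = n - missing.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        miss_frac = missing.sum(axis=0) / n
        p = np.nansum(calls, axis=0) / (2.0 * n_obs)
        maf = np.minimum(p, 1.0 - p)
        het = np.nansum(calls == 1.0, axis=0) / n_obs
    return miss_frac, maf, het


def qc_markers(
    g: GenotypeMatrix,
    max_missing: float = 0.15,
    min_maf: float = 0.01,
    max_het: float = 0.01,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers failing the missingness, MAF or heterozygosity filters.

    Thresholds follow the usual inbred-panel screen: markers with more than
    ``max_missing`` missing calls, minor allele frequency below ``min_maf``
    or heterozygote rate above ``max_het`` are dropped. MAF and
    heterozygosity are computed over non-missing calls only. Filters are
    applied in the order listed; the report attributes each marker to the
    first filter it fails.

    Raises
    ------
    ParameterError
        On an empty input matrix or if every marker is removed.
    """
    if g.n_markers == 0 or g.n_individuals == 0:
        raise ParameterError("empty genotype matrix")
    miss_frac, maf, het = _column_stats(g.calls)
    report = QCReport(n_input_markers=g.n_markers)
    keep = np.ones(g.n_markers, dtype=bool)
    for j, marker in enumerate(g.marker_ids):
        if miss_frac[j] > max_missing:
            report.removed_missing.append(marker)
            keep[j] = False
        elif np.isnan(maf[j]) or maf[j] < min_maf:
            report.removed_maf.append(marker)
            keep[j] = False
        elif het[j] > max_het:
            report.removed_het.append(marker)
            keep[j] = False
    if not keep.any():
        raise ParameterError("marker QC removed every marker; panel is empty")
    filtered = GenotypeMatrix(
        individual_ids=list(g.individual_ids),
        marker_ids=[m for m, k in zip(g.marker_ids, keep) if k],
        calls=g.calls[:, keep],
        panel=g.panel,
    )
    return filtered, report


def impute_mode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the most frequent call at that marker.

    Ties are broken toward the lower genotype code so the result is
    deterministic. Non-missing calls are never altered.

    Raises
    ------
    ParameterError
        If a marker has no observed calls at all (QC should have removed it).
    """
    calls = g.calls.copy()
    for j in range(calls.shape[1]):
        col = calls[:, j]
        missing = np.isnan(col)
        if not missing.any():
            continue
        observed = col[~missing]
        if observed.size == 0:
            raise ParameterError(f"marker {g.marker_ids[j]!r} has no observed calls to impute from")
        codes, counts = np.unique(observed, return_counts=True)
        mode = codes[np.argmax(counts)]  # np.unique sorts codes → ties go to the lower code
        col[missing] = mode
    return GenotypeMatrix(
        individual_ids=list(g.individual_ids),
        marker_ids=list(g.marker_ids),
        calls=calls,
        panel=g.panel,
    )


# ---------------------------------------------------------------------------
# relationship matrices


def vanraden_grm(g: GenotypeMatrix, epsilon: float = 1e-6) -> RelationshipMatrix:
    """VanRaden method-1 additive GRM for one (imputed, QC-passed) panel.

    G = WW′ / (2 Σ_j p_j(1−p_j)) with W the call matrix centered by twice the
    panel allele frequency. ``epsilon`` is added to the diagonal so the
    result is numerically positive definite.

    Raises
    ------
    ParameterError
        With fewer than 2 individuals or remaining missing calls.
    LinearAlgebraError
        If every marker is monomorphic (zero denominator).
    """
    if g.n_individuals < 2:
        raise ParameterError("need at least 2 individuals for a relationship matrix")
    if np.isnan(g.calls).any():
        raise ParameterError("genotypes contain missing calls; impute before building the GRM")
    p = g.calls.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise LinearAlgebraError("all markers monomorphic: VanRaden denominator is zero")
    w = g.calls - 2.0 * p
    values = (w @ w.T) / denom
    values = 0.5 * (values + values.T)  # exact symmetry against fp drift
    values[np.diag_indices_from(values)] += epsilon
    return RelationshipMatrix(ids=list(g.individual_ids), values=values, epsilon=epsilon)


def hybrid_grm(
    maternal_grm: RelationshipMatrix,
    paternal_grm: RelationshipMatrix,
    pedigree: pd.DataFrame,
    epsilon: float = 1e-6,
) -> RelationshipMatrix:
    """Additive relationships among single-cross hybrids from parental GRMs.

    Assuming maternal and paternal pools are unrelated, the relationship
    between hybrids i and j is the average of their maternal and paternal
    relationships, r_ij = 0.5 (r_{m_i,m_j} + r_{p_i,p_j}), applied to the
    diagonal as well. The result gets ``epsilon`` on the diagonal and, if
    still not positive definite (hybrids sharing both parents make it
    singular), an eigenvalue floor.

    Parameters
    ----------
    pedigree
        Columns ``hybrid_id, mother_id, father_id``; one row per hybrid.

    Raises
    ------
    PedigreeError
        If a parent id is absent from its panel GRM.
    """
    for col in ("hybrid_id", "mother_id", "father_id"):
        if col not in pedigree.columns:
            raise SchemaError(f"pedigree missing column {col!r}")
    if pedigree["hybrid_id"].duplicated().any():
        raise SchemaError("duplicate hybrid ids in pedigree")
    hybrids = [str(h) for h in pedigree["hybrid_id"]]
    mi = maternal_grm.index_of([str(m) for m in pedigree["mother_id"]])
    pi = paternal_grm.index_of([str(p) for p in pedigree["father_id"]])
    gm = maternal_grm.values[np.ix_(mi, mi)]
    gp = paternal_grm.values[np.ix_(pi, pi)]
    values = 0.5 * (gm + gp)
    values = 0.5 * (values + values.T)
    values[np.diag_indices_from(values)] += epsilon
    # Shared-parent hybrids leave the matrix singular; floor the spectrum.
    smallest = float(np.linalg.eigvalsh(values)[0])
    if smallest <= 0.0:
        values[np.diag_indices_from(values)] += epsilon - smallest
    return RelationshipMatrix(ids=hybrids, values=values, epsilon=epsilon)
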