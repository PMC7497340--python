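"""Fivefold hybrid-level cross-validation of genomic prediction.

Folds partition the hybrid set (all plots of a masked hybrid are masked
together). Per fold, the model is fit on the training hybrids' plots,
genetic values are predicted for the masked hybrids through the
relationship matrix, and accuracy is the Pearson correlation between the
masked plots' raw phenotypic values and the predicted genetic value of
their hybrid. The multi-trait variant keeps the secondary trait (a VI at
one flight) observed for *all* hybrids on the identical folds, so any
accuracy gain over the single-trait baseline comes from the genetic
correlation between the VI and the target trait. Variance components are
re-estimated inside each training fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError
from .gblup import build_st_spec, fit_mt_gblup, fit_st_gblup
from .grm import RelationshipMatrix

logger = logging.getLogger("vigblup.cv")


@dataclass
class FoldAssignment:
    """Partition of hybrids into k folds (1..k), reproducible from its seed."""

    assignment: pd.Series  # index hybrid_id, values fold 1..k
    k: int
    seed: int

    def masked_hybrids(self, fold: int) -> list[str]:
        return list(self.assignment.index[self.assignment == fold])

    def to_frame(self) -> pd.DataFrame:
        return self.assignment.rename("fold").rename_axis("hybrid_id").reset_index()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int = -1) -> "FoldAssignment":
        if not {"hybrid_id", "fold"} <= set(frame.columns):
            raise SchemaError("fold table needs columns hybrid_id, fold")
        series = frame.set_index("hybrid_id")["fold"].astype(int)
        return cls(assignment=series, k=int(series.max()), seed=seed)


@dataclass
class CVResult:
    model: str  # "ST" or "MT+<secondary>@<time>"
    trait: str
    fold_accuracies: list[float]
    masked_sizes: list[int]
    excluded_folds: list[int]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def make_folds(hybrid_ids: list[str], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Random hybrid-level partition into k folds with sizes differing by ≤ 1."""
    if k < 2:
        raise ParameterError("need at least 2 folds")
    if len(hybrid_ids) < k:
        raise ParameterError(f"{len(hybrid_ids)} hybrids cannot fill {k} folds")
    if len(set(hybrid_ids)) != len(hybrid_ids):
        raise ParameterError("duplicate hybrid ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(hybrid_ids))
    folds = np.empty(len(hybrid_ids), dtype=int)
    for f, chunk in enumerate(np.array_split(order, k), start=1):
        folds[chunk] = f
    return FoldAssignment(
        assignment=pd.Series(folds, index=list(hybrid_ids)), k=k, seed=seed
    )


def _accuracy(masked_plots: pd.DataFrame, trait: str, predictions: pd.Series) -> float | None:
    """Pearson correlation of plot-level phenotype with the hybrid prediction."""
    obs = masked_plots[trait].to_numpy(float)
    pred = predictions.loc[masked_plots["hybrid_id"].astype(str)].to_numpy(float)
    if np.std(obs) == 0.0 or np.std(pred) == 0.0:
        return None
    return float(np.corrcoef(obs, pred)[0, 1])


def run_st_cv(
    pheno: pd.DataFrame,
    trait: str,
    folds: FoldAssignment,
    grm: RelationshipMatrix,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> CVResult:
    """Single-trait GBLUP cross-validation for one end-of-season trait.

    A fold whose masked set has zero phenotypic variance is flagged and
    excluded from the mean with a warning.
    """
    pheno = pheno.copy()
    pheno["hybrid_id"] = pheno["hybrid_id"].astype(str)
    accuracies, sizes, excluded = [], [], []
    for fold in range(1, folds.k + 1):
        masked = set(folds.masked_hybrids(fold))
        train = pheno.loc[~pheno["hybrid_id"].isin(masked)]
        test = pheno.loc[pheno["hybrid_id"].isin(masked) & pheno[trait].notna()]
        spec = build_st_spec(train, trait, grm)
        fit = fit_st_gblup(spec, tol=tol, max_iter=max_iter)
        acc = _accuracy(test, trait, fit.a_hat)
        sizes.append(len(masked))
        if acc is None:
            logger.warning("fold %d: masked set has zero variance; excluded", fold)
            excluded.append(fold)
        else:
            accuracies.append(acc)
    return CVResult(
        model="ST", trait=trait, fold_accuracies=accuracies,
        masked_sizes=sizes, excluded_folds=excluded,
    )


def run_mt_cv(
    pheno: pd.DataFrame,
    trait: str,
    secondary: pd.DataFrame,
    secondary_name: str,
    folds: FoldAssignment,
    grm: RelationshipMatrix,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> CVResult:
    """Multi-trait GBLUP cross-validation with a VI as secondary trait.

    ``secondary`` is a plot table (``plot_id, hybrid_id, replicate`` plus a
    ``value`` column) for one VI at one flight; it stays observed for every
    hybrid while the target trait is masked fold by fold. Folds must be the
    same object/partition as the single-trait run for the comparison to be
    meaningful.

    Raises
    ------
    ParameterError
        If the secondary trait is missing for more than half the hybrids.
    """
    pheno = pheno.copy()
    pheno["hybrid_id"] = pheno["hybrid_id"].astype(str)
    secondary = secondary.copy()
    secondary["hybrid_id"] = secondary["hybrid_id"].astype(str)
    value_col = "value" if "value" in secondary.columns else secondary_name
    if value_col not in secondary.columns:
        raise SchemaError("secondary table needs a 'value' column")
    covered = set(secondary.loc[secondary[value_col].notna(), "hybrid_id"])
    all_hybrids = set(folds.assignment.index)
    if len(covered & all_hybrids) < 0.5 * len(all_hybrids):
        raise ParameterError("secondary trait missing for more than half the hybrids")
    accuracies, sizes, excluded = [], [], []
    for fold in range(1, folds.k + 1):
        masked = set(folds.masked_hybrids(fold))
        train = pheno.loc[~pheno["hybrid_id"].isin(masked)]
        test = pheno.loc[pheno["hybrid_id"].isin(masked) & pheno[trait].notna()]
        spec1 = build_st_spec(train, trait, grm)
        spec2 = build_st_spec(secondary.rename(columns={value_col: secondary_name}),
                              secondary_name, grm)
        fit = fit_mt_gblup(spec1, spec2, tol=tol, max_iter=max_iter)
        acc = _accuracy(test, trait, fit.a_hat[trait])
        sizes.append(len(masked))
        if acc is None:
            logger.warning("fold %d: masked set has zero variance; excluded", fold)
            excluded.append(fold)
        else:
            accuracies.append(acc)
    return CVResult(
        model=f"MT+{secondary_name}",
        trait=trait,
        fold_accuracies=accuracies,
        masked_sizes=sizes,
        excluded_folds=excluded,
    )
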