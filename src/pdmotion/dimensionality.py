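"""Standardization and PCA variance-explained analysis.

The effective dimensionality of the clinical exam, of the sensor-derived
metric set, and of their union is summarized by the cumulative fraction of
variance explained as a function of the number of principal components
retained. Variables are standardized (mean 0, SD 1, n-1 denominator);
missing metric values are imputed by the cohort median before
standardization; constant columns are dropped with a log entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pdmotion.errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Eigendecomposition of the correlation structure of a standardized
    subjects x variables table."""

    loadings: np.ndarray          # (n_components, n_variables), orthonormal rows
    explained: np.ndarray         # per-component variance fraction, sums to 1
    variable_names: list[str]

    @property
    def cum_explained(self) -> np.ndarray:
        return np.cumsum(self.explained)

    def n_components_for(self, fraction: float) -> int:
        """Smallest number of components explaining at least ``fraction``."""
        return int(np.searchsorted(self.cum_explained, fraction) + 1)

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_components": np.arange(1, self.explained.size + 1),
                "explained": self.explained,
                "cum_explained": self.cum_explained,
            }
        )


def impute_median(table: pd.DataFrame) -> pd.DataFrame:
    """Replace missing values by the per-variable cohort median."""
    return table.fillna(table.median(axis=0, skipna=True))


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each column to mean 0, SD 1 (n-1 denominator).

    Constant columns carry no correlation information and are dropped
    (logged); an all-constant table is an error.
    """
    if table.shape[0] < 2:
        raise ValidationError("standardize needs at least 2 subjects")
    sd = table.std(axis=0, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant) == len(table.columns):
        raise ValidationError("all columns are constant; nothing to standardize")
    if len(constant):
        logger.warning("dropping constant columns: %s", list(constant))
        table = table.drop(columns=constant)
        sd = sd.drop(constant)
    return (table - table.mean(axis=0)) / sd


def pca_curve(table: pd.DataFrame) -> PCAResult:
    """PCA of a standardized table via SVD; components ordered by
    explained variance."""
    if table.shape[0] < 2:
        raise ValidationError("pca needs at least 2 subjects")
    X = table.to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("pca input contains non-finite values (impute first)")
    Xc = X - X.mean(axis=0)
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    var = svals**2
    explained = var / var.sum()
    return PCAResult(loadings=vt, explained=explained, variable_names=list(table.columns))


def combined_pca(updrs_table: pd.DataFrame, metric_table: pd.DataFrame) -> PCAResult:
    """PCA of the column-concatenated standardized tables (aligned rows)."""
    if updrs_table.shape[1] == 0:
        return pca_curve(standardize(impute_median(metric_table)))
    if metric_table.shape[1] == 0:
        return pca_curve(standardize(impute_median(updrs_table)))
    if updrs_table.shape[0] != metric_table.shape[0]:
        raise ValidationError(
            f"subject mismatch: {updrs_table.shape[0]} vs {metric_table.shape[0]} rows"
        )
    left = standardize(impute_median(updrs_table.reset_index(drop=True)))
    right = standardize(impute_median(metric_table.reset_index(drop=True)))
    both = pd.concat([left, right], axis=1)
    return pca_curve(both)


def dimensionality_report(
    updrs_items: pd.DataFrame, metrics: pd.DataFrame
) -> dict[str, PCAResult]:
    """The three variance-explained curves: exam items alone, sensor
    metrics alone, and their union."""
    return {
        "updrs": pca_curve(standardize(impute_median(updrs_items))),
        "metrics": pca_curve(standardize(impute_median(metrics))),
        "combined": combined_pca(updrs_items, metrics),
    }
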