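"""Accuracy metrics, train/test comparison statistics and assembly robustness.

Error is the difference between known and predicted lifespan: absolute
error in years, relative error as a percentage of the known lifespan.
Correlations between known and predicted lifespan default to the log scale
(the model's own scale); R² is reported as the square of Pearson's r.
Train-vs-test correlations are compared with Fisher's z for independent
groups, residual distributions with Student's unpaired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EvaluationReport:
    pearson_r: float
    r_squared: float
    p_value: float
    median_absolute_error: float  # years
    median_relative_error: float  # percent
    per_species: pd.DataFrame

    def summary(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "median_absolute_error_years": self.median_absolute_error,
            "median_relative_error_percent": self.median_relative_error,
        }


def error_metrics(known: float, predicted: float) -> tuple[float, float]:
    """(absolute error in years, relative error in percent of known)."""
    if not known > 0:
        raise ValueError(f"known lifespan must be positive, got {known}")
    absolute = abs(known - predicted)
    return absolute, 100.0 * absolute / known


def correlation_summary(
    known: np.ndarray, predicted: np.ndarray, scale: str = "log"
) -> tuple[float, float, float]:
    """Pearson r, r² and two-sided p (t distribution, n-2 df).

    ``scale='log'`` correlates natural-log values (requires positive
    inputs); ``'raw'`` correlates years directly.
    """
    known = np.asarray(known, float)
    predicted = np.asarray(predicted, float)
    if len(known) < 3:
        raise ValueError("need at least 3 pairs")
    if scale == "log":
        if np.any(known <= 0) or np.any(predicted <= 0):
            raise ValueError("log-scale correlation requires positive values")
        known, predicted = np.log(known), np.log(predicted)
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    if np.std(known) == 0 or np.std(predicted) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(known, predicted)
    return float(r), float(r) ** 2, float(p)


def evaluate_predictions(
    species: list[str],
    known: np.ndarray,
    predicted: np.ndarray,
    scale: str = "log",
) -> EvaluationReport:
    """Full per-species error table plus the correlation summary."""
    known = np.asarray(known, float)
    predicted = np.asarray(predicted, float)
    abs_err = np.abs(known - predicted)
    rel_err = 100.0 * abs_err / known
    per_species = pd.DataFrame(
        {
            "species": species,
            "known": known,
            "predicted": predicted,
            "absolute_error": abs_err,
            "relative_error": rel_err,
        }
    )
    r, r2, p = correlation_summary(known, predicted, scale=scale)
    return EvaluationReport(
        pearson_r=r,
        r_squared=r2,
        p_value=p,
        median_absolute_error=float(np.median(abs_err)),
        median_relative_error=float(np.median(rel_err)),
        per_species=per_species,
    )


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher z test for two independent correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal
    p.  Used here to compare train vs test correlations.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 (atanh undefined at 1)")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("both groups need n > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def residual_t_test(
    train_residuals: np.ndarray, test_residuals: np.ndarray
) -> tuple[float, float]:
    """Unpaired two-sample t-test (pooled variance), two-sided."""
    a = np.asarray(train_residuals, float)
    b = np.asarray(test_residuals, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 residuals")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def assembly_variability(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-species mean/sd of predicted years across genome assemblies.

    ``predictions`` needs columns ``species`` and ``predicted``; the sample
    sd quantifies how sensitive the prediction is to which assembly of the
    same species was used.
    """
    grouped = predictions.groupby("species")["predicted"]
    return pd.DataFrame(
        {
            "mean": grouped.mean(),
            "sd": grouped.std(ddof=1).fillna(0.0),
            "n_assemblies": grouped.count(),
        }
    )
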