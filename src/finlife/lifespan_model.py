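"""Bagged, nested-cross-validated elastic net for log lifespan.

The model is a penalized linear regression of natural-log lifespan on
promoter CpG O/E values, minimizing

    (1/2n) * sum_i (y_i - b0 - x_i' b)^2
        + lambda * (alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2)

on standardized features (glmnet parameterization; alpha mixes L1 and L2,
lambda sets the strength).  Training is nested: the data is split 70/30 by
log-lifespan percentile 10 times (outer folds); within each outer training
set a 10-fold inner cross-validation over an alpha grid and a 100-value
lambda path picks alpha (lowest CV error, ties to the smaller alpha) and
lambda.1se (largest lambda within one standard error of the minimum CV
error — a conservative choice that favours stronger shrinkage).  The 10
fold models are bagged: predictions are averaged on the log scale, i.e. the
reported lifespan in years is the geometric mean of the component
predictions.

The coordinate-descent solver behind each fit is scikit-learn's
ElasticNet, whose objective is identical to the one above; path
construction, inner CV, lambda.1se selection, stratified splitting and
bagging are implemented here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet

from .feature_table import FeatureTable

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "ElasticNetComponent",
    "BaggedModel",
    "stratified_split",
    "build_lambda_path",
    "select_lambda_1se",
    "inner_cv_select",
    "fit_component",
    "train_bagged",
    "predict",
    "out_of_fold_predictions",
]

# cubed equal spacing: dense near 0, where ridge-like optima live
DEFAULT_ALPHA_GRID = tuple((i / 10) ** 3 for i in range(11))

_SOLVER_TOL = 1e-7
_SOLVER_MAX_ITER = 100_000
# alpha floor for lambda-path construction only (lambda_max diverges at
# alpha=0); fits still use the actual alpha
_PATH_ALPHA_FLOOR = 1e-3


@dataclass
class ElasticNetComponent:
    """One fitted elastic-net fold model, coefficients on the original scale."""

    alpha: float
    lambda_1se: float
    intercept: float
    coefficients: dict[str, float]  # absent promoter => 0
    feature_means: dict[str, float]
    feature_sds: dict[str, float]
    lambda_path: list[float] = field(default_factory=list)
    train_species: list[str] = field(default_factory=list)
    test_species: list[str] = field(default_factory=list)

    def linear_predict(self, X: np.ndarray, promoter_ids: Sequence[str]) -> np.ndarray:
        beta = np.array([self.coefficients.get(p, 0.0) for p in promoter_ids])
        return self.intercept + X @ beta


@dataclass
class BaggedModel:
    """Aggregate of outer-fold elastic-net components (mean on log scale)."""

    components: list[ElasticNetComponent]
    promoter_ids: list[str]
    aggregation: str = "mean_log"
    seed: int | None = None
    alpha_grid: list[float] = field(default_factory=lambda: list(DEFAULT_ALPHA_GRID))

    def mean_coefficients(self) -> dict[str, float]:
        """Per-promoter mean of component coefficients (absent = 0)."""
        out = {}
        k = len(self.components)
        for pid in self.promoter_ids:
            out[pid] = sum(c.coefficients.get(pid, 0.0) for c in self.components) / k
        return out

    def model_promoters(self) -> list[str]:
        """Promoters with a nonzero coefficient in at least one component."""
        return [
            pid
            for pid in self.promoter_ids
            if any(c.coefficients.get(pid, 0.0) != 0.0 for c in self.components)
        ]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": 1,
            "aggregation": self.aggregation,
            "seed": self.seed,
            "alpha_grid": list(self.alpha_grid),
            "promoter_ids": self.promoter_ids,
            "components": [
                {
                    "alpha": c.alpha,
                    "lambda_1se": c.lambda_1se,
                    "intercept": c.intercept,
                    "coefficients": c.coefficients,
                    "feature_means": c.feature_means,
                    "feature_sds": c.feature_sds,
                    "lambda_path": c.lambda_path,
                    "train_species": c.train_species,
                    "test_species": c.test_species,
                }
                for c in self.components
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "BaggedModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            components=[ElasticNetComponent(**c) for c in payload["components"]],
            promoter_ids=payload["promoter_ids"],
            aggregation=payload["aggregation"],
            seed=payload["seed"],
            alpha_grid=payload["alpha_grid"],
        )


def stratified_split(
    log_lifespan: np.ndarray,
    train_fraction: float = 0.7,
    n_bins: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile-stratified train/test split of a continuous response.

    Values are binned into ``n_bins`` empirical-percentile groups; within
    each bin ``ceil(train_fraction * bin_size)`` indices go to train by a
    seeded shuffle.  Every index lands in exactly one of the two sets, so
    both tails of the lifespan distribution are represented in both sets.
    """
    y = np.asarray(log_lifespan, dtype=float)
    n = len(y)
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if n_bins < 1 or n_bins > n:
        raise ValueError(f"n_bins must be in [1, n={n}]")
    order = np.argsort(y, kind="stable")
    bins = np.array_split(order, n_bins)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for bin_members in bins:
        members = bin_members.copy()
        rng.shuffle(members)
        n_train = int(np.ceil(train_fraction * len(members)))
        train_idx.extend(members[:n_train])
        test_idx.extend(members[n_train:])
    return np.sort(np.array(train_idx, int)), np.sort(np.array(test_idx, int))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale columns; constant columns become all-zero (coef 0)."""
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population sd, glmnet convention
    safe = np.where(sds > 0, sds, 1.0)
    Xs = (X - means) / safe
    return Xs, means, np.where(sds > 0, sds, 0.0)


def build_lambda_path(
    X_std: np.ndarray,
    y_centered: np.ndarray,
    alpha: float,
    n_lambda: int = 100,
) -> np.ndarray:
    """Descending log-spaced lambda path, glmnet style.

    lambda_max is the smallest penalty that zeroes every coefficient at the
    given alpha (alpha floored at 0.001 so the path stays finite for pure
    ridge); lambda_min = lambda_max * 1e-4 when n < p, else * 1e-2.
    """
    n, p = X_std.shape
    a = max(alpha, _PATH_ALPHA_FLOOR)
    lambda_max = np.max(np.abs(X_std.T @ y_centered)) / (n * a)
    if lambda_max <= 0:
        raise ValueError("degenerate design: lambda_max is 0")
    ratio = 1e-4 if n < p else 1e-2
    return np.logspace(np.log10(lambda_max), np.log10(lambda_max * ratio), n_lambda)


def select_lambda_1se(
    lambdas: np.ndarray, mean_cv_error: np.ndarray, se: np.ndarray | float
) -> float:
    """Largest lambda whose mean CV error is within one SE of the minimum.

    ``se`` is the standard error of the fold errors; a scalar is treated as
    the SE at the minimizing lambda, an array is indexed there.
    """
    lambdas = np.asarray(lambdas, float)
    mean_cv_error = np.asarray(mean_cv_error, float)
    i_min = int(np.argmin(mean_cv_error))
    se_at_min = float(np.asarray(se, float).flat[i_min]) if np.ndim(se) else float(se)
    threshold = mean_cv_error[i_min] + se_at_min
    eligible = lambdas[mean_cv_error <= threshold]
    return float(eligible.max())


def _fit_path(
    X_std: np.ndarray, y_centered: np.ndarray, alpha: float, lambdas: np.ndarray
) -> np.ndarray:
    """Coefficients along a descending lambda path via warm-started fits.

    Returns an array of shape (len(lambdas), p) on the standardized scale.
    """
    X_f = np.asfortranarray(X_std, dtype=np.float64)
    y_f = np.ascontiguousarray(y_centered, dtype=np.float64)
    est = ElasticNet(
        alpha=float(lambdas[0]),
        l1_ratio=alpha,
        fit_intercept=False,
        warm_start=True,
        tol=_SOLVER_TOL,
        max_iter=_SOLVER_MAX_ITER,
    )
    coefs = np.empty((len(lambdas), X_std.shape[1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, lam in enumerate(lambdas):
            est.set_params(alpha=float(lam))
            est.fit(X_f, y_f, check_input=False)
            coefs[i] = est.coef_
    return coefs


def inner_cv_select(
    X: np.ndarray,
    y: np.ndarray,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    n_folds: int = 10,
    n_lambda: int = 100,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Pick (alpha, lambda.1se) by k-fold CV over a lambda path per alpha.

    For each alpha the lambda path is built from the full training data;
    fold models are fitted along the path with fold-local standardization
    and scored by mean squared error on the held-out fold.  The winning
    alpha minimizes the minimum mean CV error (ties to the smaller alpha);
    lambda.1se comes from that alpha's CV curve.

    Returns ``(alpha_min, lambda_1se, cv_curve)`` where ``cv_curve`` is the
    winning alpha's per-lambda mean error and SE.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples, got {n}")
    if np.std(y) == 0:
        raise ValueError("degenerate response: zero variance")
    if not alpha_grid:
        raise ValueError("empty alpha grid")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    Xs_full, _, _ = _standardize(X)
    yc_full = y - y.mean()

    best: tuple[float, float, float, pd.DataFrame] | None = None  # (err, alpha, ...)
    for alpha in sorted(alpha_grid):
        lambdas = build_lambda_path(Xs_full, yc_full, alpha, n_lambda)
        fold_err = np.empty((n_folds, n_lambda))
        for f, test_members in enumerate(folds):
            mask = np.ones(n, bool)
            mask[test_members] = False
            X_tr, y_tr = X[mask], y[mask]
            X_te, y_te = X[test_members], y[test_members]
            Xs_tr, means, sds = _standardize(X_tr)
            safe = np.where(sds > 0, sds, 1.0)
            y_mean = y_tr.mean()
            coefs = _fit_path(Xs_tr, y_tr - y_mean, alpha, lambdas)
            Xs_te = (X_te - means) / safe
            preds = y_mean + Xs_te @ coefs.T  # (n_te, n_lambda)
            fold_err[f] = np.mean((preds - y_te[:, None]) ** 2, axis=0)
        mean_err = fold_err.mean(axis=0)
        se_err = fold_err.std(axis=0, ddof=1) / np.sqrt(n_folds)
        min_err = float(mean_err.min())
        curve = pd.DataFrame(
            {"lambda": lambdas, "mean_cv_error": mean_err, "se": se_err}
        )
        # strict < keeps the smaller alpha on ties (grid iterated ascending)
        if best is None or min_err < best[0]:
            best = (min_err, alpha, select_lambda_1se(lambdas, mean_err, se_err), curve)

    _, alpha_min, lambda_1se, cv_curve = best
    return alpha_min, lambda_1se, cv_curve


def fit_component(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambda_1se: float,
    promoter_ids: Sequence[str],
    lambda_path: Sequence[float] | None = None,
) -> ElasticNetComponent:
    """Fit one elastic net at fixed (alpha, lambda) on standardized features.

    Coefficients are mapped back to the original feature scale so that
    ``intercept + x @ beta`` applies directly to raw O/E rows; constant
    features get coefficient 0.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in X or y")
    Xs, means, sds = _standardize(X)
    y_mean = float(y.mean())
    yc = y - y_mean

    path = (
        np.asarray(lambda_path, float)
        if lambda_path is not None
        else np.logspace(
            np.log10(max(lambda_1se * 100, 1e-3)), np.log10(lambda_1se), 20
        )
    )
    path = np.sort(path)[::-1]
    path = path[path >= lambda_1se]
    if len(path) == 0 or path[-1] != lambda_1se:
        path = np.append(path, lambda_1se)
    coefs_std = _fit_path(Xs, yc, alpha, path)[-1]

    safe = np.where(sds > 0, sds, 1.0)
    beta = np.where(sds > 0, coefs_std / safe, 0.0)
    intercept = y_mean - float(np.sum(beta * means))
    return ElasticNetComponent(
        alpha=float(alpha),
        lambda_1se=float(lambda_1se),
        intercept=intercept,
        coefficients={
            pid: float(b) for pid, b in zip(promoter_ids, beta) if b != 0.0
        },
        feature_means={pid: float(m) for pid, m in zip(promoter_ids, means)},
        feature_sds={pid: float(s) for pid, s in zip(promoter_ids, sds)},
        lambda_path=[float(v) for v in path],
    )


def train_bagged(
    features: FeatureTable,
    n_outer: int = 10,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    seed: int = 0,
    train_fraction: float = 0.7,
    n_bins: int = 10,
    n_inner_folds: int = 10,
    n_lambda: int = 100,
    min_species: int = 30,
) -> tuple[BaggedModel, pd.DataFrame]:
    """Train the bagged model: n_outer stratified splits, nested CV each.

    Each outer fold draws its own percentile-stratified 70/30 split (fold
    seed = master seed + fold index, recorded in the model file), runs the
    inner CV on its training set, and fits one component at the selected
    (alpha, lambda.1se).  The per-fold report carries train/test Pearson r,
    R² and residual summaries on the log scale.
    """
    n = features.n_species
    if n < min_species:
        raise ValueError(
            f"need at least {min_species} species for nested CV (got {n}); "
            "reduce n_outer / n_bins for smaller studies"
        )
    X = features.matrix
    logy = features.log_lifespan
    species = np.asarray(features.species_ids)

    components: list[ElasticNetComponent] = []
    report_rows = []
    for fold in range(n_outer):
        fold_seed = seed + fold
        tr, te = stratified_split(logy, train_fraction, n_bins, fold_seed)
        alpha_min, lambda_1se, cv_curve = inner_cv_select(
            X[tr], logy[tr], alpha_grid, n_inner_folds, n_lambda, fold_seed
        )
        Xs_tr, _, _ = _standardize(X[tr])
        path = build_lambda_path(Xs_tr, logy[tr] - logy[tr].mean(), alpha_min, n_lambda)
        comp = fit_component(
            X[tr], logy[tr], alpha_min, lambda_1se, features.promoter_ids, path
        )
        comp.train_species = list(species[tr])
        comp.test_species = list(species[te])
        components.append(comp)

        pred_tr = comp.linear_predict(X[tr], features.promoter_ids)
        pred_te = comp.linear_predict(X[te], features.promoter_ids)
        # fully shrunk components predict a constant; r is undefined (NaN) then
        with np.errstate(invalid="ignore", divide="ignore"):
            r_tr = float(np.corrcoef(logy[tr], pred_tr)[0, 1])
            r_te = float(np.corrcoef(logy[te], pred_te)[0, 1])
        report_rows.append(
            {
                "fold": fold,
                "seed": fold_seed,
                "alpha": alpha_min,
                "lambda_1se": lambda_1se,
                "n_nonzero": len(comp.coefficients),
                "train_r": r_tr,
                "train_r2": r_tr**2,
                "test_r": r_te,
                "test_r2": r_te**2,
                "train_rmse_log": float(np.sqrt(np.mean((logy[tr] - pred_tr) ** 2))),
                "test_rmse_log": float(np.sqrt(np.mean((logy[te] - pred_te) ** 2))),
            }
        )
    model = BaggedModel(
        components=components,
        promoter_ids=list(features.promoter_ids),
        seed=seed,
        alpha_grid=list(alpha_grid),
    )
    return model, pd.DataFrame(report_rows)


def _align_rows(model: BaggedModel, features) -> np.ndarray:
    """Coerce input rows to the model's promoter order.

    DataFrames are reindexed: missing promoters are filled with 0, unknown
    extra columns are rejected.  Arrays must already be aligned.
    """
    if isinstance(features, FeatureTable):
        features = pd.DataFrame(
            features.matrix, index=features.species_ids, columns=features.promoter_ids
        )
    if isinstance(features, pd.DataFrame):
        extra = set(features.columns) - set(model.promoter_ids)
        if extra:
            raise ValueError(f"unknown feature columns: {sorted(extra)[:5]} ...")
        X = features.reindex(columns=model.promoter_ids, fill_value=0.0).to_numpy(float)
    else:
        X = np.atleast_2d(np.asarray(features, float))
        if X.shape[1] != len(model.promoter_ids):
            raise ValueError(
                f"feature rows have {X.shape[1]} columns; model expects "
                f"{len(model.promoter_ids)}"
            )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def predict(model: BaggedModel, features) -> np.ndarray:
    """Bagged lifespan prediction in years (strictly positive).

    Per row: exp( mean over components of (b0 + x'beta) ) — the geometric
    mean in years of the component predictions.
    """
    X = _align_rows(model, features)
    log_preds = np.mean(
        [c.linear_predict(X, model.promoter_ids) for c in model.components], axis=0
    )
    return np.exp(log_preds)


def out_of_fold_predictions(model: BaggedModel, features: FeatureTable) -> pd.Series:
    """Held-out prediction per species: mean over components whose test
    split contained it, exponentiated to years.  Species never held out
    get NaN."""
    X = _align_rows(model, features)
    acc = pd.Series(0.0, index=features.species_ids)
    cnt = pd.Series(0, index=features.species_ids)
    for comp in model.components:
        preds = comp.linear_predict(X, model.promoter_ids)
        for sp, v in zip(features.species_ids, preds):
            if sp in comp.test_species:
                acc[sp] += v
                cnt[sp] += 1
    with np.errstate(invalid="ignore"):
        return np.exp(acc / cnt.replace(0, np.nan))
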